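"""Magnitude-slope estimation and asymmetry tests.

The central model is a random-intercept linear mixed model,

    response_ij = a + b * magnitude_ij + u_i + e_ij,   u_i ~ N(0, s_u^2),

fitted by restricted maximum likelihood (REML) separately per outcome
condition: the fixed slope ``b`` measures how strongly the trial-locked
electrodermal summary (or luck rating) scales with the money at stake.
:class:`MagnitudeSlopeModel` wraps construction from a trial table and
``fit()`` returns a :class:`SlopeFitResults` carrying the fixed-effect
estimate, its uncertainty, and per-participant ordinary-least-squares
slopes used for the within-participant contrasts and across-participant
correlations.

Asymmetries are tested two ways: a paired t test on per-participant slopes
(losses vs. wins, near-losses vs. near-wins), and a Williams/Steiger test
of two dependent correlations sharing a variable (is the selection slope
more tightly correlated with the loss slope than with the win slope?).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MagnitudeSlopeModel",
    "SlopeFitResults",
    "TestResult",
    "CorrelationComparison",
    "fit_magnitude_slope",
    "paired_slope_test",
    "one_sample_t",
    "williams_test",
    "correlate_slope_profiles",
    "compare_dependent_correlations",
    "behavior_summary",
]


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    """A t-type test outcome."""

    statistic: float
    df: float
    p: float
    estimate: float
    kind: str
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "estimate": self.estimate,
            "kind": self.kind,
            "degenerate": self.degenerate,
        }


@dataclass
class CorrelationComparison:
    """Williams/Steiger comparison of r12 vs r13 sharing variable 1."""

    r12: float
    r13: float
    r23: float
    n: int
    t: float
    df: int
    p: float

    def to_dict(self) -> dict:
        return {
            "r12": self.r12,
            "r13": self.r13,
            "r23": self.r23,
            "n": self.n,
            "t": self.t,
            "df": self.df,
            "p": self.p,
        }


class SlopeFitResults:
    """Fitted magnitude slope with uncertainty and per-participant slopes.

    Attributes
    ----------
    b, se, tvalue, pvalue : float
        Fixed-effect slope, its standard error, t statistic and two-sided p.
    df : float
        Degrees of freedom used for the p value (within-participant
        residual df for the mixed fit; a Satterthwaite approximation is not
        available from the REML backend, and the approximation used is
        recorded in ``df_method``).
    intercept : float
        Fixed intercept.
    participant_slopes : pandas.Series
        Per-participant ordinary-least-squares slopes (participants with at
        least two distinct predictor values).
    method : str
        ``"mixed_reml"`` or ``"pooled_ols"`` (fallback when the
        between-participant variance is degenerate).
    """

    def __init__(
        self,
        model: "MagnitudeSlopeModel",
        b: float,
        se: float,
        intercept: float,
        df: float,
        df_method: str,
        method: str,
        participant_slopes: pd.Series,
        random_intercept_var: float,
        residual_var: float,
    ) -> None:
        self.model = model
        self.b = float(b)
        self.se = float(se)
        self.intercept = float(intercept)
        self.df = float(df)
        self.df_method = df_method
        self.method = method
        self.participant_slopes = participant_slopes
        self.random_intercept_var = float(random_intercept_var)
        self.residual_var = float(residual_var)
        self.tvalue = self.b / self.se if self.se > 0 else np.nan
        self.pvalue = float(2.0 * stats.t.sf(abs(self.tvalue), self.df)) if self.se > 0 else np.nan

    @property
    def n_obs(self) -> int:
        return self.model.n_obs

    @property
    def n_participants(self) -> int:
        return self.model.n_participants

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        half = stats.t.ppf(1.0 - alpha / 2.0, self.df) * self.se
        return self.b - half, self.b + half

    def to_dict(self) -> dict:
        return {
            "response": self.model.response_name,
            "predictor": self.model.predictor_name,
            "condition": self.model.condition,
            "b": self.b,
            "se": self.se,
            "t": self.tvalue,
            "df": self.df,
            "p": self.pvalue,
            "intercept": self.intercept,
            "n_obs": self.n_obs,
            "n_participants": self.n_participants,
            "method": self.method,
            "df_method": self.df_method,
        }

    def summary(self) -> str:
        lo, hi = self.conf_int()
        cond = self.model.condition or "all"
        lines = [
            "Magnitude slope fit (random-intercept model, REML)"
            if self.method == "mixed_reml"
            else "Magnitude slope fit (pooled OLS fallback)",
            f"  response:   {self.model.response_name}   predictor: {self.model.predictor_name}"
            f"   condition: {cond}",
            f"  n_obs = {self.n_obs}, n_participants = {self.n_participants}",
            f"  b = {self.b:.4e}  SE = {self.se:.4e}  t = {self.tvalue:.3f}"
            f"  df = {self.df:.0f} ({self.df_method})  p = {self.pvalue:.3g}",
            f"  95% CI [{lo:.4e}, {hi:.4e}]   intercept = {self.intercept:.4f}",
            f"  var(participant) = {self.random_intercept_var:.3e}"
            f"   var(residual) = {self.residual_var:.3e}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of observations with the fitted fixed-effect line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x, y = self.model.predictor, self.model.endog
        ax.plot(x, y, ".", alpha=0.3, label="trials")
        grid = np.linspace(float(np.min(x)), float(np.max(x)), 50)
        ax.plot(grid, self.intercept + self.b * grid, "r-", label=f"b = {self.b:.3g}")
        ax.set_xlabel(self.model.predictor_name)
        ax.set_ylabel(self.model.response_name)
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class MagnitudeSlopeModel:
    """Random-intercept model ``response ~ predictor + (1 | participant)``.

    Build with :meth:`from_dataframe` from a trial table (one row per
    analyzed trial) and call :meth:`fit`.
    """

    def __init__(
        self,
        endog: np.ndarray,
        predictor: np.ndarray,
        groups: np.ndarray,
        response_name: str = "response",
        predictor_name: str = "predictor",
        condition: str | None = None,
    ) -> None:
        self.endog = np.asarray(endog, dtype=float)
        self.predictor = np.asarray(predictor, dtype=float)
        self.groups = np.asarray(groups)
        self.response_name = response_name
        self.predictor_name = predictor_name
        self.condition = condition
        if not (len(self.endog) == len(self.predictor) == len(self.groups)):
            raise ValueError("endog, predictor and groups must have equal length")
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        per_group = pd.Series(self.predictor).groupby(pd.Series(self.groups)).nunique()
        if (per_group < 2).all():
            raise ValueError("no participant has two distinct predictor values")

    @classmethod
    def from_dataframe(
        cls,
        records: pd.DataFrame,
        response: str,
        predictor: str,
        condition: str | None = None,
        group: str = "participant_id",
    ) -> "MagnitudeSlopeModel":
        """Construct from a trial table, applying the analysis filters.

        Keeps rows matching ``condition`` (if given), drops fillers unless
        explicitly requested, and drops missing/unusable rows.
        """
        df = records
        if "included" in df.columns and condition != "filler":
            df = df[df["included"].astype(bool)]
        if "missing" in df.columns:
            df = df[~df["missing"].astype(bool)]
        if condition is not None:
            df = df[df["condition"] == condition]
        df = df.dropna(subset=[response, predictor])
        return cls(
            df[response].to_numpy(dtype=float),
            df[predictor].to_numpy(dtype=float),
            df[group].to_numpy(),
            response_name=response,
            predictor_name=predictor,
            condition=condition,
        )

    @property
    def n_obs(self) -> int:
        return len(self.endog)

    @property
    def n_participants(self) -> int:
        return len(pd.unique(self.groups))

    def _participant_slopes(self) -> pd.Series:
        slopes = {}
        df = pd.DataFrame({"y": self.endog, "x": self.predictor, "g": self.groups})
        for pid, grp in df.groupby("g", sort=True):
            x, y = grp["x"].to_numpy(), grp["y"].to_numpy()
            if len(np.unique(x)) < 2:
                continue
            xc = x - x.mean()
            slopes[pid] = float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))
        return pd.Series(slopes, name="slope")

    def fit(self, reml: bool = True) -> SlopeFitResults:
        """REML random-intercept fit; pooled OLS fallback on a singular fit.

        The between-participant variance can converge to (numerically) zero
        on data with no participant heterogeneity; the fixed-effect
        estimates are then those of pooled OLS, which is used directly and
        flagged in ``method``.
        """
        import statsmodels.api as sm

        exog = np.column_stack([np.ones(self.n_obs), self.predictor])
        slopes = self._participant_slopes()

        singular = False
        result = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                mm = sm.MixedLM(self.endog, exog, groups=self.groups)
                result = mm.fit(reml=reml)
                re_var = float(np.asarray(result.cov_re)[0, 0])
                resid_var = float(result.scale)
                if not np.isfinite(result.bse_fe[1]) or re_var < 1e-12 * max(resid_var, 1e-300):
                    singular = True
            except (np.linalg.LinAlgError, ValueError):
                singular = True

        if singular or result is None:
            ols = sm.OLS(self.endog, exog).fit()
            df = self.n_obs - 2
            return SlopeFitResults(
                self,
                b=ols.params[1],
                se=ols.bse[1],
                intercept=ols.params[0],
                df=df,
                df_method="ols_residual",
                method="pooled_ols",
                participant_slopes=slopes,
                random_intercept_var=0.0,
                residual_var=float(ols.mse_resid),
            )

        # within-participant residual df; conservative t reference for the
        # fixed slope (the REML backend does not provide Satterthwaite df)
        df = max(self.n_obs - self.n_participants - 1, 1)
        return SlopeFitResults(
            self,
            b=result.fe_params[1],
            se=result.bse_fe[1],
            intercept=result.fe_params[0],
            df=df,
            df_method="within_residual",
            method="mixed_reml",
            participant_slopes=slopes,
            random_intercept_var=float(np.asarray(result.cov_re)[0, 0]),
            residual_var=float(result.scale),
        )


def fit_magnitude_slope(
    records: pd.DataFrame,
    response: str,
    predictor: str,
    condition: str | None = None,
    reml: bool = True,
) -> SlopeFitResults:
    """Convenience wrapper: build and fit a :class:`MagnitudeSlopeModel`."""
    return MagnitudeSlopeModel.from_dataframe(records, response, predictor, condition).fit(reml=reml)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def one_sample_t(values, mu0: float = 0.0) -> TestResult:
    """Standard one-sample t test against ``mu0`` (df = n - 1)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("one_sample_t needs at least 2 values")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        t = 0.0 if mean == mu0 else np.inf * np.sign(mean - mu0)
        p = 1.0 if mean == mu0 else 0.0
        return TestResult(t, n - 1, p, mean - mu0, "one_sample_t", degenerate=True)
    t = (mean - mu0) / (sd / np.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return TestResult(float(t), n - 1, p, mean - mu0, "one_sample_t")


def paired_slope_test(slopes_a: pd.Series, slopes_b: pd.Series) -> TestResult:
    """Paired t test on per-participant slope differences (a - b), df = n - 1."""
    a, b = pd.Series(slopes_a), pd.Series(slopes_b)
    if set(a.index) != set(b.index):
        raise ValueError("paired_slope_test requires matching participant sets")
    b = b.reindex(a.index)
    n = len(a)
    if n < 3:
        raise ValueError("paired_slope_test needs at least 3 participants")
    diff = a.to_numpy(dtype=float) - b.to_numpy(dtype=float)
    res = one_sample_t(diff, 0.0)
    return TestResult(res.statistic, res.df, res.p, res.estimate, "paired_t", res.degenerate)


def williams_test(r12: float, r13: float, r23: float, n: int) -> CorrelationComparison:
    """Williams t (Steiger's modification) for two dependent correlations.

    Tests r12 = r13 where variables 2 and 3 are both correlated with the
    shared variable 1 and with each other (r23).  With
    ``|R| = 1 - r12^2 - r13^2 - r23^2 + 2 r12 r13 r23`` and
    ``rbar = (r12 + r13)/2``,

        t = (r12 - r13) * sqrt( (n-1)(1+r23) /
              ( 2 (n-1)/(n-3) |R| + rbar^2 (1-r23)^3 ) ),  df = n - 3.
    """
    n = int(n)
    if n < 4:
        raise ValueError("williams_test requires n >= 4")
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} = {r} must lie strictly inside (-1, 1)")
    detR = 1.0 - r12**2 - r13**2 - r23**2 + 2.0 * r12 * r13 * r23
    if detR < -1e-12:
        raise ValueError(
            f"correlations imply a non-positive-semidefinite matrix (|R| = {detR:.3e})"
        )
    detR = max(detR, 0.0)
    rbar = 0.5 * (r12 + r13)
    denom = 2.0 * ((n - 1) / (n - 3)) * detR + rbar**2 * (1.0 - r23) ** 3
    t = (r12 - r13) * np.sqrt((n - 1) * (1.0 + r23) / denom)
    df = n - 3
    p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationComparison(r12, r13, r23, n, float(t), df, p)


def correlate_slope_profiles(fit_a: SlopeFitResults, fit_b: SlopeFitResults) -> tuple[float, int]:
    """Pearson correlation between two per-participant slope vectors.

    Returns (r, n) over the shared participant set.
    """
    a, b = fit_a.participant_slopes, fit_b.participant_slopes
    shared = a.index.intersection(b.index)
    n = len(shared)
    if n < 4:
        raise ValueError("need at least 4 shared participants to correlate slopes")
    x, y = a.loc[shared].to_numpy(), b.loc[shared].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("slope vector is constant; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1]), n


def compare_dependent_correlations(
    fit_shared: SlopeFitResults, fit_a: SlopeFitResults, fit_b: SlopeFitResults
) -> CorrelationComparison:
    """Williams test of corr(shared, a) vs corr(shared, b) on slope profiles."""
    shared_idx = fit_shared.participant_slopes.index.intersection(
        fit_a.participant_slopes.index
    ).intersection(fit_b.participant_slopes.index)
    s = fit_shared.participant_slopes.loc[shared_idx].to_numpy()
    a = fit_a.participant_slopes.loc[shared_idx].to_numpy()
    b = fit_b.participant_slopes.loc[shared_idx].to_numpy()
    r12 = float(np.corrcoef(s, a)[0, 1])
    r13 = float(np.corrcoef(s, b)[0, 1])
    r23 = float(np.corrcoef(a, b)[0, 1])
    return williams_test(r12, r13, r23, len(shared_idx))


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def behavior_summary(records: pd.DataFrame) -> dict:
    """Betting-behavior statistics with group-level one-sample t tests.

    Per participant: mean bet; mean bet change after wins and after losses
    (bet[t+1] - bet[t] conditioned on trial t's outcome); total monetary
    outcome.  Group tests compare each against zero.  ``records`` needs
    columns participant_id, trial_index, condition, bet_pence,
    outcome_pence.
    """
    per = {"mean_bet": [], "post_win_change": [], "post_loss_change": [], "total_winnings": []}
    for pid, grp in records.groupby("participant_id", sort=True):
        grp = grp.sort_values("trial_index")
        bets = grp["bet_pence"].to_numpy(dtype=float)
        cond = grp["condition"].to_numpy()
        changes = np.diff(bets)
        win_mask = cond[:-1] == "win"
        loss_mask = cond[:-1] == "loss"
        per["mean_bet"].append(float(np.mean(bets)))
        per["post_win_change"].append(float(np.mean(changes[win_mask])) if win_mask.any() else np.nan)
        per["post_loss_change"].append(float(np.mean(changes[loss_mask])) if loss_mask.any() else np.nan)
        per["total_winnings"].append(float(np.sum(grp["outcome_pence"].to_numpy(dtype=float))))

    out: dict = {"per_participant": {k: list(v) for k, v in per.items()}}
    for key in ("mean_bet", "post_win_change", "post_loss_change", "total_winnings"):
        vals = np.asarray(per[key], dtype=float)
        vals = vals[~np.isnan(vals)]
        out[key] = float(np.mean(vals)) if len(vals) else np.nan
        if key != "mean_bet" and len(vals) >= 2 and np.std(vals, ddof=1) > 0:
            out[f"{key}_test"] = one_sample_t(vals, 0.0).to_dict()
        elif key != "mean_bet":
            out[f"{key}_test"] = None
    return out
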