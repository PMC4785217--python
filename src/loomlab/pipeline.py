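"""End-to-end orchestration: simulate -> preprocess -> infer.

:func:`run_experiment` produces, for one synthetic cohort, the full results
set of the analysis: the selection-related slope (electrodermal summary vs.
bet size), the four outcome-related slopes (wins, losses, near-wins,
near-losses vs. magnitude), the two within-participant slope contrasts, the
four selection-outcome slope correlations with two Williams comparisons,
the luck-rating slopes and contrasts, and the betting-behavior summary.

:func:`recovery_study` repeats the experiment over independently seeded
replicate cohorts and aggregates bias, RMSE, confidence-interval coverage
and test rejection rates for every generative slope — the package's own
check that the estimator recovers the data-generating parameters.  Two
calibration studies (:func:`williams_type1_study`,
:func:`paired_test_type1_study`) measure empirical type-I error of the two
asymmetry tests under their respective null models.

Seeding: every source of randomness descends from a single master seed via
``numpy`` SeedSequence-style spawn keys; participant i of replicate r uses
``default_rng([master_seed, tag, r, i])`` so runs are reproducible and
replicate streams never collide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import inference, preprocess, synth
from .schedule import (
    LOSS,
    NEAR_LOSS,
    NEAR_WIN,
    WIN,
    LatencyModel,
    ScheduleConfig,
    build_event_timeline,
    generate_schedule,
)
from .synth import AmplitudeModel, BetPolicy, LuckParams

__all__ = [
    "RunConfig",
    "run_experiment",
    "recovery_study",
    "williams_type1_study",
    "paired_test_type1_study",
    "simulate_participant_records",
    "format_report",
]

_OUTCOME_CONDITIONS = (WIN, LOSS, NEAR_WIN, NEAR_LOSS)


def _paired_on_common(slopes_a, slopes_b):
    """Paired slope contrast restricted to participants with both slopes.

    A participant whose bets never varied within a condition has no defined
    per-participant slope there and drops out of the pair.
    """
    common = slopes_a.index.intersection(slopes_b.index)
    return inference.paired_slope_test(slopes_a.loc[common], slopes_b.loc[common])


def _guarded(fn, *args, **kwargs):
    """Run a statistic, degrading to an error record on degenerate cohorts.

    Tiny cohorts (e.g. 2 participants) cannot support the paired contrasts
    (n >= 3) or the correlation comparisons (n >= 4); the experiment still
    runs, with the affected entries replaced by a diagnostic.
    """
    import warnings

    try:
        out = fn(*args, **kwargs)
        return out.to_dict() if hasattr(out, "to_dict") else out
    except (ValueError, preprocess.PipelineError) as exc:
        warnings.warn(f"{fn.__name__} degenerate: {exc}", stacklevel=2)
        return {"error": str(exc)}


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration of one simulated experiment.

    ``synthesis`` selects the generative route: ``"trace"`` builds
    continuous conductance traces and reduces them through the signal
    pipeline; ``"summary"`` draws the analyzed trial summaries directly
    from the same linear model (used for large replicate studies).
    """

    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    bet_policy: BetPolicy = field(default_factory=BetPolicy)
    amplitude: AmplitudeModel = field(default_factory=AmplitudeModel)
    luck: LuckParams = field(default_factory=LuckParams)
    preprocess: preprocess.PreprocessConfig = field(default_factory=preprocess.PreprocessConfig)
    latency: LatencyModel = field(default_factory=LatencyModel)
    n_participants: int = 50
    master_seed: int = 0
    synthesis: str = "trace"
    sampling_rate: float = 100.0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be at least 2")
        if self.synthesis not in ("trace", "summary"):
            raise ValueError("synthesis must be 'trace' or 'summary'")

    def participant_rng(self, participant_index: int, replicate: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.master_seed, 0, replicate, participant_index])

    def replicate_config(self, replicate: int) -> "RunConfig":
        return replace(self)


def simulate_participant_records(
    config: RunConfig, participant_index: int, replicate: int = 0
) -> pd.DataFrame:
    """Simulate one participant end to end, returning their trial table."""
    rng = config.participant_rng(participant_index, replicate)
    pid = f"p{participant_index:03d}"
    trials = generate_schedule(config.schedule, seed=rng)
    trials = synth.simulate_bets(trials, config.bet_policy, seed=rng, config=config.schedule)
    ratings = synth.simulate_luck_ratings(trials, config.luck, seed=rng)
    trials["luck_rating"] = ratings
    if config.synthesis == "summary":
        participant = config.amplitude.draw_participant(rng)
        rec = synth.simulate_trial_records(
            trials, config.amplitude, luck=None, seed=rng,
            participant_id=pid, participant=participant,
        )
        rec["luck_rating"] = ratings
        return rec
    timeline = build_event_timeline(trials, config.schedule, config.latency, rng=rng)
    trace = synth.synthesize_trace(
        timeline, trials, config.amplitude, seed=rng, sampling_rate=config.sampling_rate
    )
    return preprocess.extract_trial_table(
        trace, trials, timeline, config.preprocess, participant_id=pid, luck_ratings=ratings
    )


def _simulate_cohort(config: RunConfig, replicate: int = 0) -> pd.DataFrame:
    tables = [
        simulate_participant_records(config, i, replicate)
        for i in range(config.n_participants)
    ]
    return pd.concat(tables, ignore_index=True)


def _cohort_fits(records: pd.DataFrame, response: str) -> dict:
    """Per-condition magnitude-slope fits for one response variable."""
    fits = {}
    for cond in _OUTCOME_CONDITIONS:
        fits[cond] = inference.fit_magnitude_slope(
            records, response, "magnitude_pence", condition=cond
        )
    return fits


def run_experiment(config: RunConfig, out_dir=None) -> dict:
    """Run one full cohort and return the results-shaped dictionary.

    Writes ``results.json``, ``report.txt`` and the pooled trial table to
    ``out_dir`` when given.  Fully reproducible from (config, master_seed).
    """
    records = _simulate_cohort(config)
    included, excluded = preprocess.screen_nonresponders(records, config.preprocess)
    records = records[records["participant_id"].isin(included)]

    selection_fit = inference.fit_magnitude_slope(
        records, "selection_eda", "bet_pence", condition=None
    )
    eda_fits = _cohort_fits(records, "outcome_eda")
    luck_fits = _cohort_fits(records, "luck_rating")

    def contrasts(fits):
        return {
            "loss_vs_win": _guarded(
                _paired_on_common,
                fits[LOSS].participant_slopes, fits[WIN].participant_slopes,
            ),
            "near_loss_vs_near_win": _guarded(
                _paired_on_common,
                fits[NEAR_LOSS].participant_slopes, fits[NEAR_WIN].participant_slopes,
            ),
        }

    eda_contrasts = contrasts(eda_fits)
    luck_contrasts = contrasts(luck_fits)

    def correlation(cond):
        out = _guarded(inference.correlate_slope_profiles, selection_fit, eda_fits[cond])
        if isinstance(out, tuple):
            return {"r": out[0], "n": out[1]}
        return out

    correlations = {cond: correlation(cond) for cond in _OUTCOME_CONDITIONS}
    williams = {
        "loss_vs_win": _guarded(
            inference.compare_dependent_correlations,
            selection_fit, eda_fits[LOSS], eda_fits[WIN],
        ),
        "near_loss_vs_near_win": _guarded(
            inference.compare_dependent_correlations,
            selection_fit, eda_fits[NEAR_LOSS], eda_fits[NEAR_WIN],
        ),
    }
    behavior = inference.behavior_summary(records)

    results = {
        "meta": {
            "master_seed": config.master_seed,
            "n_participants_simulated": config.n_participants,
            "n_participants_analyzed": len(included),
            "nonresponders_excluded": list(excluded),
            "synthesis": config.synthesis,
            "n_records": int(len(records)),
            "n_records_analyzed": int(records["included"].sum()),
        },
        "selection_eda": selection_fit.to_dict(),
        "outcome_eda": {c: f.to_dict() for c, f in eda_fits.items()},
        "eda_slope_contrasts": eda_contrasts,
        "selection_outcome_correlations": correlations,
        "williams": williams,
        "luck": {c: f.to_dict() for c, f in luck_fits.items()},
        "luck_slope_contrasts": luck_contrasts,
        "behavior": {k: v for k, v in behavior.items() if k != "per_participant"},
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "results.json", "w") as fh:
            json.dump(results, fh, indent=2)
        preprocess.write_trial_table(records, out_dir / "trial_table.tsv")
        with open(out_dir / "report.txt", "w") as fh:
            fh.write(format_report(results))
    return results


def format_report(results: dict) -> str:
    """Human-readable text report mirroring the analysis structure."""
    def slope_line(d: dict) -> str:
        return (
            f"b = {d['b']:.4e}, SE = {d['se']:.4e}, t = {d['t']:.2f}, "
            f"df = {d['df']:.0f}, p = {d['p']:.3g} ({d['method']})"
        )

    def test_line(d: dict) -> str:
        if d is None or "error" in d:
            return f"unavailable ({d['error'] if d else 'no data'})"
        return f"t = {d['statistic']:.3f}, df = {d['df']:.0f}, p = {d['p']:.3g}"

    r = results
    lines = [
        "loomlab experiment report",
        "=" * 60,
        f"participants analyzed: {r['meta']['n_participants_analyzed']}"
        f" (excluded as nonresponders: {len(r['meta']['nonresponders_excluded'])})",
        "",
        "Behavior",
        f"  mean bet: {r['behavior']['mean_bet']:.1f} p",
        f"  bet change after wins: {r['behavior']['post_win_change']:.2f} p"
        f"  [{test_line(r['behavior']['post_win_change_test'])}]",
        f"  bet change after losses: {r['behavior']['post_loss_change']:.2f} p"
        f"  [{test_line(r['behavior']['post_loss_change_test'])}]",
        f"  total winnings: {r['behavior']['total_winnings'] / 100:.2f} GBP"
        f"  [{test_line(r['behavior']['total_winnings_test'])}]",
        "",
        "Selection-related EDA (summary ~ bet)",
        f"  {slope_line(r['selection_eda'])}",
        "",
        "Outcome-related EDA (summary ~ magnitude)",
    ]
    for cond in _OUTCOME_CONDITIONS:
        lines.append(f"  {cond:10s} {slope_line(r['outcome_eda'][cond])}")
    lines += [
        f"  loss vs win slopes:            {test_line(r['eda_slope_contrasts']['loss_vs_win'])}",
        f"  near-loss vs near-win slopes:  "
        f"{test_line(r['eda_slope_contrasts']['near_loss_vs_near_win'])}",
        "",
        "Selection-outcome slope correlations",
    ]
    for cond in _OUTCOME_CONDITIONS:
        c = r["selection_outcome_correlations"][cond]
        if "error" in c:
            lines.append(f"  selection vs {cond:10s} unavailable ({c['error']})")
        else:
            lines.append(f"  selection vs {cond:10s} r = {c['r']:+.3f} (n = {c['n']})")
    for key, label in (
        ("loss_vs_win", "loss vs win"),
        ("near_loss_vs_near_win", "near-loss vs near-win"),
    ):
        w = r["williams"][key]
        if "error" in w:
            lines.append(f"  Williams {label}: unavailable ({w['error']})")
            continue
        lines.append(
            f"  Williams {label}: t = {w['t']:.3f}, df = {w['df']}, p = {w['p']:.3g}"
            f" (r12 = {w['r12']:.3f}, r13 = {w['r13']:.3f}, r23 = {w['r23']:.3f})"
        )
    lines += ["", "Luck ratings (rating ~ magnitude)"]
    for cond in _OUTCOME_CONDITIONS:
        lines.append(f"  {cond:10s} {slope_line(r['luck'][cond])}")
    lines += [
        f"  loss vs win slopes:            {test_line(r['luck_slope_contrasts']['loss_vs_win'])}",
        f"  near-loss vs near-win slopes:  "
        f"{test_line(r['luck_slope_contrasts']['near_loss_vs_near_win'])}",
        "",
    ]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# replicate studies
# ---------------------------------------------------------------------------

def recovery_study(
    config: RunConfig,
    n_replicates: int = 500,
    alpha: float = 0.05,
) -> dict:
    """Parameter-recovery study over independently seeded replicate cohorts.

    For each replicate, simulates a cohort (summary route unless the config
    says otherwise), fits the five magnitude slopes, and runs the two paired
    slope contrasts.  Aggregates, per slope: generative value, mean
    estimate, bias, relative bias, RMSE and CI coverage; per contrast:
    rejection rate at ``alpha`` and the fraction of replicates with the
    loss-type slope above the win-type slope.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be at least 2")
    amp = config.amplitude
    truth = {
        "selection": amp.selection_slope,
        WIN: amp.win_slope,
        LOSS: amp.loss_slope,
        NEAR_WIN: amp.near_win_slope,
        NEAR_LOSS: amp.near_loss_slope,
    }
    estimates = {k: [] for k in truth}
    covered = {k: [] for k in truth}
    reject = {"loss_vs_win": [], "near_loss_vs_near_win": []}
    ordered = {"loss_vs_win": [], "near_loss_vs_near_win": []}

    for rep in range(n_replicates):
        rep_config = replace(config, master_seed=config.master_seed)
        records = pd.concat(
            [
                simulate_participant_records(rep_config, i, replicate=rep + 1)
                for i in range(config.n_participants)
            ],
            ignore_index=True,
        )
        sel = inference.fit_magnitude_slope(records, "selection_eda", "bet_pence")
        fits = {"selection": sel}
        for cond in _OUTCOME_CONDITIONS:
            fits[cond] = inference.fit_magnitude_slope(
                records, "outcome_eda", "magnitude_pence", condition=cond
            )
        for key, fit in fits.items():
            estimates[key].append(fit.b)
            lo, hi = fit.conf_int(alpha)
            covered[key].append(lo <= truth[key] <= hi)
        for key, (ca, cb) in (
            ("loss_vs_win", (LOSS, WIN)),
            ("near_loss_vs_near_win", (NEAR_LOSS, NEAR_WIN)),
        ):
            test = _paired_on_common(
                fits[ca].participant_slopes, fits[cb].participant_slopes
            )
            reject[key].append(test.p < alpha)
            ordered[key].append(fits[ca].b > fits[cb].b)

    report = {"n_replicates": n_replicates, "parameters": {}, "tests": {}}
    for key, tv in truth.items():
        est = np.asarray(estimates[key], dtype=float)
        bias = float(np.mean(est) - tv)
        report["parameters"][key] = {
            "truth": tv,
            "mean_estimate": float(np.mean(est)),
            "bias": bias,
            "relative_bias": bias / tv if tv != 0 else np.nan,
            "rmse": float(np.sqrt(np.mean((est - tv) ** 2))),
            "ci_coverage": float(np.mean(covered[key])),
        }
    for key in reject:
        report["tests"][key] = {
            "rejection_rate": float(np.mean(reject[key])),
            "ordering_rate": float(np.mean(ordered[key])),
        }
    return report


def williams_type1_study(
    n_reps: int = 5000,
    n: int = 50,
    rho: float = 0.5,
    rho23: float = 0.3,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical type-I error of the Williams test under r12 = r13 = rho.

    Draws ``n_reps`` samples of size ``n`` from a trivariate normal with
    corr(1,2) = corr(1,3) = rho and corr(2,3) = rho23, applies the Williams
    test to the sample correlations, and returns the rejection rate at
    ``alpha`` (with its binomial Monte-Carlo standard error).
    """
    rng = np.random.default_rng([seed, 2])
    cov = np.array([[1.0, rho, rho], [rho, 1.0, rho23], [rho, rho23, 1.0]])
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((n_reps, n, 3)) @ chol.T
    zc = z - z.mean(axis=1, keepdims=True)
    ss = np.sqrt((zc**2).sum(axis=1))
    r12 = (zc[:, :, 0] * zc[:, :, 1]).sum(axis=1) / (ss[:, 0] * ss[:, 1])
    r13 = (zc[:, :, 0] * zc[:, :, 2]).sum(axis=1) / (ss[:, 0] * ss[:, 2])
    r23 = (zc[:, :, 1] * zc[:, :, 2]).sum(axis=1) / (ss[:, 1] * ss[:, 2])

    detR = 1.0 - r12**2 - r13**2 - r23**2 + 2.0 * r12 * r13 * r23
    rbar = 0.5 * (r12 + r13)
    denom = 2.0 * ((n - 1) / (n - 3)) * np.maximum(detR, 0.0) + rbar**2 * (1.0 - r23) ** 3
    t = (r12 - r13) * np.sqrt((n - 1) * (1.0 + r23) / denom)
    p = 2.0 * stats.t.sf(np.abs(t), n - 3)
    rate = float(np.mean(p < alpha))
    return {
        "n_reps": n_reps,
        "n": n,
        "rho": rho,
        "rho23": rho23,
        "rejection_rate": rate,
        "mc_se": float(np.sqrt(alpha * (1 - alpha) / n_reps)),
    }


def paired_test_type1_study(
    config: RunConfig | None = None,
    n_reps: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical type-I error of the paired slope contrast under equal slopes.

    Generates replicate cohorts from the summary-level model with the loss
    slope set equal to the win slope, computes per-participant OLS slopes
    for each condition, and applies the paired t test — all vectorized
    across replicates.  Returns the rejection rate at ``alpha``.
    """
    config = config or RunConfig(synthesis="summary")
    amp = replace(config.amplitude, loss_slope=config.amplitude.win_slope)
    n_part = config.n_participants
    sched = config.schedule
    n_each = min(sched.n_win, sched.n_loss)
    rng = np.random.default_rng([seed, 3])

    grid = np.asarray(sched.bet_levels, dtype=float)
    shape = (n_reps, n_part, n_each)
    # magnitudes: payoff multiplier x a random grid bet, iid across trials
    mag_w = sched.payoff_multiplier * rng.choice(grid, size=shape)
    mag_l = sched.payoff_multiplier * rng.choice(grid, size=shape)
    sd = amp.participant_gain_sd
    gain = (
        rng.lognormal(-0.5 * sd * sd, sd, size=(n_reps, n_part, 1)) if sd > 0 else 1.0
    )
    b_i = rng.normal(0.0, amp.participant_intercept_sd, size=(n_reps, n_part, 1))
    y_w = amp.outcome_intercept + b_i + gain * amp.win_slope * mag_w
    y_w += rng.normal(0.0, amp.trial_noise_sd, size=shape)
    y_l = amp.outcome_intercept + b_i + gain * amp.loss_slope * mag_l
    y_l += rng.normal(0.0, amp.trial_noise_sd, size=shape)

    def ols_slopes(x, y):
        xc = x - x.mean(axis=2, keepdims=True)
        yc = y - y.mean(axis=2, keepdims=True)
        return (xc * yc).sum(axis=2) / (xc**2).sum(axis=2)

    diff = ols_slopes(mag_l, y_l) - ols_slopes(mag_w, y_w)  # (reps, participants)
    mean = diff.mean(axis=1)
    se = diff.std(axis=1, ddof=1) / np.sqrt(n_part)
    t = mean / se
    p = 2.0 * stats.t.sf(np.abs(t), n_part - 1)
    rate = float(np.mean(p < alpha))
    return {
        "n_reps": n_reps,
        "n_participants": n_part,
        "n_trials_per_condition": n_each,
        "rejection_rate": rate,
        "mc_se": float(np.sqrt(alpha * (1 - alpha) / n_reps)),
    }
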