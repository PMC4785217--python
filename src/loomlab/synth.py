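"""Ground-truth-known synthetic behavior and skin-conductance generation.

Three generators live here, all seeded and reproducible:

* a betting agent with asymmetric post-win/post-loss adjustment (the
  "asymmetric gambler's fallacy": bets drop after wins by more than they
  rise after losses), emitting bets on the task's pence grid;
* a luck-rating generator on the 1-9 scale, linear in the obtained or
  counterfactual outcome magnitude;
* a continuous electrodermal trace generator that superposes phasic skin
  conductance responses (SCRs, a bi-exponential kernel) on a slowly
  drifting tonic level, with event amplitudes linear in bet or outcome
  magnitude at condition-specific slopes.

Amplitudes are specified in log10-conductance units and the trace is built
as ``10**(log-tonic + sum of phasic components)``, so that the downstream
log transform makes the ground truth exactly linear in the analyzed space.
A summary-level shortcut (:func:`simulate_trial_records`) draws the
analyzed trial summaries directly from the same linear model, bypassing
trace synthesis, for large replicate studies.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schedule import (
    FILLER,
    LOSS,
    NEAR_LOSS,
    NEAR_WIN,
    WIN,
    ConfigurationError,
    ScheduleConfig,
    compute_outcomes,
)

__all__ = [
    "BetPolicy",
    "LuckParams",
    "AmplitudeModel",
    "EDATrace",
    "simulate_bets",
    "simulate_luck_ratings",
    "scr_kernel",
    "scr_peak_time",
    "kernel_bin_means",
    "summary_attenuation",
    "synthesize_trace",
    "simulate_trial_records",
    "write_trace",
    "read_trace",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# betting agent
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BetPolicy:
    """Asymmetric bet-adjustment policy on the task's pence grid.

    The next bet is the previous bet plus a condition-dependent shift
    (``post_win_shift`` after wins, ``post_loss_shift`` after losses, zero
    after null outcomes) plus Gaussian noise, rounded to the nearest grid
    level and clipped to the grid range.  Defaults reproduce the observed
    mean adjustments of -5.77 p after wins and +3.40 p after losses with
    trial-to-trial spread of about 9 p.
    """

    anchor: float = 50.0
    post_win_shift: float = -5.77
    post_loss_shift: float = 3.40
    shift_sd: float = 9.0
    grid: tuple[float, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90)

    def __post_init__(self) -> None:
        if len(self.grid) == 0:
            raise ConfigurationError("bet grid must be non-empty")
        if self.shift_sd < 0:
            raise ConfigurationError("shift_sd must be non-negative")

    def snap(self, value: float) -> float:
        """Nearest grid level (ties resolve to the lower level)."""
        grid = np.asarray(self.grid, dtype=float)
        return float(grid[np.argmin(np.abs(grid - value))])


def simulate_bets(
    trials: pd.DataFrame,
    policy: BetPolicy,
    seed=None,
    config: ScheduleConfig | None = None,
) -> pd.DataFrame:
    """Run the betting agent over a session and fill bets and outcomes.

    The first bet is the anchor (snapped to the grid); subsequent bets
    follow the policy's post-outcome random walk.  Obtained and
    counterfactual outcomes are recomputed from the simulated bets.
    """
    rng = _as_rng(seed)
    config = config or ScheduleConfig()
    trials = trials.sort_values("trial_index").reset_index(drop=True)
    cond = trials["condition"].to_numpy()
    n = len(trials)
    bets = np.empty(n)
    bet = policy.snap(policy.anchor)
    for t in range(n):
        bets[t] = bet
        if cond[t] == WIN:
            shift = policy.post_win_shift
        elif cond[t] == LOSS:
            shift = policy.post_loss_shift
        else:
            shift = 0.0
        noise = rng.normal(0.0, policy.shift_sd) if policy.shift_sd > 0 else 0.0
        bet = policy.snap(bet + shift + noise)
    trials["bet_pence"] = bets
    return compute_outcomes(trials, config)


# ---------------------------------------------------------------------------
# luck ratings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LuckParams:
    """Linear model for trial-by-trial luck ratings on the 1-9 scale.

    ``rating = clip(round(baseline + slope * magnitude + noise), 1, 9)``,
    where magnitude is the obtained magnitude for wins/losses and the
    counterfactual magnitude for near outcomes (fillers get baseline plus
    noise).  Slope magnitudes default to the reported coefficients
    (2.56e-3, 2.29e-3, 1.34e-3, 1.21e-3 rating units per pence).

    The reported coefficient signs for losses and near-losses conflict with
    the described directions (larger losses felt *unluckier*; near-losses
    felt *luckier*), so the sign coding is explicit: ``sign_convention =
    "prose"`` (default) applies the described directions (win +, loss -,
    near-win -, near-loss +); ``"printed"`` applies the printed signs
    verbatim (win +, loss +, near-win -, near-loss -).
    """

    baseline: float = 5.0
    win_slope: float = 2.56e-3
    loss_slope: float = 2.29e-3
    near_win_slope: float = -1.34e-3
    near_loss_slope: float = -1.21e-3
    noise_sd: float = 1.5
    sign_convention: str = "prose"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.sign_convention not in ("prose", "printed"):
            raise ConfigurationError("sign_convention must be 'prose' or 'printed'")

    def slope_for(self, condition: str) -> float:
        """Effective slope (rating units per pence of magnitude)."""
        if self.sign_convention == "printed":
            table = {
                WIN: self.win_slope,
                LOSS: self.loss_slope,
                NEAR_WIN: self.near_win_slope,
                NEAR_LOSS: self.near_loss_slope,
            }
        else:
            table = {
                WIN: abs(self.win_slope),
                LOSS: -abs(self.loss_slope),
                NEAR_WIN: -abs(self.near_win_slope),
                NEAR_LOSS: abs(self.near_loss_slope),
            }
        return table.get(condition, 0.0)


def trial_magnitudes(trials: pd.DataFrame) -> np.ndarray:
    """Unsigned per-trial magnitude in pence.

    Obtained |outcome| for wins/losses, counterfactual magnitude for near
    outcomes, zero for fillers.
    """
    cond = trials["condition"].to_numpy()
    obtained = np.abs(trials["outcome_pence"].to_numpy(dtype=float))
    counterfactual = trials["counterfactual_pence"].to_numpy(dtype=float)
    return np.where(np.isin(cond, (NEAR_WIN, NEAR_LOSS)), counterfactual, obtained)


def simulate_luck_ratings(
    trials: pd.DataFrame, params: LuckParams, seed=None
) -> np.ndarray:
    """Integer luck ratings in [1, 9], one per trial."""
    rng = _as_rng(seed)
    cond = trials["condition"].to_numpy()
    mag = trial_magnitudes(trials)
    slopes = np.array([params.slope_for(c) for c in cond])
    noise = rng.normal(0.0, params.noise_sd, size=len(trials)) if params.noise_sd > 0 else 0.0
    raw = params.baseline + slopes * mag + noise
    return np.clip(np.round(raw), 1, 9).astype(int)


# ---------------------------------------------------------------------------
# SCR kernel
# ---------------------------------------------------------------------------

def scr_kernel(t, rise: float = 0.75, decay: float = 4.0) -> np.ndarray:
    """Unit-peak bi-exponential SCR shape, ``h(t) = c (e^{-t/decay} - e^{-t/rise})``.

    ``h(0) = 0``, the maximum over t >= 0 equals 1, and h is zero for t < 0.
    ``rise`` must be strictly smaller than ``decay``.
    """
    if rise <= 0 or decay <= 0 or rise >= decay:
        raise ValueError("scr_kernel requires 0 < rise < decay")
    t = np.asarray(t, dtype=float)
    tp = scr_peak_time(rise, decay)
    peak = math.exp(-tp / decay) - math.exp(-tp / rise)
    out = (np.exp(-t / decay) - np.exp(-t / rise)) / peak
    return np.where(t < 0, 0.0, out)


def scr_peak_time(rise: float, decay: float) -> float:
    """Closed-form argmax of the bi-exponential kernel."""
    return (math.log(decay) - math.log(rise)) / (1.0 / rise - 1.0 / decay)


def kernel_bin_means(
    rise: float,
    decay: float,
    latency: float,
    bin_width: float = 2.0,
    n_bins: int = 4,
) -> np.ndarray:
    """Exact mean of the unit-peak kernel over each post-onset analysis bin.

    Bin k covers [ (k-1) w, k w ) seconds after the *event* onset; the
    kernel starts ``latency`` seconds later.  The mean over a bin has a
    closed form from integrating the two exponentials.
    """
    tp = scr_peak_time(rise, decay)
    peak = math.exp(-tp / decay) - math.exp(-tp / rise)

    def integral(a: float, b: float) -> float:
        # integral of unit-peak kernel from a to b (kernel time)
        a = max(a, 0.0)
        if b <= a:
            return 0.0
        term = lambda tau: tau * (math.exp(-a / tau) - math.exp(-b / tau))
        return (term(decay) - term(rise)) / peak

    means = np.empty(n_bins)
    for k in range(n_bins):
        lo = k * bin_width - latency
        hi = (k + 1) * bin_width - latency
        means[k] = integral(lo, hi) / bin_width
    return means


def summary_attenuation(
    rise: float = 0.75,
    decay: float = 4.0,
    latency: float = 1.0,
    bin_width: float = 2.0,
    n_bins: int = 4,
    summary_bins: tuple[int, ...] = (2, 3, 4),
) -> float:
    """Max bin-mean of the unit-peak kernel over the summary bins.

    This is the factor by which the binned max-change summary attenuates a
    unit-peak SCR; the trace generator divides event amplitudes by it so
    that nominal amplitudes are recovered on the summary scale.
    """
    means = kernel_bin_means(rise, decay, latency, bin_width, n_bins)
    return float(max(means[k - 1] for k in summary_bins))


# ---------------------------------------------------------------------------
# trace synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmplitudeModel:
    """Generative model for event-locked SCR amplitudes (log10 uS units).

    Choice-onset events have amplitude ``selection_intercept + b_i +
    g_i * selection_slope * bet``; outcome-onset events have amplitude
    ``outcome_intercept + b_i + g_i * condition_slope * magnitude`` with the
    counterfactual magnitude on near trials.  ``b_i`` is a participant
    random intercept and ``g_i`` a participant gain factor (log-normal,
    mean 1) shared across phases, which induces the across-participant
    correlation between selection- and outcome-related slopes.  Slope
    defaults are the reported fixed-effect coefficients.  Amplitude noise is
    Gaussian with SD ``trial_noise_sd``; trace-mode amplitudes are floored
    at zero.
    """

    selection_slope: float = 6.30e-4
    win_slope: float = 2.625e-5
    loss_slope: float = 8.35e-5
    near_win_slope: float = 6.34e-5
    near_loss_slope: float = 7.23e-5
    selection_intercept: float = 0.10
    outcome_intercept: float = 0.15
    participant_intercept_sd: float = 0.05
    participant_gain_sd: float = 0.8
    trial_noise_sd: float = 0.08
    tonic_level: float = 0.3
    tonic_level_sd: float = 0.15
    drift_amplitude: float = 0.05
    drift_period: float = 120.0
    measurement_noise_sd: float = 0.005
    scr_rise: float = 0.75
    scr_decay: float = 4.0
    scr_latency: float = 1.0
    calibrate_summary: bool = True

    def __post_init__(self) -> None:
        for name in (
            "participant_intercept_sd",
            "participant_gain_sd",
            "trial_noise_sd",
            "tonic_level_sd",
            "measurement_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not 0 < self.scr_rise < self.scr_decay:
            raise ConfigurationError("requires 0 < scr_rise < scr_decay")

    def outcome_slope_for(self, condition: str) -> float:
        return {
            WIN: self.win_slope,
            LOSS: self.loss_slope,
            NEAR_WIN: self.near_win_slope,
            NEAR_LOSS: self.near_loss_slope,
            FILLER: 0.0,
        }[condition]

    def draw_participant(self, rng: np.random.Generator) -> dict:
        """Participant-level latent variables (tonic level, intercept, gain)."""
        sd = self.participant_gain_sd
        gain = float(rng.lognormal(-0.5 * sd * sd, sd)) if sd > 0 else 1.0
        return {
            "tonic": float(rng.normal(self.tonic_level, self.tonic_level_sd)),
            "intercept": float(rng.normal(0.0, self.participant_intercept_sd)),
            "gain": gain,
            "drift_phase": float(rng.uniform(0.0, 2.0 * math.pi)),
        }


@dataclass
class EDATrace:
    """A sampled continuous skin-conductance signal.

    ``values`` are conductance in microsiemens (all positive);
    ``sampling_rate`` in Hz; ``t0`` is the session time of the first sample.
    """

    sampling_rate: float
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.values) / self.sampling_rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.sampling_rate


def _event_amplitudes(
    trials: pd.DataFrame,
    amp: AmplitudeModel,
    participant: dict,
    rng: np.random.Generator,
    floor: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """(selection, outcome) nominal amplitudes per trial, log10 uS summary units."""
    bet = trials["bet_pence"].to_numpy(dtype=float)
    mag = trial_magnitudes(trials)
    slopes = np.array([amp.outcome_slope_for(c) for c in trials["condition"]])
    g, b_i = participant["gain"], participant["intercept"]
    n = len(trials)
    noise_sel = rng.normal(0.0, amp.trial_noise_sd, n) if amp.trial_noise_sd > 0 else 0.0
    noise_out = rng.normal(0.0, amp.trial_noise_sd, n) if amp.trial_noise_sd > 0 else 0.0
    a_sel = amp.selection_intercept + b_i + g * amp.selection_slope * bet + noise_sel
    a_out = amp.outcome_intercept + b_i + g * slopes * mag + noise_out
    if floor:
        a_sel = np.maximum(a_sel, 0.0)
        a_out = np.maximum(a_out, 0.0)
    return a_sel, a_out


def synthesize_trace(
    timeline: pd.DataFrame,
    trials: pd.DataFrame,
    amp: AmplitudeModel,
    seed=None,
    sampling_rate: float = 100.0,
    participant: dict | None = None,
) -> EDATrace:
    """Build a continuous conductance trace for one session.

    The log10 trace is tonic level + slow sinusoidal drift + white
    measurement noise + the superposition of SCR kernels at every choice and
    outcome onset (fixed event-to-response latency).  When
    ``amp.calibrate_summary`` is set, the kernel is scaled so the binned
    max-change summary of an isolated event equals its nominal amplitude.
    The returned values are ``10**logtrace`` microsiemens, strictly positive.
    """
    rng = _as_rng(seed)
    participant = participant or amp.draw_participant(rng)
    duration = float(timeline["iti_end"].iloc[-1]) + 1.0
    n_samples = int(round(duration * sampling_rate))
    t = np.arange(n_samples) / sampling_rate

    log_trace = np.full(n_samples, participant["tonic"])
    if amp.drift_amplitude > 0:
        log_trace += amp.drift_amplitude * np.sin(
            2.0 * math.pi * t / amp.drift_period + participant["drift_phase"]
        )
    if amp.measurement_noise_sd > 0:
        log_trace += rng.normal(0.0, amp.measurement_noise_sd, n_samples)

    scale = 1.0
    if amp.calibrate_summary:
        scale = 1.0 / summary_attenuation(amp.scr_rise, amp.scr_decay, amp.scr_latency)

    a_sel, a_out = _event_amplitudes(trials, amp, participant, rng, floor=True)
    onsets_sel = timeline["choice_onset"].to_numpy(dtype=float)
    onsets_out = timeline["outcome_onset"].to_numpy(dtype=float)
    support = int(round((amp.scr_latency + 12.0 * amp.scr_decay) * sampling_rate))
    for onsets, amps in ((onsets_sel, a_sel), (onsets_out, a_out)):
        for onset, a in zip(onsets, amps):
            if a == 0.0:
                continue
            i0 = int(math.ceil((onset + amp.scr_latency) * sampling_rate))
            i1 = min(i0 + support, n_samples)
            if i0 >= n_samples:
                continue
            tau = t[i0:i1] - onset - amp.scr_latency
            log_trace[i0:i1] += a * scale * scr_kernel(tau, amp.scr_rise, amp.scr_decay)

    return EDATrace(sampling_rate=sampling_rate, values=10.0 ** log_trace, t0=0.0)


# ---------------------------------------------------------------------------
# summary-level shortcut
# ---------------------------------------------------------------------------

def simulate_trial_records(
    trials: pd.DataFrame,
    amp: AmplitudeModel,
    luck: LuckParams | None = None,
    seed=None,
    participant_id: str = "p000",
    participant: dict | None = None,
) -> pd.DataFrame:
    """Draw analyzed trial summaries directly from the generative linear model.

    Produces the same table as trace synthesis followed by preprocessing,
    but on the summary scale: ``selection_eda`` and ``outcome_eda`` are
    intercept + participant effect + gain x slope x magnitude + noise (no
    flooring; summaries are signed).  Used for large replicate studies.
    """
    rng = _as_rng(seed)
    participant = participant or amp.draw_participant(rng)
    sel, out = _event_amplitudes(trials, amp, participant, rng, floor=False)
    ratings = (
        simulate_luck_ratings(trials, luck, rng)
        if luck is not None
        else trials.get("luck_rating", pd.Series(np.full(len(trials), 5))).to_numpy()
    )
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "trial_index": trials["trial_index"].to_numpy(),
            "condition": trials["condition"].to_numpy(),
            "bet_pence": trials["bet_pence"].to_numpy(dtype=float),
            "outcome_pence": trials["outcome_pence"].to_numpy(dtype=float),
            "magnitude_pence": trial_magnitudes(trials),
            "selection_eda": sel,
            "outcome_eda": out,
            "baseline_selection": 0.0,
            "baseline_outcome": 0.0,
            "luck_rating": ratings,
            "included": trials["condition"].to_numpy() != FILLER,
            "missing": False,
        }
    )


# ---------------------------------------------------------------------------
# trace IO
# ---------------------------------------------------------------------------

def write_trace(trace: EDATrace, path, participant_id: str, seed=None) -> None:
    """Write a trace as gzipped TSV (time_s, conductance_uS) + JSON sidecar."""
    path = str(path)
    with gzip.open(path, "wt") as fh:
        fh.write("time_s\tconductance_uS\n")
        for t, v in zip(trace.times(), trace.values):
            fh.write(f"{t:.4f}\t{v:.8f}\n")
    sidecar = {
        "sampling_rate_hz": trace.sampling_rate,
        "t0_s": trace.t0,
        "participant_id": participant_id,
        "seed": seed,
        "units": "microsiemens",
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_trace(path) -> tuple[EDATrace, dict]:
    """Read a gzipped trace TSV and its JSON sidecar."""
    path = str(path)
    df = pd.read_csv(path, sep="\t", compression="gzip")
    with open(_sidecar_path(path)) as fh:
        sidecar = json.load(fh)
    trace = EDATrace(
        sampling_rate=float(sidecar["sampling_rate_hz"]),
        values=df["conductance_uS"].to_numpy(),
        t0=float(sidecar.get("t0_s", 0.0)),
    )
    return trace, sidecar


def _sidecar_path(path: str) -> str:
    for suffix in (".tsv.gz", ".gz", ".tsv"):
        if path.endswith(suffix):
            return path[: -len(suffix)] + ".json"
    return path + ".json"
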