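"""Electrodermal signal reduction to a trial-level analysis table.

Pipeline: resample the raw conductance signal to the analysis rate (100 Hz),
log10-transform it (conductance distributions are positively skewed), take
the mean over the last 2 s of each trial's preceding intertrial interval as
a trial-by-trial baseline (controlling slow tonic drift), average the signal
in four 2-s bins from the choice onset and from the outcome onset, and
summarize each phase as the maximum signed change of bins 2-4 relative to
the baseline (the first bin is discarded because skin conductance responses
lag their eliciting event).  Participants whose outcome summaries show
essentially no variation across trials are screened out as nonresponders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .schedule import FILLER
from .synth import EDATrace, trial_magnitudes

__all__ = [
    "PreprocessConfig",
    "PipelineError",
    "resample_trace",
    "log_transform",
    "baseline_value",
    "phase_summary",
    "extract_trial_table",
    "screen_nonresponders",
    "write_trial_table",
    "read_trial_table",
]

TRIAL_RECORD_COLUMNS = [
    "participant_id",
    "trial_index",
    "condition",
    "bet_pence",
    "outcome_pence",
    "magnitude_pence",
    "selection_eda",
    "outcome_eda",
    "baseline_selection",
    "baseline_outcome",
    "luck_rating",
    "included",
    "missing",
]


class PipelineError(RuntimeError):
    """Raised when a preprocessing stage cannot produce a usable output."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Signal-reduction parameters.

    target_rate
        analysis sampling rate in Hz after decimation.
    log_floor
        conductance floor (uS) applied before the log10 transform; well
        below physiological range, it only guards against zeros.
    baseline_window
        seconds of intertrial interval, counted back from ITI end, averaged
        into the trial baseline.
    n_bins, bin_width
        number and width (s) of post-onset averaging bins.
    summary_bins
        1-based bins entering the max-change summary (default 2-4, i.e.
        2-8 s post onset).
    nonresponder_min_sd
        minimum across-trial SD of the outcome summary (log units) for a
        participant to count as an electrodermal responder.
    """

    target_rate: float = 100.0
    log_floor: float = 1e-3
    baseline_window: float = 2.0
    n_bins: int = 4
    bin_width: float = 2.0
    summary_bins: tuple[int, ...] = (2, 3, 4)
    nonresponder_min_sd: float = 1e-4

    def __post_init__(self) -> None:
        if self.target_rate <= 0 or self.baseline_window <= 0 or self.bin_width <= 0:
            raise ValueError("rates and durations must be positive")
        if self.n_bins < 1:
            raise ValueError("n_bins must be at least 1")
        if not self.summary_bins or not set(self.summary_bins) <= set(range(1, self.n_bins + 1)):
            raise ValueError("summary_bins must be a non-empty subset of 1..n_bins")

    @property
    def window_length(self) -> float:
        """Seconds of post-onset signal required per phase."""
        return self.n_bins * self.bin_width


def resample_trace(trace: EDATrace, target_rate: float) -> EDATrace:
    """Anti-alias filtered decimation to ``target_rate``.

    The source rate must be an integer multiple of the target.  Uses a
    polyphase FIR filter with linear-extension padding, which preserves DC
    exactly and the physiological passband to well under a percent.
    """
    ratio = trace.sampling_rate / target_rate
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError(
            f"sampling rate {trace.sampling_rate} is not an integer multiple of {target_rate}"
        )
    q = int(round(ratio))
    if q == 1:
        return EDATrace(target_rate, trace.values.copy(), trace.t0)
    values = resample_poly(trace.values, 1, q, padtype="line")
    return EDATrace(target_rate, values, trace.t0)


def log_transform(values: np.ndarray, log_floor: float = 1e-3) -> np.ndarray:
    """Elementwise log10 of the floored conductance values."""
    return np.log10(np.maximum(np.asarray(values, dtype=float), log_floor))


def _window_slice(n: int, rate: float, t0: float, start: float, stop: float) -> slice:
    """Sample slice covering session times [start, stop)."""
    i0 = int(np.ceil((start - t0) * rate - 1e-9))
    i1 = int(np.ceil((stop - t0) * rate - 1e-9))
    if i0 < 0 or i1 > n:
        raise PipelineError(
            f"window [{start}, {stop}) s falls outside the recorded trace"
        )
    return slice(i0, i1)


def baseline_value(
    log_values: np.ndarray,
    rate: float,
    iti_end: float,
    baseline_window: float = 2.0,
    t0: float = 0.0,
) -> float:
    """Mean log conductance over the last ``baseline_window`` s before ``iti_end``."""
    sl = _window_slice(len(log_values), rate, t0, iti_end - baseline_window, iti_end)
    if sl.stop <= sl.start:
        raise PipelineError("baseline window contains no samples")
    return float(np.mean(log_values[sl]))


def phase_summary(
    log_values: np.ndarray,
    rate: float,
    onset: float,
    baseline: float,
    config: PreprocessConfig,
    t0: float = 0.0,
) -> float:
    """Max signed change of the summary bins relative to baseline.

    Bin k (1-based) averages the log signal over
    [onset + (k-1) w, onset + k w); the summary is the maximum of
    (bin mean - baseline) over ``config.summary_bins``.  Raises
    :class:`PipelineError` if the window is truncated.
    """
    w = config.bin_width
    bin_means = np.empty(config.n_bins)
    for k in range(config.n_bins):
        sl = _window_slice(len(log_values), rate, t0, onset + k * w, onset + (k + 1) * w)
        if sl.stop <= sl.start:
            raise PipelineError("empty analysis bin")
        bin_means[k] = np.mean(log_values[sl])
    return float(max(bin_means[k - 1] for k in config.summary_bins) - baseline)


def extract_trial_table(
    trace: EDATrace,
    trials: pd.DataFrame,
    timeline: pd.DataFrame,
    config: PreprocessConfig | None = None,
    participant_id: str = "p000",
    luck_ratings=None,
) -> pd.DataFrame:
    """One analyzed record per trial for a single participant.

    Resamples and log-transforms the trace, then computes the choice-locked
    and outcome-locked max-change summaries against each trial's own
    preceding-ITI baseline.  The first trial, which has no preceding ITI,
    uses the tail of the pre-task rest recording instead.  Trials whose
    analysis windows are not fully recorded are flagged ``missing`` rather
    than dropped.  Fillers are flagged ``included = False`` (excluded from
    inference but retained in the table).
    """
    config = config or PreprocessConfig()
    trace = resample_trace(trace, config.target_rate)
    log_values = log_transform(trace.values, config.log_floor)
    rate, t0 = trace.sampling_rate, trace.t0

    trials = trials.sort_values("trial_index").reset_index(drop=True)
    timeline = timeline.sort_values("trial_index").reset_index(drop=True)
    if luck_ratings is None:
        luck_ratings = trials.get("luck_rating", pd.Series(np.full(len(trials), np.nan)))
    luck_ratings = np.asarray(luck_ratings)

    magnitudes = trial_magnitudes(trials)
    records = []
    prev_iti_end = None
    for i in range(len(trials)):
        tr, tl = trials.iloc[i], timeline.iloc[i]
        # first trial: tail of the pre-task rest serves as the ITI surrogate
        baseline_anchor = prev_iti_end if prev_iti_end is not None else float(tl["choice_onset"])
        missing = False
        try:
            baseline = baseline_value(log_values, rate, baseline_anchor, config.baseline_window, t0)
            sel = phase_summary(log_values, rate, float(tl["choice_onset"]), baseline, config, t0)
            out = phase_summary(log_values, rate, float(tl["outcome_onset"]), baseline, config, t0)
        except PipelineError:
            baseline, sel, out, missing = np.nan, np.nan, np.nan, True
        records.append(
            {
                "participant_id": participant_id,
                "trial_index": int(tr["trial_index"]),
                "condition": tr["condition"],
                "bet_pence": float(tr["bet_pence"]),
                "outcome_pence": float(tr["outcome_pence"]),
                "magnitude_pence": float(magnitudes[i]),
                "selection_eda": sel,
                "outcome_eda": out,
                "baseline_selection": baseline,
                "baseline_outcome": baseline,
                "luck_rating": luck_ratings[i],
                "included": tr["condition"] != FILLER,
                "missing": missing,
            }
        )
        prev_iti_end = float(tl["iti_end"])
    return pd.DataFrame(records, columns=TRIAL_RECORD_COLUMNS)


def screen_nonresponders(
    records: pd.DataFrame, config: PreprocessConfig | None = None
) -> tuple[list, list]:
    """Split participants into (included, excluded) by outcome-summary variation.

    A participant whose across-trial SD of the outcome summary falls below
    ``nonresponder_min_sd`` shows no usable phasic reactivity and is
    excluded.  Raises :class:`PipelineError` if nobody survives.
    """
    config = config or PreprocessConfig()
    included, excluded = [], []
    for pid, grp in records.groupby("participant_id", sort=True):
        vals = grp.loc[~grp["missing"], "outcome_eda"].to_numpy(dtype=float)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        (excluded if sd < config.nonresponder_min_sd else included).append(pid)
    if not included:
        raise PipelineError(
            f"all {len(excluded)} participants screened out as nonresponders "
            f"(min SD criterion {config.nonresponder_min_sd})"
        )
    return included, excluded


def write_trial_table(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_trial_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
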