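"""Wheel-of-fortune session structure.

The task is a computerized wheel divided into four 90-degree segments: a gain
segment and a loss segment (opposite each other) separated by two null
segments.  On each trial the player stakes a bet on a 9-level pence grid; a
spinner decelerates over a jittered anticipation interval and stops either
inside the gain segment (win, +multiplier x bet), inside the loss segment
(loss, -multiplier x bet), just beside one of those segments (near-win /
near-loss: objectively null but a narrowly missed outcome), or near the
middle of a null segment (filler).  This module generates the trial
conditions, the stop-angle geometry, and the per-trial event timeline
(choice -> spin -> outcome -> luck rating -> intertrial interval), and reads
and writes the session as a BIDS-style ``events.tsv``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "WIN",
    "LOSS",
    "NEAR_WIN",
    "NEAR_LOSS",
    "FILLER",
    "CONDITIONS",
    "ScheduleConfig",
    "LatencyModel",
    "generate_schedule",
    "assign_outcome_geometry",
    "compute_outcomes",
    "build_event_timeline",
    "write_events_tsv",
    "read_events_tsv",
]

WIN = "win"
LOSS = "loss"
NEAR_WIN = "near_win"
NEAR_LOSS = "near_loss"
FILLER = "filler"
CONDITIONS = (WIN, LOSS, NEAR_WIN, NEAR_LOSS, FILLER)

#: auditory feedback accompanying each outcome class
SOUND_FOR_CONDITION = {
    WIN: "applause",
    LOSS: "boo",
    NEAR_WIN: "thud",
    NEAR_LOSS: "thud",
    FILLER: "thud",
}

# Fixed wheel geometry (degrees): gain and loss segments opposite each other,
# separated by two null segments.  Segment boundaries sit at multiples of 90.
WIN_SEGMENT = (0.0, 90.0)
NULL_SEGMENT_A = (90.0, 180.0)
LOSS_SEGMENT = (180.0, 270.0)
NULL_SEGMENT_B = (270.0, 360.0)
_BOUNDARIES = np.array([0.0, 90.0, 180.0, 270.0, 360.0])

_EVENT_COLUMNS = [
    "onset",
    "duration",
    "trial_index",
    "phase",
    "condition",
    "bet_pence",
    "outcome_pence",
    "counterfactual_pence",
    "angular_offset_deg",
    "sound",
]


class ConfigurationError(ValueError):
    """Raised for an internally inconsistent session configuration."""


@dataclass(frozen=True)
class ScheduleConfig:
    """Session design parameters.

    Defaults reproduce the 76-trial session: 19 wins, 19 losses, 10
    near-wins, 10 near-losses and 18 fillers; bets on a 10-90 pence grid
    anchored at 50 p with a x10 payoff; near outcomes within 1.8 degrees of
    the relevant segment boundary; a 5.3-6.9 s anticipation spin; a 1 s
    outcome phase followed by a 1 s numeric display; a 10 s intertrial
    interval; and a 300 s pre-task rest recording.
    """

    n_win: int = 19
    n_loss: int = 19
    n_near_win: int = 10
    n_near_loss: int = 10
    n_filler: int = 18
    payoff_multiplier: float = 10.0
    bet_levels: tuple[float, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90)
    bet_anchor: float = 50.0
    near_offset_max: float = 1.8
    filler_center_margin: float = 20.0
    anticipation_range: tuple[float, float] = (5.3, 6.9)
    outcome_duration: float = 1.0
    numeric_display_duration: float = 1.0
    iti_duration: float = 10.0
    rest_duration: float = 300.0
    seed: int | None = None

    def __post_init__(self) -> None:
        counts = (self.n_win, self.n_loss, self.n_near_win, self.n_near_loss, self.n_filler)
        if any(c < 0 for c in counts):
            raise ConfigurationError("trial counts must be non-negative")
        if self.n_trials <= 0:
            raise ConfigurationError("total trial count must be positive")
        if self.payoff_multiplier <= 0:
            raise ConfigurationError("payoff_multiplier must be positive")
        if self.near_offset_max <= 0:
            raise ConfigurationError("near_offset_max must be positive")
        levels = np.asarray(self.bet_levels, dtype=float)
        if levels.size == 0 or np.any(levels <= 0) or np.any(np.diff(levels) <= 0):
            raise ConfigurationError("bet_levels must be strictly increasing and positive")
        lo, hi = self.anticipation_range
        if not lo < hi:
            raise ConfigurationError("anticipation_range lower bound must be below upper bound")
        for name in ("outcome_duration", "numeric_display_duration", "iti_duration"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.filler_center_margin <= self.near_offset_max:
            raise ConfigurationError("filler_center_margin must exceed near_offset_max")

    @property
    def n_trials(self) -> int:
        return self.n_win + self.n_loss + self.n_near_win + self.n_near_loss + self.n_filler

    def with_seed(self, seed: int) -> "ScheduleConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class LatencyModel:
    """Log-normal response-latency model for the self-paced phases.

    Means and SDs default to typical values for bet selection
    (2.91 s, SD 2.0) and luck rating (2.44 s, SD 1.75); draws are floored at
    ``floor`` seconds.
    """

    choice_mean: float = 2.91
    choice_sd: float = 2.0
    rating_mean: float = 2.44
    rating_sd: float = 1.75
    floor: float = 0.2

    @staticmethod
    def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
        sigma2 = math.log1p((sd / mean) ** 2)
        mu = math.log(mean) - sigma2 / 2.0
        return mu, math.sqrt(sigma2)

    def _draw(self, rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
        if mean <= 0:
            return np.full(n, self.floor)
        if sd == 0:
            return np.maximum(np.full(n, float(mean)), self.floor)
        mu, sigma = self._lognormal_params(mean, sd)
        return np.maximum(rng.lognormal(mu, sigma, size=n), self.floor)

    def draw_choice(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self._draw(rng, self.choice_mean, self.choice_sd, n)

    def draw_rating(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self._draw(rng, self.rating_mean, self.rating_sd, n)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _offset_from_nearest_boundary(stop_angle: np.ndarray) -> np.ndarray:
    """Angular distance (deg) from the nearest segment boundary."""
    stop = np.mod(np.asarray(stop_angle, dtype=float), 360.0)
    return np.min(np.abs(stop[:, None] - _BOUNDARIES[None, :]), axis=1)


def assign_outcome_geometry(
    trials: pd.DataFrame, config: ScheduleConfig, rng
) -> pd.DataFrame:
    """Draw a spinner stop angle for every trial, consistent with its condition.

    Win/loss stops fall in the interior of their segment (offset from both
    boundaries greater than ``near_offset_max``); near-win/near-loss stops
    fall inside a null segment within ``near_offset_max`` degrees of the
    win/loss boundary; filler stops stay at least ``filler_center_margin``
    degrees from any boundary, near the middle of a null segment.
    """
    rng = _as_rng(rng)
    trials = trials.copy()
    n = len(trials)
    stop = np.empty(n)
    cond = trials["condition"].to_numpy()

    for i in range(n):
        c = cond[i]
        # uniform in (0, 1]: guarantees a strictly positive near offset
        u = 1.0 - rng.random()
        side = rng.integers(2)
        if c == WIN:
            lo, hi = WIN_SEGMENT
            stop[i] = rng.uniform(lo + config.near_offset_max, hi - config.near_offset_max)
        elif c == LOSS:
            lo, hi = LOSS_SEGMENT
            stop[i] = rng.uniform(lo + config.near_offset_max, hi - config.near_offset_max)
        elif c == NEAR_WIN:
            off = u * config.near_offset_max
            # null segment beside the win segment, either side
            stop[i] = WIN_SEGMENT[1] + off if side else WIN_SEGMENT[0] - off
        elif c == NEAR_LOSS:
            off = u * config.near_offset_max
            stop[i] = LOSS_SEGMENT[0] - off if side else LOSS_SEGMENT[1] + off
        elif c == FILLER:
            seg = NULL_SEGMENT_A if side else NULL_SEGMENT_B
            m = config.filler_center_margin
            stop[i] = rng.uniform(seg[0] + m, seg[1] - m)
        else:  # pragma: no cover - guarded upstream
            raise ConfigurationError(f"unknown condition {c!r}")

    trials["stop_angle_deg"] = np.mod(stop, 360.0)
    trials["angular_offset_deg"] = _offset_from_nearest_boundary(trials["stop_angle_deg"].to_numpy())
    return trials


def compute_outcomes(trials: pd.DataFrame, config: ScheduleConfig) -> pd.DataFrame:
    """Fill obtained and counterfactual outcomes from bets and conditions.

    Wins pay +multiplier x bet, losses -multiplier x bet; near-wins,
    near-losses and fillers are objectively null, with the near conditions
    carrying a counterfactual magnitude of multiplier x bet (the outcome
    narrowly missed).
    """
    trials = trials.copy()
    bet = trials["bet_pence"].to_numpy(dtype=float)
    cond = trials["condition"].to_numpy()
    m = config.payoff_multiplier
    outcome = np.where(cond == WIN, m * bet, np.where(cond == LOSS, -m * bet, 0.0))
    counterfactual = np.where(np.isin(cond, (NEAR_WIN, NEAR_LOSS)), m * bet, 0.0)
    trials["outcome_pence"] = outcome
    trials["counterfactual_pence"] = counterfactual
    return trials


def generate_schedule(config: ScheduleConfig, seed=None) -> pd.DataFrame:
    """Generate a randomized session: one row per trial.

    Conditions appear in a fully shuffled order with exactly the configured
    counts.  Bets are initialised to the anchor (a betting agent may
    overwrite them; see :func:`loomlab.synth.simulate_bets`), and outcomes
    are derived from the bets.  ``seed`` overrides ``config.seed``.
    """
    rng = _as_rng(config.seed if seed is None else seed)
    conditions = (
        [WIN] * config.n_win
        + [LOSS] * config.n_loss
        + [NEAR_WIN] * config.n_near_win
        + [NEAR_LOSS] * config.n_near_loss
        + [FILLER] * config.n_filler
    )
    order = rng.permutation(len(conditions))
    trials = pd.DataFrame(
        {
            "trial_index": np.arange(len(conditions)),
            "condition": np.asarray(conditions, dtype=object)[order],
        }
    )
    trials["bet_pence"] = float(config.bet_anchor)
    trials = assign_outcome_geometry(trials, config, rng)
    trials = compute_outcomes(trials, config)
    trials["sound"] = trials["condition"].map(SOUND_FOR_CONDITION)
    return trials


def build_event_timeline(
    trials: pd.DataFrame,
    config: ScheduleConfig,
    latency_model: LatencyModel | None = None,
    rng=None,
) -> pd.DataFrame:
    """Compute per-trial event onsets for the session.

    Each trial runs choice -> spin (anticipation, uniform on the configured
    interval) -> outcome (outcome + numeric display) -> luck rating ->
    intertrial interval; the next trial starts at the previous trial's ITI
    end.  The session opens with the pre-task rest period, so the first
    choice onset equals ``config.rest_duration``.
    """
    latency_model = latency_model or LatencyModel()
    rng = _as_rng(rng)
    n = len(trials)
    choice_lat = latency_model.draw_choice(rng, n)
    anticipation = rng.uniform(*config.anticipation_range, size=n)
    rating_lat = latency_model.draw_rating(rng, n)

    trial_dur = (
        choice_lat
        + anticipation
        + config.outcome_duration
        + config.numeric_display_duration
        + rating_lat
        + config.iti_duration
    )
    choice_onset = config.rest_duration + np.concatenate(([0.0], np.cumsum(trial_dur[:-1])))
    spin_onset = choice_onset + choice_lat
    outcome_onset = spin_onset + anticipation
    rating_onset = outcome_onset + config.outcome_duration + config.numeric_display_duration
    iti_start = rating_onset + rating_lat
    iti_end = iti_start + config.iti_duration

    return pd.DataFrame(
        {
            "trial_index": trials["trial_index"].to_numpy(),
            "choice_onset": choice_onset,
            "spin_onset": spin_onset,
            "outcome_onset": outcome_onset,
            "rating_onset": rating_onset,
            "iti_start": iti_start,
            "iti_end": iti_end,
            "anticipation_duration": anticipation,
        }
    )


def write_events_tsv(trials: pd.DataFrame, timeline: pd.DataFrame, path) -> None:
    """Write the session as a BIDS-style long-format events table.

    One row per trial phase (choice, spin, outcome, rating, iti) with onset
    and duration in seconds; trial attributes are repeated on every phase
    row.  Numeric columns are written with fixed precision so identical
    sessions serialize byte-identically.
    """
    merged = trials.merge(timeline, on="trial_index")
    phase_bounds = {
        "choice": ("choice_onset", "spin_onset"),
        "spin": ("spin_onset", "outcome_onset"),
        "outcome": ("outcome_onset", "rating_onset"),
        "rating": ("rating_onset", "iti_start"),
        "iti": ("iti_start", "iti_end"),
    }
    rows = []
    for _, tr in merged.iterrows():
        for phase, (a, b) in phase_bounds.items():
            rows.append(
                {
                    "onset": tr[a],
                    "duration": tr[b] - tr[a],
                    "trial_index": int(tr["trial_index"]),
                    "phase": phase,
                    "condition": tr["condition"],
                    "bet_pence": tr["bet_pence"],
                    "outcome_pence": tr["outcome_pence"],
                    "counterfactual_pence": tr["counterfactual_pence"],
                    "angular_offset_deg": tr["angular_offset_deg"],
                    "sound": tr["sound"],
                }
            )
    events = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    events.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events_tsv(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read an events table back into (trials, timeline) frames."""
    events = pd.read_csv(path, sep="\t")
    wide = events.pivot(index="trial_index", columns="phase", values="onset")
    dur = events.pivot(index="trial_index", columns="phase", values="duration")
    timeline = pd.DataFrame(
        {
            "trial_index": wide.index.to_numpy(),
            "choice_onset": wide["choice"].to_numpy(),
            "spin_onset": wide["spin"].to_numpy(),
            "outcome_onset": wide["outcome"].to_numpy(),
            "rating_onset": wide["rating"].to_numpy(),
            "iti_start": wide["iti"].to_numpy(),
            "iti_end": (wide["iti"] + dur["iti"]).to_numpy(),
            "anticipation_duration": dur["spin"].to_numpy(),
        }
    ).reset_index(drop=True)
    first = events[events["phase"] == "choice"].sort_values("trial_index")
    trial_cols = [
        "trial_index",
        "condition",
        "bet_pence",
        "outcome_pence",
        "counterfactual_pence",
        "angular_offset_deg",
        "sound",
    ]
    trials = first[trial_cols].reset_index(drop=True)
    return trials, timeline
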