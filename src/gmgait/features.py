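"""Gait-phase segmentation, envelope features, and TD-referenced norm distances.

The gait cycle is split into ten (partly overlapping) phases: the whole
stride, stance, swing, and the seven Perry subphases — loading response
(LR), mid stance (MSt), terminal stance (TSt), pre-swing (PSw), initial
swing (ISw), mid swing (MSw), terminal swing (TSw).  The subphases tile
0-100 % of the cycle without overlap; PSw ends and ISw begins at the
subject's foot-off.  From each phase window six statistics of the envelope
are taken (max, min, their temporal positions, range = max - min, mean),
giving a 60-entry feature vector per subject-side.

Patient features are standardized against the typically-developed (TD)
cohort as a *norm distance*: the absolute deviation from the TD mean in
units of the TD standard deviation,

    ND_i = |F_pi - mean_TD(F_i)| / SD_TD(F_i).

A norm distance of 0 means "at the TD mean"; 2 means "two TD standard
deviations away" on either side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ENVELOPE_COLUMNS, GRID_PCT, N_GRID, EmgEnvelope, envelope_values
from .errors import InsufficientDataError, PhaseDegeneracyError, SchemaError

logger = logging.getLogger(__name__)

# Perry subphases in cycle order with their canonical bounds (percent of
# gait cycle); PSw/ISw boundaries are replaced by the subject's foot-off.
SUBPHASES = ["LR", "MSt", "TSt", "PSw", "ISw", "MSw", "TSw"]
_CANONICAL = {"LR": (0.0, 10.0), "MSt": (10.0, 30.0), "TSt": (30.0, 50.0),
              "PSw": (50.0, None), "ISw": (None, 73.0), "MSw": (73.0, 87.0),
              "TSw": (87.0, 100.0)}

PHASE_ORDER = ["stride", "stance", "swing"] + SUBPHASES
STAT_ORDER = ["max", "min", "tmax", "tmin", "range", "mean"]
FEATURE_NAMES = [f"{ph}_{st}" for ph in PHASE_ORDER for st in STAT_ORDER]


@dataclass(frozen=True)
class GaitPhase:
    """A named window of the gait cycle, half-open unless ``closed_end``."""

    name: str
    start_pct: float
    end_pct: float
    closed_end: bool = False

    def sample_indices(self) -> np.ndarray:
        """Grid indices (= integer percents) falling inside the window."""
        if self.closed_end:
            mask = (GRID_PCT >= self.start_pct) & (GRID_PCT <= self.end_pct)
        else:
            mask = (GRID_PCT >= self.start_pct) & (GRID_PCT < self.end_pct)
        return np.nonzero(mask)[0]


def phase_windows(foot_off_pct: float) -> list[GaitPhase]:
    """Build the ten phase windows for one subject.

    Stance runs [0, foot_off), swing [foot_off, 100]; PSw ends and ISw
    starts at foot-off.  Raises :class:`PhaseDegeneracyError` if any
    window contains no grid sample (e.g. foot-off at or below 50 %
    empties PSw; at or above 73 % it empties ISw).
    """
    if not 0.0 < foot_off_pct < 100.0:
        raise PhaseDegeneracyError(f"foot_off_pct {foot_off_pct} outside (0, 100)")
    phases = [
        GaitPhase("stride", 0.0, 100.0, closed_end=True),
        GaitPhase("stance", 0.0, foot_off_pct),
        GaitPhase("swing", foot_off_pct, 100.0, closed_end=True),
    ]
    for name in SUBPHASES:
        lo, hi = _CANONICAL[name]
        lo = foot_off_pct if lo is None else lo
        hi = foot_off_pct if hi is None else hi
        phases.append(GaitPhase(name, lo, hi, closed_end=(name == "TSw")))
    for ph in phases:
        if ph.start_pct >= ph.end_pct or ph.sample_indices().size == 0:
            raise PhaseDegeneracyError(
                f"phase {ph.name} is empty for foot_off_pct={foot_off_pct}"
            )
    return phases


def _phase_stats(values: np.ndarray, phase: GaitPhase) -> dict[str, float]:
    idx = phase.sample_indices()
    win = values[idx]
    i_max = int(np.argmax(win))  # first extremal sample wins ties
    i_min = int(np.argmin(win))
    vmax, vmin = float(win[i_max]), float(win[i_min])
    return {
        "max": vmax,
        "min": vmin,
        "tmax": float(GRID_PCT[idx[i_max]]),
        "tmin": float(GRID_PCT[idx[i_min]]),
        "range": vmax - vmin,
        "mean": float(win.mean()),
    }


def extract_features(envelope: EmgEnvelope, phases: list[GaitPhase] | None = None) -> pd.Series:
    """Extract the 60 named features from one envelope.

    Temporal positions (tmax/tmin) are expressed in percent of the gait
    cycle, ties broken by the earliest grid index.
    """
    if phases is None:
        phases = phase_windows(envelope.foot_off_pct)
    vals: dict[str, float] = {}
    for ph in phases:
        stats = _phase_stats(envelope.values, ph)
        for st in STAT_ORDER:
            vals[f"{ph.name}_{st}"] = stats[st]
    return pd.Series(vals, index=FEATURE_NAMES, dtype=float)


def extract_feature_matrix(frame: pd.DataFrame) -> pd.DataFrame:
    """Feature vectors for every row of a wide cohort frame.

    Rows sharing a foot-off percentage share phase windows, so the
    extraction is vectorized per foot-off group.
    """
    values = envelope_values(frame)
    out = np.empty((len(frame), len(FEATURE_NAMES)))
    fo = frame["foot_off_pct"].to_numpy(dtype=float)
    for fo_val in np.unique(fo):
        rows = np.nonzero(fo == fo_val)[0]
        block = values[rows]
        col = 0
        for ph in phase_windows(fo_val):
            idx = ph.sample_indices()
            win = block[:, idx]
            i_max = np.argmax(win, axis=1)
            i_min = np.argmin(win, axis=1)
            vmax = win[np.arange(len(rows)), i_max]
            vmin = win[np.arange(len(rows)), i_min]
            out[rows, col + 0] = vmax
            out[rows, col + 1] = vmin
            out[rows, col + 2] = GRID_PCT[idx[i_max]]
            out[rows, col + 3] = GRID_PCT[idx[i_min]]
            out[rows, col + 4] = vmax - vmin
            out[rows, col + 5] = win.mean(axis=1)
            col += 6
    return pd.DataFrame(out, columns=FEATURE_NAMES, index=frame["subject_id"].to_numpy())


@dataclass
class TDReference:
    """Per-feature mean and SD of the typically-developed cohort."""

    f_bar: pd.Series
    sd: pd.Series
    n_td: int
    flagged: list[str] = field(default_factory=list)


@dataclass
class NormalizedFeatureMatrix:
    """Subjects x features matrix of norm distances (unitless, >= 0)."""

    nd: pd.DataFrame

    @property
    def feature_names(self) -> list[str]:
        return list(self.nd.columns)

    @property
    def subject_ids(self) -> list:
        return list(self.nd.index)


def build_td_reference(td_features: pd.DataFrame) -> TDReference:
    """Per-feature sample mean and SD (n-1 denominator) over TD subjects.

    Features with zero TD variance are flagged: the norm distance is
    undefined for them and they are dropped downstream.
    """
    if len(td_features) < 2:
        raise InsufficientDataError("TD reference needs at least 2 subjects")
    f_bar = td_features.mean(axis=0)
    sd = td_features.std(axis=0, ddof=1)
    flagged = list(sd.index[sd <= 0.0])
    if flagged:
        logger.warning("TD reference: %d zero-variance features flagged: %s",
                       len(flagged), flagged[:8])
    return TDReference(f_bar=f_bar, sd=sd, n_td=len(td_features), flagged=flagged)


def normalize_features(cohort: pd.DataFrame, ref: TDReference) -> NormalizedFeatureMatrix:
    """Norm distances |F - mean_TD| / SD_TD for every subject and feature."""
    if list(cohort.columns) != list(ref.f_bar.index):
        raise SchemaError("cohort feature names do not match the TD reference")
    keep = [c for c in cohort.columns if c not in set(ref.flagged)]
    nd = (cohort[keep] - ref.f_bar[keep]).abs() / ref.sd[keep]
    return NormalizedFeatureMatrix(nd=nd)
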