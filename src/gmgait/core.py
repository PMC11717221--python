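"""Shared containers for gait-cycle EMG envelopes.

An envelope is one subject-side gluteus medius activation curve over a
single gait cycle, sampled on the conventional 101-point grid (0, 1, ...,
100 % of the cycle) and amplitude-normalized so that its mean is 100
(percent-of-mean units).  Cohorts are carried as wide pandas DataFrames
with one row per subject-side and columns ``t000`` ... ``t100`` plus
identifying metadata, the same dialect the CSV interfaces use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateSignalError

N_GRID = 101
GRID_PCT = np.arange(N_GRID, dtype=float)
ENVELOPE_COLUMNS = [f"t{i:03d}" for i in range(N_GRID)]
META_COLUMNS = ["subject_id", "side", "group_true", "foot_off_pct"]

MEAN_RTOL = 1e-6  # relative tolerance on the mean-100 invariant


@dataclass
class EmgEnvelope:
    """One subject-side gait-cycle envelope in percent-of-mean units."""

    values: np.ndarray
    foot_off_pct: float = 60.0
    subject_id: str = ""
    side: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def validate(self) -> "EmgEnvelope":
        """Check the envelope invariants; return self for chaining."""
        if self.values.shape != (N_GRID,):
            raise ValueError(f"envelope must have {N_GRID} samples, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("envelope contains non-finite samples")
        if np.any(self.values < 0):
            raise ValueError("envelope contains negative samples")
        m = float(self.values.mean())
        if abs(m - 100.0) > 100.0 * MEAN_RTOL:
            raise DegenerateSignalError(f"envelope mean is {m!r}, expected 100")
        if not 0.0 < self.foot_off_pct < 100.0:
            raise ValueError(f"foot_off_pct {self.foot_off_pct} outside (0, 100)")
        return self


def envelopes_to_frame(envelopes: list[EmgEnvelope]) -> pd.DataFrame:
    """Stack envelopes into the wide cohort DataFrame dialect."""
    rows = []
    for env in envelopes:
        row = {
            "subject_id": env.subject_id,
            "side": env.side,
            "group_true": env.group,
            "foot_off_pct": env.foot_off_pct,
        }
        row.update(dict(zip(ENVELOPE_COLUMNS, env.values)))
        rows.append(row)
    return pd.DataFrame(rows, columns=META_COLUMNS + ENVELOPE_COLUMNS)


def frame_to_envelopes(frame: pd.DataFrame) -> list[EmgEnvelope]:
    """Inverse of :func:`envelopes_to_frame`."""
    out = []
    for _, row in frame.iterrows():
        out.append(
            EmgEnvelope(
                values=row[ENVELOPE_COLUMNS].to_numpy(dtype=float),
                foot_off_pct=float(row["foot_off_pct"]),
                subject_id=str(row["subject_id"]),
                side=str(row.get("side", "")),
                group=str(row.get("group_true", "")),
            )
        )
    return out


def envelope_values(frame: pd.DataFrame) -> np.ndarray:
    """Return the (n_subjects, 101) sample block of a cohort frame."""
    return frame[ENVELOPE_COLUMNS].to_numpy(dtype=float)
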