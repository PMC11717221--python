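"""Seeded synthetic cohorts of gluteus medius EMG envelopes and outcomes.

The clinical database behind the published cluster statistics is not
redistributable, so this module generates cohorts with the same printed
statistical structure: three cerebral-palsy envelope archetypes (low /
medium / high loading-response activity) plus a typically-developed (TD)
archetype, each defined by per-subphase envelope means and between-subject
SDs and by hip clinical-exam scalars; and paired pre/post-treatment (E1/E2)
outcome tables with a responder (SUB_1) / non-responder (SUB_2) structure.

An envelope is synthesized by drawing one target activation level per
Perry subphase from the archetype's Normal, fitting a shape-preserving
periodic cubic (PCHIP) through the subphase midpoints whose knots are then
iteratively adjusted so the within-subphase sample averages match the
drawn targets, clipping at zero, and amplitude-normalizing to mean 100.
Because the archetypes' duration-weighted activation averages sit slightly
below 100, the final normalization inflates all subphase levels by a
common factor of roughly 1-3 %; this is the only systematic deviation of
cohort subphase means from their targets.

All randomness flows through ``numpy.random.Generator`` streams derived
from explicit integer seeds; identical seeds reproduce cohorts
bit-for-bit.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import PchipInterpolator

from .core import ENVELOPE_COLUMNS, GRID_PCT, N_GRID, EmgEnvelope, envelopes_to_frame
from .errors import InvalidSpecError, MissingSeedError
from .features import SUBPHASES, phase_windows

# Continuous subphase widths (percent of cycle) at the canonical foot-off
# of 60 %: LR 10, MSt 20, TSt 20, PSw 10, ISw 13, MSw 14, TSw 13.
_SUBPHASE_WIDTH = {"LR": 10.0, "MSt": 20.0, "TSt": 20.0, "PSw": 10.0,
                   "ISw": 13.0, "MSw": 14.0, "TSw": 13.0}
_KNOT_MID = np.array([5.0, 20.0, 40.0, 55.0, 66.5, 80.0, 93.5])

SYNTH_FOOT_OFF = 60.0  # per-subject foot-off is not modelled

CLIN_COLUMNS = ["rom_hip_abd_90", "rom_hip_abd_0", "strength_90", "strength_0"]
OUTCOME_PARAMS = ["rom_trunk_obl", "rom_pelvic_obl",
                  "max_hip_abd_mst", "max_hip_abd_moment_mst"]
EMG_COLUMNS = ["emg_mean", "emg_min", "emg_max"]


@dataclass(frozen=True)
class ArchetypeSpec:
    """Envelope + clinical-exam distribution of one cohort archetype."""

    name: str
    phase_mean: dict[str, float]
    phase_sd: dict[str, float]
    clin_mean: dict[str, float] = field(default_factory=dict)
    clin_sd: dict[str, float] = field(default_factory=dict)

    def validate(self) -> "ArchetypeSpec":
        for d in (self.phase_mean, self.phase_sd):
            if sorted(d) != sorted(SUBPHASES):
                raise InvalidSpecError(
                    f"{self.name}: phase maps must cover exactly {SUBPHASES}"
                )
        if any(sd < 0 for sd in self.phase_sd.values()):
            raise InvalidSpecError(f"{self.name}: negative phase SD")
        if any(sd < 0 for sd in self.clin_sd.values()):
            raise InvalidSpecError(f"{self.name}: negative clinical SD")
        w = np.array([_SUBPHASE_WIDTH[p] for p in SUBPHASES]) / 100.0
        m = np.array([self.phase_mean[p] for p in SUBPHASES])
        wavg = float(w @ m)
        if not 90.0 <= wavg <= 110.0:
            raise InvalidSpecError(
                f"{self.name}: duration-weighted activation {wavg:.1f} outside "
                "[90, 110]; inconsistent with amplitude normalization to 100"
            )
        return self

    def mean_vector(self) -> np.ndarray:
        return np.array([self.phase_mean[p] for p in SUBPHASES])

    def sd_vector(self) -> np.ndarray:
        return np.array([self.phase_sd[p] for p in SUBPHASES])


@dataclass(frozen=True)
class OutcomeSpec:
    """Paired-examination outcome distribution of one responder group."""

    group: str
    e1_mean: dict[str, float]
    e1_sd: dict[str, float]
    e2_mean: dict[str, float]
    e2_sd: dict[str, float]
    emg_e1_mean: dict[str, float]
    emg_e1_sd: dict[str, float]
    emg_e2_mean: dict[str, float]
    emg_e2_sd: dict[str, float]
    exam_mean: dict[str, float] = field(default_factory=dict)
    exam_sd: dict[str, float] = field(default_factory=dict)

    def validate(self) -> "OutcomeSpec":
        for d, cols in ((self.e1_mean, OUTCOME_PARAMS), (self.e2_mean, OUTCOME_PARAMS),
                        (self.emg_e1_mean, EMG_COLUMNS), (self.emg_e2_mean, EMG_COLUMNS)):
            if sorted(d) != sorted(cols):
                raise InvalidSpecError(f"{self.group}: outcome maps must cover {cols}")
        for d in (self.e1_sd, self.e2_sd, self.emg_e1_sd, self.emg_e2_sd, self.exam_sd):
            if any(sd < 0 for sd in d.values()):
                raise InvalidSpecError(f"{self.group}: negative SD")
        for d in (self.e1_mean, self.e2_mean):
            if not all(np.isfinite(list(d.values()))):
                raise InvalidSpecError(f"{self.group}: non-finite kinematic mean")
        return self


@dataclass
class SyntheticCohort:
    """Envelopes, true archetype labels and clinical scalars of one draw."""

    envelopes: pd.DataFrame
    clinical: pd.DataFrame
    true_cluster: pd.Series
    seed: int

    def __len__(self) -> int:
        return len(self.envelopes)


def _load_defaults() -> dict:
    ref = importlib.resources.files("gmgait") / "data" / "archetypes.yaml"
    return yaml.safe_load(ref.read_text())


def load_default_archetypes() -> dict[str, ArchetypeSpec]:
    """Archetype defaults shipped with the package (versioned YAML)."""
    raw = _load_defaults()["archetypes"]
    return {name: ArchetypeSpec(name=name, **entry).validate()
            for name, entry in raw.items()}


def load_default_outcomes() -> dict[str, OutcomeSpec]:
    """Responder / non-responder outcome defaults (versioned YAML)."""
    raw = _load_defaults()["outcomes"]
    return {name: OutcomeSpec(group=name, **entry).validate()
            for name, entry in raw.items()}


def _fit_envelope_block(targets: np.ndarray, n_iter: int = 12) -> np.ndarray:
    """Periodic PCHIP envelopes whose subphase averages match ``targets``.

    ``targets`` is (n_subjects, 7) in subphase order.  Knot values at the
    subphase midpoints are adjusted by damped fixed-point iteration until
    the within-window sample averages reproduce the targets, then each
    curve is clipped at zero and scaled to mean 100.
    """
    targets = np.clip(np.asarray(targets, dtype=float), 0.0, None)
    windows = [ph.sample_indices() for ph in phase_windows(SYNTH_FOOT_OFF)
               if ph.name in SUBPHASES]
    # periodic extension of the midpoint knots keeps the PCHIP slope
    # estimates cyclic over [0, 100]
    x = np.concatenate([_KNOT_MID - 100.0, _KNOT_MID, _KNOT_MID + 100.0])
    knots = targets.copy()
    for _ in range(n_iter):
        y = np.concatenate([knots, knots, knots], axis=1)
        curve = PchipInterpolator(x, y, axis=1)(GRID_PCT)
        achieved = np.stack([curve[:, w].mean(axis=1) for w in windows], axis=1)
        knots = np.clip(knots + (targets - achieved), 0.0, None)
    y = np.concatenate([knots, knots, knots], axis=1)
    curve = np.clip(PchipInterpolator(x, y, axis=1)(GRID_PCT), 0.0, None)
    return curve * (100.0 / curve.mean(axis=1, keepdims=True))


def _draw_envelope_block(spec: ArchetypeSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    targets = rng.normal(spec.mean_vector(), spec.sd_vector(), size=(n, len(SUBPHASES)))
    return _fit_envelope_block(targets)


def generate_envelope(spec: ArchetypeSpec, rng: np.random.Generator) -> EmgEnvelope:
    """Draw one synthetic envelope from an archetype.

    With all phase SDs zero and all phase means 100 the result is the
    constant envelope 100 (the normalization fixed point).
    """
    if rng is None:
        raise MissingSeedError("generate_envelope requires a seeded Generator")
    spec.validate()
    values = _draw_envelope_block(spec, 1, rng)[0]
    return EmgEnvelope(values=values, foot_off_pct=SYNTH_FOOT_OFF, group=spec.name)


def generate_cohort(mixture: dict[str, int], seed: int,
                    archetypes: dict[str, ArchetypeSpec] | None = None) -> SyntheticCohort:
    """Generate a labelled cohort from an archetype -> count mixture.

    Clinical scalars are drawn as truncated Normals: RoM clipped at 0,
    MRC strength clipped to [0, 5] and kept continuous.  Deterministic
    under ``seed``; subjects appear in mixture insertion order.
    """
    if not mixture:
        raise InvalidSpecError("empty mixture")
    if any(n < 1 for n in mixture.values()):
        raise InvalidSpecError("mixture counts must be >= 1")
    if archetypes is None:
        archetypes = load_default_archetypes()
    rng = np.random.default_rng(seed)
    env_rows, clin_rows, labels, ids = [], [], [], []
    for name, n in mixture.items():
        spec = archetypes[name].validate()
        block = _draw_envelope_block(spec, n, rng)
        mu = np.array([spec.clin_mean[c] for c in CLIN_COLUMNS])
        sd = np.array([spec.clin_sd[c] for c in CLIN_COLUMNS])
        clin = rng.normal(mu, sd, size=(n, len(CLIN_COLUMNS)))
        clin[:, :2] = np.clip(clin[:, :2], 0.0, None)       # RoM >= 0
        clin[:, 2:] = np.clip(clin[:, 2:], 0.0, 5.0)        # MRC in [0, 5]
        for i in range(n):
            sid = f"{name}_{i:04d}"
            ids.append(sid)
            labels.append(name)
            env_rows.append(EmgEnvelope(values=block[i], foot_off_pct=SYNTH_FOOT_OFF,
                                        subject_id=sid, side="R", group=name))
            clin_rows.append(dict(zip(CLIN_COLUMNS, clin[i])))
    clinical = pd.DataFrame(clin_rows)
    clinical.insert(0, "subject_id", ids)
    clinical.insert(1, "group_true", labels)
    return SyntheticCohort(
        envelopes=envelopes_to_frame(env_rows),
        clinical=clinical,
        true_cluster=pd.Series(labels, index=ids, name="group_true"),
        seed=seed,
    )


def generate_paired_outcomes(n1: int, n2: int, spec1: OutcomeSpec, spec2: OutcomeSpec,
                             seed: int) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Paired E1/E2 outcome tables for two responder groups.

    Every column is drawn independently from the group's stated Normal at
    the corresponding examination.  The E1 table additionally carries the
    four physical-exam scalars (pre-treatment only).  Returns
    ``(e1, e2, true_labels)``.
    """
    if n1 < 2 or n2 < 2:
        raise InvalidSpecError("each outcome group needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    e1_rows, e2_rows, labels, ids = [], [], [], []
    for spec, n in ((spec1.validate(), n1), (spec2.validate(), n2)):
        def vec(d: dict, cols: list[str]) -> np.ndarray:
            return np.array([d[c] for c in cols])

        k1 = rng.normal(vec(spec.e1_mean, OUTCOME_PARAMS),
                        vec(spec.e1_sd, OUTCOME_PARAMS), size=(n, 4))
        k2 = rng.normal(vec(spec.e2_mean, OUTCOME_PARAMS),
                        vec(spec.e2_sd, OUTCOME_PARAMS), size=(n, 4))
        m1 = rng.normal(vec(spec.emg_e1_mean, EMG_COLUMNS),
                        vec(spec.emg_e1_sd, EMG_COLUMNS), size=(n, 3))
        m2 = rng.normal(vec(spec.emg_e2_mean, EMG_COLUMNS),
                        vec(spec.emg_e2_sd, EMG_COLUMNS), size=(n, 3))
        if spec.exam_mean:
            ex = rng.normal(vec(spec.exam_mean, CLIN_COLUMNS),
                            vec(spec.exam_sd, CLIN_COLUMNS), size=(n, 4))
            ex[:, :2] = np.clip(ex[:, :2], 0.0, None)
            ex[:, 2:] = np.clip(ex[:, 2:], 0.0, 5.0)
        else:
            ex = np.full((n, 4), np.nan)
        for i in range(n):
            sid = f"{spec.group}_{i:04d}"
            ids.append(sid)
            labels.append(spec.group)
            e1_rows.append({"subject_id": sid,
                            **dict(zip(OUTCOME_PARAMS, k1[i])),
                            **dict(zip(EMG_COLUMNS, m1[i])),
                            **dict(zip(CLIN_COLUMNS, ex[i]))})
            e2_rows.append({"subject_id": sid,
                            **dict(zip(OUTCOME_PARAMS, k2[i])),
                            **dict(zip(EMG_COLUMNS, m2[i]))})
    e1 = pd.DataFrame(e1_rows)
    e2 = pd.DataFrame(e2_rows)
    return e1, e2, pd.Series(labels, index=ids, name="group_true")


def scale_archetype_separation(archetypes: dict[str, ArchetypeSpec], factor: float,
                               groups: list[str] | None = None) -> dict[str, ArchetypeSpec]:
    """Rescale the between-archetype spread of the CP phase means.

    Deviations of each listed archetype's phase means from the unweighted
    across-archetype mean are multiplied by ``factor`` (SDs untouched);
    used by recovery simulations to probe separability.
    """
    if groups is None:
        groups = [g for g in archetypes if g != "TD"]
    center = {p: float(np.mean([archetypes[g].phase_mean[p] for g in groups]))
              for p in SUBPHASES}
    out = dict(archetypes)
    for g in groups:
        spec = archetypes[g]
        pm = {p: center[p] + factor * (spec.phase_mean[p] - center[p]) for p in SUBPHASES}
        out[g] = ArchetypeSpec(name=spec.name, phase_mean=pm, phase_sd=dict(spec.phase_sd),
                               clin_mean=dict(spec.clin_mean), clin_sd=dict(spec.clin_sd))
    return out


def generate_raw_trace(seed: int, fs: float = 2000.0, n_strides: int = 4,
                       stride_s: float = 1.1, foot_off_frac: float = 0.6,
                       burst_level: float = 1.0) -> tuple[np.ndarray, float, list[tuple[str, float]]]:
    """Band-limited noise bursts with gait events, for exercising preprocessing.

    Emits one activation burst per stride (white noise band-passed to
    20-350 Hz, amplitude-modulated by a smooth per-stride window) plus a
    low noise floor.  Returns ``(samples, fs, events)`` where events are
    ``(type, time_s)`` tuples alternating foot_strike / foot_off.  This is
    deliberately not a physiological EMG model.
    """
    from scipy.signal import butter, sosfiltfilt

    rng = np.random.default_rng(seed)
    total_s = (n_strides + 0.5) * stride_s
    n = int(total_s * fs)
    t = np.arange(n) / fs
    noise = rng.standard_normal(n)
    sos = butter(4, [20.0, 350.0], btype="bandpass", fs=fs, output="sos")
    carrier = sosfiltfilt(sos, noise)
    gate = np.full(n, 0.05)
    events: list[tuple[str, float]] = []
    for s in range(n_strides + 1):
        strike = s * stride_s
        if strike < total_s:
            events.append(("foot_strike", strike))
        if s < n_strides:
            events.append(("foot_off", strike + foot_off_frac * stride_s))
        # raised-cosine burst around early stance
        c = strike + 0.15 * stride_s
        w = 0.25 * stride_s
        gate += burst_level * np.clip(np.cos(np.pi * (t - c) / w), 0.0, None) ** 2
    return carrier * gate, fs, events
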