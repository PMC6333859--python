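"""Synthetic dynamic-FDG-PET cohort generator.

Builds a fully synthetic study with the statistical structure the analysis
assumes: a bolus-shaped plasma input, per-subject kinetic truth with
controllable side-to-side asymmetry in the micro-parameters (K1, k2, k3),
frame-averaged noisy tissue curves on the 39-frame dynamic protocol,
carotid measurements mixed from the true input and a background curve via
recovery/spill-in coefficients, late-window static concentrations, and
(optionally) labelled volumes for the region-extraction round trip.

Asymmetry is injected only into the micro-parameters: the ipsilateral value
is derived from the contralateral one by inverting the ASYM formula,
``ipsi = contra*(2 - a)/(2 + a)``.  Ki and static-AC asymmetry are never
injected — they emerge from the kinetics, which preserves the causal
structure under study (phosphorylation drives hypometabolism) and makes the
macro-parameter consistency checks meaningful.

Everything is driven by one master seed through per-subject child streams,
so a cohort is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .acquisition import FrameSchedule, make_frame_schedule
from .asymmetry_stats import asym_index
from .idif import CarotidMeasurement, PVCCoefficients, mix_carotid
from .kinetics import (
    PlasmaInput,
    TissueTAC,
    TwoTCMParams,
    _convolve_2tcm,
    _fine_grid_min,
    forward_2tcm,
)

__all__ = [
    "FengBolus",
    "CohortSpec",
    "RegionTruth",
    "TruthRecord",
    "SubjectData",
    "Cohort",
    "simulate_input_function",
    "draw_subject_truth",
    "simulate_subject_data",
    "carotid_sample_times",
    "simulate_cohort",
    "make_synthetic_atlas",
    "paint_dynamic_volume",
    "paint_static_volume",
    "EVAL_REGIONS",
    "REFERENCE_REGIONS",
    "DEFAULT_FRAME_GROUPS",
]

# 39-frame, 60-minute clinical brain protocol: 12x5s, 6x10s, 6x30s, 5x60s, 10x300s
DEFAULT_FRAME_GROUPS = [(12, 5), (6, 10), (6, 30), (5, 60), (10, 300)]

# the six focus-type evaluation regions (five lobes) and their cohort
# frequencies in a 17-patient study, plus four large reference regions
EVAL_REGIONS = (
    "hippocampus",
    "occipital_inf",
    "frontal_sup_mid",
    "frontal_inf_orb",
    "supramarginal_angular",
    "insula",
)
EVAL_REGION_COUNTS_17 = (11, 2, 1, 1, 1, 1)
REFERENCE_REGIONS = ("frontal_ref", "parietal_ref", "occipital_ref", "temporal_ref")


@dataclass(frozen=True)
class FengBolus:
    """Feng tri-exponential bolus plasma curve.

    ``Cp(u) = (A1*u - A2 - A3)*e^(-l1*u) + A2*e^(-l2*u) + A3*e^(-l3*u)``
    for ``u = t - tau >= 0`` and 0 before the appearance time tau — the
    standard smooth bolus of FDG simulation studies: continuous at onset,
    fast rise peaking well inside the first two minutes, slow bi-exponential
    tail.  Amplitudes in kBq/mL (A1 in kBq/mL/min), rates in 1/min, tau in
    min.
    """

    A1: float = 800.0
    A2: float = 20.0
    A3: float = 21.0
    lam1: float = 4.1
    lam2: float = 0.01
    lam3: float = 0.12
    tau: float = 0.5
    amplitude: float = 1.0

    def __call__(self, t_min) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        u = np.maximum(t - self.tau, 0.0)
        curve = np.where(
            t > self.tau,
            (self.A1 * u - self.A2 - self.A3) * np.exp(-self.lam1 * u)
            + self.A2 * np.exp(-self.lam2 * u)
            + self.A3 * np.exp(-self.lam3 * u),
            0.0,
        )
        return self.amplitude * curve


def simulate_input_function(
    dose_proxy: float = 1.0,
    bolus: FengBolus | None = None,
    t_end_min: float = 67.0,
    step_min: float = 0.5 / 60.0,
) -> PlasmaInput:
    """Densely sampled bolus plasma input scaled by a dose proxy.

    The curve must be nonnegative everywhere with its peak inside the first
    two minutes after appearance; violations are a specification error.
    """
    if dose_proxy <= 0:
        raise ValueError("dose proxy must be positive")
    b = bolus or FengBolus()
    inp = PlasmaInput.from_function(lambda t: dose_proxy * b(t), t_end_min, step_min)
    if np.any(inp.values < 0):
        raise ValueError("bolus parameters produce negative concentrations")
    t_peak = inp.times_min[int(np.argmax(inp.values))]
    if t_peak > b.tau + 2.0:
        raise ValueError(f"bolus peaks at {t_peak:.2f} min, outside the first 2 min")
    return inp


class CohortSpec(BaseModel):
    """Study-design parameters of the synthetic cohort.

    Defaults encode the emulated study: 17 patients, 8 controls, the
    39-frame dynamic protocol, patient epileptogenic micro-parameter
    asymmetries centred on the reported cohort means (K1 0.12, k2 0.14,
    k3 0.21), contralateral rate constants in gray-matter FDG ranges, 3 %
    frame-noise coefficient of variation, and a late static window.
    """

    n_patients: int = Field(default=17, ge=0)
    n_controls: int = Field(default=8, ge=0)
    frame_groups: list[tuple[int, float]] = Field(default_factory=lambda: list(DEFAULT_FRAME_GROUPS))
    asym_means: dict[str, float] = Field(default_factory=lambda: {"K1": 0.12, "k2": 0.14, "k3": 0.21})
    asym_sd: float = 0.05
    control_jitter_sd: float = 0.0
    nonepi_jitter_sd: float = 0.02
    param_ranges: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {"K1": (0.08, 0.12), "k2": (0.10, 0.16), "k3": (0.04, 0.08)}
    )
    vb_true: float = 0.0
    noise_cv: float = 0.03
    noise_ref_duration_s: float = 5.0  # CV anchors at the shortest frames
    rc_true: float = 0.8
    sp_true: float = 0.2
    static_window_min: tuple[float, float] = (45.0, 60.0)
    dose_jitter: float = 0.2  # per-subject uniform amplitude jitter, +/- fraction
    include_reference_regions: bool = True
    seed: int

    @model_validator(mode="after")
    def _check(self):
        for p, m in self.asym_means.items():
            if not -2 < m < 2:
                raise ValueError(f"ASYM mean for {p} outside (-2, 2)")
        if self.asym_sd < 0 or self.control_jitter_sd < 0 or self.nonepi_jitter_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        for p, (lo, hi) in self.param_ranges.items():
            if lo <= 0 or hi <= lo:
                raise ValueError(f"invalid range for {p}")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be nonnegative")
        return self

    def schedule(self) -> FrameSchedule:
        return make_frame_schedule([tuple(g) for g in self.frame_groups])

    def pvc(self) -> PVCCoefficients:
        return PVCCoefficients(RC=self.rc_true, SP=self.sp_true)


@dataclass(frozen=True)
class RegionTruth:
    region_id: str
    region_class: str  # epileptogenic | non_epileptogenic | evaluation
    params_ipsi: TwoTCMParams
    params_contra: TwoTCMParams
    static_ac_ipsi: float
    static_ac_contra: float
    true_asym: dict[str, float]


@dataclass(frozen=True)
class TruthRecord:
    subject_id: str
    group: str  # patients | controls
    focus_side: str  # left | right (controls: nominal left)
    input_fn: PlasmaInput
    regions: tuple[RegionTruth, ...]


@dataclass(frozen=True)
class SubjectData:
    subject_id: str
    group: str
    tacs: pd.DataFrame  # shared TAC-table format
    carotid: CarotidMeasurement
    static: pd.DataFrame
    schedule: FrameSchedule = field(repr=False, default=None)


@dataclass(frozen=True)
class Cohort:
    spec: CohortSpec
    truth: tuple[TruthRecord, ...]
    data: tuple[SubjectData, ...]

    def manifest(self) -> dict:
        return {
            "spec": self.spec.model_dump(mode="json"),
            "n_subjects": len(self.truth),
            "subject_seed_policy": "numpy SeedSequence(seed).spawn(n_subjects)",
        }


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

def _ipsi_from_asym(contra: float, a: float) -> float:
    """Invert ASYM = (c - i)*2/(c + i) for the ipsilateral value."""
    return contra * (2.0 - a) / (2.0 + a)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return mean
    for _ in range(100):
        a = rng.normal(mean, sd)
        if -2 < a < 2:
            return a
    raise RuntimeError("could not draw ASYM inside (-2, 2)")


def _late_window_ac(params: TwoTCMParams, inp: PlasmaInput, schedule: FrameSchedule,
                    window_min: tuple[float, float]) -> float:
    """Noiseless model concentration averaged over the static window."""
    t = _fine_grid_min(schedule, 0.5)
    cp = inp(t)
    fine = (1.0 - params.vB) * _convolve_2tcm(params.K1, params.k2, params.k3, cp, t[1] - t[0]) \
        + params.vB * cp
    lo, hi = window_min
    sel = (t >= lo) & (t <= hi)
    return float(np.trapezoid(fine[sel], t[sel]) / (t[sel][-1] - t[sel][0]))


def _region_truth(rng: np.random.Generator, spec: CohortSpec, region_id: str,
                  region_class: str, asym_draw: dict[str, float],
                  inp: PlasmaInput, schedule: FrameSchedule) -> RegionTruth:
    contra = {p: rng.uniform(*spec.param_ranges[p]) for p in ("K1", "k2", "k3")}
    ipsi = {p: _ipsi_from_asym(contra[p], asym_draw[p]) for p in ("K1", "k2", "k3")}
    p_contra = TwoTCMParams(vB=spec.vb_true, **contra)
    p_ipsi = TwoTCMParams(vB=spec.vb_true, **ipsi)
    ac_contra = _late_window_ac(p_contra, inp, schedule, spec.static_window_min)
    ac_ipsi = _late_window_ac(p_ipsi, inp, schedule, spec.static_window_min)
    true_asym = {p: asym_index(contra[p], ipsi[p]) for p in ("K1", "k2", "k3")}
    true_asym["Ki"] = asym_index(p_contra.Ki, p_ipsi.Ki)
    true_asym["staticAC"] = asym_index(ac_contra, ac_ipsi)
    return RegionTruth(region_id=region_id, region_class=region_class,
                       params_ipsi=p_ipsi, params_contra=p_contra,
                       static_ac_ipsi=ac_ipsi, static_ac_contra=ac_contra,
                       true_asym=true_asym)


def _patient_epi_regions(spec: CohortSpec, rng: np.random.Generator) -> list[str]:
    if spec.n_patients == 17:
        out = []
        for name, count in zip(EVAL_REGIONS, EVAL_REGION_COUNTS_17):
            out.extend([name] * count)
        return out
    w = np.array(EVAL_REGION_COUNTS_17, dtype=float)
    return list(rng.choice(EVAL_REGIONS, size=spec.n_patients, p=w / w.sum()))


def draw_subject_truth(spec: CohortSpec, group: str, rng: np.random.Generator,
                       subject_id: str, epi_region: str | None = None) -> TruthRecord:
    """Draw one subject's ground truth.

    Patients get one epileptogenic region with per-parameter ASYM drawn from
    Normal(mean, sd) truncated to (-2, 2), plus the reference regions with
    small jitter.  Controls get the six evaluation regions with
    zero-centred jitter (default exactly zero).
    """
    if group not in ("patients", "controls"):
        raise ValueError("group must be 'patients' or 'controls'")
    schedule = spec.schedule()
    amp = 1.0 + rng.uniform(-spec.dose_jitter, spec.dose_jitter)
    inp = simulate_input_function(dose_proxy=amp,
                                  t_end_min=schedule.total_duration / 60.0 + 1.0)
    focus_side = "left" if group == "controls" else ("left", "right")[rng.integers(2)]

    regions: list[RegionTruth] = []
    if group == "patients":
        region_id = epi_region or str(rng.choice(EVAL_REGIONS))
        a = {p: _truncated_normal(rng, spec.asym_means.get(p, 0.0), spec.asym_sd)
             for p in ("K1", "k2", "k3")}
        regions.append(_region_truth(rng, spec, region_id, "epileptogenic",
                                     a, inp, schedule))
        if spec.include_reference_regions:
            for ref in REFERENCE_REGIONS:
                a = {p: _truncated_normal(rng, 0.0, spec.nonepi_jitter_sd)
                     for p in ("K1", "k2", "k3")}
                regions.append(_region_truth(rng, spec, ref, "non_epileptogenic",
                                             a, inp, schedule))
    else:
        for region_id in EVAL_REGIONS:
            a = {p: _truncated_normal(rng, 0.0, spec.control_jitter_sd)
                 for p in ("K1", "k2", "k3")}
            regions.append(_region_truth(rng, spec, region_id, "evaluation",
                                         a, inp, schedule))
        if spec.include_reference_regions:
            for ref in REFERENCE_REGIONS:
                a = {p: _truncated_normal(rng, 0.0, spec.nonepi_jitter_sd)
                     for p in ("K1", "k2", "k3")}
                regions.append(_region_truth(rng, spec, ref, "non_epileptogenic",
                                             a, inp, schedule))

    return TruthRecord(subject_id=subject_id, group=group, focus_side=focus_side,
                       input_fn=inp, regions=tuple(regions))


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def _frame_noise_sd(values: np.ndarray, durations_s: np.ndarray, spec: CohortSpec) -> np.ndarray:
    return spec.noise_cv * np.abs(values) * np.sqrt(spec.noise_ref_duration_s / durations_s)


def carotid_sample_times(schedule: FrameSchedule, gap_fast_s: float = 2.0,
                         gap_slow_s: float = 30.0, fast_frame_max_s: float = 30.0
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Carotid sampling grid: sub-frame time samples and effective durations.

    The carotid curve is recorded per time sample rather than per frame
    (short effective samples while the bolus changes quickly, coarser ones
    late), so the piecewise-linear input reconstruction does not inherit the
    5-minute late-frame spacing.  Returns (times_min, durations_s).
    """
    times, durs = [], []
    for s, d in zip(schedule.starts, schedule.durations):
        gap = gap_fast_s if d <= fast_frame_max_s else gap_slow_s
        n = max(int(np.ceil(d / gap)), 1)
        times.extend(s + d * (np.arange(n) + 0.5) / n)
        durs.extend([d / n] * n)
    return np.asarray(times) / 60.0, np.asarray(durs)


def simulate_subject_data(truth: TruthRecord, spec: CohortSpec,
                          rng: np.random.Generator) -> SubjectData:
    """Noisy frame data for one subject.

    Tissue TACs are the frame-averaged forward model plus zero-mean Gaussian
    noise with sd = CV * value * sqrt(T_ref / T_frame) (longer frames are
    less noisy).  The carotid measurement mixes the frame-averaged true
    input with a background curve (the subject's mean tissue curve) via the
    RC/SP truth; the static concentration is the noiseless late-window value
    plus CV-level noise.
    """
    schedule = spec.schedule()
    rows = []
    fine_t = _fine_grid_min(schedule, 0.5)
    cp_fine = truth.input_fn(fine_t)
    fine_curves = []
    for region in truth.regions:
        for side, params in (("ipsi", region.params_ipsi), ("contra", region.params_contra)):
            tac = forward_2tcm(params, truth.input_fn, schedule,
                               voi_id=region.region_id, side=side)
            fine = (1.0 - params.vB) * _convolve_2tcm(
                params.K1, params.k2, params.k3, cp_fine, fine_t[1] - fine_t[0]) \
                + params.vB * cp_fine
            fine_curves.append(fine)
            noisy = tac.values + rng.normal(0.0, 1.0, schedule.n_frames) * \
                _frame_noise_sd(tac.values, schedule.durations, spec)
            for s, d, v in zip(schedule.starts, schedule.durations, noisy):
                rows.append({"frame_start_s": s, "frame_duration_s": d,
                             "value_kBq_per_mL": v, "voi_id": region.region_id,
                             "side": side, "subject_id": truth.subject_id})
    tac_table = pd.DataFrame(rows)

    # carotid: true input sampled on the sub-frame grid, mixed with the
    # population-like background (mean tissue curve) via the RC/SP truth
    times_min, durs_s = carotid_sample_times(schedule)
    bkgd_fine = np.mean(fine_curves, axis=0)
    bkgd = np.interp(times_min, fine_t, bkgd_fine)
    true_input_samples = PlasmaInput(times_min=times_min,
                                     values=np.maximum(truth.input_fn(times_min), 0.0))
    clean = mix_carotid(true_input_samples, bkgd, spec.pvc())
    cmeas = clean.cmeas + rng.normal(0.0, 1.0, len(times_min)) * \
        _frame_noise_sd(clean.cmeas, durs_s, spec)
    cbkgd = clean.cbkgd + rng.normal(0.0, 1.0, len(times_min)) * \
        _frame_noise_sd(clean.cbkgd, durs_s, spec)
    carotid = CarotidMeasurement(times_min=times_min, cmeas=cmeas, cbkgd=cbkgd)

    static_rows = []
    for region in truth.regions:
        for side, ac in (("ipsi", region.static_ac_ipsi), ("contra", region.static_ac_contra)):
            noisy_ac = ac + rng.normal(0.0, spec.noise_cv * abs(ac)) if spec.noise_cv > 0 else ac
            static_rows.append({"subject_id": truth.subject_id, "voi_id": region.region_id,
                                "side": side, "static_ac_kBq_per_mL": noisy_ac})
    static_table = pd.DataFrame(static_rows)

    return SubjectData(subject_id=truth.subject_id, group=truth.group,
                       tacs=tac_table, carotid=carotid, static=static_table,
                       schedule=schedule)


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate the full patient + control cohort from the master seed."""
    n_total = spec.n_patients + spec.n_controls
    streams = np.random.SeedSequence(spec.seed).spawn(n_total)
    truths: list[TruthRecord] = []
    data: list[SubjectData] = []
    rng_regions = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(n_total + 1)[-1])
    epi_regions = _patient_epi_regions(spec, rng_regions)
    for i in range(spec.n_patients):
        rng = np.random.default_rng(streams[i])
        t = draw_subject_truth(spec, "patients", rng, f"patient_{i + 1:02d}",
                               epi_region=epi_regions[i])
        truths.append(t)
        data.append(simulate_subject_data(t, spec, rng))
    for j in range(spec.n_controls):
        rng = np.random.default_rng(streams[spec.n_patients + j])
        t = draw_subject_truth(spec, "controls", rng, f"control_{j + 1:02d}")
        truths.append(t)
        data.append(simulate_subject_data(t, spec, rng))
    return Cohort(spec=spec, truth=tuple(truths), data=tuple(data))


# ---------------------------------------------------------------------------
# volume painting (regions-module round trips and optional NIfTI output)
# ---------------------------------------------------------------------------

def make_synthetic_atlas(n_pairs: int = 6, shape: tuple[int, int, int] = (20, 20, 10)):
    """Small left/right-symmetric label atlas for tests and demos.

    Left-hemisphere labels are 1..n_pairs, their right homologs
    n_pairs+1..2*n_pairs, laid out as paired blocks.
    """
    from .regions import LabelAtlas

    nx, ny, nz = shape
    labels = np.zeros(shape, dtype=np.int32)
    half = nx // 2
    per = max(ny // n_pairs, 1)
    for k in range(n_pairs):
        y0, y1 = k * per, min((k + 1) * per, ny)
        labels[1:half - 1, y0:y1, 1:nz - 1] = k + 1
        labels[nx - half + 1:nx - 1, y0:y1, 1:nz - 1] = n_pairs + k + 1
    rows = []
    for k in range(n_pairs):
        rows.append({"label_id": k + 1, "name": f"region{k + 1}_L",
                     "hemisphere": "left", "homolog_id": n_pairs + k + 1})
        rows.append({"label_id": n_pairs + k + 1, "name": f"region{k + 1}_R",
                     "hemisphere": "right", "homolog_id": k + 1})
    return LabelAtlas(labels=labels, lut=pd.DataFrame(rows))


def paint_dynamic_volume(atlas, curves: dict[int, np.ndarray]) -> np.ndarray:
    """Write per-label frame curves into a 4-D volume (background 0)."""
    n_frames = len(next(iter(curves.values())))
    vol = np.zeros(atlas.labels.shape + (n_frames,), dtype=float)
    for label_id, curve in curves.items():
        vol[atlas.labels == label_id] = np.asarray(curve, dtype=float)
    return vol


def paint_static_volume(atlas, values: dict[int, float]) -> np.ndarray:
    """Write per-label scalars into a 3-D volume (background 0)."""
    vol = np.zeros(atlas.labels.shape, dtype=float)
    for label_id, v in values.items():
        vol[atlas.labels == label_id] = v
    return vol
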