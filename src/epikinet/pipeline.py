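"""End-to-end orchestration: simulate/load -> IDIF -> fit -> ASYM -> statistics.

A run is fully described by a :class:`RunConfig` (validated before any
computation) and a master seed; it writes a self-contained run directory::

    run_dir/
      manifest.json          # config, seed, version, completion flag
      truth.json             # simulated ground truth (simulation runs)
      tacs/<subject>.csv     # shared TAC-table format
      carotid/<subject>.csv  # carotid + background curves
      static.csv, regions.csv
      fits/fits.csv
      asym.csv
      stats/                 # group tests, paired tests, correlations
      report.md

Re-running over a completed run directory with ``resume=True`` performs no
recomputation.  Every number in the report is read back from the emitted
tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import io as ekio
from .asymmetry_stats import (
    PARAMETERS,
    asym_index,
    compare_groups,
    control_mean_abs_asym,
    correlate_asym,
)
from .idif import CylinderROISpec, PVCCoefficients, correct_idif, estimate_rc_sp
from .kinetics import FitConfig, fit_2tcm
from .synthetic_cohort import Cohort, CohortSpec, simulate_cohort

__all__ = [
    "RunConfig",
    "IDIFSettings",
    "FitSettings",
    "StatsSettings",
    "PipelineDataError",
    "ConvergenceError",
    "run_pipeline",
    "fit_cohort",
    "build_asym_table",
    "cohort_statistics",
]


class PipelineDataError(RuntimeError):
    """Missing or inconsistent subject/region data; aborts the run."""


class ConvergenceError(RuntimeError):
    """A kinetic fit failed to converge and the run treats that as fatal."""


class IDIFSettings(BaseModel):
    """Either known RC/SP coefficients or a geometry to estimate them from."""

    mode: str = "known"  # known | estimate
    rc: float = 0.8
    sp: float = 0.2
    fwhm_mm: float = 5.4
    vessel_diameter_mm: float = 6.0
    roi_radius_mm: float = 1.0

    def coefficients(self) -> PVCCoefficients:
        if self.mode == "known":
            return PVCCoefficients(RC=self.rc, SP=self.sp)
        if self.mode == "estimate":
            return estimate_rc_sp(self.fwhm_mm, self.vessel_diameter_mm,
                                  CylinderROISpec(roi_radius_mm=self.roi_radius_mm))
        raise ValueError(f"unknown IDIF mode {self.mode!r}")


class FitSettings(BaseModel):
    fit_vb: bool = False
    weights: str = "duration"
    n_starts: int = 5
    convergence_fatal: bool = False

    def fit_config(self, seed: int) -> FitConfig:
        return FitConfig(fit_vb=self.fit_vb, weights=self.weights,
                         n_starts=self.n_starts, seed=seed)


class StatsSettings(BaseModel):
    pooled_nonepi: bool = True  # pool reference regions per subject before testing
    holm: bool = False


class RunConfig(BaseModel):
    """One reproducible analysis run."""

    simulate: CohortSpec | None = None
    inputs_dir: str | None = None
    idif: IDIFSettings = Field(default_factory=IDIFSettings)
    fit: FitSettings = Field(default_factory=FitSettings)
    stats: StatsSettings = Field(default_factory=StatsSettings)
    seed: int | None = None  # overrides simulate.seed when set

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def canonical_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


# ---------------------------------------------------------------------------
# fitting and asymmetry assembly
# ---------------------------------------------------------------------------

def fit_cohort(cohort: Cohort, pvc: PVCCoefficients,
               fit_settings: FitSettings | None = None) -> pd.DataFrame:
    """IDIF-correct and fit every (subject, VOI, side) TAC of a cohort.

    Returns one row per fit with the micro-parameters, derived Ki, WRSS and
    convergence flag.  The per-fit seed is derived from the cohort master
    seed and the subject index, so results are reproducible and independent
    of iteration order.
    """
    fs = fit_settings or FitSettings()
    rows = []
    for i, subj in enumerate(cohort.data):
        inp = correct_idif(subj.carotid, pvc)
        for tac in ekio.tacs_from_table(subj.tacs):
            res = fit_2tcm(tac, inp, fs.fit_config(seed=(cohort.spec.seed + i) % 2 ** 31))
            if fs.convergence_fatal and not res.converged:
                raise ConvergenceError(
                    f"fit did not converge: {subj.subject_id}/{tac.voi_id}/{tac.side}")
            rows.append({"subject_id": subj.subject_id, "group": subj.group,
                         "voi_id": tac.voi_id, "side": tac.side,
                         **res.params.as_dict(), "wrss": res.wrss,
                         "converged": res.converged, "degenerate": res.degenerate})
    return pd.DataFrame(rows)


def build_asym_table(fits: pd.DataFrame, static: pd.DataFrame,
                     region_classes: pd.DataFrame) -> pd.DataFrame:
    """Long-format ASYM table from fitted parameters and static concentrations.

    ``region_classes`` maps (subject_id, voi_id) to region_class and group.
    Output columns: subject_id, group, region_id, region_class, parameter,
    ipsi, contra, asym, abs_asym.
    """
    cls = region_classes.set_index(["subject_id", "voi_id"])
    merged = fits.merge(
        static.rename(columns={"static_ac_kBq_per_mL": "staticAC"}),
        on=["subject_id", "voi_id", "side"], how="left")
    rows = []
    for (subject, voi), g in merged.groupby(["subject_id", "voi_id"], sort=True):
        sides = dict(zip(g["side"], g.index))
        if "ipsi" not in sides or "contra" not in sides:
            raise PipelineDataError(f"missing side for {subject}/{voi}")
        try:
            info = cls.loc[(subject, voi)]
        except KeyError:
            raise PipelineDataError(f"no region class for {subject}/{voi}") from None
        gi, gc = g.loc[sides["ipsi"]], g.loc[sides["contra"]]
        for param in PARAMETERS:
            ipsi, contra = float(gi[param]), float(gc[param])
            a = asym_index(contra, ipsi)
            rows.append({"subject_id": subject, "group": str(info["group"]),
                         "region_id": voi, "region_class": str(info["region_class"]),
                         "parameter": param, "ipsi": ipsi, "contra": contra,
                         "asym": a, "abs_asym": abs(a)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group-level statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortStatistics:
    cohort_means: pd.DataFrame
    group_tests: pd.DataFrame
    paired_tests: pd.DataFrame
    correlation_rho: pd.DataFrame
    correlation_p: pd.DataFrame
    summary: dict


def cohort_statistics(asym: pd.DataFrame, settings: StatsSettings | None = None) -> CohortStatistics:
    """The group-level analysis of an ASYM table.

    * cohort means: signed epileptogenic ASYM in patients, mean absolute
      left/right ASYM over the evaluation regions in controls, and pooled
      absolute ASYM in the non-epileptogenic reference regions of both
      groups;
    * rank-sum tests patients vs controls (epileptogenic vs control
      evaluation regions, and reference regions);
    * paired signed-rank tests of static-AC ASYM against each kinetic
      parameter's ASYM within patients;
    * Spearman correlation matrix of the per-patient epileptogenic ASYMs.
    """
    st = settings or StatsSettings()
    patients = asym[asym["group"] == "patients"]
    controls = asym[asym["group"] == "controls"]

    epi = patients[patients["region_class"] == "epileptogenic"]
    ctrl_eval = controls[controls["region_class"] == "evaluation"]

    mean_rows = []
    tests = []
    paired = []

    ctrl_subject_means = {}
    if not ctrl_eval.empty:
        eval_regions = sorted(ctrl_eval["region_id"].unique())
        for subject, g in ctrl_eval.groupby("subject_id"):
            ctrl_subject_means[subject] = control_mean_abs_asym(g, eval_regions)

    for param in PARAMETERS:
        epi_vals = epi[epi["parameter"] == param]["asym"].to_numpy()
        if len(epi_vals):
            mean_rows.append({"group": "patients", "region_class": "epileptogenic",
                              "parameter": param, "mean_asym": float(epi_vals.mean()),
                              "convention": "signed", "n": len(epi_vals)})
        ctrl_vals = np.array([m[param] for m in ctrl_subject_means.values()
                              if param in m.index]) if ctrl_subject_means else np.array([])
        if len(ctrl_vals):
            mean_rows.append({"group": "controls", "region_class": "evaluation",
                              "parameter": param, "mean_asym": float(ctrl_vals.mean()),
                              "convention": "mean_abs", "n": len(ctrl_vals)})
        if len(epi_vals) >= 3 and len(ctrl_vals) >= 3:
            cmp = compare_groups(epi_vals, ctrl_vals, paired=False)
            tests.append({"comparison": "patients_epi_vs_controls_eval", "parameter": param,
                          "test": cmp.test_name, "statistic": cmp.statistic,
                          "pvalue": cmp.pvalue, "exact": cmp.exact,
                          "degenerate": cmp.degenerate})

        for group_name, df in (("patients", patients), ("controls", controls)):
            nonepi = df[(df["region_class"] == "non_epileptogenic") & (df["parameter"] == param)]
            if nonepi.empty:
                continue
            if st.pooled_nonepi:
                vals = nonepi.groupby("subject_id")["abs_asym"].mean().to_numpy()
            else:
                vals = nonepi["abs_asym"].to_numpy()
            mean_rows.append({"group": group_name, "region_class": "non_epileptogenic",
                              "parameter": param, "mean_asym": float(vals.mean()),
                              "convention": "mean_abs", "n": len(vals)})

    # patients vs controls in the reference regions
    for param in PARAMETERS:
        def _nonepi_vals(df):
            sub = df[(df["region_class"] == "non_epileptogenic") & (df["parameter"] == param)]
            if sub.empty:
                return np.array([])
            return (sub.groupby("subject_id")["abs_asym"].mean().to_numpy()
                    if st.pooled_nonepi else sub["abs_asym"].to_numpy())

        pv, cv = _nonepi_vals(patients), _nonepi_vals(controls)
        if len(pv) >= 3 and len(cv) >= 3:
            cmp = compare_groups(pv, cv, paired=False)
            tests.append({"comparison": "patients_vs_controls_nonepi", "parameter": param,
                          "test": cmp.test_name, "statistic": cmp.statistic,
                          "pvalue": cmp.pvalue, "exact": cmp.exact,
                          "degenerate": cmp.degenerate})

    # within-patient comparisons of static AC against each kinetic parameter
    wide = epi.pivot_table(index="subject_id", columns="parameter", values="asym")
    if "staticAC" in wide.columns and len(wide) >= 3:
        for param in ("K1", "k2", "k3", "Ki"):
            if param not in wide.columns:
                continue
            both = wide[["staticAC", param]].dropna()
            if len(both) >= 3:
                cmp = compare_groups(both["staticAC"].to_numpy(), both[param].to_numpy(),
                                     paired=True)
                paired.append({"comparison": f"staticAC_vs_{param}", "parameter": param,
                               "test": cmp.test_name, "statistic": cmp.statistic,
                               "pvalue": cmp.pvalue, "exact": cmp.exact,
                               "degenerate": cmp.degenerate})

    if len(wide) >= 5:
        corr = correlate_asym(wide)
        rho, pvals = corr.rho, corr.pvalues
    else:
        rho = pd.DataFrame()
        pvals = pd.DataFrame()

    cohort_means = pd.DataFrame(mean_rows)
    group_tests = pd.DataFrame(tests)
    paired_tests = pd.DataFrame(paired)

    if st.holm and not group_tests.empty:
        from .asymmetry_stats import holm_correction

        group_tests["pvalue_holm"] = holm_correction(group_tests["pvalue"].to_numpy())

    summary = {
        "cohort_mean_asym": {
            f"{r['group']}::{r['region_class']}::{r['parameter']}": r["mean_asym"]
            for r in mean_rows
        },
        "n_group_tests": len(group_tests),
        "n_paired_tests": len(paired_tests),
        "correlation_parameters": list(rho.columns) if not rho.empty else [],
    }
    return CohortStatistics(cohort_means=cohort_means, group_tests=group_tests,
                            paired_tests=paired_tests, correlation_rho=rho,
                            correlation_p=pvals, summary=summary)


# ---------------------------------------------------------------------------
# run directory orchestration
# ---------------------------------------------------------------------------

def _truth_to_json(cohort: Cohort) -> list[dict]:
    out = []
    for t in cohort.truth:
        out.append({
            "subject_id": t.subject_id,
            "group": t.group,
            "focus_side": t.focus_side,
            "regions": [{
                "region_id": r.region_id,
                "region_class": r.region_class,
                "params_ipsi": r.params_ipsi.as_dict(),
                "params_contra": r.params_contra.as_dict(),
                "static_ac_ipsi": r.static_ac_ipsi,
                "static_ac_contra": r.static_ac_contra,
                "true_asym": r.true_asym,
            } for r in t.regions],
        })
    return out


def _region_class_table(cohort: Cohort) -> pd.DataFrame:
    stashed = getattr(cohort, "_region_classes", None)
    if stashed is not None:
        return stashed
    rows = []
    for t in cohort.truth:
        for r in t.regions:
            rows.append({"subject_id": t.subject_id, "group": t.group,
                         "voi_id": r.region_id, "region_class": r.region_class})
    return pd.DataFrame(rows)


def _static_table(cohort: Cohort) -> pd.DataFrame:
    return pd.concat([s.static for s in cohort.data], ignore_index=True)


def _write_report(out: Path, stats: CohortStatistics) -> None:
    lines = ["# Cohort asymmetry report", ""]
    means = pd.read_csv(out / "stats" / "cohort_means.csv")
    lines += ["## Cohort-mean ASYM", "", means.to_markdown(index=False), ""]
    gt_path = out / "stats" / "group_tests.csv"
    if gt_path.exists():
        lines += ["## Group comparisons (Wilcoxon rank-sum)", "",
                  pd.read_csv(gt_path).to_markdown(index=False), ""]
    pt_path = out / "stats" / "paired_tests.csv"
    if pt_path.exists():
        lines += ["## Within-patient parameter comparisons (Wilcoxon signed-rank)", "",
                  pd.read_csv(pt_path).to_markdown(index=False), ""]
    rho_path = out / "stats" / "correlation_rho.csv"
    if rho_path.exists():
        lines += ["## Spearman correlations of epileptogenic ASYM", "",
                  pd.read_csv(rho_path, index_col=0).to_markdown(), ""]
    (out / "report.md").write_text("\n".join(lines))


def run_pipeline(config: RunConfig, out_dir, resume: bool = False) -> Path:
    """Execute a full run into ``out_dir``; returns the run directory path.

    Deterministic given config + seed; with ``resume=True`` a completed run
    with an identical config hash is left untouched.
    """
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    cfg_hash = config.canonical_hash()
    if resume and manifest_path.exists():
        manifest = ekio.read_json(manifest_path)
        if manifest.get("complete") and manifest.get("config_hash") == cfg_hash:
            return out

    if config.simulate is None and config.inputs_dir is None:
        raise PipelineDataError("config must provide a simulation spec or an inputs directory")

    out.mkdir(parents=True, exist_ok=True)
    (out / "tacs").mkdir(exist_ok=True)
    (out / "carotid").mkdir(exist_ok=True)
    (out / "fits").mkdir(exist_ok=True)
    (out / "stats").mkdir(exist_ok=True)

    if config.simulate is not None:
        spec = config.simulate
        if config.seed is not None:
            spec = spec.model_copy(update={"seed": config.seed})
        cohort = simulate_cohort(spec)
    else:
        cohort = load_cohort_inputs(config.inputs_dir)

    write_cohort_inputs(cohort, out, include_manifest=False)
    region_classes = _region_class_table(cohort)
    static = _static_table(cohort)

    pvc = config.idif.coefficients()
    fits = fit_cohort(cohort, pvc, config.fit)
    fits.to_csv(out / "fits" / "fits.csv", index=False)

    asym = build_asym_table(fits, static, region_classes)
    asym.to_csv(out / "asym.csv", index=False)

    stats = cohort_statistics(asym, config.stats)
    stats.cohort_means.to_csv(out / "stats" / "cohort_means.csv", index=False)
    if not stats.group_tests.empty:
        stats.group_tests.to_csv(out / "stats" / "group_tests.csv", index=False)
    if not stats.paired_tests.empty:
        stats.paired_tests.to_csv(out / "stats" / "paired_tests.csv", index=False)
    if not stats.correlation_rho.empty:
        stats.correlation_rho.to_csv(out / "stats" / "correlation_rho.csv")
        stats.correlation_p.to_csv(out / "stats" / "correlation_p.csv")
    ekio.write_json(stats.summary, out / "stats" / "summary.json")

    _write_report(out, stats)

    from . import __version__

    ekio.write_json({"config": config.model_dump(mode="json"),
                     "config_hash": cfg_hash,
                     "pvc": {"RC": pvc.RC, "SP": pvc.SP},
                     "version": __version__,
                     "complete": True}, manifest_path)
    return out


def write_cohort_inputs(cohort: Cohort, out_dir, include_manifest: bool = True) -> Path:
    """Write a cohort's measured data (and truth, if present) to a directory."""
    out = Path(out_dir)
    (out / "tacs").mkdir(parents=True, exist_ok=True)
    (out / "carotid").mkdir(exist_ok=True)
    for subj in cohort.data:
        ekio.write_tac_table(subj.tacs, out / "tacs" / f"{subj.subject_id}.csv")
        pd.DataFrame({"time_min": subj.carotid.times_min,
                      "cmeas_kBq_per_mL": subj.carotid.cmeas,
                      "cbkgd_kBq_per_mL": subj.carotid.cbkgd,
                      "subject_id": subj.subject_id}).to_csv(
            out / "carotid" / f"{subj.subject_id}.csv", index=False)
    _region_class_table(cohort).to_csv(out / "regions.csv", index=False)
    _static_table(cohort).to_csv(out / "static.csv", index=False)
    if cohort.truth:
        ekio.write_json(_truth_to_json(cohort), out / "truth.json")
    if include_manifest:
        ekio.write_json(cohort.manifest(), out / "manifest.json")
    return out


def load_cohort_inputs(inputs_dir) -> Cohort:
    """Load a cohort from a directory in the layout `epikinet simulate` writes."""
    from .synthetic_cohort import SubjectData

    root = Path(inputs_dir)
    if not root.exists():
        raise PipelineDataError(f"inputs directory {root} does not exist")
    manifest = ekio.read_json(root / "manifest.json")
    spec = CohortSpec.model_validate(manifest["spec"])
    region_classes = pd.read_csv(root / "regions.csv")
    static = pd.read_csv(root / "static.csv")
    data = []
    for tac_path in sorted((root / "tacs").glob("*.csv")):
        subject = tac_path.stem
        tacs = ekio.read_tac_table(tac_path)
        car_path = root / "carotid" / f"{subject}.csv"
        if not car_path.exists():
            raise PipelineDataError(f"missing carotid curve for subject {subject}")
        carotid = ekio.carotid_from_table(pd.read_csv(car_path))
        grp_rows = region_classes[region_classes["subject_id"] == subject]
        if grp_rows.empty:
            raise PipelineDataError(f"missing region classes for subject {subject}")
        data.append(SubjectData(
            subject_id=subject, group=str(grp_rows["group"].iloc[0]), tacs=tacs,
            carotid=carotid, static=static[static["subject_id"] == subject],
            schedule=ekio.schedule_from_table(tacs)))
    if not data:
        raise PipelineDataError(f"no TAC tables under {root / 'tacs'}")

    # truth is not available for measured-data runs; carry the class table along
    cohort = Cohort(spec=spec, truth=tuple(), data=tuple(data))
    object.__setattr__(cohort, "_region_classes", region_classes)
    return cohort
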