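"""End-to-end study pipeline: simulate -> fit -> ROI-measure -> calibrate,
classify and compute agreement statistics, plus recomputation of the
published contingency-table arithmetic.

Everything is driven by a :class:`PipelineConfig` (YAML-serializable) and
is deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement as ag
from .calibration import (ClassificationScheme, classify, lic, load_registry)
from .fitting import FitConfig, detect_and_reverse_swap, fit_voxels
from .roi import default_rois, patient_r2star, roi_mask
from .signal import FatSpectrum, NoiseModel, Protocol, load_protocol
from .synth import CohortSpec, PatientRecord, PhantomSpec, simulate_cohort

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "reproduce_tables",
    "load_paper_tables",
    "load_printed_statistics",
    "dump_report",
]

#: arm played by each engine in the emulated study
DEFAULT_ENGINES = {"me-gre": "truncation", "qdixon": "dixon",
                   "qdixon-wip": "noise_corrected"}


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    output_dir: str = "out"
    protocols: tuple[str, ...] = ("me-gre", "qdixon", "qdixon-wip")
    cohort: CohortSpec = field(default_factory=CohortSpec)
    fit: dict = field(default_factory=dict)          # per-arm FitConfig kwargs
    engines: dict = field(default_factory=lambda: dict(DEFAULT_ENGINES))
    calibrations: tuple[str, ...] = ("henninger", "wood", "garbowski",
                                     "hankins")
    yes_no_threshold: float = 36.0
    easl_boundaries: tuple[float, float, float] | None = (36.0, 150.0, 300.0)
    roi_diameter_mm: float = 12.0
    lic_arm: str = "qdixon"
    swap_exclude_arm: str = "qdixon"   # product emulation: exclude, don't fix
    qdixon_cap: float | None = 400.0

    def __post_init__(self) -> None:
        for name in self.protocols:
            if name not in self.engines:
                raise ValueError(f"no engine mapped for protocol {name!r}")
        registry = load_registry()
        for name in self.calibrations:
            if name not in registry:
                raise ValueError(f"unknown calibration {name!r}")
        if self.lic_arm not in self.protocols:
            raise ValueError("lic_arm must be one of the configured protocols")

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        if "cohort" in doc and isinstance(doc["cohort"], dict):
            cdoc = dict(doc["cohort"])
            if "phantom" in cdoc and isinstance(cdoc["phantom"], dict):
                pdoc = {k: tuple(v) if isinstance(v, list) else v
                        for k, v in cdoc["phantom"].items()}
                if "vessels" in pdoc:
                    pdoc["vessels"] = tuple(tuple(v) for v in pdoc["vessels"])
                cdoc["phantom"] = PhantomSpec(**pdoc)
            if "r2star_bounds" in cdoc:
                cdoc["r2star_bounds"] = tuple(cdoc["r2star_bounds"])
            doc["cohort"] = CohortSpec(**cdoc)
        for key in ("protocols", "calibrations"):
            if key in doc and isinstance(doc[key], list):
                doc[key] = tuple(doc[key])
        if doc.get("easl_boundaries") is not None:
            doc["easl_boundaries"] = tuple(doc["easl_boundaries"])
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        return doc

    def scheme(self) -> ClassificationScheme:
        return ClassificationScheme(yes_no_threshold=self.yes_no_threshold,
                                    easl_boundaries=self.easl_boundaries)


def _fit_config_for(config: PipelineConfig, arm: str) -> FitConfig:
    kwargs = dict(config.fit.get(arm, {}))
    kwargs.setdefault("mode", "global")
    if arm == "qdixon" and "r2star_cap" not in kwargs:
        kwargs["r2star_cap"] = config.qdixon_cap
    return FitConfig(**kwargs)


def _fit_patient_arm(record: PatientRecord, protocol: Protocol, engine: str,
                     union_mask: np.ndarray, spectrum: FatSpectrum,
                     noise: NoiseModel, fitcfg: FitConfig):
    stack = record.series_by_protocol[protocol.name]
    return fit_voxels(stack, union_mask, engine, protocol,
                      spectrum=spectrum, noise=noise, config=fitcfg)


def _map_from_flat(flat: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.full(mask.shape, np.nan)
    out[mask] = flat
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full emulated study and return the report as a dict.

    The product-sequence arm keeps its fitted maps as-is: a detected global
    fat/water swap there excludes the patient from every comparison
    involving that arm (as in the study).  The improved arm reverses
    detected swaps instead of excluding.
    """
    protocols = [load_protocol(name) for name in config.protocols]
    cohort_spec = dataclasses.replace(config.cohort, seed=config.seed)
    spectrum = FatSpectrum.default()
    records = simulate_cohort(cohort_spec, protocols, spectrum=spectrum)

    phantom = cohort_spec.phantom
    rois = default_rois(phantom, diameter_mm=config.roi_diameter_mm)
    roi_masks = [roi_mask(r, phantom.grid_shape, phantom.pixel_spacing)
                 for r in rois]
    union_mask = np.any(roi_masks, axis=0)
    noise = NoiseModel(cohort_spec.sigma)

    measurements = []   # rows: patient, sequence, r2star, true r2star
    exclusions = []
    for record in records:
        maps_by_seq = {}
        excluded_arms = set()
        for protocol in protocols:
            arm = protocol.name
            fitcfg = _fit_config_for(config, arm)
            fits = _fit_patient_arm(record, protocol, config.engines[arm],
                                    union_mask, spectrum, noise, fitcfg)
            if config.engines[arm] != "truncation":
                reverse = arm != config.swap_exclude_arm
                fits, swap_report = detect_and_reverse_swap(
                    fits, np.ones(fits["pdff"].shape, dtype=bool),
                    reverse=reverse)
                if swap_report["swap"] and not reverse:
                    excluded_arms.add(arm)
                    exclusions.append({
                        "patient_id": record.id, "arm": arm,
                        "reason": "global fat/water swap detected",
                        "median_pdff": swap_report["median_pdff"]})
            maps_by_seq[arm] = _map_from_flat(fits["r2star"], union_mask)
        meas = patient_r2star(maps_by_seq, rois, phantom.pixel_spacing,
                              patient_id=record.id)
        for arm, value in meas.per_sequence_r2star.items():
            measurements.append({
                "patient_id": record.id, "sequence": arm, "r2star": value,
                "true_r2star": record.true_state.r2star,
                "swap_applied": record.swap_applied,
                "excluded": arm in excluded_arms})
    df = pd.DataFrame(measurements)

    report = {
        "seed": config.seed,
        "n_patients": cohort_spec.n_patients,
        "protocols": list(config.protocols),
        "exclusions": exclusions,
        "pairwise": {},
        "truth_recovery": {},
        "lic_analysis": {},
    }

    wide = df.pivot(index="patient_id", columns="sequence", values="r2star")
    excl = df.pivot(index="patient_id", columns="sequence", values="excluded")
    truth = df.pivot(index="patient_id", columns="sequence",
                     values="true_r2star")

    for a, b in combinations(config.protocols, 2):
        keep = ~(excl[a] | excl[b])
        x = wide.loc[keep, a].to_numpy()
        y = wide.loc[keep, b].to_numpy()
        entry = {"n": int(keep.sum())}
        if keep.sum() >= 3 and np.ptp(x) > 0:
            slope, intercept, r2 = ag.linear_regression(x, y)
            ba = ag.bland_altman(x, y)
            ccc = ag.lin_ccc(x, y)
            entry.update({
                "slope": slope, "intercept": intercept, "r_squared": r2,
                "bland_altman": dataclasses.asdict(ba),
                "ccc": ccc.value, "ccc_ci": ccc.ci,
                "ccc_rating": ccc.extra["rating"]})
        report["pairwise"][f"{a}_vs_{b}"] = entry

    for arm in config.protocols:
        keep = ~excl[arm]
        x = truth.loc[keep, arm].to_numpy()
        y = wide.loc[keep, arm].to_numpy()
        if keep.sum() >= 3 and np.ptp(x) > 0:
            slope, intercept, r2 = ag.linear_regression(x, y)
            report["truth_recovery"][arm] = {
                "n": int(keep.sum()), "slope": slope,
                "intercept": intercept, "r_squared": r2}

    # LIC classification agreement between calibrations, on the chosen arm
    keep = ~excl[config.lic_arm]
    r2star_vec = wide.loc[keep, config.lic_arm].to_numpy()
    if r2star_vec.size == 0:
        report["lic_analysis"] = {"skipped": "no patients left in the "
                                             f"{config.lic_arm} arm"}
        report["measurements"] = df.to_dict(orient="records")
        return report
    registry = load_registry()
    scheme = config.scheme()
    labels_yn = ("yes", "no")
    labels_easl = ("0", "1", "2", "3")
    classes = {}
    for name in config.calibrations:
        lic_vals = lic(registry[name], r2star_vec)
        cl = [classify(v, scheme) for v in np.atleast_1d(lic_vals)]
        classes[name] = cl
    for a, b in combinations(config.calibrations, 2):
        pair = {}
        t_yn = ag.build_contingency([c.yes_no for c in classes[a]],
                                    [c.yes_no for c in classes[b]], labels_yn)
        kap = ag.cohens_kappa(t_yn)
        pair["yesno"] = {
            "counts": t_yn.counts.tolist(),
            "overall_agreement_pct": ag.overall_agreement(t_yn),
            "kappa": kap.value, "kappa_se": kap.se}
        if scheme.easl_boundaries is not None:
            t_e = ag.build_contingency(
                [str(c.easl_group) for c in classes[a]],
                [str(c.easl_group) for c in classes[b]], labels_easl)
            kap_e = ag.cohens_kappa(t_e)
            pair["easl"] = {
                "counts": t_e.counts.tolist(),
                "overall_agreement_pct": ag.overall_agreement(t_e),
                "kappa": kap_e.value, "kappa_se": kap_e.se}
        report["lic_analysis"][f"{a}_vs_{b}"] = pair

    report["measurements"] = df.to_dict(orient="records")
    return report


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def dump_report(report: dict, path: str | Path) -> Path:
    """Write a report as deterministic (sorted-key) JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True,
                               cls=_NumpyEncoder) + "\n")
    return path


# ---------------------------------------------------------------------------
# published-table arithmetic
# ---------------------------------------------------------------------------

def _tables_from_frame(frame: pd.DataFrame) -> dict[str, ag.ContingencyTable]:
    out = {}
    for comparison, sub in frame.groupby("comparison", sort=True):
        labels = sorted(sub["row_class"].astype(str).unique(),
                        key=lambda x: ({"yes": 0, "no": 1}.get(x, x)))
        n = len(labels)
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((n, n), dtype=np.int64)
        for _, row in sub.iterrows():
            counts[index[str(row["row_class"])],
                   index[str(row["col_class"])]] = int(row["count"])
        out[comparison] = ag.ContingencyTable(counts, tuple(labels))
    return out


def load_paper_tables(scheme: str,
                      directory: str | Path | None = None
                      ) -> dict[str, ag.ContingencyTable]:
    """Published contingency tables (scheme: ``yesno`` or ``easl``)."""
    if scheme not in ("yesno", "easl"):
        raise ValueError("scheme must be 'yesno' or 'easl'")
    name = f"contingency_{scheme}.csv"
    if directory is not None:
        frame = pd.read_csv(Path(directory) / name)
    else:
        ref = resources.files("liveriron.data").joinpath(
            f"paper_tables/{name}")
        with resources.as_file(ref) as path:
            frame = pd.read_csv(path)
    return _tables_from_frame(frame)


def load_printed_statistics(directory: str | Path | None = None) -> pd.DataFrame:
    if directory is not None:
        return pd.read_csv(Path(directory) / "printed_statistics.csv")
    ref = resources.files("liveriron.data").joinpath(
        "paper_tables/printed_statistics.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def reproduce_tables(tables: dict[str, dict[str, ag.ContingencyTable]]
                     | None = None,
                     printed: pd.DataFrame | None = None,
                     se_tolerance: float = 0.005) -> dict:
    """Recompute percent agreement and kappa from contingency counts.

    Compares against the published values (after half-up rounding to the
    printed precision: 2 decimals for percentages, 3 for kappa).  Standard
    errors are compared loosely (``se_tolerance``), since the original
    statistics package is not reproduced bit-for-bit.  Passing an empty
    ``tables`` dict yields an empty passing report.
    """
    if tables is None:
        tables = {scheme: load_paper_tables(scheme)
                  for scheme in ("yesno", "easl")}
    if printed is None and tables:
        printed = load_printed_statistics()

    results = []
    for scheme, tabset in sorted(tables.items()):
        for comparison, table in sorted(tabset.items()):
            pct = ag.round_half_up(ag.overall_agreement(table), 2)
            kap = ag.cohens_kappa(table)
            kval = ag.round_half_up(kap.value, 3)
            kse = ag.round_half_up(kap.se, 3) if kap.se is not None else None
            entry = {"comparison": comparison, "scheme": scheme,
                     "overall_agreement_pct": pct, "kappa": kval,
                     "kappa_se": kse, "n": table.n}
            if printed is not None:
                sub = printed[(printed["comparison"] == comparison)
                              & (printed["scheme"] == scheme)]
                expected = dict(zip(sub["statistic"], sub["value"]))
                checks = {}
                if "overall_agreement_pct" in expected:
                    checks["overall_agreement_pct"] = bool(
                        pct == round(float(expected["overall_agreement_pct"]), 2))
                if "kappa" in expected:
                    checks["kappa"] = bool(
                        kval == round(float(expected["kappa"]), 3))
                if "kappa_se" in expected and kse is not None:
                    checks["kappa_se"] = bool(
                        abs(kse - float(expected["kappa_se"])) <= se_tolerance)
                entry["expected"] = expected
                entry["pass"] = all(checks.values())
                entry["checks"] = checks
            results.append(entry)
    return {"results": results,
            "all_pass": all(e.get("pass", True) for e in results)}
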