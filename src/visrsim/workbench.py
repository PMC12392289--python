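"""End-to-end seeded studies: cohort -> images -> E/B -> models -> report.

``run_study`` executes the whole pipeline for every lesion view, builds the
seven E/B feature-subset classifiers ({PD}, {RE}, {RV} and combinations) and
collects the study statistics; ``export_report`` writes the CSV/TIFF/PNG
artifacts.  Every source of randomness is derived from the single master
seed, so a report is fully regenerable from its configuration.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .eb_measurement import (MeasureSettings, adjust_endpoints,
                             eb_ratio, largest_diameter,
                             lesion_characteristics, quality_flag)
from .msd_model import TrackingSequenceSpec
from .param_imaging import (CalibrationSpec, ImagingSettings,
                            ParametricImageSet, apply_corrections,
                            build_calibration, compute_images)
from .phantom import CohortSpec, lesion_boundary, make_phantom
from .rf_tracking import AcousticsSpec, KernelSpec
from .study_stats import (FEATURE_SETS, MODALITIES, correlate,
                          model_roc_for_subset, ranksum)

log = logging.getLogger(__name__)


def child_seed(master: int, stage: str, *ids: int) -> int:
    """Stable per-stage seed below 2**31 derived from the master seed."""
    key = f"{master}:{stage}:" + ":".join(map(str, ids))
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


@dataclass(frozen=True)
class StudyConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    ac: AcousticsSpec = field(default_factory=AcousticsSpec)
    imaging: ImagingSettings = field(default_factory=ImagingSettings)
    kernel: KernelSpec = field(default_factory=KernelSpec)
    measure: MeasureSettings = field(
        default_factory=lambda: MeasureSettings(cnr_threshold=0.1))
    mode: str = "ideal"               # ideal | rf
    corrections: bool = True
    seed: int = 0

    @property
    def seq(self) -> TrackingSequenceSpec:
        return self.cohort.seq


def config_to_yaml(cfg: StudyConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)


def config_from_yaml(path) -> StudyConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)

    def _tupled(d):
        return {k: tuple(v) if isinstance(v, list) else v
                for k, v in d.items()}

    cohort_raw = _tupled(raw.pop("cohort"))
    seq = TrackingSequenceSpec(**cohort_raw.pop("seq"))
    cohort = CohortSpec(seq=seq, **cohort_raw)
    from .msd_model import FitSettings
    imaging_raw = _tupled(raw.pop("imaging"))
    fit = FitSettings(**_tupled(imaging_raw.pop("fit")))
    return StudyConfig(
        cohort=cohort,
        ac=AcousticsSpec(**raw.pop("ac")),
        imaging=ImagingSettings(fit=fit, **imaging_raw),
        kernel=KernelSpec(**raw.pop("kernel")),
        measure=MeasureSettings(**raw.pop("measure")),
        **raw)


class StageError(RuntimeError):
    pass


@dataclass
class StudyReport:
    records: pd.DataFrame           # one row per lesion-view-modality
    characteristics: pd.DataFrame   # one row per lesion
    model_summary: pd.DataFrame     # 7 rows: feature_set, auc, sens, spec, n
    corr_eb: pd.DataFrame
    corr_unsure: pd.DataFrame
    ranksum_eb: pd.DataFrame
    unsure_fraction: dict
    exclusions: pd.DataFrame
    manifest: dict
    example_images: ParametricImageSet | None = None


def run_study(cfg: StudyConfig) -> StudyReport:
    t_start = time.perf_counter()
    cohort = replace(cfg.cohort, seed=child_seed(cfg.seed, "cohort"))
    lesions = _stage("sample_cohort", None, lambda: _sample(cohort))

    cal = None
    if cfg.corrections:
        cal = _stage("calibration", None, lambda: build_calibration(
            cohort.seq, cfg.ac, cohort.grid_shape, cohort.axial_spacing,
            CalibrationSpec(E=cohort.background_E, mu=cohort.background_mu),
            settings=cfg.imaging))

    rows, char_rows = [], []
    example = None
    spacings = (cohort.axial_spacing, cohort.lateral_spacing)
    for les in lesions:
        views = []
        for r, spec in enumerate(les.specs):
            def build(spec=spec, r=r):
                ph = make_phantom(spec)
                img = compute_images(
                    ph, cohort.seq, cfg.ac, mode=cfg.mode,
                    seed=child_seed(cfg.seed, "acq", les.lesion_id, r),
                    settings=cfg.imaging, kernel=cfg.kernel)
                if cal is not None:
                    img = apply_corrections(img, cal)
                return ph, img
            ph, img = _stage("imaging", les.lesion_id, build)
            boundary = _stage("boundary", les.lesion_id,
                              lambda ph=ph: lesion_boundary(ph))
            views.append((img, boundary))
            if example is None:
                example = img

            def measure(img=img, boundary=boundary, spec=spec):
                broi = largest_diameter(boundary)
                out = []
                for mod in MODALITIES:
                    adj = adjust_endpoints(broi, img.modality(mod), spacings,
                                           boundary, cfg.measure,
                                           modality=mod)
                    q = quality_flag(img.modality(mod), boundary, spacings,
                                     threshold=cfg.measure.cnr_threshold,
                                     modality=mod)
                    out.append({
                        "lesion_id": les.lesion_id,
                        "rotation_deg": spec.lesion_rotation,
                        "modality": mod,
                        "bmode_length_mm": broi.length,
                        "param_length_mm": adj.roi.length,
                        "eb": eb_ratio(adj.roi, broi),
                        "cnr": q.cnr,
                        "low_contrast": adj.low_contrast,
                        "unsure": bool(q.unsure or adj.low_contrast),
                        "label": les.label,
                        "subtype": les.subtype,
                    })
                return out
            rows.extend(_stage("measurement", les.lesion_id, measure))

        ch = _stage("characteristics", les.lesion_id,
                    lambda v=views: lesion_characteristics(v))
        char_rows.append({"lesion_id": les.lesion_id, "label": les.label,
                          "subtype": les.subtype,
                          "depth_mm": ch.depth_mm, "area_mm2": ch.area_mm2,
                          "circularity": ch.circularity,
                          "doa_pd": ch.doa["pd"], "doa_re": ch.doa["re"],
                          "doa_rv": ch.doa["rv"]})

    records = pd.DataFrame(rows)
    characteristics = pd.DataFrame(char_rows)

    model_rows = []
    for subset in FEATURE_SETS:
        try:
            _, roc = model_roc_for_subset(records, subset)
            model_rows.append({"feature_set": "+".join(subset),
                               "auc": roc.auc, "sensitivity": roc.sensitivity,
                               "specificity": roc.specificity, "n": roc.n})
        except ValueError as err:
            model_rows.append({"feature_set": "+".join(subset),
                               "auc": np.nan, "sensitivity": np.nan,
                               "specificity": np.nan, "n": 0})
            log.warning("model %s not fit: %s", "+".join(subset), err)
    model_summary = pd.DataFrame(model_rows)

    corr_eb = _eb_correlations(records, characteristics)
    corr_unsure = _unsure_correlations(records, characteristics)
    ranksum_rows = []
    for mod in MODALITIES:
        sub = records[(records["modality"] == mod) & ~records["unsure"]]
        a = sub.loc[sub["label"] == "malignant", "eb"]
        b = sub.loc[sub["label"] == "benign", "eb"]
        if len(a) and len(b):
            w, p = ranksum(a, b)
            ranksum_rows.append({"modality": mod, "W": w, "p": p,
                                 "median_malignant": a.median(),
                                 "median_benign": b.median()})
    ranksum_eb = pd.DataFrame(ranksum_rows)

    unsure_fraction = {mod: float(records.loc[records["modality"] == mod,
                                              "unsure"].mean())
                       for mod in MODALITIES}
    exclusions = records[records["unsure"]].reset_index(drop=True)
    manifest = {
        "seed": cfg.seed, "mode": cfg.mode,
        "n_lesions": cohort.n_lesions,
        "rotations": list(cohort.rotations),
        "margin_mode": cohort.margin_mode,
        "n_records": len(records),
        "n_excluded": len(exclusions),
        "corrections": cfg.corrections,
        "runtime_s": round(time.perf_counter() - t_start, 2),
    }
    log.info("study complete: %s", manifest)
    return StudyReport(records=records, characteristics=characteristics,
                       model_summary=model_summary, corr_eb=corr_eb,
                       corr_unsure=corr_unsure, ranksum_eb=ranksum_eb,
                       unsure_fraction=unsure_fraction,
                       exclusions=exclusions, manifest=manifest,
                       example_images=example)


def _sample(cohort: CohortSpec):
    from .phantom import sample_cohort
    return sample_cohort(cohort)


def _stage(name: str, lesion_id, fn):
    t0 = time.perf_counter()
    try:
        out = fn()
    except Exception as err:
        where = f" (lesion {lesion_id})" if lesion_id is not None else ""
        raise StageError(f"stage '{name}'{where} failed: {err}") from err
    log.debug("stage %s%s: %.3f s", name,
              f"[{lesion_id}]" if lesion_id is not None else "",
              time.perf_counter() - t0)
    return out


def _eb_correlations(records: pd.DataFrame,
                     characteristics: pd.DataFrame) -> pd.DataFrame:
    props = ["depth_mm", "area_mm2", "circularity",
             "doa_pd", "doa_re", "doa_rv"]
    merged = records[~records["unsure"]].merge(characteristics,
                                               on="lesion_id", how="left")
    out = []
    for mod in MODALITIES:
        sub = merged[merged["modality"] == mod]
        for prop in props:
            x = sub[prop].to_numpy(dtype=float)
            y = sub["eb"].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            try:
                r, p = correlate(x[ok], y[ok], "pearson")
            except ValueError:
                r, p = np.nan, np.nan
            out.append({"modality": mod, "property": prop, "r": r, "p": p})
    return pd.DataFrame(out)


def _unsure_correlations(records: pd.DataFrame,
                         characteristics: pd.DataFrame) -> pd.DataFrame:
    props = ["depth_mm", "area_mm2", "circularity",
             "doa_pd", "doa_re", "doa_rv"]
    counts = records.groupby("lesion_id")["unsure"].sum().rename("n_unsure")
    merged = characteristics.merge(counts, on="lesion_id")
    out = []
    for prop in props:
        x = merged[prop].to_numpy(dtype=float)
        y = merged["n_unsure"].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        try:
            r, p = correlate(x[ok], y[ok], "spearman")
        except ValueError:
            r, p = np.nan, np.nan
        out.append({"property": prop, "spearman_r": r, "p": p})
    return pd.DataFrame(out)


def export_report(report: StudyReport, out_dir) -> list[Path]:
    """Write the report tables (CSV) and example image renderings."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _csv(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False)
        written.append(path)

    _csv(report.records, "eb_records.csv")
    _csv(report.characteristics, "lesion_characteristics.csv")
    _csv(report.model_summary, "model_summary.csv")
    _csv(report.corr_eb, "correlation_eb_properties.csv")
    _csv(report.corr_unsure, "correlation_unsure_properties.csv")
    _csv(report.ranksum_eb, "ranksum_eb.csv")
    _csv(report.exclusions, "exclusions.csv")
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(report.manifest, fh, sort_keys=False)
    written.append(out / "manifest.yaml")
    if report.example_images is not None:
        report.example_images.save_png(out / "example_images.png")
        report.example_images.save_tiff(out / "example_images.tiff")
        written += [out / "example_images.png", out / "example_images.tiff"]
    return written
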