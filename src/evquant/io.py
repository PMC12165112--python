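"""File I/O, run configuration and the end-to-end pipeline.

Interchange formats are deliberately plain: multi-page TIFF for image
stacks (16-bit unsigned with an affine scale recorded in a JSON sidecar;
float TIFF accepted on input), CSV for TFI tables and per-sample calls,
JSON for cutoffs, fits and metrics, YAML or JSON for run configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .classify import ClassifyConfig, CohortReport, classify_cohort
from .quant import QuantConfig, TIRFField, sample_tfi, well_tfi
from .simulate import FieldGroundTruth

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_field_stack",
    "write_field_stack",
    "read_cohort_csv",
    "write_cohort_csv",
    "load_config",
    "save_config",
    "quantify_manifest",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------


def write_field_stack(
    fields: Sequence[TIRFField],
    path,
    truths: Sequence[FieldGroundTruth] | None = None,
) -> None:
    """Write fields as a multi-page 16-bit TIFF plus a JSON sidecar.

    Pixels are affinely scaled to the uint16 range; the common scale factor,
    pixel size and (when given) per-field ground-truth spot lists go into
    ``<path>.json`` so a read round-trips within quantization error.
    """
    path = Path(path)
    if not fields:
        raise ValueError("no fields to write")
    peak = max(float(f.pixels.max()) for f in fields)
    scale = 65535.0 / peak if peak > 0 else 1.0
    pages = np.stack([np.round(f.pixels * scale).astype(np.uint16) for f in fields])
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "scale": scale,
        "pixel_size_um": fields[0].pixel_size_um,
        "channel": fields[0].channel,
        "n_fields": len(fields),
    }
    if truths is not None:
        sidecar["ground_truth"] = [
            {"spots": [list(s) for s in t.spots], "true_field_tfi": t.true_field_tfi}
            for t in truths
        ]
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_field_stack(
    path,
    pages: tuple[int, int] | None = None,
    pixel_size_um: float | None = None,
    channel: str = "",
) -> list[TIRFField]:
    """Read a multi-page TIFF into a list of fields, page order preserved.

    ``pages = (start, stop)`` selects a half-open page range.  When a JSON
    sidecar written by :func:`write_field_stack` exists, its intensity scale
    and pixel size are applied; integer inputs without a sidecar are taken
    as raw intensities.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read TIFF stack: {path}")
    with tifffile.TiffFile(path) as tif:
        n_pages = len(tif.pages)
        if pages is None:
            sel = range(n_pages)
        else:
            start, stop = pages
            if start < 0 or stop > n_pages or start >= stop:
                raise IOError(
                    f"page range [{start}, {stop}) out of bounds for {path} with {n_pages} pages"
                )
            sel = range(start, stop)
        arrays = [tif.pages[i].asarray().astype(float) for i in sel]

    scale = 1.0
    sidecar_path = Path(str(path) + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        scale = float(sidecar.get("scale", 1.0))
        pixel_size_um = pixel_size_um or float(sidecar.get("pixel_size_um", 0.15625))
        channel = channel or str(sidecar.get("channel", ""))
    pixel_size_um = pixel_size_um or 0.15625
    return [
        TIRFField(
            pixels=a / scale,
            pixel_size_um=pixel_size_um,
            field_index=i,
            channel=channel,
        )
        for i, a in zip(sel, arrays)
    ]


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise ValueError(f"{path}: cohort CSV needs sample_id and group columns")
    return df


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, serializable losslessly."""

    quant: QuantConfig = dc_field(default_factory=QuantConfig)
    classify: ClassifyConfig = dc_field(default_factory=ClassifyConfig)
    seed: int = 0
    output_dir: str = "evquant_out"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classify"]["tf_markers"] = dict(d["classify"]["tf_markers"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        quant = QuantConfig(**d.get("quant", {}))
        cd = dict(d.get("classify", {}))
        for key in ("case_groups", "dll3_markers", "combined_markers"):
            if key in cd:
                cd[key] = tuple(cd[key])
        classify = ClassifyConfig(**cd)
        return cls(
            quant=quant,
            classify=classify,
            seed=int(d.get("seed", 0)),
            output_dir=str(d.get("output_dir", "evquant_out")),
            log_level=str(d.get("log_level", "INFO")),
        )


def load_config(path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    return RunConfig.from_dict(data or {})


def save_config(cfg: RunConfig, path) -> None:
    path = Path(path)
    d = cfg.to_dict()
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=1))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def quantify_manifest(manifest: pd.DataFrame, cfg: QuantConfig) -> pd.DataFrame:
    """Quantify every well listed in a manifest into a cohort TFI table.

    Manifest columns: sample_id, group, marker, well_id, path and optional
    page_start/page_stop.  Wells of the same (sample, marker) are averaged
    into the per-sample TFI; the result is a wide table with one column per
    marker.
    """
    needed = {"sample_id", "group", "marker", "well_id", "path"}
    missing = needed - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing column(s): {sorted(missing)}")
    dup = manifest.duplicated(subset=["sample_id", "marker", "well_id"])
    if dup.any():
        raise ValueError("manifest has duplicate (sample_id, marker, well_id) rows")
    records = []
    for (sid, group, marker), rows in manifest.groupby(
        ["sample_id", "group", "marker"], sort=True
    ):
        wells = []
        for _, r in rows.iterrows():
            pages = None
            if "page_start" in r and pd.notna(r.get("page_start")):
                pages = (int(r["page_start"]), int(r["page_stop"]))
            fields = read_field_stack(r["path"], pages=pages, channel=marker)
            wells.append(well_tfi(fields, cfg, well_id=str(r["well_id"]), marker=marker))
        st = sample_tfi(wells, sample_id=str(sid), group=str(group), cv_limit=cfg.cv_limit)
        records.append(
            {"sample_id": st.sample_id, "group": st.group, "marker": marker,
             "tfi": st.tfi, "qc_flag": st.qc_flag}
        )
    long = pd.DataFrame(records)
    wide = long.pivot_table(index=["sample_id", "group"], columns="marker", values="tfi")
    wide = wide.reset_index()
    wide.columns.name = None
    return wide


def _report_to_files(report: CohortReport, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    cutoffs_payload = {
        "control_group": report.cutoffs.control_group,
        "cutoffs": {m: float(v) for m, v in report.cutoffs.cutoffs.items()},
        "method": dict(report.cutoffs.method),
        "meta": {m: dict(v) for m, v in report.cutoffs.meta.items()},
    }
    (out / "cutoffs.json").write_text(json.dumps(cutoffs_payload, indent=1, sort_keys=True))
    report.subtype_calls.to_csv(out / "subtype_calls.csv", index=False)
    report.subtype_prevalence.to_csv(out / "subtype_prevalence.csv", index=False)
    report.dual_calls.to_csv(out / "dual_calls.csv", index=False)
    report.ratio_matrix.to_csv(out / "ratio_matrix.csv", index=False)
    roc_rows = []
    for key, r in report.roc.items():
        set_name, case_name = key.split("|")
        roc_rows.append(
            {"marker_set": set_name, "case_group": case_name, "auc": r.auc,
             "n_cases": r.n_cases, "n_controls": r.n_controls}
        )
    pd.DataFrame(roc_rows).to_csv(out / "roc_auc.csv", index=False)
    metrics_payload = {
        key: {"sensitivity": v[0], "specificity": v[1], "accuracy": v[2]}
        for key, v in report.metrics.items()
    }
    (out / "metrics.json").write_text(json.dumps(metrics_payload, indent=1, sort_keys=True))
    return {
        "cutoffs": cutoffs_payload["cutoffs"],
        "auc": {row["marker_set"] + "|" + row["case_group"]: row["auc"] for row in roc_rows},
        "metrics": metrics_payload,
        "subtype_prevalence": dict(
            zip(report.subtype_prevalence["subtype"], report.subtype_prevalence["fraction"])
        ),
    }


def run_pipeline(
    config: RunConfig,
    cohort_csv=None,
    manifest_csv=None,
    output_dir=None,
) -> dict:
    """Execute quantify → cutoffs → classify and write all artifacts.

    Input is either a cohort TFI table (CSV) or a well manifest pointing at
    TIFF stacks to quantify first.  Writes per-sample calls, cutoffs, ROC
    AUCs and confusion metrics plus ``summary.json`` embedding the exact
    configuration; identical config and inputs produce identical outputs.
    """
    if (cohort_csv is None) == (manifest_csv is None):
        raise ValueError("provide exactly one of cohort_csv or manifest_csv")
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if manifest_csv is not None:
        try:
            manifest = pd.read_csv(manifest_csv)
            cohort = quantify_manifest(manifest, config.quant)
        except Exception as exc:
            raise RuntimeError(f"[quantify] {exc}") from exc
        cohort.to_csv(out / "cohort_tfi.csv", index=False)
    else:
        cohort = read_cohort_csv(cohort_csv)
    try:
        report = classify_cohort(cohort, config.classify)
    except Exception as exc:
        raise RuntimeError(f"[classify] {exc}") from exc
    summary = _report_to_files(report, out)
    summary["config"] = config.to_dict()
    summary["n_samples"] = int(len(cohort))
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
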