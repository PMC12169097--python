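"""End-to-end per-biopsy processing and cohort orchestration.

:func:`process_biopsy` runs one image through the full chain —
colour normalisation, tissue detection, non-contributory-fragment
removal, ROI erosion, collagen segmentation, fibre extraction, the three
trait layers, qFT assembly and CPA.  :func:`analyse_cohort` maps it over
an in-memory cohort; :func:`run_pipeline` is the file-based variant used
by the CLI (reads an image manifest CSV, writes masks, tables and a
manifest carrying the configuration hash).

Images are processed independently — there is no cross-image coupling
before the cohort stage — so a rerun with identical configuration and
inputs is bit-identical apart from file timestamps.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .preprocessing import (
    AnalysisROI,
    TissueMask,
    detect_tissue,
    erode_roi,
    normalize_stain,
    remove_noncontributory,
)
from .qft import QFTMatrix, QFTVector, assemble_qft_vector, compute_cpa, expected_qft_count
from .segmentation import CollagenMask, extract_fibres, segment_collagen
from .stains import SlideImage, get_palette
from .synthetic import CohortBiopsy
from .traits import TraitTable, architecture_traits, deposition_traits, morphometric_traits

logger = logging.getLogger(__name__)

__all__ = ["BiopsyResult", "process_biopsy", "analyse_cohort", "run_pipeline", "load_image"]


@dataclass
class BiopsyResult:
    """Everything the pipeline derives from one biopsy image."""

    biopsy_id: str
    tissue: TissueMask
    roi: AnalysisROI
    collagen: CollagenMask
    fibres: list
    traits: TraitTable
    qft: QFTVector
    cpa_percent: float
    warnings: list[str] = field(default_factory=list)

    @property
    def fibre_table(self) -> pd.DataFrame:
        """Per-fibre CSV table: morphometry plus class."""
        return self.traits.per_fibre.merge(self.traits.per_fibre_deposition, on="fibre_id")


def process_biopsy(image: SlideImage, config: PipelineConfig | None = None) -> BiopsyResult:
    """Run the full single-biopsy analysis chain."""
    cfg = config or PipelineConfig()
    profile = get_palette(cfg.palette)
    warnings: list[str] = []

    norm = normalize_stain(image, profile)
    tissue = detect_tissue(norm, min_fragment_area_um2=cfg.min_fragment_area_um2)
    if tissue.warning:
        warnings.append(tissue.warning)

    # provisional collagen estimate on the whole tissue drives the
    # >90%-fibrosis fragment-removal rule, before the ROI is fixed
    roi_all = AnalysisROI(mask=tissue.mask.copy(), margin_um=0.0)
    coll_all = segment_collagen(
        norm, roi_all, profile, cfg.collagen_threshold, cfg.min_fibre_area_um2
    )
    tissue, removal_report = remove_noncontributory(
        tissue, coll_all.mask & tissue.mask, cfg.fibrosis_fraction_cutoff
    )
    removed = [r for r in removal_report if not r["kept"]]
    if removed:
        warnings.append(f"removed {len(removed)} hyper-fibrotic fragment(s)")

    roi = erode_roi(tissue, cfg.margin_um, image.mpp)
    if roi.dropped_fragments:
        warnings.append(f"{len(roi.dropped_fragments)} fragment(s) eroded away by ROI margin")

    collagen = segment_collagen(
        norm, roi, profile, cfg.collagen_threshold, cfg.min_fibre_area_um2
    )
    if collagen.warning:
        warnings.append(collagen.warning)
    fibres = extract_fibres(
        collagen,
        image.mpp,
        min_fibre_area_um2=cfg.min_fibre_area_um2,
        connectivity=cfg.connectivity,
        branch_cutoff=cfg.branch_cutoff,
    )

    morpho_rows = []
    for f in fibres:
        row = {"fibre_id": f.fibre_id, "fibre_class": f.fibre_class}
        row.update(morphometric_traits(f, image.mpp))
        row.pop("degenerate", None)
        morpho_rows.append(row)
    per_fibre = pd.DataFrame(morpho_rows)
    dep_fibre, dep_slide = deposition_traits(fibres, collagen, roi, norm, image.mpp, profile)
    per_tile = architecture_traits(collagen, norm, roi, cfg.glcm, profile)
    traits = TraitTable(
        per_fibre=per_fibre,
        per_fibre_deposition=dep_fibre,
        per_tile=per_tile,
        slide_deposition=dep_slide,
    )
    qft = assemble_qft_vector(traits, biopsy_id=image.id)

    try:
        cpa = compute_cpa(collagen, tissue, roi)
    except ValueError:
        cpa = float("nan")
        warnings.append("CPA undefined (no tissue in ROI)")
    return BiopsyResult(
        biopsy_id=image.id,
        tissue=tissue,
        roi=roi,
        collagen=collagen,
        fibres=fibres,
        traits=traits,
        qft=qft,
        cpa_percent=cpa,
        warnings=warnings,
    )


def analyse_cohort(
    cohort: list[CohortBiopsy], config: PipelineConfig | None = None
) -> tuple[QFTMatrix, pd.DataFrame]:
    """Process an in-memory synthetic cohort.

    Returns the cohort :class:`~fibroquant.qft.QFTMatrix` and a
    per-biopsy records table (patient, segment, CPA, planted severity).
    """
    cfg = config or PipelineConfig()
    vectors, rows = [], []
    for rec in cohort:
        res = process_biopsy(rec.image, cfg)
        vectors.append(res.qft)
        rows.append(
            {
                "biopsy_id": rec.image.id,
                "patient_id": rec.liver_id,
                "segment_id": rec.segment_id,
                "cpa_percent": res.cpa_percent,
                "planted_severity": rec.truth.planted_severity,
                "n_fibres": res.qft.n_fibres,
            }
        )
    records = pd.DataFrame(rows).set_index("biopsy_id")
    labels = records[["patient_id", "segment_id", "planted_severity"]]
    matrix = QFTMatrix.from_vectors(vectors, labels)
    return matrix, records


def load_image(path, mpp: float | None = None, mpp_default: float = 0.5) -> SlideImage:
    """Read a TIFF/PNG image into a :class:`SlideImage`.

    TIFF resolution metadata is used when present; otherwise
    ``mpp_default`` (20X convention) applies.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            pixels = page.asarray()
            if mpp is None:
                try:
                    xres = page.tags["XResolution"].value
                    mpp = 1e4 * xres[1] / xres[0]  # resolution is px/cm
                except (KeyError, ZeroDivisionError):
                    mpp = None
    else:
        from PIL import Image as PILImage

        pixels = np.asarray(PILImage.open(path).convert("RGB"))
    return SlideImage(pixels=pixels, mpp=mpp or mpp_default, id=path.stem)


def _write_mask(mask: np.ndarray, path: Path) -> None:
    from PIL import Image as PILImage

    PILImage.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(path)


def run_pipeline(config: PipelineConfig, manifest_csv, outdir) -> Path:
    """File-based pipeline: image manifest CSV in, result directory out.

    The manifest needs columns ``image`` (path) and ``patient_id`` (or
    ``liver_id``) and ``segment_id``; optional ``mpp`` and stage-label
    columns are carried through.  Unreadable inputs are recorded and
    skipped; an empty cohort is an error.
    """
    outdir = Path(outdir)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    (outdir / "fibres").mkdir(exist_ok=True)
    table = pd.read_csv(manifest_csv, comment="#")
    if "patient_id" not in table.columns and "liver_id" in table.columns:
        table = table.rename(columns={"liver_id": "patient_id"})

    vectors, rows, errors = [], [], []
    t0 = time.time()
    for _, row in table.iterrows():
        try:
            mpp = float(row["mpp"]) if "mpp" in row and pd.notna(row.get("mpp")) else None
            image = load_image(row["image"], mpp=mpp, mpp_default=config.mpp_default)
            image.id = f"{row['patient_id']}_{row['segment_id']}"
            res = process_biopsy(image, config)
        except Exception as exc:  # keep going; record the failure
            logger.error("failed on %s: %s", row.get("image"), exc)
            errors.append({"image": str(row.get("image")), "error": str(exc)})
            continue
        _write_mask(res.tissue.mask, outdir / "masks" / f"{image.id}_tissue.png")
        _write_mask(res.roi.mask, outdir / "masks" / f"{image.id}_roi.png")
        _write_mask(res.collagen.mask, outdir / "masks" / f"{image.id}_collagen.png")
        if len(res.fibre_table):
            res.fibre_table.to_csv(outdir / "fibres" / f"{image.id}_fibres.csv", index=False)
        vectors.append(res.qft)
        rows.append(
            {
                "biopsy_id": image.id,
                "patient_id": row["patient_id"],
                "segment_id": row["segment_id"],
                "cpa_percent": res.cpa_percent,
                "n_fibres": res.qft.n_fibres,
                "n_warnings": len(res.warnings),
            }
        )
    if not vectors:
        raise RuntimeError("empty cohort: no image processed successfully")

    records = pd.DataFrame(rows).set_index("biopsy_id")
    labels = records[["patient_id", "segment_id"]]
    matrix = QFTMatrix.from_vectors(vectors, labels)

    header = f"# config_hash={config.hash}\n"
    for name, frame in (("qft_matrix", matrix.data), ("biopsy_records", records)):
        path = outdir / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(header)
            frame.to_csv(fh)
    manifest = {
        "config_hash": config.hash,
        "config": config.to_dict(),
        "n_biopsies": len(rows),
        "n_patients": int(records["patient_id"].nunique()),
        "n_qfts": len(vectors[0]),
        "expected_qft_count": expected_qft_count(),
        "errors": errors,
        "elapsed_s": round(time.time() - t0, 2),
        "outputs": ["qft_matrix.csv", "biopsy_records.csv", "masks/", "fibres/"],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
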