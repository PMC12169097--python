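"""Quantitative fibrosis traits (qFTs): histogram statistics per biopsy.

Each histological trait measured on a population of objects (fibres or
texture tiles) is summarised by five histogram statistics — mean, median,
standard deviation, skewness and kurtosis.  One statistic of one trait
over one population is a *quantitative fibrosis trait* (qFT), a single
continuous parameter of the biopsy.  Per-fibre traits are summarised over
three populations (all fibres, assembled only, fine only); architecture
traits over tiles; slide-level deposition densities enter as-is.

Conventions
-----------
* SD uses the population denominator ``n`` (the convention that
  reproduces this package's cohort summary tables).
* Skewness is Fisher–Pearson ``g1``; kurtosis is excess ``g2`` (normal
  -> 0).  With ``n < 3`` or zero variance both are reported as 0 and
  flagged ``degenerate``.
* An empty population yields *missing* statistics (``NaN`` plus a
  ``missing`` flag) — absent assembled fibres are not zero-valued
  biology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocessing import AnalysisROI, TissueMask
from .segmentation import CollagenMask
from .traits import (
    ARCHITECTURE_TRAITS,
    DEPOSITION_FIBRE_TRAITS,
    DEPOSITION_SLIDE_TRAITS,
    MORPHOMETRY_TRAITS,
    REGISTRY_VERSION,
    TraitTable,
)

__all__ = [
    "HistogramStats",
    "QFTVector",
    "QFTMatrix",
    "STATISTICS",
    "POPULATIONS",
    "histogram_stats",
    "assemble_qft_vector",
    "compute_cpa",
    "expected_qft_count",
]

STATISTICS = ("mean", "median", "sd", "skewness", "kurtosis")
POPULATIONS = ("all", "assembled", "fine")


@dataclass
class HistogramStats:
    """Five-number histogram description of one trait distribution."""

    mean: float
    median: float
    sd: float
    skewness: float
    kurtosis: float
    n: int
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {s: getattr(self, s) for s in STATISTICS}


def histogram_stats(values) -> HistogramStats:
    """Mean, median, population SD, g1 skewness, excess kurtosis.

    Empty input returns NaN statistics flagged ``missing``; ``n < 3`` or
    zero variance returns skewness/kurtosis 0 flagged ``degenerate``.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        nan = float("nan")
        return HistogramStats(nan, nan, nan, nan, nan, 0, flags=("missing",))
    mean = float(arr.mean())
    median = float(np.median(arr))
    sd = float(arr.std())  # population denominator
    # zero variance up to float round-off (e.g. quantised intensities)
    if arr.size < 3 or sd <= 1e-12 * max(1.0, abs(mean)):
        return HistogramStats(mean, median, sd, 0.0, 0.0, arr.size, flags=("degenerate",))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        skew = float(sps.skew(arr, bias=True))
        kurt = float(sps.kurtosis(arr, bias=True, fisher=True))
    return HistogramStats(mean, median, sd, skew, kurt, arr.size)


@dataclass
class QFTVector:
    """The full named qFT parameter set of one biopsy."""

    biopsy_id: str
    values: dict[str, float]
    flags: dict[str, tuple[str, ...]] = field(default_factory=dict)
    n_fibres: int = 0
    n_assembled: int = 0
    n_fine: int = 0
    n_tiles: int = 0
    registry_version: str = REGISTRY_VERSION

    def __len__(self) -> int:
        return len(self.values)

    def names(self) -> list[str]:
        return list(self.values)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.biopsy_id)


@dataclass
class QFTMatrix:
    """Cohort matrix: one qFT row per biopsy plus label columns."""

    data: pd.DataFrame  # index = biopsy_id, columns = qFT names
    labels: pd.DataFrame  # index = biopsy_id; liver/segment/stage columns

    @classmethod
    def from_vectors(cls, vectors: list[QFTVector], labels: pd.DataFrame) -> "QFTMatrix":
        names = vectors[0].names()
        for v in vectors[1:]:
            if v.names() != names:
                raise ValueError(f"qFT name set mismatch for biopsy {v.biopsy_id}")
        data = pd.DataFrame([v.as_series() for v in vectors])
        return cls(data=data, labels=labels.loc[data.index])


def expected_qft_count(
    n_morphometry: int = len(MORPHOMETRY_TRAITS),
    n_deposition_fibre: int = len(DEPOSITION_FIBRE_TRAITS),
    n_deposition_slide: int = len(DEPOSITION_SLIDE_TRAITS),
    n_architecture: int = len(ARCHITECTURE_TRAITS),
) -> int:
    """Registry parameter count for the default composition scheme.

    Per-fibre layers expand over 3 populations x 5 statistics;
    architecture over tiles x 5 statistics; slide-level traits enter
    as-is.  Default registry: (13 + 7) x 3 x 5 + 7 x 5 + 5 = 340.
    """
    per_fibre = (n_morphometry + n_deposition_fibre) * len(POPULATIONS) * len(STATISTICS)
    return per_fibre + n_architecture * len(STATISTICS) + n_deposition_slide


def _population_frames(per_fibre: pd.DataFrame) -> dict[str, pd.DataFrame]:
    return {
        "all": per_fibre,
        "assembled": per_fibre[per_fibre["fibre_class"] == "assembled"],
        "fine": per_fibre[per_fibre["fibre_class"] == "fine"],
    }


def assemble_qft_vector(traits: TraitTable, biopsy_id: str) -> QFTVector:
    """Build the biopsy's qFT vector from its trait tables.

    qFT names are ``<layer>.<trait>.<population>.<statistic>``;
    slide-level deposition traits are named
    ``deposition.<trait>.slide.value``.  Name order is deterministic for
    a fixed registry.
    """
    values: dict[str, float] = {}
    flags: dict[str, tuple[str, ...]] = {}

    per_fibre = traits.per_fibre
    dep = traits.per_fibre_deposition
    if "fibre_class" not in dep.columns and len(per_fibre) and len(dep) == len(per_fibre):
        dep = dep.assign(fibre_class=per_fibre["fibre_class"].values)

    def emit(layer: str, trait: str, pop: str, series) -> None:
        st = histogram_stats(series.dropna()) if len(series) else histogram_stats([])
        for stat_name, val in st.as_dict().items():
            name = f"{layer}.{trait}.{pop}.{stat_name}"
            values[name] = val
            if st.flags:
                flags[name] = st.flags

    for layer, table, trait_names in (
        ("morphometry", per_fibre, MORPHOMETRY_TRAITS),
        ("deposition", dep, DEPOSITION_FIBRE_TRAITS),
    ):
        pops = _population_frames(table) if len(table) else {
            p: table for p in POPULATIONS
        }
        for trait in trait_names:
            for pop in POPULATIONS:
                frame = pops[pop]
                series = frame[trait] if trait in frame.columns else pd.Series(dtype=float)
                emit(layer, trait, pop, series)

    for trait in ARCHITECTURE_TRAITS:
        series = (
            traits.per_tile[trait] if trait in traits.per_tile.columns else pd.Series(dtype=float)
        )
        emit("architecture", trait, "tiles", series)

    for trait in DEPOSITION_SLIDE_TRAITS:
        values[f"deposition.{trait}.slide.value"] = float(
            traits.slide_deposition.get(trait, 0.0)
        )

    n_fibres = len(per_fibre)
    n_assembled = int((per_fibre["fibre_class"] == "assembled").sum()) if n_fibres else 0
    return QFTVector(
        biopsy_id=biopsy_id,
        values=values,
        flags=flags,
        n_fibres=n_fibres,
        n_assembled=n_assembled,
        n_fine=n_fibres - n_assembled,
        n_tiles=len(traits.per_tile),
    )


def compute_cpa(
    collagen: CollagenMask | np.ndarray,
    tissue: TissueMask | np.ndarray,
    roi: AnalysisROI | np.ndarray,
) -> float:
    """Collagen proportionate area: 100 x |collagen n ROI| / |tissue n ROI|.

    Raises ``ValueError`` when no tissue falls inside the ROI (CPA
    undefined).  Invariant to fibre labelling and classification — it is
    a pure pixel-area ratio.
    """
    cmask = collagen.mask if isinstance(collagen, CollagenMask) else np.asarray(collagen, bool)
    tmask = tissue.mask if isinstance(tissue, TissueMask) else np.asarray(tissue, bool)
    rmask = roi.mask if isinstance(roi, AnalysisROI) else np.asarray(roi, bool)
    denom = int((tmask & rmask).sum())
    if denom == 0:
        raise ValueError("CPA undefined: no tissue inside the ROI")
    return 100.0 * float((cmask & rmask).sum()) / denom
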