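"""Phenotypic trait quantification: morphometry, deposition, architecture.

Three trait layers are computed per biopsy, mirroring how phenotypic
fibrosis platforms decompose the histology:

* **morphometry** — 13 per-fibre shape descriptors;
* **deposition** — 12 collagen-amount descriptors: 7 per fibre
  (optical-density statistics and ROI coverage) plus 5 slide-level
  densities (CPA, fibre count density, assembled/fine area fractions,
  mean nearest-fibre distance);
* **architecture** — 7 grey-level co-occurrence (GLCM) texture features
  computed on rectangular tiles of the collagen optical-density channel.

The exact published trait lists of commercial platforms are proprietary;
this registry is an explicit, versioned stand-in with the same layer
structure and counts, built from standard morphometric and Haralick
descriptors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, cKDTree
from skimage.feature import graycomatrix, graycoprops
from skimage.measure import regionprops

from .preprocessing import AnalysisROI
from .segmentation import CollagenMask, FibreObject
from .stains import SlideImage, StainProfile, collagen_channel, get_palette

logger = logging.getLogger(__name__)

__all__ = [
    "GLCMSpec",
    "TraitTable",
    "REGISTRY_VERSION",
    "MORPHOMETRY_TRAITS",
    "DEPOSITION_FIBRE_TRAITS",
    "DEPOSITION_SLIDE_TRAITS",
    "ARCHITECTURE_TRAITS",
    "morphometric_traits",
    "deposition_traits",
    "glcm_features",
    "architecture_traits",
    "feret_diameters",
]

REGISTRY_VERSION = "fq-registry-1.0"

MORPHOMETRY_TRAITS = (
    "area_um2",
    "perimeter_um",
    "skeleton_length_um",
    "mean_width_um",
    "feret_max_um",
    "feret_min_um",
    "aspect_ratio",
    "circularity",
    "solidity",
    "eccentricity",
    "tortuosity",
    "branch_count",
    "endpoint_count",
)

DEPOSITION_FIBRE_TRAITS = (
    "od_mean",
    "od_median",
    "od_sd",
    "od_min",
    "od_max",
    "integrated_od_um2",
    "roi_area_fraction",
)

DEPOSITION_SLIDE_TRAITS = (
    "cpa_percent",
    "fibre_density_per_mm2",
    "assembled_area_fraction",
    "fine_area_fraction",
    "mean_nearest_fibre_distance_um",
)

ARCHITECTURE_TRAITS = (
    "entropy",
    "contrast",
    "homogeneity",
    "energy",
    "correlation",
    "dissimilarity",
    "cluster_shade",
)


@dataclass(frozen=True)
class GLCMSpec:
    """Grey-level co-occurrence configuration for architecture tiles."""

    tile_width_px: int = 256
    tile_height_px: int = 256
    distances: tuple[int, ...] = (2,)
    angles_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    grey_levels: int = 32
    symmetric: bool = True
    normalised: bool = True
    min_tile_coverage: float = 0.5

    def __post_init__(self):
        if self.grey_levels < 2:
            raise ValueError("grey_levels must be >= 2")
        if not self.distances or not self.angles_deg:
            raise ValueError("at least one offset (distance, angle) is required")


@dataclass
class TraitTable:
    """Per-biopsy trait tables for the three phenotype layers."""

    per_fibre: pd.DataFrame  # fibre_id, fibre_class, 13 morphometric traits
    per_fibre_deposition: pd.DataFrame  # fibre_id, 7 deposition traits
    per_tile: pd.DataFrame  # tile_id, bounds, 7 architecture traits
    slide_deposition: dict[str, float]
    registry_version: str = REGISTRY_VERSION
    flags: dict = field(default_factory=dict)


def feret_diameters(coords: np.ndarray) -> tuple[float, float]:
    """Max and min Feret diameters (px) of a pixel set.

    Computed on the convex hull of the pixel *corners* (each pixel
    contributes its four corners), so a 1-px-wide line has min Feret 1.
    Min Feret by rotating calipers: the smallest width over hull-edge
    normal directions.
    """
    pts = coords[:, None, :] + np.array(
        [[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]]
    )
    pts = pts.reshape(-1, 2)
    if len(np.unique(coords[:, 0])) == 1 or len(np.unique(coords[:, 1])) == 1:
        # degenerate row/col: hull is a rectangle; handle directly
        spans = pts.max(axis=0) - pts.min(axis=0)
        lo, hi = sorted(spans)
        return float(np.hypot(*spans)), float(lo)
    hull = ConvexHull(pts)
    hp = pts[hull.vertices]
    diff = hp[:, None, :] - hp[None, :, :]
    feret_max = float(np.sqrt((diff**2).sum(-1)).max())
    edges = np.diff(np.vstack([hp, hp[:1]]), axis=0)
    norms = np.linalg.norm(edges, axis=1)
    normals = np.column_stack([-edges[:, 1], edges[:, 0]]) / norms[:, None]
    widths = np.ptp(hp @ normals.T, axis=0)
    return feret_max, float(widths.min())


def _skeleton_length_px(skel_coords: np.ndarray) -> float:
    """Polyline length of a skeleton: axial links count 1, diagonal sqrt(2)."""
    if len(skel_coords) < 2:
        return 0.0
    pix = set(map(tuple, skel_coords))
    axial = diag = 0
    for r, c in pix:
        for dr, dc in ((0, 1), (1, 0)):
            if (r + dr, c + dc) in pix:
                axial += 1
        for dr, dc in ((1, 1), (1, -1)):
            if (r + dr, c + dc) in pix:
                diag += 1
    return axial + diag * np.sqrt(2.0)


def morphometric_traits(fibre: FibreObject, mpp: float) -> dict[str, float]:
    """The registry's 13 morphometric traits for one fibre (um / um^2).

    Degenerate fibres (zero skeleton length) fall back to
    ``tortuosity = 1`` and ``mean_width = sqrt(area)`` and are flagged
    via the ``"degenerate"`` key.
    """
    if fibre.n_pixels == 0:
        raise ValueError("empty fibre")
    local, _ = fibre.local_mask()
    props = regionprops(local.astype(np.uint8))[0]
    area_um2 = fibre.n_pixels * mpp**2
    perimeter_um = max(props.perimeter, 1.0) * mpp
    feret_max_px, feret_min_px = feret_diameters(fibre.pixel_coords)
    skel_len_um = _skeleton_length_px(fibre.skeleton_coords) * mpp

    degenerate = skel_len_um <= 0
    if degenerate:
        mean_width = float(np.sqrt(area_um2))
        tortuosity = 1.0
    else:
        mean_width = area_um2 / skel_len_um
        tortuosity = skel_len_um / (feret_max_px * mpp)

    out = {
        "area_um2": area_um2,
        "perimeter_um": perimeter_um,
        "skeleton_length_um": skel_len_um,
        "mean_width_um": mean_width,
        "feret_max_um": feret_max_px * mpp,
        "feret_min_um": feret_min_px * mpp,
        "aspect_ratio": feret_max_px / max(feret_min_px, 1e-12),
        "circularity": 4.0 * np.pi * area_um2 / perimeter_um**2,
        "solidity": float(props.solidity),
        "eccentricity": float(props.eccentricity),
        "tortuosity": tortuosity,
        "branch_count": float(fibre.branch_count),
        "endpoint_count": float(fibre.endpoint_count),
    }
    if degenerate:
        out["degenerate"] = True
    return out


def deposition_traits(
    fibres: list[FibreObject],
    collagen: CollagenMask,
    roi: AnalysisROI,
    image: SlideImage,
    mpp: float,
    palette: str | StainProfile = "trichrome",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """The registry's 12 deposition traits.

    Returns ``(per_fibre_table, slide_level)``: 7 per-fibre entries
    (collagen-channel OD statistics, integrated OD, ROI coverage) and
    5 slide-level densities.  CPA here is collagen area over ROI area;
    the ROI is tissue by construction, so this matches collagen pixel
    area over total (analysed) tissue area.
    """
    profile = palette if isinstance(palette, StainProfile) else get_palette(palette)
    conc = collagen_channel(image.pixels, profile)
    rows = []
    for f in fibres:
        vals = conc[f.pixel_coords[:, 0], f.pixel_coords[:, 1]]
        in_roi = roi.mask[f.pixel_coords[:, 0], f.pixel_coords[:, 1]]
        rows.append(
            {
                "fibre_id": f.fibre_id,
                "od_mean": float(vals.mean()),
                "od_median": float(np.median(vals)),
                "od_sd": float(vals.std()),
                "od_min": float(vals.min()),
                "od_max": float(vals.max()),
                "integrated_od_um2": float(vals.sum()) * mpp**2,
                "roi_area_fraction": float(in_roi.mean()),
            }
        )
    per_fibre = pd.DataFrame(rows, columns=["fibre_id", *DEPOSITION_FIBRE_TRAITS])

    roi_px = int(roi.mask.sum())
    mask = collagen.mask if isinstance(collagen, CollagenMask) else collagen
    slide: dict[str, float] = dict.fromkeys(DEPOSITION_SLIDE_TRAITS, 0.0)
    if roi_px:
        slide["cpa_percent"] = 100.0 * float((mask & roi.mask).sum()) / roi_px
        roi_mm2 = roi_px * mpp**2 / 1e6
        slide["fibre_density_per_mm2"] = len(fibres) / roi_mm2
    if fibres:
        total = sum(f.n_pixels for f in fibres)
        assembled = sum(f.n_pixels for f in fibres if f.fibre_class == "assembled")
        slide["assembled_area_fraction"] = assembled / total
        slide["fine_area_fraction"] = (total - assembled) / total
        if len(fibres) >= 2:
            centroids = np.array([f.pixel_coords.mean(axis=0) for f in fibres])
            d, _ = cKDTree(centroids).query(centroids, k=2)
            slide["mean_nearest_fibre_distance_um"] = float(d[:, 1].mean()) * mpp
    return per_fibre, slide


def _quantise(tile: np.ndarray, levels: int, vmax: float | None = None) -> np.ndarray:
    """Quantise a non-negative float tile to ``levels`` grey levels."""
    tile = np.asarray(tile)
    if np.issubdtype(tile.dtype, np.integer):
        if tile.max() >= levels:
            raise ValueError("integer tile exceeds grey_levels")
        return tile.astype(np.uint8)
    vmax = float(tile.max()) if vmax is None else vmax
    if vmax <= 0:
        return np.zeros(tile.shape, dtype=np.uint8)
    q = np.floor(np.clip(tile / vmax, 0.0, 1.0) * levels).astype(np.uint8)
    return np.minimum(q, levels - 1)


def glcm_features(
    tile: np.ndarray, spec: GLCMSpec, vmax: float | None = None
) -> dict[str, float]:
    """Seven GLCM texture features of a tile, averaged over offsets.

    Entropy is in bits (base-2 log of the normalised, symmetric GLCM).
    A constant tile produces entropy 0, contrast 0, homogeneity 1,
    energy 1; its correlation is undefined (zero variance) and reported
    as 0 with the ``"zero_variance"`` flag.
    """
    if tile.ndim != 2 or min(tile.shape) < 2:
        raise ValueError("tile must be 2-D and at least 2x2")
    q = _quantise(tile, spec.grey_levels, vmax)
    angles = [np.deg2rad(a) for a in spec.angles_deg]
    P = graycomatrix(
        q,
        distances=list(spec.distances),
        angles=angles,
        levels=spec.grey_levels,
        symmetric=spec.symmetric,
        normed=spec.normalised,
    )
    feats = {k: float(np.mean(graycoprops(P, k))) for k in
             ("contrast", "homogeneity", "energy", "dissimilarity")}

    # entropy, correlation and cluster shade by hand, per offset then averaged
    ent, corr, shade = [], [], []
    zero_var = False
    i = np.arange(spec.grey_levels, dtype=float)
    for di in range(P.shape[2]):
        for ai in range(P.shape[3]):
            p = P[:, :, di, ai].astype(float)
            s = p.sum()
            if s > 0 and not spec.normalised:
                p = p / s
            nz = p[p > 0]
            ent.append(float(-(nz * np.log2(nz)).sum()))
            pi = p.sum(axis=1)
            pj = p.sum(axis=0)
            mu_i, mu_j = float(i @ pi), float(i @ pj)
            var_i = float(((i - mu_i) ** 2) @ pi)
            var_j = float(((i - mu_j) ** 2) @ pj)
            ii, jj = np.meshgrid(i, i, indexing="ij")
            shade.append(float(((ii + jj - mu_i - mu_j) ** 3 * p).sum()))
            if var_i <= 0 or var_j <= 0:
                corr.append(0.0)
                zero_var = True
            else:
                cov = float(((ii - mu_i) * (jj - mu_j) * p).sum())
                corr.append(cov / np.sqrt(var_i * var_j))
    feats["entropy"] = float(np.mean(ent))
    feats["correlation"] = float(np.mean(corr))
    feats["cluster_shade"] = float(np.mean(shade))
    if zero_var:
        feats["zero_variance"] = True
    return feats


def architecture_traits(
    collagen: CollagenMask,
    image: SlideImage,
    roi: AnalysisROI,
    spec: GLCMSpec = GLCMSpec(),
    palette: str | StainProfile = "trichrome",
) -> pd.DataFrame:
    """GLCM texture rows for rectangular tiles covering the ROI.

    Tiles a fixed grid over the ROI bounding box, keeps tiles whose ROI
    coverage is at least ``spec.min_tile_coverage``, and computes
    :func:`glcm_features` on the collagen-channel optical density.  Grey
    levels are quantised against the 99.5th percentile of the channel
    within the ROI (deterministic, robust to outliers).
    """
    profile = palette if isinstance(palette, StainProfile) else get_palette(palette)
    cols = ["tile_id", "row0", "col0", "row1", "col1", *ARCHITECTURE_TRAITS]
    if not roi.mask.any():
        logger.warning("%s: empty ROI; no architecture tiles", image.id)
        return pd.DataFrame(columns=cols)
    conc = collagen_channel(image.pixels, profile)
    vmax = float(np.percentile(conc[roi.mask], 99.5))
    if vmax <= 0:
        vmax = 1.0
    rs, cs = np.nonzero(roi.mask)
    r0, r1, c0, c1 = rs.min(), rs.max() + 1, cs.min(), cs.max() + 1
    th, tw = spec.tile_height_px, spec.tile_width_px
    rows = []
    tile_id = 0
    for tr in range(r0, r1, th):
        for tc in range(c0, c1, tw):
            sub_roi = roi.mask[tr : tr + th, tc : tc + tw]
            coverage = sub_roi.sum() / (th * tw)
            if coverage < spec.min_tile_coverage:
                continue
            tile = conc[tr : tr + th, tc : tc + tw]
            feats = glcm_features(tile, spec, vmax=vmax)
            rows.append(
                {
                    "tile_id": tile_id,
                    "row0": tr,
                    "col0": tc,
                    "row1": min(tr + th, r1),
                    "col1": min(tc + tw, c1),
                    **{k: feats[k] for k in ARCHITECTURE_TRAITS},
                }
            )
            tile_id += 1
    if not rows:
        logger.warning("%s: no tile met the %.0f%% ROI-coverage rule",
                       image.id, 100 * spec.min_tile_coverage)
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols)
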