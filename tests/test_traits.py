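"""Morphometry, deposition and GLCM architecture traits."""

import numpy as np
import pytest
from skimage.draw import disk

from fibroquant.preprocessing import AnalysisROI
from fibroquant.segmentation import CollagenMask, extract_fibres
from fibroquant.stains import TRICHROME, SlideImage, od_to_rgb
from fibroquant.traits import (
    ARCHITECTURE_TRAITS,
    DEPOSITION_FIBRE_TRAITS,
    DEPOSITION_SLIDE_TRAITS,
    MORPHOMETRY_TRAITS,
    GLCMSpec,
    architecture_traits,
    deposition_traits,
    glcm_features,
    morphometric_traits,
)

from conftest import MPP

SIMPLE_SPEC = GLCMSpec(grey_levels=2, distances=(1,), angles_deg=(0.0,))


def render_trichrome(collagen_mask: np.ndarray, counter_conc=0.35) -> SlideImage:
    """Render a mask with the trichrome reference profile (no noise)."""
    S = TRICHROME.matrix
    od = (
        collagen_mask[..., None] * 1.0 * S[0]
        + (~collagen_mask[..., None]) * counter_conc * S[1]
    )
    return SlideImage(od_to_rgb(od), mpp=1.0, id="render")


class TestMorphometry:
    def test_registry_has_thirteen_traits(self):
        assert len(MORPHOMETRY_TRAITS) == 13

    def test_digital_disk(self):
        mask = np.zeros((70, 70), bool)
        rr, cc = disk((35, 35), 20.5)
        mask[rr, cc] = True
        fibre = extract_fibres(mask, mpp=1.0)[0]
        m = morphometric_traits(fibre, mpp=1.0)
        assert 0.9 <= m["circularity"] <= 1.1
        assert m["solidity"] >= 0.98
        assert 0.95 <= m["aspect_ratio"] <= 1.1

    def test_elongated_rectangle(self):
        mask = np.zeros((20, 110), bool)
        mask[5:15, 5:105] = True
        fibre = extract_fibres(mask, mpp=1.0)[0]
        m = morphometric_traits(fibre, mpp=1.0)
        assert 9.0 <= m["aspect_ratio"] <= 11.0
        assert m["solidity"] >= 0.98
        assert m["feret_min_um"] == pytest.approx(10.0, abs=0.5)

    def test_solidity_bounded_for_convex_shapes(self):
        for shape in [(10, 10), (3, 40), (25, 7)]:
            mask = np.zeros((np.array(shape) + 10), dtype=bool)
            mask[5 : 5 + shape[0], 5 : 5 + shape[1]] = True
            fibre = extract_fibres(mask, mpp=1.0, min_fibre_area_um2=1.0)[0]
            m = morphometric_traits(fibre, mpp=1.0)
            assert m["solidity"] <= 1.0 + 1e-9

    def test_translation_invariance(self):
        base = np.zeros((120, 120), bool)
        base[10:40, 10:70] = True
        base[20:25, 60:90] = True
        shifted = np.roll(np.roll(base, 17, axis=0), 23, axis=1)
        m1 = morphometric_traits(extract_fibres(base, 1.0)[0], 1.0)
        m2 = morphometric_traits(extract_fibres(shifted, 1.0)[0], 1.0)
        for k in MORPHOMETRY_TRAITS:
            assert m1[k] == pytest.approx(m2[k], rel=1e-9), k

    def test_scaling_with_resolution(self):
        """Area ~ mpp^2, lengths ~ mpp under 2x resampling, within 5%."""
        mask = np.zeros((60, 60), bool)
        rr, cc = disk((30, 30), 18.5)
        mask[rr, cc] = True
        fine = np.zeros((120, 120), bool)  # same disk imaged at half the mpp
        rr, cc = disk((60, 60), 37.0)
        fine[rr, cc] = True
        m_coarse = morphometric_traits(extract_fibres(mask, 1.0)[0], mpp=1.0)
        m_fine = morphometric_traits(extract_fibres(fine, 0.5)[0], mpp=0.5)
        assert m_fine["area_um2"] == pytest.approx(m_coarse["area_um2"], rel=0.05)
        assert m_fine["feret_max_um"] == pytest.approx(m_coarse["feret_max_um"], rel=0.05)
        assert m_fine["perimeter_um"] == pytest.approx(m_coarse["perimeter_um"], rel=0.05)

    def test_degenerate_single_pixelish_fibre_flagged(self):
        mask = np.zeros((10, 10), bool)
        mask[4, 4] = True
        fibre = extract_fibres(mask, 1.0, min_fibre_area_um2=0.5)[0]
        m = morphometric_traits(fibre, 1.0)
        assert m.get("degenerate") is True
        assert m["tortuosity"] == 1.0
        assert m["mean_width_um"] == pytest.approx(np.sqrt(m["area_um2"]))


class TestGLCM:
    def test_constant_tile(self):
        f = glcm_features(np.zeros((8, 8), int), SIMPLE_SPEC)
        assert f["entropy"] == 0.0
        assert f["contrast"] == 0.0
        assert f["homogeneity"] == 1.0
        assert f["energy"] == 1.0
        assert f["correlation"] == 0.0 and f.get("zero_variance") is True

    def test_checkerboard_closed_form(self):
        """Symmetric normalised GLCM of a 2-level checkerboard at (1, 0 deg)
        has two off-diagonal cells of probability 0.5 each."""
        cb = np.indices((8, 8)).sum(axis=0) % 2
        f = glcm_features(cb, SIMPLE_SPEC)
        assert f["contrast"] == pytest.approx(1.0)
        assert f["entropy"] == pytest.approx(1.0)  # bits
        assert f["homogeneity"] == pytest.approx(0.5)

    def test_entropy_bounded_by_level_count(self):
        rng = np.random.default_rng(0)
        spec = GLCMSpec(grey_levels=8, distances=(1,), angles_deg=(0.0, 90.0))
        tile = rng.integers(0, 8, size=(32, 32))
        f = glcm_features(tile, spec)
        assert f["entropy"] <= np.log2(8**2) + 1e-9

    def test_entropy_energy_invariant_under_level_permutation(self):
        """Order-reversal of grey levels permutes GLCM cells: entropy and
        energy are unchanged, contrast generally is not."""
        rng = np.random.default_rng(1)
        spec = GLCMSpec(grey_levels=6, distances=(1,), angles_deg=(0.0,))
        tile = rng.integers(0, 6, size=(24, 24))
        a = glcm_features(tile, spec)
        b = glcm_features(5 - tile, spec)
        assert a["entropy"] == pytest.approx(b["entropy"])
        assert a["energy"] == pytest.approx(b["energy"])

    def test_tiny_tile_rejected(self):
        with pytest.raises(ValueError):
            glcm_features(np.zeros((1, 5), int), SIMPLE_SPEC)


class TestDeposition:
    def test_registry_has_twelve_traits(self):
        assert len(DEPOSITION_FIBRE_TRAITS) + len(DEPOSITION_SLIDE_TRAITS) == 12

    def test_full_collagen_roi_conserves_fractions(self):
        mask = np.zeros((300, 300), bool)
        mask[20:280, 20:280] = True
        image = render_trichrome(mask)
        roi = AnalysisROI(mask=mask.copy(), margin_um=0.0)
        collagen = CollagenMask(mask=mask.copy(), threshold=0.2)
        fibres = extract_fibres(collagen, mpp=1.0)
        per_fibre, slide = deposition_traits(fibres, collagen, roi, image, 1.0)
        assert slide["cpa_percent"] == pytest.approx(100.0)
        assert slide["assembled_area_fraction"] + slide["fine_area_fraction"] == pytest.approx(1.0)
        assert per_fibre["roi_area_fraction"].iloc[0] == pytest.approx(1.0)

    def test_uniform_collagen_has_negligible_od_spread(self):
        mask = np.zeros((120, 120), bool)
        mask[30:90, 30:90] = True
        image = render_trichrome(mask)
        roi = AnalysisROI(mask=np.ones_like(mask), margin_um=0.0)
        collagen = CollagenMask(mask=mask, threshold=0.2)
        fibres = extract_fibres(collagen, mpp=1.0)
        per_fibre, _ = deposition_traits(fibres, collagen, roi, image, 1.0)
        assert per_fibre["od_sd"].iloc[0] <= 0.02

    def test_empty_fibre_list_gives_zero_slide_traits(self):
        empty = CollagenMask(mask=np.zeros((64, 64), bool), threshold=0.2)
        roi = AnalysisROI(mask=np.ones((64, 64), bool), margin_um=0.0)
        image = render_trichrome(np.zeros((64, 64), bool))
        per_fibre, slide = deposition_traits([], empty, roi, image, 1.0)
        assert per_fibre.empty
        assert slide["cpa_percent"] == 0.0
        assert slide["fibre_density_per_mm2"] == 0.0


class TestArchitecture:
    def test_registry_has_seven_traits(self):
        assert len(ARCHITECTURE_TRAITS) == 7

    def test_roi_smaller_than_tile(self):
        mask = np.zeros((200, 200), bool)
        mask[50:150, 50:150] = True  # 100x100 ROI
        image = render_trichrome(mask & False)
        spec = GLCMSpec(tile_width_px=128, tile_height_px=128)
        roi = AnalysisROI(mask=mask, margin_um=0.0)
        collagen = CollagenMask(mask=np.zeros_like(mask), threshold=0.2)
        table = architecture_traits(collagen, image, roi, spec)
        # 100x100 of ROI inside a 128x128 tile: coverage 61% -> one tile
        assert len(table) == 1

    def test_uniform_texture_has_low_between_tile_spread(self):
        rng = np.random.default_rng(3)
        mask = rng.random((256, 512)) < 0.3  # iid speckle everywhere
        image = render_trichrome(mask)
        roi = AnalysisROI(mask=np.ones_like(mask), margin_um=0.0)
        collagen = CollagenMask(mask=mask, threshold=0.2)
        spec = GLCMSpec(tile_width_px=64, tile_height_px=64)
        table = architecture_traits(collagen, image, roi, spec)
        assert len(table) == 32
        assert table["entropy"].std() <= 0.05 * table["entropy"].mean()

    def test_fine_septa_have_higher_entropy_than_coarse_nodules(self):
        from fibroquant.preprocessing import detect_tissue, erode_roi
        from fibroquant.segmentation import segment_collagen
        from fibroquant.synthetic import PhenotypeParams, generate_biopsy

        spec = GLCMSpec(tile_width_px=64, tile_height_px=64)
        means = {}
        for label, nodule_um in (("fine", 80.0), ("coarse", 240.0)):
            params = PhenotypeParams(
                severity=0.5, n_fragments=1, nodule_diameter_um=nodule_um, seed=2
            )
            image, _ = generate_biopsy(params, 512, 256, MPP)
            tissue = detect_tissue(image)
            roi = erode_roi(tissue, 50.0, image.mpp)
            collagen = segment_collagen(image, roi, "trichrome")
            table = architecture_traits(collagen, image, roi, spec)
            means[label] = table["entropy"].mean()
        assert means["fine"] > means["coarse"]

    def test_empty_roi_gives_empty_table_with_columns(self):
        image = render_trichrome(np.zeros((64, 64), bool))
        roi = AnalysisROI(mask=np.zeros((64, 64), bool), margin_um=0.0)
        collagen = CollagenMask(mask=np.zeros((64, 64), bool), threshold=0.2)
        table = architecture_traits(collagen, image, roi)
        assert table.empty and "entropy" in table.columns
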