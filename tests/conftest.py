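import numpy as np
import pytest
from scipy import ndimage as ndi

from fibroquant.preprocessing import TissueMask, detect_tissue, erode_roi
from fibroquant.segmentation import segment_collagen
from fibroquant.synthetic import PhenotypeParams, generate_biopsy

# desk-scale rendering used throughout the suite: 512x256 px at 2 um/px
IMG_W, IMG_H, MPP = 512, 256, 2.0


@pytest.fixture(scope="session")
def default_params():
    """Noise-free mid-severity phenotype; two tissue fragments."""
    return PhenotypeParams(severity=0.5, n_fragments=2, seed=11)


@pytest.fixture(scope="session")
def biopsy(default_params):
    return generate_biopsy(default_params, IMG_W, IMG_H, MPP)


@pytest.fixture(scope="session")
def preprocessed(biopsy):
    """(image, truth, tissue mask, 50-um ROI, collagen mask) of the fixture biopsy."""
    image, truth = biopsy
    tissue = detect_tissue(image)
    roi = erode_roi(tissue, 50.0, image.mpp)
    collagen = segment_collagen(image, roi, "trichrome")
    return image, truth, tissue, roi, collagen


def square_tissue(side: int, pad: int = 10) -> TissueMask:
    """Solid square tissue mask fixture for erosion geometry oracles."""
    mask = np.zeros((side + 2 * pad, side + 2 * pad), dtype=bool)
    mask[pad : pad + side, pad : pad + side] = True
    labels, n = ndi.label(mask, structure=np.ones((3, 3), int))
    return TissueMask(mask=mask, fragment_labels=labels, n_fragments=n)
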