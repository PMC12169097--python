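"""Stain models and optical-density arithmetic.

Brightfield histology follows the Beer–Lambert law: a pixel's optical
density ``OD = -log(I / I0)`` is (to good approximation) a non-negative
linear combination of per-stain absorption vectors.  Collagen stains used
for fibrosis work come in two common palettes:

* Masson's trichrome — collagen in aniline blue-green, tissue counterstained
  red (Biebrich scarlet / acid fuchsin);
* Picro-Sirius red (PSR) — collagen in red, tissue in pale picric yellow.

Each palette is described by a :class:`StainProfile` holding two unit OD
vectors.  The profiles below are the package's reference profiles: the
synthetic generator renders with them and the colour-normalisation stage
maps estimated per-image vectors back onto them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: white point of an 8-bit brightfield scan
I0 = 255.0

#: OD below which a pixel is treated as background (glass/white)
BACKGROUND_OD = 0.15


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class StainProfile:
    """Two-stain absorption model: collagen stain plus counterstain.

    ``collagen`` and ``counterstain`` are unit vectors in OD space
    (rows of the 2x3 stain matrix).
    """

    name: str
    collagen: tuple[float, float, float]
    counterstain: tuple[float, float, float]

    @property
    def matrix(self) -> np.ndarray:
        """2x3 stain matrix; row 0 = collagen, row 1 = counterstain."""
        return np.vstack([_unit(self.collagen), _unit(self.counterstain)])


#: Masson's trichrome: blue-green collagen absorbs red/green light.
TRICHROME = StainProfile(
    name="trichrome",
    collagen=(0.74, 0.61, 0.28),
    counterstain=(0.18, 0.73, 0.66),
)

#: Picro-Sirius red: red collagen, pale-yellow picric counterstain.
PSR = StainProfile(
    name="psr",
    collagen=(0.15, 0.75, 0.64),
    counterstain=(0.10, 0.30, 0.95),
)

_PALETTES = {"trichrome": TRICHROME, "psr": PSR}


def get_palette(name: str) -> StainProfile:
    try:
        return _PALETTES[name]
    except KeyError:
        raise ValueError(
            f"unknown stain palette {name!r}; expected one of {sorted(_PALETTES)}"
        ) from None


def rgb_to_od(pixels: np.ndarray) -> np.ndarray:
    """Convert 8-bit RGB to optical density (natural log)."""
    arr = np.asarray(pixels, dtype=float)
    return -np.log(np.clip(arr, 1.0, I0) / I0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Convert optical density back to 8-bit RGB (rounded, clipped)."""
    rgb = I0 * np.exp(-np.asarray(od, dtype=float))
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def stain_concentrations(pixels: np.ndarray, profile_matrix: np.ndarray) -> np.ndarray:
    """Unmix an RGB image into per-stain concentration maps.

    Least-squares projection of each pixel's OD onto the rows of
    ``profile_matrix`` (2x3), clipped to non-negative concentrations.
    Returns an array of shape ``(2, H, W)``.
    """
    od = rgb_to_od(pixels)
    flat = od.reshape(-1, 3)
    conc, *_ = np.linalg.lstsq(profile_matrix.T, flat.T, rcond=None)
    conc = np.clip(conc, 0.0, None)
    return conc.reshape(2, *od.shape[:2])


def collagen_channel(pixels: np.ndarray, profile: StainProfile) -> np.ndarray:
    """Collagen-stain concentration map (H x W) of an RGB image."""
    return stain_concentrations(pixels, profile.matrix)[0]


@dataclass
class SlideImage:
    """An RGB brightfield image with physical pixel size.

    Attributes
    ----------
    pixels : uint8 array, shape (H, W, 3)
    mpp : float
        Microns per pixel (isotropic).
    id : str
        Stable identifier used in reports and file names.
    """

    pixels: np.ndarray
    mpp: float
    id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("SlideImage requires an (H, W, 3) RGB array")
        if self.pixels.dtype != np.uint8:
            self.pixels = np.clip(np.rint(self.pixels), 0, 255).astype(np.uint8)
        if not (self.mpp > 0):
            raise ValueError("mpp must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def area_um2(self) -> float:
        h, w = self.shape
        return h * w * self.mpp**2
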