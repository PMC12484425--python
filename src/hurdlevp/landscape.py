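"""Land-cover rasters and window-based landscape metrics.

Habitat around a sampling site is summarised over a square buffer of a
categorical land-cover raster: class proportions, an adjacency-based
clumpiness (aggregation) index of the merged forest mask, and the Shannon
(marginal) entropy of class composition.
"""
from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

#: Land-cover legend shared by the whole package.
LEGEND: Mapping[int, str] = {
    1: "broadleaf_forest",
    2: "coniferous_forest",
    3: "mixed_forest",
    4: "seminatural_herbaceous",
    5: "wetland",
    6: "water",
    7: "urban",
    8: "agriculture",
}

#: Codes merged into the binary forest mask used for clumpiness.
FOREST_CODES: tuple[int, ...] = (1, 2, 3)

#: The four class proportions used as model covariates.
HABITAT_COVARIATE_CODES: tuple[int, ...] = (1, 2, 3, 4)


@dataclass
class LandscapeRaster:
    """Categorical land-cover raster for one epoch.

    Parameters
    ----------
    categories
        Integer array (rows x cols) of legend codes.
    pixel_size
        Pixel edge length in metres.
    epoch
        Year label of the land-cover epoch (e.g. 2000).
    legend
        Mapping code -> class name.
    """

    categories: np.ndarray
    pixel_size: float = 20.0
    epoch: int = 2000
    legend: Mapping[int, str] = field(default_factory=lambda: dict(LEGEND))

    def __post_init__(self) -> None:
        self.categories = np.asarray(self.categories)
        if self.categories.ndim != 2:
            raise ValueError("categories must be a 2-D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        codes = np.unique(self.categories)
        illegal = [c for c in codes if c not in self.legend]
        if illegal:
            raise ValueError(f"illegal category codes present: {illegal}")
        if codes.size < 2:
            raise ValueError("raster must contain at least 2 categories")

    @property
    def shape(self) -> tuple[int, int]:
        return self.categories.shape

    def write_tiff(self, path: str | Path) -> None:
        """Write the raster as an 8-bit TIFF with a legend sidecar CSV."""
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.categories.astype(np.uint8))
        with open(path.with_suffix(".legend.csv"), "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["code", "name", "pixel_size_m", "epoch"])
            for code, name in sorted(self.legend.items()):
                w.writerow([code, name, self.pixel_size, self.epoch])


def _window_slices(
    raster: LandscapeRaster, center: tuple[int, int], buffer_side: float
) -> tuple[slice, slice]:
    """Pixel slices of a square buffer (metres) centred on a pixel index.

    A buffer partially outside the raster is clipped to the intersection
    with a warning; a buffer fully outside raises ValueError.
    """
    nrow, ncol = raster.shape
    side_px = max(1, int(round(buffer_side / raster.pixel_size)))
    half = side_px // 2
    r, c = int(center[0]), int(center[1])
    r0, r1 = r - half, r - half + side_px
    c0, c1 = c - half, c - half + side_px
    if r1 <= 0 or c1 <= 0 or r0 >= nrow or c0 >= ncol:
        raise ValueError("buffer lies entirely outside the raster")
    if r0 < 0 or c0 < 0 or r1 > nrow or c1 > ncol:
        warnings.warn(
            "buffer extends beyond the raster; using the intersection",
            stacklevel=3,
        )
    return slice(max(r0, 0), min(r1, nrow)), slice(max(c0, 0), min(c1, ncol))


def buffer_proportions(
    raster: LandscapeRaster,
    center: tuple[int, int],
    buffer_side: float = 500.0,
) -> dict[int, float]:
    """Class-proportion map over a square buffer around ``center`` (pixels).

    Returns fractions for every legend code (zero where absent); fractions
    sum to 1 over the full legend.
    """
    rs, cs = _window_slices(raster, center, buffer_side)
    window = raster.categories[rs, cs]
    n = window.size
    return {
        code: float(np.count_nonzero(window == code)) / n
        for code in raster.legend
    }


def clumpiness(
    window: np.ndarray,
    focal_class_set: Sequence[int] = FOREST_CODES,
) -> float:
    """Clumpiness (aggregation) index of a focal class set, in [-1, 1].

    With P the focal proportion and G = g_ff / sum_k g_fk the like-adjacency
    fraction (rook adjacency, double-count convention, within-window only):

        CLUMPY = (G - P) / P        if G < P and P < 0.5
                 (G - P) / (1 - P)  otherwise

    -1 is a maximally disaggregated pattern (checkerboard), +1 a single
    solid block. P = 0 or P = 1 yields NaN (undefined).
    """
    window = np.asarray(window)
    if window.size == 0:
        raise ValueError("window must be non-empty")
    mask = np.isin(window, list(focal_class_set))
    p = mask.mean()
    if p == 0.0 or p == 1.0:
        return float("nan")
    m = mask.astype(np.int64)
    # double-count convention: each ordered pair of rook neighbours counts once
    like = 2 * (
        np.count_nonzero(m[:, :-1] & m[:, 1:])
        + np.count_nonzero(m[:-1, :] & m[1:, :])
    )
    # adjacencies involving a focal pixel = sum over focal pixels of their
    # in-window rook degree
    deg = np.zeros_like(m)
    deg[:, :-1] += 1
    deg[:, 1:] += 1
    deg[:-1, :] += 1
    deg[1:, :] += 1
    total = int((deg * m).sum())
    if total == 0:
        return float("nan")
    g = like / total
    if g < p and p < 0.5:
        return float((g - p) / p)
    return float((g - p) / (1.0 - p))


def marginal_entropy(window: np.ndarray, base: float = 2.0) -> float:
    """Shannon entropy of category composition in a window (bits by default).

    0 * log 0 is treated as 0; the maximum is log(K) for K observed classes.
    """
    window = np.asarray(window)
    if window.size == 0:
        raise ValueError("window must be non-empty")
    _, counts = np.unique(window, return_counts=True)
    p = counts / window.size
    p = p[p > 0]
    return float(-(p * (np.log(p) / np.log(base))).sum())


def habitat_features(
    raster: LandscapeRaster,
    center: tuple[int, int],
    buffer_side: float = 500.0,
    entropy_base: float = 2.0,
) -> dict[str, float]:
    """The six habitat covariates for one buffer.

    Four class proportions (broadleaf, conifer, mixed, semi-natural), the
    clumpiness of the merged forest mask, and the marginal entropy of the
    full composition. Clumpiness is NaN when the window is forest-free or
    all-forest.
    """
    rs, cs = _window_slices(raster, center, buffer_side)
    window = raster.categories[rs, cs]
    n = window.size
    props = {
        code: float(np.count_nonzero(window == code)) / n
        for code in HABITAT_COVARIATE_CODES
    }
    return {
        "hab_prop_broadleaf": props[1],
        "hab_prop_conifer": props[2],
        "hab_prop_mixed": props[3],
        "hab_prop_seminatural": props[4],
        "hab_clumpiness": clumpiness(window),
        "hab_entropy": marginal_entropy(window, base=entropy_base),
    }
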