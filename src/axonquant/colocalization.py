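"""Colocalization, puncta-association and PLA dot-count metrics.

Manders coefficients M1/M2 measure the fraction of one channel's integrated
intensity lying inside the other channel's thresholded region.  Puncta
association is the fraction of channel-A centroids lying within a given
radius of any channel-B centroid.  PLA dots are assigned to the central or
peripheral growth-cone domain by point-in-polygon tests (boundary dots count
as central) and summarized as a C/P ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon
from shapely.prepared import prep
from skimage.filters import threshold_otsu

__all__ = [
    "PunctumSet",
    "PlaResult",
    "manders",
    "puncta_association",
    "pla_counts",
]


@dataclass
class PunctumSet:
    """Detected puncta centroids (um) for one channel."""

    channel: str
    centroids: np.ndarray  # (N, 2)
    intensities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        if self.intensities is not None:
            self.intensities = np.asarray(self.intensities, dtype=float)
            if len(self.intensities) != len(self.centroids):
                raise ValueError("intensities/centroids length mismatch")

    def __len__(self) -> int:
        return len(self.centroids)


@dataclass
class PlaResult:
    n_central: int
    n_peripheral: int
    n_outside: int

    @property
    def cp_ratio(self) -> float:
        if self.n_peripheral == 0:
            raise ValueError("C/P ratio undefined: no peripheral dots")
        return self.n_central / self.n_peripheral


def manders(
    ch1: np.ndarray,
    ch2: np.ndarray,
    mask1: np.ndarray | None = None,
    mask2: np.ndarray | None = None,
) -> tuple[float, float]:
    """Manders split coefficients from thresholded masks.

    M1 = sum of ch1 over (mask1 & mask2) / sum of ch1 over mask1; M2 is
    symmetric.  Missing masks are derived by Otsu thresholding of the
    corresponding channel.  A zero denominator raises (undefined, never 0).
    """
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if ch1.shape != ch2.shape:
        raise ValueError("channel shapes differ")
    m1 = np.asarray(mask1, dtype=bool) if mask1 is not None else ch1 > threshold_otsu(ch1)
    m2 = np.asarray(mask2, dtype=bool) if mask2 is not None else ch2 > threshold_otsu(ch2)
    both = m1 & m2
    d1, d2 = ch1[m1].sum(), ch2[m2].sum()
    if d1 <= 0 or d2 <= 0:
        raise ValueError("Manders coefficient undefined: zero total signal in a mask")
    return float(ch1[both].sum() / d1), float(ch2[both].sum() / d2)


def puncta_association(set_a: PunctumSet, set_b: PunctumSet, radius: float = 0.5) -> float:
    """Fraction of A puncta within ``radius`` um of some B punctum."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if len(set_a) == 0:
        raise ValueError("puncta_association: empty channel-A set")
    if len(set_b) == 0:
        return 0.0
    tree = cKDTree(set_b.centroids)
    dists, _ = tree.query(set_a.centroids, k=1)
    return float(np.count_nonzero(dists <= radius) / len(set_a))


def pla_counts(dots: PunctumSet, central: Polygon, peripheral: Polygon) -> PlaResult:
    """Assign PLA dots to growth-cone domains and count them.

    Dots on the shared central/peripheral boundary count as central
    (documented tie-break); dots outside both regions are reported as
    ``n_outside``, never silently dropped.
    """
    pc, pp = prep(central), prep(peripheral)
    n_c = n_p = n_o = 0
    for xy in dots.centroids:
        pt = Point(xy)
        if pc.covers(pt):
            n_c += 1
        elif pp.covers(pt):
            n_p += 1
        else:
            n_o += 1
    return PlaResult(n_c, n_p, n_o)
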