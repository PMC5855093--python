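"""Growth-cone morphometrics: domain partition, filopodia, ROI intensity.

A growth cone is described per frame by its outline polygon (um
coordinates), a central-domain polygon (traced manually or derived by
inward erosion), and optional intensity channels.  A filopodium is a
protrusion from the periphery whose skeleton length is >= 2 um (inclusive).
Dynamics over a 5-min recording sampled every 5 s are summarized as
formation / retraction / stable events with lifetimes and active-phase
elongation/retraction speeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import draw, graph, morphology

__all__ = [
    "GrowthConeFrame",
    "FilopodiumTrace",
    "DynamicsSummary",
    "RoiIntensity",
    "partition_domains",
    "detect_filopodia",
    "classify_dynamics",
    "roi_intensity",
    "tip_accumulation",
]


@dataclass
class GrowthConeFrame:
    """One time point of a growth cone: outline, domains, optional channels."""

    time: float
    outline: np.ndarray  # (N, 2) closed polygon, um
    central_domain: np.ndarray | None = None
    intensity: np.ndarray | None = None
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.outline = np.asarray(self.outline, dtype=float)
        if self.central_domain is not None:
            self.central_domain = np.asarray(self.central_domain, dtype=float)
        if not Polygon(self.outline).is_valid:
            raise ValueError("outline polygon is not simple")
        if self.intensity is not None and self.pixel_size is None:
            raise ValueError("intensity channel supplied without pixel_size metadata")


@dataclass
class FilopodiumTrace:
    """Per-frame length series of one filopodium over a recording.

    ``lengths`` is aligned to the recording frames (one value every
    ``frame_interval`` seconds); 0 marks frames where the protrusion is
    absent, NaN marks missing measurements (an error for dynamics).
    A frame counts as "present" iff length >= 2 um.
    ``skeletons`` optionally carries the base-to-tip skeleton polyline
    (um coordinates) for each frame, used for tip-marker sampling.
    """

    filopodium_id: str
    lengths: np.ndarray
    frame_interval: float = 5.0
    skeletons: list[np.ndarray | None] | None = None

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if np.nanmin(self.lengths) < 0:
            raise ValueError("lengths must be >= 0")

    def present(self, threshold: float = 2.0) -> np.ndarray:
        return self.lengths >= threshold

    @property
    def birth_frame(self) -> int:
        idx = np.flatnonzero(self.present())
        return int(idx[0]) if idx.size else -1

    @property
    def death_frame(self) -> int:
        idx = np.flatnonzero(self.present())
        return int(idx[-1]) if idx.size else -1


@dataclass
class DynamicsSummary:
    n_formation: int
    n_retraction: int
    n_stable: int
    lifetimes: list[float] = field(default_factory=list)
    elongation_speeds: list[float] = field(default_factory=list)
    retraction_speeds: list[float] = field(default_factory=list)


@dataclass
class RoiIntensity:
    region: str
    mean_intensity: float  # background-corrected; may be negative


def partition_domains(
    frame: GrowthConeFrame,
    mode: Literal["manual", "auto"] = "auto",
    erosion_um: float = 3.0,
) -> tuple[Polygon, Polygon]:
    """Split the growth cone into central and peripheral domain polygons.

    Manual mode returns the supplied central domain; auto mode erodes the
    outline inward by ``erosion_um`` (a stand-in for manual tracing).  The
    peripheral domain is always outline minus central.
    """
    outline = Polygon(frame.outline)
    if mode == "manual":
        if frame.central_domain is None:
            raise ValueError("manual mode requires frame.central_domain")
        central = Polygon(frame.central_domain)
    else:
        central = outline.buffer(-erosion_um)
        if central.is_empty or central.area == 0:
            raise ValueError(
                f"erosion by {erosion_um} um annihilates the outline; use a smaller erosion_um"
            )
    if not outline.contains(central.representative_point()):
        raise ValueError("central domain must lie inside the outline")
    peripheral = outline.difference(central)
    return central, peripheral


def detect_filopodia(
    mask: np.ndarray,
    pixel_size: float,
    min_length_um: float = 2.0,
    opening_radius_um: float = 0.6,
) -> list[dict]:
    """Find peripheral protrusions of a binary growth-cone mask.

    Protrusion candidates are connected components of the mask minus its
    morphological opening by a disk (radius ``opening_radius_um``); the
    length of each is the geodesic distance from its base (pixels adjacent
    to the opened body) to its farthest pixel.  Protrusions with length >=
    ``min_length_um`` (inclusive) are filopodia.

    Returns a list of dicts with keys ``length_um``, ``tip`` (row, col px),
    ``base`` (row, col px), and ``pixels`` (component coordinate array).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    r_open = max(int(round(opening_radius_um / pixel_size)), 1)
    body = morphology.opening(mask, morphology.disk(r_open))
    protrusions = mask & ~body
    labels, nlab = ndimage.label(protrusions)
    base_ring = ndimage.binary_dilation(body) & protrusions
    out: list[dict] = []
    for lab in range(1, nlab + 1):
        comp = labels == lab
        starts = np.argwhere(comp & base_ring)
        if starts.size == 0:
            continue  # floating speckle, not attached to the body
        costs = np.where(comp, 1.0, np.inf)
        mcp = graph.MCP_Geometric(costs)
        dist, _ = mcp.find_costs([tuple(s) for s in starts])
        dist = np.where(comp, dist, -np.inf)
        tip = np.unravel_index(int(np.argmax(dist)), dist.shape)
        # corrected chain-code step weights (0.948 axial / 1.343 diagonal)
        # remove the staircase bias of the naive (1, sqrt 2) pixel metric
        # coarsened-polyline chord sum removes the staircase bias of the
        # naive pixel metric; +1 px covers the half-pixel lost to
        # rasterization at the body surface and at the tip
        path = np.asarray(mcp.traceback(tip))
        nodes = np.vstack([path[::5], path[-1:]]).astype(float)
        length = (
            float(np.sum(np.linalg.norm(np.diff(nodes, axis=0), axis=1))) + 1.0
        ) * pixel_size
        if length >= min_length_um:
            out.append(
                {
                    "length_um": length,
                    "tip": tuple(int(v) for v in tip),
                    "base": tuple(int(v) for v in starts[0]),
                    "pixels": np.argwhere(comp),
                }
            )
    return out


def _active_run_speeds(
    lengths: np.ndarray, dt: float, threshold: float
) -> tuple[float | None, float | None]:
    """Mean per-interval speed during the monotone growth run ending at the
    maximum, and the monotone shrink run after it down to < threshold."""
    imax = int(np.argmax(lengths))
    # growth: walk back while strictly increasing
    i = imax
    while i > 0 and lengths[i - 1] < lengths[i]:
        i -= 1
    elong = None
    if imax > i:
        incs = np.diff(lengths[i : imax + 1])
        elong = float(np.mean(incs / dt))
    # retraction: walk forward while strictly decreasing, stop once < threshold
    j = imax
    while j + 1 < len(lengths) and lengths[j + 1] < lengths[j]:
        j += 1
        if lengths[j] < threshold:
            break
    retr = None
    if j > imax:
        decs = -np.diff(lengths[imax : j + 1])
        retr = float(np.mean(decs / dt))
    return elong, retr


def classify_dynamics(
    traces: list[FilopodiumTrace],
    recording: float = 300.0,
    sampling: float = 5.0,
    threshold: float = 2.0,
) -> DynamicsSummary:
    """Summarize filopodial dynamics over one recording.

    A filopodium is a "formation" if its first present frame is after frame
    0, a "retraction" if it drops below the length threshold and never
    recovers within the recording, and "stable" if present in every frame;
    one trace may count as both formation and retraction.  Lifetime is the
    total time the length stayed >= threshold.  Speeds come from the active
    (monotone) phases only.
    """
    n_frames = int(round(recording / sampling))
    summary = DynamicsSummary(0, 0, 0)
    for tr in traces:
        if abs(tr.frame_interval - sampling) > 0.1 * sampling:
            warnings.warn(
                f"trace {tr.filopodium_id!r}: frame interval {tr.frame_interval}s "
                f"differs from expected {sampling}s",
                stacklevel=2,
            )
        if np.isnan(tr.lengths).any():
            raise ValueError(f"trace {tr.filopodium_id!r} has missing frames")
        if len(tr.lengths) < n_frames:
            raise ValueError(
                f"trace {tr.filopodium_id!r} covers {len(tr.lengths)} frames; "
                f"recording needs {n_frames}"
            )
        lengths = tr.lengths[:n_frames]
        present = lengths >= threshold
        if not present.any():
            continue
        first, last = int(np.flatnonzero(present)[0]), int(np.flatnonzero(present)[-1])
        if present.all():
            summary.n_stable += 1
        else:
            if first > 0:
                summary.n_formation += 1
            if last < n_frames - 1:
                summary.n_retraction += 1
        summary.lifetimes.append(float(np.count_nonzero(present) * sampling))
        elong, retr = _active_run_speeds(lengths, sampling, threshold)
        if elong is not None:
            summary.elongation_speeds.append(elong)
        if retr is not None:
            summary.retraction_speeds.append(retr)
    return summary


def _polygon_mask(poly_um: np.ndarray, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    return draw.polygon2mask(shape, np.asarray(poly_um, dtype=float) / pixel_size)


def roi_intensity(
    image: np.ndarray,
    pixel_size: float,
    region_polygon: np.ndarray,
    background_polygon: np.ndarray,
    region: str = "global",
) -> RoiIntensity:
    """Background-corrected mean intensity of a traced ROI.

    The background ROI is the same outline placed in an adjacent area; its
    mean is subtracted from the region mean (negative results are reported,
    not clipped).  Overlapping region/background ROIs are an error.
    """
    image = np.asarray(image, dtype=float)
    m_region = _polygon_mask(region_polygon, image.shape, pixel_size)
    m_bg = _polygon_mask(background_polygon, image.shape, pixel_size)
    if not m_region.any() or not m_bg.any():
        raise ValueError("ROI rasterizes to zero pixels; check coordinates and pixel_size")
    if (m_region & m_bg).any():
        raise ValueError("region and background ROIs overlap")
    return RoiIntensity(region, float(image[m_region].mean() - image[m_bg].mean()))


def tip_accumulation(
    trace: FilopodiumTrace,
    marker: np.ndarray,
    pixel_size: float,
    enrichment_factor: float = 1.5,
    tip_um: float = 1.0,
    threshold: float = 2.0,
) -> tuple[bool, list[bool]]:
    """Score tip enrichment of a marker along a filopodium.

    For each present frame, marker intensity is sampled along the stored
    skeleton polyline; the tip ROI is the distal ``tip_um`` of arc length and
    the frame is enriched iff mean(tip) >= enrichment_factor x mean(rest).
    The per-filopodium call is enrichment in >= 50% of present frames.
    """
    if trace.skeletons is None:
        raise ValueError("trace carries no skeleton polylines")
    marker = np.asarray(marker, dtype=float)
    calls: list[bool] = []
    for frame, skel in enumerate(trace.skeletons):
        if skel is None or trace.lengths[frame] < threshold:
            continue
        skel = np.asarray(skel, dtype=float)
        seg = np.linalg.norm(np.diff(skel, axis=0), axis=1)
        arc_from_tip = np.concatenate([[0.0], np.cumsum(seg[::-1])])[::-1]
        if arc_from_tip[0] <= tip_um:
            raise ValueError(
                f"filopodium {trace.filopodium_id!r} frame {frame}: shorter than tip ROI"
            )
        coords = (skel / pixel_size).T  # (row, col) um -> px
        vals = ndimage.map_coordinates(marker, coords, order=1, mode="nearest")
        tip_sel = arc_from_tip <= tip_um
        calls.append(bool(vals[tip_sel].mean() >= enrichment_factor * vals[~tip_sel].mean()))
    if not calls:
        raise ValueError("no present frames with skeletons to score")
    return sum(calls) >= 0.5 * len(calls), calls
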