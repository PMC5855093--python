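"""Seeded generators for every input type, with ground-truth labels.

Each generator emulates one class of input the quantification modules
consume — two-brachium tract images, 1-D granule tracks, contact-aligned
domain-count time courses, growth-cone mask sequences with scripted
filopodia, encounter-event geometries, and punctum point sets — and emits a
machine-readable truth record sufficient to score the corresponding
analysis without re-deriving it.  Identical seeds give bit-identical
output; all randomness comes from one ``numpy.random.Generator`` per call.

The named fixture profiles (``fig6b``, ``fig2c``, ``fig2i_homo``, the
382/118 domain baseline, the 84/100 puncta set) are minimal integer
reconstructions of published summary percentages; they are reconstructions
with known ground truth, not measured data, and are labeled as such in
their truth records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import draw as skdraw

from .encounters import EncounterEvent, FilopodialContact
from .granule_transport import DomainCounts, MotionClass, Track
from .growth_cone import FilopodiumTrace
from .tract_sorting import ReferenceLine, TractImage

__all__ = [
    "GeneratorConfig",
    "make_tract_image",
    "default_reference_line",
    "make_track_fixture",
    "make_domain_timecourse",
    "make_gc_mask",
    "make_gc_sequence",
    "make_encounter",
    "make_puncta_fixture",
]


@dataclass
class GeneratorConfig:
    """Shared generator defaults: seed, calibration and noise level."""

    seed: int = 0
    pixel_size: float = 0.5
    frame_interval: float = 30.0
    noise_sigma: float = 0.0


# --------------------------------------------------------------------------
# tract images
# --------------------------------------------------------------------------

def make_tract_image(
    missorted_fraction: float,
    band_centers: tuple[float, float] = (30.0, 70.0),
    band_sigma: float = 5.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    pixel_size: float = 0.5,
    shape: tuple[int, int] = (100, 200),
    amplitude: float = 100.0,
) -> tuple[TractImage, dict]:
    """Two-channel tract image with a tunable missorted dorsal-dye fraction.

    Columns run across the tract.  ``band_centers`` (um) are the sorted
    (ventral-brachium, where dorsal axons belong) and missorted
    (dorsal-brachium) band positions.  The dorsal channel carries mass
    ``1-f`` in the sorted band and ``f`` in the missorted band; the ventral
    channel occupies the dorsal brachium, where ventral axons sort, so the
    combined profile always shows two bands.
    """
    f = float(missorted_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError("missorted_fraction must be in [0, 1]")
    c_sorted, c_missorted = band_centers
    if abs(c_missorted - c_sorted) < 2 * band_sigma:
        warnings.warn("bands overlap within 2 sigma; automatic split may be ambiguous", stacklevel=2)
    rng = np.random.default_rng(seed)
    x = np.arange(shape[1]) * pixel_size

    def band(center: float) -> np.ndarray:
        return amplitude * np.exp(-0.5 * ((x - center) / band_sigma) ** 2)

    dorsal_1d = (1.0 - f) * band(c_sorted) + f * band(c_missorted)
    ventral_1d = band(c_missorted)
    dorsal = np.tile(dorsal_1d, (shape[0], 1))
    ventral = np.tile(ventral_1d, (shape[0], 1))
    if noise_sigma > 0:
        dorsal = np.clip(dorsal + rng.normal(0, noise_sigma, shape), 0, None)
        ventral = np.clip(ventral + rng.normal(0, noise_sigma, shape), 0, None)
    orientation = "high" if c_missorted > c_sorted else "low"
    image = TractImage(dorsal, ventral, pixel_size, orientation)
    truth = {
        "missorted_fraction": f,
        "band_centers_um": tuple(band_centers),
        "band_sigma_um": band_sigma,
        "midpoint_um": 0.5 * (c_sorted + c_missorted),
        "dm_side": orientation,
        "synthetic": True,
    }
    return image, truth


def default_reference_line(image: TractImage) -> ReferenceLine:
    """Horizontal mid-image line spanning the full tract width."""
    row = (image.dorsal.shape[0] - 1) / 2
    return ReferenceLine((row, 0.0), (row, float(image.dorsal.shape[1] - 1)))


# --------------------------------------------------------------------------
# granule tracks
# --------------------------------------------------------------------------

# fig6b composition: minimal integer reconstruction of the published
# 54.72 / 24.53 / 20.75 % motion-class split over 53 tracks
_FIG6B = {"static": 29, "retrograde": 13, "anterograde": 11}


def _confined_track(rng: np.random.Generator, n: int, step_sigma: float, clip: float) -> np.ndarray:
    pos = np.empty(n)
    pos[0] = rng.uniform(0, 100)
    for i in range(1, n):
        step = rng.normal(0, step_sigma)
        nxt = pos[i - 1] + step
        nxt = np.clip(nxt, pos[0] - clip, pos[0] + clip)
        pos[i] = nxt
    return pos


def _drift_track(rng: np.random.Generator, n: int, v: float, noise: float, dt: float) -> np.ndarray:
    t = np.arange(n) * dt
    return rng.uniform(0, 100) + v * t + rng.normal(0, noise, n)


def make_track_fixture(
    profile: str = "fig6b",
    seed: int = 7,
    n: int = 10,
    drift: float = 0.05,
    duration: float = 60.0,
    dt: float = 1.0,
) -> tuple[list[Track], list[MotionClass]]:
    """Granule tracks with known motion-class labels.

    ``fig6b``: 53 tracks of 61 samples at 1 Hz — 29 confined (reflected
    random walk, step sigma 0.2 um, excursion hard-clipped to 1.5 um),
    13 retrograde and 11 anterograde (drift -/+0.05 um/s, additive noise
    sigma 0.05 um).  Kinematics keep every track >= 0.5 um from the 2 um
    decision boundary.  ``custom``: ``n`` tracks with signed ``drift``.
    """
    rng = np.random.default_rng(seed)
    nsamp = int(round(duration / dt)) + 1
    times = np.arange(nsamp) * dt
    tracks: list[Track] = []
    labels: list[MotionClass] = []
    if profile == "fig6b":
        plan = (
            [(MotionClass.STATIC_OSCILLATORY, 0.0)] * _FIG6B["static"]
            + [(MotionClass.RETROGRADE, -0.05)] * _FIG6B["retrograde"]
            + [(MotionClass.ANTEROGRADE, 0.05)] * _FIG6B["anterograde"]
        )
        order = rng.permutation(len(plan))
        for k, idx in enumerate(order):
            label, v = plan[idx]
            if label is MotionClass.STATIC_OSCILLATORY:
                pos = _confined_track(rng, nsamp, step_sigma=0.2, clip=1.5)
            else:
                pos = _drift_track(rng, nsamp, v, noise=0.05, dt=dt)
            tracks.append(Track(f"g{k:03d}", times, pos))
            labels.append(label)
    elif profile == "custom":
        for k in range(n):
            if drift == 0.0:
                pos = _confined_track(rng, nsamp, step_sigma=0.2, clip=1.5)
                label = MotionClass.STATIC_OSCILLATORY
            else:
                pos = _drift_track(rng, nsamp, drift, noise=0.05, dt=dt)
                label = MotionClass.ANTEROGRADE if drift > 0 else MotionClass.RETROGRADE
            tracks.append(Track(f"g{k:03d}", times, pos))
            labels.append(label)
    else:
        raise ValueError(f"unknown profile {profile!r}; expected 'fig6b' or 'custom'")
    return tracks, labels


# --------------------------------------------------------------------------
# domain-count time courses
# --------------------------------------------------------------------------

_BASELINE_PERIPHERAL = 0.236  # published isolated-growth-cone peripheral share


def make_domain_timecourse(
    contact: str = "none",
    seed: int = 3,
    n_per_bin: int = 25,
    n_bins: int = 20,
    bin_s: float = 30.0,
    baseline: float = _BASELINE_PERIPHERAL,
) -> tuple[list[DomainCounts], list[dict]]:
    """Central/peripheral granule counts per 30-s bin around contact (T=0).

    ``none``: flat baseline occupancy; pooled counts reproduce the baseline
    fraction exactly (largest-remainder allocation, seed shuffles which bins
    carry the remainder).  ``heterotypic``: occupancy ramps after T=0 to a
    sustained 0.45 plateau within 3.5 min.  ``homotypic``: transient rise to
    0.37 at 3 min, back to baseline by 8 min.  Truth records the intended
    occupancy per bin.
    """
    rng = np.random.default_rng(seed)
    if contact == "none":
        t_bins = np.arange(n_bins) * bin_s
        occ = np.full(n_bins, baseline)
        total_p = int(round(baseline * n_per_bin * n_bins))
        base, extra = divmod(total_p, n_bins)
        per_bin = np.full(n_bins, base, dtype=int)
        per_bin[rng.choice(n_bins, size=extra, replace=False)] += 1
    elif contact in ("heterotypic", "homotypic"):
        n_pre = 4
        t_bins = np.arange(-n_pre, n_bins) * bin_s
        occ = np.full(len(t_bins), baseline)
        for i, t in enumerate(t_bins):
            if t <= 0:
                continue
            if contact == "heterotypic":
                occ[i] = baseline + (0.45 - baseline) * min(t / 210.0, 1.0)
            else:
                if t <= 180.0:
                    occ[i] = baseline + (0.3675 - baseline) * (t / 180.0)
                elif t <= 480.0:
                    occ[i] = 0.3675 + (baseline - 0.3675) * ((t - 180.0) / 300.0)
        per_bin = np.rint(occ * n_per_bin).astype(int)
    else:
        raise ValueError(f"unknown contact {contact!r}")
    counts = [
        DomainCounts(float(t), int(n_per_bin - k), int(k)) for t, k in zip(t_bins, per_bin)
    ]
    truth = [
        {"time_bin": float(t), "occupancy_peripheral": float(o), "synthetic": True}
        for t, o in zip(t_bins, occ)
    ]
    return counts, truth


# --------------------------------------------------------------------------
# growth-cone masks and filopodium schedules
# --------------------------------------------------------------------------

def make_gc_mask(
    spike_lengths: list[float],
    angles: list[float] | None = None,
    pixel_size: float = 0.1,
    shape: tuple[int, int] = (240, 240),
    body_axes: tuple[float, float] = (2.5, 1.8),
    spike_width_px: int = 3,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Binary growth-cone mask: elliptical body plus radial spikes.

    ``spike_lengths`` are the programmed protrusion lengths (um) measured
    from the body boundary outward; ``angles`` (radians) default to evenly
    spaced directions with seeded jitter.
    """
    rng = np.random.default_rng(seed)
    nspikes = len(spike_lengths)
    if angles is None:
        base = np.linspace(0, 2 * np.pi, nspikes, endpoint=False)
        angles = list(base + rng.uniform(-0.1, 0.1, nspikes))
    cy, cx = shape[0] / 2, shape[1] / 2
    a, b = body_axes[0] / pixel_size, body_axes[1] / pixel_size
    mask = np.zeros(shape, dtype=bool)
    rr, cc = skdraw.ellipse(cy, cx, a, b, shape=shape)
    mask[rr, cc] = True
    bases = []
    for L, th in zip(spike_lengths, angles):
        if L <= 0:
            bases.append(None)
            continue
        # radial boundary point of the ellipse at polar angle th
        r_edge = 1.0 / np.sqrt((np.cos(th) / a) ** 2 + (np.sin(th) / b) ** 2)
        d = np.array([np.cos(th), np.sin(th)])
        nvec = np.array([-np.sin(th), np.cos(th)])
        base = np.array([cy, cx]) + r_edge * d
        tip = base + (L / pixel_size) * d
        root = base - 3.0 * d  # anchor the spike inside the body
        half_w = spike_width_px / 2
        corners = np.array(
            [root + half_w * nvec, root - half_w * nvec, tip - half_w * nvec, tip + half_w * nvec]
        )
        rr, cc = skdraw.polygon(corners[:, 0], corners[:, 1], shape=shape)
        mask[rr, cc] = True
        bases.append(base)
    truth = {
        "spike_lengths_um": list(map(float, spike_lengths)),
        "angles": list(map(float, angles)),
        "bases_px": [None if bpt is None else tuple(map(float, bpt)) for bpt in bases],
        "pixel_size": pixel_size,
        "synthetic": True,
    }
    return mask, truth


def make_gc_sequence(
    n_filopodia: int = 4,
    event_schedule: list[dict] | None = None,
    seed: int = 5,
    recording: float = 300.0,
    dt: float = 5.0,
    pixel_size: float = 0.1,
    shape: tuple[int, int] = (240, 240),
) -> tuple[np.ndarray, list[FilopodiumTrace], dict]:
    """Growth-cone mask stack with scripted filopodium length trajectories.

    ``event_schedule`` entries are dicts with ``kind`` in
    {"stable", "formation", "retraction", "transient"} and optional
    ``max_length`` (um), ``rate`` (um/s), ``t_start`` / ``t_shrink`` (s);
    omitted, a seeded random schedule with ``n_filopodia`` entries is drawn.
    Returns (mask stack, truth traces, event log).  The truth traces record
    the scripted per-frame lengths; the event log gives the expected
    formation/retraction/stable counts, lifetimes and active-phase speeds.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(round(recording / dt))
    if event_schedule is None:
        kinds = rng.choice(["stable", "formation", "retraction", "transient"], n_filopodia)
        event_schedule = [{"kind": str(k)} for k in kinds]
    nspikes = len(event_schedule)
    base_angles = np.linspace(0, 2 * np.pi, max(nspikes, 1), endpoint=False) + rng.uniform(
        -0.1, 0.1, max(nspikes, 1)
    )
    length_series = []
    for spec in event_schedule:
        kind = spec["kind"]
        L_max = float(spec.get("max_length", rng.uniform(3.0, 4.5)))
        rate = float(spec.get("rate", 0.2))  # um/s
        per_frame = rate * dt
        t_start = float(spec.get("t_start", rng.uniform(30, 90)))
        t_shrink = float(spec.get("t_shrink", rng.uniform(180, 240)))
        L = np.zeros(n_frames)
        for i in range(n_frames):
            t = i * dt
            if kind == "stable":
                L[i] = L_max
            elif kind == "formation":
                L[i] = np.clip((t - t_start) * rate, 0, L_max) if t >= t_start else 0.0
            elif kind == "retraction":
                L[i] = max(L_max - max(t - t_shrink, 0) * rate, 0.0)
            elif kind == "transient":
                if t < t_start:
                    L[i] = 0.0
                elif t < t_shrink:
                    L[i] = min((t - t_start) * rate, L_max)
                else:
                    L[i] = max(min((t_shrink - t_start) * rate, L_max) - (t - t_shrink) * rate, 0.0)
            else:
                raise ValueError(f"unknown filopodium kind {kind!r}")
        length_series.append(L)

    stack = np.zeros((n_frames, *shape), dtype=bool)
    for i in range(n_frames):
        lengths_now = [L[i] for L in length_series]
        angles = list(base_angles[: len(lengths_now)])
        frame_mask, _ = make_gc_mask(
            [l for l in lengths_now], angles=angles, pixel_size=pixel_size, shape=shape, seed=0
        )
        stack[i] = frame_mask

    traces = [
        FilopodiumTrace(f"f{k}", L, frame_interval=dt) for k, L in enumerate(length_series)
    ]
    log = {"n_formation": 0, "n_retraction": 0, "n_stable": 0, "lifetimes": [], "kinds": []}
    for spec, L in zip(event_schedule, length_series):
        present = L >= 2.0
        if not present.any():
            log["kinds"].append(spec["kind"])
            continue
        if present.all():
            log["n_stable"] += 1
        else:
            if np.flatnonzero(present)[0] > 0:
                log["n_formation"] += 1
            if np.flatnonzero(present)[-1] < n_frames - 1:
                log["n_retraction"] += 1
        log["lifetimes"].append(float(np.count_nonzero(present) * dt))
        log["kinds"].append(spec["kind"])
    log["synthetic"] = True
    return stack, traces, log


# --------------------------------------------------------------------------
# encounter events
# --------------------------------------------------------------------------

_CANONICAL = ("fasciculation", "crossing", "tracking", "stalling", "retraction")

# fig2c: 23 in-vivo events, minimal integer reconstruction of
# 47.83 / 30.43 / 21.74 %; fig2i_homo: 100 homotypic events reproducing the
# 0.51 fasciculation and 0.43 crossing ratios (51/43/6)
_FIG2C = [("fasciculation", 11), ("crossing", 7), ("tracking", 5)]
_FIG2I_HOMO = [("fasciculation", 51), ("crossing", 43), ("stalling", 3), ("retraction", 3)]


def _canonical_event(kind: str, rng: np.random.Generator, jitter: float = 0.05) -> EncounterEvent:
    """One encounter of the given class in a random rigid frame."""
    dt, speed = 30.0, 0.6  # s per frame, um per frame
    n_pre, n_post = 20, 90  # 10 min approach, 45 min observation
    pre_t = np.arange(-n_pre, 0) * dt
    post_t = np.arange(0, n_post + 1) * dt
    pre = np.stack([np.arange(-n_pre, 0) * speed, np.zeros(n_pre)], axis=1)

    def ray(angle_deg: float, k: np.ndarray) -> np.ndarray:
        th = np.radians(angle_deg)
        return np.stack([k * np.cos(th), k * np.sin(th)], axis=1)

    contacts: list[FilopodialContact] = []
    if kind == "fasciculation":
        u = 40.0
        path = np.array([[-40 * np.cos(np.radians(u)), -40 * np.sin(np.radians(u))],
                         [60 * np.cos(np.radians(u)), 60 * np.sin(np.radians(u))]])
        post = ray(u, np.arange(n_post + 1) * speed)
        contacts = [FilopodialContact("c0", 0.0, 120.0)]
    elif kind == "crossing":
        th = np.radians(60.0)
        path = np.array([[-40 * np.cos(th), -40 * np.sin(th)], [40 * np.cos(th), 40 * np.sin(th)]])
        post = np.stack([np.arange(n_post + 1) * speed, np.zeros(n_post + 1)], axis=1)
        contacts = [FilopodialContact("c0", 0.0, 60.0)]
    elif kind == "tracking":
        u = 40.0
        th = np.radians(u)
        n_vec = np.array([-np.sin(th), np.cos(th)])
        a = -2.0 * n_vec  # path offset 2 um from the trajectory
        d_vec = np.array([np.cos(th), np.sin(th)])
        path = np.stack([a - 40 * d_vec, a + 60 * d_vec])
        post = ray(u, np.arange(n_post + 1) * speed)
        contacts = [FilopodialContact(f"c{i}", 60.0 * i, 60.0 * i + 90.0) for i in range(4)]
    elif kind == "retraction":
        th = np.radians(60.0)
        path = np.array([[-40 * np.cos(th), -40 * np.sin(th)], [40 * np.cos(th), 40 * np.sin(th)]])
        post = np.stack([-np.arange(n_post + 1) * speed, np.zeros(n_post + 1)], axis=1)
    elif kind == "stalling":
        th = np.radians(60.0)
        anchor = np.array([3.0, 0.0])  # axon lies just ahead of the stalled cone
        path = np.stack(
            [anchor + np.array([-40 * np.cos(th), -40 * np.sin(th)]),
             anchor + np.array([40 * np.cos(th), 40 * np.sin(th)])]
        )
        xs = 0.3 * (-1.0) ** np.arange(n_post + 1)
        xs[0] = 0.0
        post = np.stack([xs, np.zeros(n_post + 1)], axis=1)
        contacts = [FilopodialContact("c0", 0.0, 2700.0)]
    else:
        raise ValueError(f"unknown encounter profile {kind!r}")

    times = np.concatenate([pre_t, post_t])
    points = np.vstack([pre, post])
    if jitter > 0:
        points = points + rng.normal(0, jitter, points.shape)
    # random rigid transform
    phi = rng.uniform(0, 2 * np.pi)
    R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    shift = rng.uniform(-100, 100, 2)
    points = points @ R.T + shift
    path = path @ R.T + shift
    return EncounterEvent(times, points, path, contact_time=0.0, contacts=contacts)


def make_encounter(
    profile: str, seed: int = 0, n: int = 1
) -> tuple[list[EncounterEvent], list[str]]:
    """Encounter events with ground-truth class labels.

    ``profile`` is a canonical class name (returns ``n`` randomized events of
    that class), ``fig2c`` (23 events: 11 fasciculation, 7 crossing, 5
    tracking) or ``fig2i_homo`` (100 homotypic events: 51/43/3/3
    fasciculation/crossing/stalling/retraction).
    """
    rng = np.random.default_rng(seed)
    events: list[EncounterEvent] = []
    labels: list[str] = []
    if profile in _CANONICAL:
        plan = [(profile, n)]
        origins = None
    elif profile == "fig2c":
        plan = _FIG2C
        origins = None
    elif profile == "fig2i_homo":
        plan = _FIG2I_HOMO
        origins = [("D", "D"), ("V", "V")]
    else:
        raise ValueError(
            f"unknown profile {profile!r}; expected one of {_CANONICAL + ('fig2c', 'fig2i_homo')}"
        )
    k = 0
    for kind, count in plan:
        for _ in range(count):
            ev = _canonical_event(kind, rng)
            ev.event_id = f"e{k:03d}"
            if origins is not None:
                ev.origin = origins[k % len(origins)]
            events.append(ev)
            labels.append(kind)
            k += 1
    order = rng.permutation(len(events))
    return [events[i] for i in order], [labels[i] for i in order]


# --------------------------------------------------------------------------
# puncta
# --------------------------------------------------------------------------

def make_puncta_fixture(
    n: int = 100,
    associated: int = 84,
    radius: float = 0.5,
    seed: int = 13,
    roi: tuple[float, float] = (50.0, 10.0),
) -> tuple["PunctumSet", "PunctumSet", dict]:
    """Two punctum sets with an exact known association fraction.

    ``associated`` channel-A puncta are placed within ``radius/2`` of some
    channel-B punctum; the remaining ``n - associated`` lie farther than
    ``2 * radius`` from every B punctum, so the association fraction at the
    query radius is exactly ``associated / n``.
    """
    from .colocalization import PunctumSet

    if not 0 <= associated <= n:
        raise ValueError("need 0 <= associated <= n")
    rng = np.random.default_rng(seed)
    b_pts = np.stack([rng.uniform(0, roi[0], n), rng.uniform(0, roi[1], n)], axis=1)
    a_pts = np.empty((n, 2))
    flags = np.zeros(n, dtype=bool)
    for i in range(associated):
        j = rng.integers(n)
        r = rng.uniform(0, radius / 2)
        th = rng.uniform(0, 2 * np.pi)
        a_pts[i] = b_pts[j] + r * np.array([np.cos(th), np.sin(th)])
        flags[i] = True
    i = associated
    while i < n:
        cand = np.array([rng.uniform(0, roi[0]), rng.uniform(0, roi[1])])
        if np.min(np.linalg.norm(b_pts - cand, axis=1)) > 2 * radius:
            a_pts[i] = cand
            i += 1
    truth = {"n": n, "associated": associated, "radius": radius, "flags": flags, "synthetic": True}
    return PunctumSet("A", a_pts), PunctumSet("B", b_pts), truth
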