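"""Growth-cone / axon encounter classification and contact statistics.

An encounter event records the growth-cone centroid trajectory (frames every
30 s), the contacted axon's path, the contact time (T=0), and individual
filopodial-contact intervals.  Behaviors after contact are classified by an
explicit geometric cascade mirroring the by-eye definitions: fasciculation
(the axon shaft merges with and follows the encountered axon), crossing (the
growth cone crosses straight over it), tracking (repeated filopodial
contacts steer the heading parallel to the axon at a distance), retraction,
and stalling (no net advance over the 45-min observation window).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import LineString, Point

from .config import RunConfig
from .granule_transport import _round_half_up

__all__ = [
    "EncounterEvent",
    "FilopodialContact",
    "BehaviorClass",
    "classify_behavior",
    "behavior_fractions",
    "contact_stats",
    "compare_groups",
]


class BehaviorClass(str, enum.Enum):
    FASCICULATION = "fasciculation"
    CROSSING = "crossing"
    TRACKING = "tracking"
    STALLING = "stalling"
    RETRACTION = "retraction"
    UNCLASSIFIED = "unclassified"
    INDETERMINATE = "indeterminate (censored)"


@dataclass
class FilopodialContact:
    """One filopodium-axon contact interval (seconds)."""

    filopodium_id: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("contact end must be >= start")

    @property
    def duration_min(self) -> float:
        return (self.end - self.start) / 60.0


@dataclass
class EncounterEvent:
    """One growth-cone/axon encounter.

    ``times`` (s) and ``points`` ((N, 2) um) give the centroid trajectory;
    ``target_path`` is the contacted axon polyline; ``contact_time`` is T=0.
    """

    times: np.ndarray
    points: np.ndarray
    target_path: np.ndarray
    contact_time: float
    contacts: list[FilopodialContact] = field(default_factory=list)
    observation_end: float | None = None
    origin: tuple[str, str] | None = None  # e.g. ("D", "V"): gc origin -> axon origin
    event_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        self.target_path = np.asarray(self.target_path, dtype=float)
        if self.times[0] > self.contact_time or self.times[-1] < self.contact_time:
            raise ValueError("trajectory must span the contact time")
        if self.observation_end is None:
            self.observation_end = float(self.times[-1])

    @property
    def homotypic(self) -> bool | None:
        if self.origin is None:
            return None
        return self.origin[0] == self.origin[1]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        return np.zeros_like(v)
    return v / n


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Unsigned angle (degrees) between two direction vectors."""
    c = float(np.clip(np.dot(_unit(u), _unit(v)), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def _signed_sides(points: np.ndarray, path: LineString) -> np.ndarray:
    """Sign of each point relative to its nearest path segment (left/right)."""
    coords = np.asarray(path.coords)
    signs = np.zeros(len(points))
    for i, p in enumerate(points):
        # nearest segment by projected distance
        best, best_d = 0, np.inf
        for j in range(len(coords) - 1):
            d = LineString(coords[j : j + 2]).distance(Point(p))
            if d < best_d:
                best, best_d = j, d
        a, b = coords[best], coords[best + 1]
        t = b - a
        signs[i] = np.sign(t[0] * (p[1] - a[1]) - t[1] * (p[0] - a[0]))
    return signs


def classify_behavior(event: EncounterEvent, params: RunConfig | None = None) -> BehaviorClass:
    """Classify one encounter with the geometric decision cascade.

    Evaluated in order after T=0: fasciculation, crossing, tracking,
    retraction, stalling; events matching none are reported unclassified
    (never dropped), and events observed for less than the stall window
    without triggering rules 1-4 are censored.
    """
    p = params or RunConfig()
    path = LineString(event.target_path)
    post_sel = event.times >= event.contact_time
    pre_sel = event.times <= event.contact_time
    post = event.points[post_sel]
    pre = event.points[pre_sel]
    if len(post) < 2 or len(pre) < 2:
        return BehaviorClass.INDETERMINATE
    h_pre = _unit(pre[-1] - pre[0])
    dists = np.array([path.distance(Point(q)) for q in post])

    # (1) fasciculation: trajectory hugs the path for >= min_follow of arc
    close = dists <= p.merge_tol_um
    arc = 0.0
    for i in range(1, len(post)):
        if close[i] and close[i - 1]:
            arc += float(np.linalg.norm(post[i] - post[i - 1]))
            if arc >= p.min_follow_um:
                return BehaviorClass.FASCICULATION
        else:
            arc = 0.0

    h_post = _unit(post[-1] - post[0])
    turn = _angle_between(h_pre, h_post)

    # (2) crossing: side flip relative to the path, proceeding >= cross_dist
    # beyond it, with a near-straight heading
    sides = np.concatenate([_signed_sides(pre[:-1], path), _signed_sides(post, path)])
    nz = sides[sides != 0]
    if len(nz) >= 2 and nz[0] != nz[-1]:
        far_side = dists[_signed_sides(post, path) == nz[-1]]
        if far_side.size and far_side.max() >= p.cross_dist_um and turn < p.cross_max_turn_deg:
            return BehaviorClass.CROSSING

    # (3) tracking: repeated filopodial contacts steer the heading toward the
    # path tangent while the centroid keeps its distance
    if len(event.contacts) >= 2 and np.all(dists[1:] > p.merge_tol_um):
        q = np.asarray(path.interpolate(path.project(Point(post[-1]))).coords)[0]
        coords = np.asarray(path.coords)
        seg = np.argmin([LineString(coords[j : j + 2]).distance(Point(q)) for j in range(len(coords) - 1)])
        tangent = _unit(coords[seg + 1] - coords[seg])
        if np.dot(tangent, h_pre) < 0:
            tangent = -tangent
        if turn > p.track_min_turn_deg and _angle_between(h_post, tangent) < _angle_between(
            h_pre, tangent
        ):
            return BehaviorClass.TRACKING

    # (4) retraction: net displacement along the pre-contact heading
    advance = float(np.dot(post[-1] - post[0], h_pre))
    if advance < -p.retract_tol_um:
        return BehaviorClass.RETRACTION

    # (5) stalling requires the full observation window
    observed_min = (event.observation_end - event.contact_time) / 60.0
    if observed_min < p.stall_window_min:
        return BehaviorClass.INDETERMINATE
    if abs(advance) < p.stall_tol_um:
        return BehaviorClass.STALLING
    return BehaviorClass.UNCLASSIFIED


def behavior_fractions(
    events: list[EncounterEvent],
    params: RunConfig | None = None,
    ndigits: int = 2,
) -> pd.DataFrame:
    """Percentage of events per behavior class, overall and per origin pair.

    Returns a tidy DataFrame with columns ``group`` (``all``, ``homotypic``,
    ``heterotypic``, and each origin pair present), ``behavior``, ``n`` and
    ``percent`` (half-up, ``ndigits`` decimals).  Percentages within a group
    sum to 100 before rounding; unclassified/censored events are reported.
    """
    if not events:
        raise ValueError("behavior_fractions: need at least one event")
    classes = [classify_behavior(e, params) for e in events]
    rows = []

    def add_group(name: str, idx: list[int]) -> None:
        n = len(idx)
        for bc in BehaviorClass:
            k = sum(classes[i] is bc for i in idx)
            if k or bc not in (BehaviorClass.UNCLASSIFIED, BehaviorClass.INDETERMINATE):
                rows.append((name, bc.value, k, _round_half_up(100.0 * k / n, ndigits)))

    add_group("all", list(range(len(events))))
    if any(e.origin for e in events):
        homo = [i for i, e in enumerate(events) if e.homotypic]
        hetero = [i for i, e in enumerate(events) if e.homotypic is False]
        if homo:
            add_group("homotypic", homo)
        if hetero:
            add_group("heterotypic", hetero)
        for pair in sorted({e.origin for e in events if e.origin}):
            add_group("->".join(pair), [i for i, e in enumerate(events) if e.origin == pair])
    return pd.DataFrame(rows, columns=["group", "behavior", "n", "percent"])


def contact_stats(events: list[EncounterEvent]) -> pd.DataFrame:
    """Per-event filopodial-contact count and mean duration (minutes).

    Events without contacts get NaN duration (flagged, not imputed).
    """
    rows = []
    for i, e in enumerate(events):
        n = len(e.contacts)
        mean_dur = float(np.mean([c.duration_min for c in e.contacts])) if n else np.nan
        rows.append((e.event_id or str(i), n, mean_dur))
    return pd.DataFrame(rows, columns=["event_id", "n_contacts", "mean_duration_min"])


def compare_groups(
    a, b, test: str = "fisher"
) -> dict:
    """Two-sided group comparison via the standard tests used in this field.

    ``fisher`` and ``chi2`` expect ``a``/``b`` as the two rows of a
    contingency table; ``mannwhitney`` expects two samples.  For chi2, a
    note recommends Fisher's exact test when any expected count is < 5.
    """
    out: dict = {"test": test, "two_sided": True}
    if test == "fisher":
        table = np.array([a, b])
        stat, pval = stats.fisher_exact(table, alternative="two-sided")
        out.update(statistic=float(stat), p=float(pval))
    elif test == "chi2":
        table = np.array([a, b])
        res = stats.chi2_contingency(table, correction=False)
        out.update(statistic=float(res.statistic), p=float(res.pvalue))
        if (res.expected_freq < 5).any():
            out["note"] = "expected counts < 5; Fisher's exact test recommended"
    elif test == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        out.update(statistic=float(res.statistic), p=float(res.pvalue))
    else:
        raise ValueError(f"unknown test {test!r}; expected fisher|chi2|mannwhitney")
    return out
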