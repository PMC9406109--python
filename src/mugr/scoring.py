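"""Operational scoring of one longitudinal section.

Implements the quantitative definitions used to measure enteric ganglion
density against circular muscle units:

* a *junction* is a valley of the circular-muscle outer-edge profile whose
  prominence-style depth is at least 30 µm; junctions partition the strip
  into *muscle units*;
* a *ganglion* is a single-linkage cluster (30 µm cutoff) of at least two
  HuC/D+ neurons, with nearby glia and unlabelled nuclei as members;
* a *hypertrophic nerve bundle* is an S100B+ structure wider than 40 µm
  containing no neurons; the *transition zone* runs from the most proximal
  hypertrophic bundle to the most distal ganglion;
* the *muscle-unit-to-ganglion ratio* (MGR) of a zone is the mean number of
  muscle units spanned between consecutive ganglia whose interval midpoint
  falls inside the zone.

The longitudinal axis is in µm, origin at the proximal (oral) end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal, sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, Point
from sklearn.neighbors import radius_neighbors_graph

from .params import Thresholds

__all__ = [
    "BoundaryProfile",
    "Junction",
    "MuscleUnit",
    "Ganglion",
    "NerveBundle",
    "ZonePartition",
    "IntervalRecord",
    "SectionScore",
    "detect_junctions",
    "segment_muscle_units",
    "measure_unit_width",
    "cluster_ganglia",
    "classify_bundles",
    "partition_zones",
    "count_interval_units",
    "compute_mgr",
    "compute_mgr_totals",
    "ganglion_composition",
    "score_section",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class BoundaryProfile:
    """Sampled depth curve of the circular-muscle outer edge.

    ``depth[i]`` is the recession (µm, >= 0) of the outer edge below its
    slowly-varying envelope at longitudinal position ``positions[i]``;
    junction valleys appear as local maxima of ``depth``.
    """

    positions: np.ndarray  # µm, strictly increasing, uniform step
    depth: np.ndarray  # µm, finite, >= 0
    step: float  # µm

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        dep = np.asarray(self.depth, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "depth", dep)
        if pos.ndim != 1 or pos.shape != dep.shape:
            raise ValueError("positions and depth must be matching 1-D arrays")
        if pos.size >= 2 and not np.all(np.diff(pos) > 0):
            raise ValueError("positions must be strictly increasing")
        if not np.all(np.isfinite(dep)) or np.any(dep < 0):
            raise ValueError("depth must be finite and non-negative")

    @property
    def extent(self) -> tuple[float, float]:
        return (
            float(self.positions[0] - self.step / 2),
            float(self.positions[-1] + self.step / 2),
        )


@dataclass(frozen=True)
class Junction:
    position: float  # µm
    depth: float  # µm (prominence of the valley)


@dataclass(frozen=True)
class MuscleUnit:
    start: float
    end: float  # half-open [start, end)
    width: float  # µm, measured width (defaults to interval length)

    @property
    def interval_length(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class Ganglion:
    id: int
    centroid_x: float  # µm, mean of member-neuron x positions
    centroid_y: float
    n_dapi: int
    n_neurons: int
    n_glia: int
    n_other: int

    def __post_init__(self) -> None:
        if self.n_dapi != self.n_neurons + self.n_glia + self.n_other:
            raise ValueError("member counts must sum to n_dapi")


@dataclass(frozen=True)
class NerveBundle:
    position: float  # µm
    width: float  # µm (maximal inscribed-disk diameter)
    hypertrophic: bool


@dataclass(frozen=True)
class ZonePartition:
    """Spans of the normal, transition and aganglionic zones.

    ``normal = [0, z1)``, ``transition = [z1, z2]``, ``aganglionic =
    (z2, end]`` where ``z1`` is the most proximal hypertrophic bundle and
    ``z2`` the most distal ganglion. Absent zones are ``None``.
    """

    normal: tuple[float, float] | None
    transition: tuple[float, float] | None
    aganglionic: tuple[float, float] | None
    z1: float | None
    z2: float | None

    def zone_of(self, x: float) -> str | None:
        if self.normal is not None and self.normal[0] <= x < self.normal[1]:
            return "normal"
        if self.transition is not None and self.transition[0] <= x <= self.transition[1]:
            return "transition"
        if self.aganglionic is not None and self.aganglionic[0] < x <= self.aganglionic[1]:
            return "aganglionic"
        # fall back for the open end-points of half-open spans
        if self.normal is not None and x == self.normal[1] and self.transition is None:
            return "normal"
        return None


@dataclass(frozen=True)
class IntervalRecord:
    midpoint: float
    unit_count: int
    zone: str | None


@dataclass
class SectionScore:
    """Scored quantities for one section."""

    intervals: list[IntervalRecord]
    mgr: dict[str, float]  # per-zone mean of interval unit counts
    mgr_totals: dict[str, float]  # secondary definition: units / ganglia
    partition: ZonePartition
    junctions: list[Junction]
    units: list[MuscleUnit]
    ganglia: list[Ganglion]
    bundles: list[NerveBundle]
    thresholds: Thresholds = field(default_factory=Thresholds)

    def composition_table(self) -> pd.DataFrame:
        """Per-ganglion composition metrics with zone labels."""
        rows = []
        for g in self.ganglia:
            size, pct_hu, gpn = ganglion_composition(g)
            rows.append(
                {
                    "ganglion_id": g.id,
                    "x_um": g.centroid_x,
                    "zone": self.partition.zone_of(g.centroid_x),
                    "n_dapi": size,
                    "pct_hu": pct_hu,
                    "glia_per_neuron": gpn,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "ganglion_id",
                "x_um",
                "zone",
                "n_dapi",
                "pct_hu",
                "glia_per_neuron",
            ],
        )


# --------------------------------------------------------------------------
# junctions and muscle units
# --------------------------------------------------------------------------
def detect_junctions(profile: BoundaryProfile, th: Thresholds | None = None) -> list[Junction]:
    """Find junction valleys: local maxima of ``depth`` with prominence
    >= ``junction_min_depth`` (the 30 µm criterion is inclusive).

    Returns one junction per valley, at the deepest sample, sorted by
    position.
    """
    th = th or Thresholds()
    depth = profile.depth
    if depth.size < 3:
        return []
    peaks, _ = signal.find_peaks(depth)
    if peaks.size == 0:
        return []
    prominences = signal.peak_prominences(depth, peaks)[0]
    keep = prominences >= th.junction_min_depth
    return [
        Junction(position=float(profile.positions[i]), depth=float(p))
        for i, p in zip(peaks[keep], prominences[keep])
    ]


def segment_muscle_units(
    junctions: Sequence[Junction], extent: tuple[float, float]
) -> list[MuscleUnit]:
    """Tile ``extent`` into half-open units separated at junction positions."""
    lo, hi = float(extent[0]), float(extent[1])
    if hi <= lo:
        raise ValueError("extent must be a non-empty span")
    pos = [j.position for j in junctions]
    if any(b <= a for a, b in zip(pos, pos[1:])):
        raise ValueError("junction positions must be strictly increasing")
    if pos and (pos[0] <= lo or pos[-1] >= hi):
        raise ValueError("junctions must lie strictly inside the extent")
    edges = [lo, *pos, hi]
    return [
        MuscleUnit(start=a, end=b, width=b - a) for a, b in zip(edges, edges[1:])
    ]


def measure_unit_width(
    unit: MuscleUnit, profile: BoundaryProfile, th: Thresholds | None = None
) -> float:
    """Width of a unit measured along the line ``width_offset`` µm inward
    from the longitudinal-muscle-facing edge.

    Computed as the summed sample spacing over positions inside the unit
    where the edge recession is smaller than the offset, i.e. the chord of
    the muscle mask at that depth. Units narrower than two sampling steps
    are flagged and reported at their interval length.
    """
    th = th or Thresholds()
    if unit.interval_length < 2 * profile.step:
        warnings.warn(
            f"unit [{unit.start:.1f}, {unit.end:.1f}) narrower than twice the "
            "sampling step; reporting interval length",
            stacklevel=2,
        )
        return unit.interval_length
    i0 = int(np.searchsorted(profile.positions, unit.start, side="left"))
    i1 = int(np.searchsorted(profile.positions, unit.end, side="left"))
    if i1 <= i0:
        return unit.interval_length
    return float(
        np.count_nonzero(profile.depth[i0:i1] < th.width_offset) * profile.step
    )


# --------------------------------------------------------------------------
# ganglia
# --------------------------------------------------------------------------
_REQUIRED_CELL_COLUMNS = ("x_um", "y_um", "cell_class")


def cluster_ganglia(cells: pd.DataFrame, th: Thresholds | None = None) -> list[Ganglion]:
    """Cluster classified cells into ganglia.

    Neurons are single-linkage clustered at ``ganglion_link_distance``
    (equivalently: connected components of the <=d neighbour graph).
    Clusters with at least ``min_neurons_per_ganglion`` neurons become
    ganglia; glia and other nuclei falling within the cluster's convex hull
    dilated by the link distance are assigned as members (nearest cluster on
    ties). The centroid is the mean neuron position.
    """
    th = th or Thresholds()
    for col in _REQUIRED_CELL_COLUMNS:
        if col not in cells.columns:
            raise KeyError(f"cells table lacks required column {col!r}")
    neurons = cells[cells["cell_class"] == "neuron"]
    if len(neurons) == 0:
        return []
    pts = neurons[["x_um", "y_um"]].to_numpy(dtype=float)
    if len(pts) == 1:
        labels = np.zeros(1, dtype=int)
    else:
        graph = radius_neighbors_graph(
            pts, radius=th.ganglion_link_distance, mode="connectivity"
        )
        _, labels = connected_components(sparse.csr_matrix(graph), directed=False)

    others = cells[cells["cell_class"] != "neuron"]
    other_pts = others[["x_um", "y_um"]].to_numpy(dtype=float)
    other_cls = others["cell_class"].to_numpy()

    ganglia: list[Ganglion] = []
    hulls = []
    cluster_ids = []
    for cid in np.unique(labels):
        members = pts[labels == cid]
        if len(members) < th.min_neurons_per_ganglion:
            continue
        hull = MultiPoint([tuple(p) for p in members]).convex_hull.buffer(
            th.ganglion_link_distance
        )
        hulls.append((hull, members))
        cluster_ids.append(cid)

    # assign non-neuron nuclei to the nearest covering hull; a KD-tree
    # prefilter keeps this linear in the number of nuclei
    counts = {cid: {"glia": 0, "other": 0} for cid in cluster_ids}
    if len(other_pts) and cluster_ids:
        tree = cKDTree(other_pts)
        best_cid = np.full(len(other_pts), -1, dtype=object)
        best_d = np.full(len(other_pts), np.inf)
        for cid, (hull, members) in zip(cluster_ids, hulls):
            centroid = members.mean(axis=0)
            radius = float(
                np.max(np.linalg.norm(members - centroid, axis=1))
                + th.ganglion_link_distance
                + 1e-9
            )
            for j in tree.query_ball_point(centroid, radius):
                if not hull.covers(Point(other_pts[j])):
                    continue
                d = float(np.min(np.linalg.norm(members - other_pts[j], axis=1)))
                if d < best_d[j]:
                    best_d[j], best_cid[j] = d, cid
        for j, cid in enumerate(best_cid):
            if cid != -1:
                key = "glia" if other_cls[j] == "glia" else "other"
                counts[cid][key] += 1

    # order ganglia by longitudinal centroid
    ordered = sorted(
        zip(cluster_ids, hulls),
        key=lambda item: float(np.mean(item[1][1][:, 0])),
    )
    for gid, (cid, (hull, members)) in enumerate(ordered):
        n_neu = len(members)
        n_glia = counts[cid]["glia"]
        n_other = counts[cid]["other"]
        ganglia.append(
            Ganglion(
                id=gid,
                centroid_x=float(np.mean(members[:, 0])),
                centroid_y=float(np.mean(members[:, 1])),
                n_dapi=n_neu + n_glia + n_other,
                n_neurons=n_neu,
                n_glia=n_glia,
                n_other=n_other,
            )
        )
    return ganglia


# --------------------------------------------------------------------------
# bundles and zones
# --------------------------------------------------------------------------
def classify_bundles(
    components: pd.DataFrame,
    ganglia: Sequence[Ganglion],
    th: Thresholds | None = None,
) -> list[NerveBundle]:
    """Classify S100B+ components into nerve bundles.

    Components containing a neuron are ganglion-like and excluded. The
    hypertrophy comparison against ``bundle_hypertrophy_width`` is strict by
    default (``>``); set ``bundle_width_inclusive`` for ``>=``.
    """
    th = th or Thresholds()
    if len(components) == 0:
        return []
    for col in ("x_um", "width_um", "contains_neuron"):
        if col not in components.columns:
            raise KeyError(f"components table lacks required column {col!r}")
    bundles = []
    for _, row in components.iterrows():
        if bool(row["contains_neuron"]):
            continue
        w = float(row["width_um"])
        if th.bundle_width_inclusive:
            hyper = w >= th.bundle_hypertrophy_width
        else:
            hyper = w > th.bundle_hypertrophy_width
        bundles.append(
            NerveBundle(position=float(row["x_um"]), width=w, hypertrophic=hyper)
        )
    return sorted(bundles, key=lambda b: b.position)


def partition_zones(
    ganglia: Sequence[Ganglion],
    bundles: Sequence[NerveBundle],
    extent: tuple[float, float],
) -> ZonePartition:
    """Partition the strip into normal / transition / aganglionic zones."""
    lo, hi = float(extent[0]), float(extent[1])
    hyper = sorted(b.position for b in bundles if b.hypertrophic)
    gpos = sorted(g.centroid_x for g in ganglia)
    if not gpos:
        return ZonePartition(
            normal=None, transition=None, aganglionic=(lo, hi), z1=None, z2=None
        )
    z2 = gpos[-1]
    if not hyper:
        return ZonePartition(
            normal=(lo, z2),
            transition=None,
            aganglionic=(z2, hi) if z2 < hi else None,
            z1=None,
            z2=z2,
        )
    z1 = hyper[0]
    if z2 < z1:
        warnings.warn(
            "all ganglia lie proximal to the first hypertrophic bundle; "
            "transition span is empty",
            stacklevel=2,
        )
        return ZonePartition(
            normal=(lo, z1),
            transition=None,
            aganglionic=(z1, hi) if z1 < hi else None,
            z1=z1,
            z2=z2,
        )
    return ZonePartition(
        normal=(lo, z1) if z1 > lo else None,
        transition=(z1, z2),
        aganglionic=(z2, hi) if z2 < hi else None,
        z1=z1,
        z2=z2,
    )


# --------------------------------------------------------------------------
# interval counts and the ratio
# --------------------------------------------------------------------------
def count_interval_units(
    ganglia: Sequence[Ganglion], junctions: Sequence[Junction]
) -> list[IntervalRecord]:
    """For each pair of adjacent ganglia, count junctions strictly between
    their centroids (equals the difference of containing-unit indices)."""
    gx = sorted(g.centroid_x for g in ganglia)
    if len(gx) < 2:
        warnings.warn("fewer than two ganglia; no intervals to count", stacklevel=2)
        return []
    jx = np.asarray(sorted(j.position for j in junctions), dtype=float)
    out = []
    for a, b in zip(gx, gx[1:]):
        count = int(
            np.searchsorted(jx, b, side="left") - np.searchsorted(jx, a, side="right")
        )
        out.append(IntervalRecord(midpoint=(a + b) / 2, unit_count=count, zone=None))
    return out


def _label_intervals(
    intervals: Iterable[IntervalRecord], partition: ZonePartition
) -> list[IntervalRecord]:
    return [
        IntervalRecord(
            midpoint=iv.midpoint,
            unit_count=iv.unit_count,
            zone=partition.zone_of(iv.midpoint),
        )
        for iv in intervals
    ]


def compute_mgr(
    intervals: Sequence[IntervalRecord], partition: ZonePartition
) -> dict[str, float]:
    """Per-zone MGR: mean interval unit count, zones without intervals omitted."""
    labelled = _label_intervals(intervals, partition)
    out: dict[str, float] = {}
    for zone in ("normal", "transition", "aganglionic"):
        vals = [iv.unit_count for iv in labelled if iv.zone == zone]
        if vals:
            out[zone] = float(np.mean(vals))
    return out


def compute_mgr_totals(
    units: Sequence[MuscleUnit],
    ganglia: Sequence[Ganglion],
    partition: ZonePartition,
) -> dict[str, float]:
    """Secondary MGR definition: total units / total ganglia per zone.

    A unit belongs to the zone of its midpoint; a ganglion to the zone of
    its centroid. Zones without ganglia are omitted.
    """
    out: dict[str, float] = {}
    for zone in ("normal", "transition", "aganglionic"):
        n_units = sum(
            1 for u in units if partition.zone_of((u.start + u.end) / 2) == zone
        )
        n_gang = sum(1 for g in ganglia if partition.zone_of(g.centroid_x) == zone)
        if n_gang > 0:
            out[zone] = n_units / n_gang
    return out


def ganglion_composition(g: Ganglion) -> tuple[int, float, float]:
    """(size, %Hu+ of DAPI+, glia-per-neuron) for one ganglion."""
    pct_hu = 100.0 * g.n_neurons / g.n_dapi
    gpn = g.n_glia / g.n_neurons
    return (g.n_dapi, pct_hu, gpn)


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------
def score_section(
    *,
    cells: pd.DataFrame,
    extent: tuple[float, float],
    th: Thresholds | None = None,
    profile: BoundaryProfile | None = None,
    junctions: Sequence[Junction] | None = None,
    components: pd.DataFrame | None = None,
    bundles: Sequence[NerveBundle] | None = None,
) -> SectionScore:
    """Score one section from object records.

    Junctions may be supplied directly (e.g. generator truth) or detected
    from a boundary profile; likewise nerve bundles may be supplied or
    classified from S100B components.
    """
    th = th or Thresholds()
    if junctions is None:
        if profile is None:
            raise ValueError("either junctions or a boundary profile is required")
        junctions = detect_junctions(profile, th)
    junctions = sorted(junctions, key=lambda j: j.position)
    units = segment_muscle_units(junctions, extent)
    if profile is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            units = [
                MuscleUnit(u.start, u.end, measure_unit_width(u, profile, th))
                for u in units
            ]
    ganglia = cluster_ganglia(cells, th)
    if bundles is None:
        bundles = (
            classify_bundles(components, ganglia, th)
            if components is not None
            else []
        )
    partition = partition_zones(ganglia, bundles, extent)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        intervals = _label_intervals(count_interval_units(ganglia, junctions), partition)
    return SectionScore(
        intervals=intervals,
        mgr=compute_mgr(intervals, partition),
        mgr_totals=compute_mgr_totals(units, ganglia, partition),
        partition=partition,
        junctions=list(junctions),
        units=units,
        ganglia=ganglia,
        bundles=list(bundles),
        thresholds=th,
    )
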