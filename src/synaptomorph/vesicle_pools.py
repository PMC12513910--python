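"""Vesicle distance analysis and pool assignment (modified Scholl binning).

Each synaptic vesicle mark records a diameter and, from this module, the
minimal 2D distance between the vesicle's outer membrane and the nearest
PreAZ outline on its own section.  Distances are binned at 10 nm intervals
and mapped onto the structurally defined pools:

========================  =========================
distance d (nm)           pool
========================  =========================
d <= 10                   putative RRP (p10)
10 < d <= 20              putative RRP (p20)
20 < d <= 60              interzone (reported as its
                          own column, never merged)
60 < d <= 200             putative recycling pool
d > 200                   putative resting pool
========================  =========================

Bin edges are closed below: a vesicle exactly at 10 nm belongs to the RRP.
The p20 RRP count reported in :class:`PoolTable` is cumulative (p10 subset of
p20).  Dense-core vesicles are deduplicated across adjacent sections before
counting, keeping each one only where it appears largest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import LineString, Point

from .contour_io import Contour, SectionStack, VesicleMark

__all__ = [
    "POOLS",
    "POOL_EDGES",
    "VesicleRecord",
    "PoolTable",
    "min_distance_to_preaz",
    "assign_pool",
    "build_vesicle_records",
    "build_pool_table",
    "dedup_dcv",
    "count_docked",
    "count_docked_in_stack",
    "associated_azs",
    "pool_tables_to_frame",
]

POOLS = ("rrp_p10", "rrp_p20", "interzone_20_60", "rp_60_200", "resting_gt200")
POOL_EDGES = (10.0, 20.0, 60.0, 200.0)

#: Scholl histogram: 10 nm bins from 0 to 500 nm plus an overflow bin.
SCHOLL_BIN_WIDTH = 10.0
SCHOLL_MAX = 500.0
N_SCHOLL_BINS = int(SCHOLL_MAX / SCHOLL_BIN_WIDTH) + 1  # last bin is > 500

#: Unflagged vesicles within this distance (nm) of the PreAZ count as docked.
DEFAULT_DOCKED_EPSILON = 2.0

#: A PreAZ belongs to a bouton when its outline comes within this 2D distance
#: (nm) of the bouton membrane on some shared section.
AZ_ASSOCIATION_NM = 30.0


def assign_pool(distance: float) -> str:
    """Map a membrane-to-PreAZ distance (nm) onto its pool bin.

    Returns the *bin* label; note that the RRP at the p20 criterion is the
    cumulative count of the ``rrp_p10`` and ``rrp_p20`` bins.
    """
    if distance < 0 or not np.isfinite(distance):
        raise ValueError("distance must be finite and >= 0")
    if distance <= 10.0:
        return "rrp_p10"
    if distance <= 20.0:
        return "rrp_p20"
    if distance <= 60.0:
        return "interzone_20_60"
    if distance <= 200.0:
        return "rp_60_200"
    return "resting_gt200"


def min_distance_to_preaz(
    mark: VesicleMark, preaz_outlines: Sequence[Contour]
) -> float:
    """Minimal 2D distance (nm) from the vesicle's outer membrane to a PreAZ.

    Computed as ``max(0, d_center - diameter/2)`` where ``d_center`` is the
    minimal point-to-polyline distance from the mark center to any outline.
    A touching or overlapping vesicle has distance 0.
    """
    if not preaz_outlines:
        raise ValueError("need at least one PreAZ outline")
    p = Point(mark.center)
    d_center = min(LineString(c.points).distance(p) for c in preaz_outlines)
    return max(0.0, d_center - 0.5 * mark.diameter)


@dataclass
class VesicleRecord:
    """One vesicle mark with its measured distance and pool assignment.

    ``cross_section`` flags distances computed against a neighbouring
    section's outline (Pythagorean, using section mid-plane z) because the
    vesicle's own section carries no PreAZ trace.  ``min_dist_preaz`` is NaN
    and ``pool`` is None when no outline exists within one section.
    """

    object_id: str
    section_index: int
    kind: str
    diameter: float
    min_dist_preaz: float
    assigned_az: str | None
    pool: str | None
    docked: bool
    cross_section: bool = False


@dataclass
class PoolTable:
    """Per-bouton vesicle pool counts and the 10 nm Scholl histogram.

    ``n_rrp_p20`` is cumulative (includes ``n_rrp_p10``); the bin counts
    therefore satisfy ``n_rrp_p20 + n_interzone + n_rp + n_resting ==
    total_svs``.  ``total_svs`` counts clear vesicles with a defined
    distance; ``n_undefined`` counts the rest.
    """

    bouton_id: str
    total_svs: int
    scholl_histogram: np.ndarray
    n_rrp_p10: int
    n_rrp_p20: int
    n_interzone: int
    n_rp: int
    n_resting: int
    n_dcv: int
    n_docked: int
    n_undefined: int = 0
    records: list[VesicleRecord] = field(default_factory=list, repr=False)


def associated_azs(
    stack: SectionStack,
    bouton_id: str,
    max_dist_nm: float = AZ_ASSOCIATION_NM,
) -> list[str]:
    """PreAZ object ids whose outline touches the bouton membrane.

    A PreAZ is assigned to the bouton when, on some section carrying both, the
    outline comes within ``max_dist_nm`` of the membrane contour.
    """
    membrane_by_sec = {
        c.section_index: LineString(np.vstack([c.points, c.points[:1]]))
        for c in stack.contours_for(bouton_id)
        if c.role == "bouton_membrane" and c.closed
    }
    out = []
    for az_id in stack.object_ids(role="preaz"):
        for c in stack.contours_for(az_id):
            membrane = membrane_by_sec.get(c.section_index)
            if membrane is None:
                continue
            if LineString(c.points).distance(membrane) <= max_dist_nm:
                out.append(az_id)
                break
    return out


def _scholl_bin(distance: float) -> int:
    if distance > SCHOLL_MAX:
        return N_SCHOLL_BINS - 1
    return max(0, int(np.ceil(distance / SCHOLL_BIN_WIDTH)) - 1)


def build_vesicle_records(
    stack: SectionStack,
    bouton_id: str,
    az_ids: Sequence[str] | None = None,
) -> list[VesicleRecord]:
    """Measure every clear vesicle mark of a bouton against its PreAZs.

    Distances are measured in-plane on the vesicle's own section when it
    carries a PreAZ outline of the bouton; otherwise against the nearest
    outline within +-1 section, augmented by the out-of-plane offset between
    section mid-planes (flagged ``cross_section``).  Marks with no outline in
    reach get NaN distance and no pool.
    """
    if az_ids is None:
        az_ids = associated_azs(stack, bouton_id)
    center_z = stack.section_center_z()
    outlines: dict[tuple[str, int], list[Contour]] = {}
    az_sections: dict[int, list[str]] = {}
    for az in az_ids:
        for c in stack.contours_for(az):
            outlines.setdefault((az, c.section_index), []).append(c)
            if az not in az_sections.setdefault(c.section_index, []):
                az_sections[c.section_index].append(az)
    geoms = {
        key: [LineString(c.points) for c in cs if len(c.points) >= 2]
        for key, cs in outlines.items()
    }

    records: list[VesicleRecord] = []
    for mark in stack.marks_for(bouton_id, kind="clear"):
        sec = mark.section_index
        point = Point(mark.center)
        best: tuple[float, str, bool] | None = None  # (distance, az, cross)
        if sec in az_sections:
            for az in az_sections[sec]:
                d_center = min(g.distance(point) for g in geoms[(az, sec)])
                d = max(0.0, d_center - 0.5 * mark.diameter)
                if best is None or d < best[0]:
                    best = (d, az, False)
        else:
            for neighbour in (sec - 1, sec + 1):
                if neighbour not in az_sections or neighbour not in center_z:
                    continue
                dz = abs(center_z.get(sec, np.nan) - center_z[neighbour])
                for az in az_sections[neighbour]:
                    d2 = min(g.distance(point) for g in geoms[(az, neighbour)])
                    d = max(0.0, float(np.hypot(d2, dz)) - 0.5 * mark.diameter)
                    if best is None or d < best[0]:
                        best = (d, az, True)
        if best is None:
            records.append(
                VesicleRecord(
                    object_id=bouton_id,
                    section_index=sec,
                    kind=mark.kind,
                    diameter=mark.diameter,
                    min_dist_preaz=float("nan"),
                    assigned_az=None,
                    pool=None,
                    docked=bool(mark.docked),
                )
            )
        else:
            d, az, cross = best
            records.append(
                VesicleRecord(
                    object_id=bouton_id,
                    section_index=sec,
                    kind=mark.kind,
                    diameter=mark.diameter,
                    min_dist_preaz=d,
                    assigned_az=az,
                    pool=assign_pool(d),
                    docked=bool(mark.docked),
                    cross_section=cross,
                )
            )
    return records


def build_pool_table(
    stack: SectionStack,
    bouton_id: str,
    az_ids: Sequence[str] | None = None,
    docked_epsilon: float = DEFAULT_DOCKED_EPSILON,
) -> PoolTable:
    """Full pool analysis of one bouton.

    Clear vesicle marks are trusted once per vesicle (no dedup); dense-core
    vesicles are deduplicated across adjacent sections before counting.  A
    bouton without any associated PreAZ yields a table with undefined
    distances and empty pools, with a warning.
    """
    if az_ids is None:
        az_ids = associated_azs(stack, bouton_id)
    if not az_ids:
        warnings.warn(
            f"bouton {bouton_id!r} has no associated PreAZ; distances undefined",
            stacklevel=2,
        )
    records = build_vesicle_records(stack, bouton_id, az_ids)
    hist = np.zeros(N_SCHOLL_BINS, dtype=int)
    bins = {p: 0 for p in POOLS}
    n_undefined = 0
    for r in records:
        if r.pool is None:
            n_undefined += 1
            continue
        hist[_scholl_bin(r.min_dist_preaz)] += 1
        bins[r.pool] += 1
    dcv_marks = stack.marks_for(bouton_id, kind="dense_core")
    n_dcv = len(dedup_dcv(dcv_marks))
    n_docked = count_docked(records, epsilon=docked_epsilon)
    total = int(hist.sum())
    return PoolTable(
        bouton_id=bouton_id,
        total_svs=total,
        scholl_histogram=hist,
        n_rrp_p10=bins["rrp_p10"],
        n_rrp_p20=bins["rrp_p10"] + bins["rrp_p20"],  # cumulative
        n_interzone=bins["interzone_20_60"],
        n_rp=bins["rp_60_200"],
        n_resting=bins["resting_gt200"],
        n_dcv=n_dcv,
        n_docked=n_docked,
        n_undefined=n_undefined,
        records=records,
    )


# ---------------------------------------------------------------------------
# dense-core vesicle dedup and docked counting
# ---------------------------------------------------------------------------

def _cluster_marks(marks: Sequence[VesicleMark]) -> list[list[int]]:
    """Connected components of the adjacent-section overlap graph.

    Two marks are linked when they sit on adjacent sections and their centers
    lie within the larger mark's radius in-plane.  Maximal components make
    the dedup idempotent: representatives of distinct components can never
    overlap-and-adjoin each other.
    """
    n = len(marks)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_section: dict[int, list[int]] = {}
    for i, m in enumerate(marks):
        by_section.setdefault(m.section_index, []).append(i)
    for sec, idxs in by_section.items():
        for i in idxs:
            for j in by_section.get(sec + 1, ()):
                a, b = marks[i], marks[j]
                radius = 0.5 * max(a.diameter, b.diameter)
                if np.linalg.norm(a.center - b.center) <= radius:
                    union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def dedup_dcv(marks: Sequence[VesicleMark]) -> list[VesicleMark]:
    """Collapse multi-section dense-core vesicle marks to one mark each.

    Marks on adjacent sections whose centers lie within one (larger) radius
    in-plane are treated as the same vesicle; the representative is the
    largest-diameter mark, ties broken toward the lower section index.
    Never increases the count and is idempotent.
    """
    out = []
    for group in _cluster_marks(marks):
        best = min(
            group, key=lambda i: (-marks[i].diameter, marks[i].section_index)
        )
        out.append(marks[best])
    out.sort(key=lambda m: (m.section_index, m.center[0], m.center[1]))
    return out


def count_docked(
    records: Sequence[VesicleRecord], epsilon: float = DEFAULT_DOCKED_EPSILON
) -> int:
    """Count docked vesicles: flagged records plus unflagged ones within epsilon.

    The explicit annotation takes precedence; distance only recruits records
    that were not flagged.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    n = 0
    for r in records:
        if r.docked:
            n += 1
        elif np.isfinite(r.min_dist_preaz) and r.min_dist_preaz <= epsilon:
            n += 1
    return n


def count_docked_in_stack(
    stack: SectionStack,
    bouton_id: str,
    epsilon: float = DEFAULT_DOCKED_EPSILON,
    az_ids: Sequence[str] | None = None,
) -> int:
    """Count unique docked vesicles in a stack, deduplicating across sections.

    In thin-section stacks (tomograms) one vesicle is cut by many planes and
    yields a run of marks on consecutive sections; marks are clustered with
    the same adjacent-section overlap rule used for dense-core vesicles and
    each cluster counts once.  A cluster is docked when any of its marks is
    flagged docked, or, for unflagged clusters, when its minimal measured
    distance is within ``epsilon``.
    """
    if az_ids is None:
        az_ids = associated_azs(stack, bouton_id)
    marks = stack.marks_for(bouton_id, kind="clear")
    records = build_vesicle_records(stack, bouton_id, az_ids)
    n = 0
    for group in _cluster_marks(marks):
        if any(marks[i].docked for i in group):
            n += 1
            continue
        dists = [
            records[i].min_dist_preaz
            for i in group
            if np.isfinite(records[i].min_dist_preaz)
        ]
        if dists and min(dists) <= epsilon:
            n += 1
    return n


def pool_tables_to_frame(tables: Iterable[PoolTable]):
    """Pool tables as a DataFrame: one row per bouton, histogram columns
    ``h_0_10 ... h_490_500, h_gt500`` plus the named pool counts."""
    import pandas as pd

    rows = []
    for t in tables:
        row = {
            "bouton_id": t.bouton_id,
            "total_svs": t.total_svs,
            "n_rrp_p10": t.n_rrp_p10,
            "n_rrp_p20": t.n_rrp_p20,
            "n_interzone_20_60": t.n_interzone,
            "n_rp_60_200": t.n_rp,
            "n_resting_gt200": t.n_resting,
            "n_dcv": t.n_dcv,
            "n_docked": t.n_docked,
            "n_undefined": t.n_undefined,
        }
        for b in range(N_SCHOLL_BINS - 1):
            row[f"h_{b * 10}_{b * 10 + 10}"] = int(t.scholl_histogram[b])
        row["h_gt500"] = int(t.scholl_histogram[-1])
        rows.append(row)
    return pd.DataFrame(rows)
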