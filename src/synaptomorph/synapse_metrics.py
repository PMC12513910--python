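"""Active-zone morphometry: PreAZ area, PSD area estimate, shape, cleft width.

The presynaptic density (PreAZ) is measured as the part of the reconstructed
bouton membrane covered by the density: on every section, the sub-arc of the
bouton contour lying within a coincidence distance (default 30 nm) of the
traced PreAZ outline is extracted, and those sub-arcs are stitched into a
band whose area is ``sa_preaz``.  End sections contribute half-thickness
flanges so that a density ending mid-section is not truncated.

The postsynaptic density (PSD) is not reconstructed independently; its area
is estimated from the PreAZ area by the perimeter ratio of the two traced
outlines, under the assumption that both membrane specializations run
parallel to each other across the cleft::

    SA_PSD = SA_PreAZ * l_PSD / l_PreAZ

Cleft width is measured by the annotator at the two lateral edges and the
center of a perpendicularly cut synapse; this module only aggregates the
triples (the perpendicularity criterion is visual and stays with the
annotator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import unary_union

from .contour_io import Contour, SectionStack
from .reconstruct3d import resample_closed, resample_open

__all__ = [
    "CleftMeasurement",
    "AZMeasurement",
    "measure_preaz",
    "estimate_psd_area",
    "classify_az_shape",
    "measure_cleft",
    "aggregate_clefts",
    "measure_az",
    "az_table",
]

#: Membrane within this 2D distance (nm) of the PreAZ outline counts as
#: covered by the density.
DEFAULT_COINCIDENCE_NM = 30.0

#: A single fully-enclosed hole larger than this fraction of the filled
#: patch makes the patch a ring rather than a perforation.
RING_HOLE_AREA_FRACTION = 0.25

#: Projected patches with convex-hull solidity below this are horseshoes.
HORSESHOE_SOLIDITY = 0.6

AZ_SHAPES = ("macular", "perforated", "horseshoe", "ring")


# ---------------------------------------------------------------------------
# cleft
# ---------------------------------------------------------------------------

@dataclass
class CleftMeasurement:
    """Cleft widths (nm) at the two lateral edges and the center of one AZ.

    ``lateral_mean`` averages the two edges; ``cleft_mean``/``cleft_sd`` are
    the mean and sample SD of {lateral_mean, center}.
    """

    lateral_1: float
    lateral_2: float
    center: float
    lateral_mean: float = field(init=False)
    cleft_mean: float = field(init=False)
    cleft_sd: float = field(init=False)

    def __post_init__(self) -> None:
        if min(self.lateral_1, self.lateral_2, self.center) <= 0:
            raise ValueError("cleft widths must be positive")
        self.lateral_mean = 0.5 * (self.lateral_1 + self.lateral_2)
        pair = np.array([self.lateral_mean, self.center])
        self.cleft_mean = float(pair.mean())
        self.cleft_sd = float(np.std(pair, ddof=1))


def measure_cleft(lateral_1: float, lateral_2: float, center: float) -> CleftMeasurement:
    """Build a :class:`CleftMeasurement` from the three width readings (nm)."""
    return CleftMeasurement(float(lateral_1), float(lateral_2), float(center))


def aggregate_clefts(
    measurements: Sequence[CleftMeasurement],
) -> tuple[float, float, int]:
    """Mean and sample SD of per-synapse mean cleft widths.

    With a single measurement the SD is reported as 0.0 (with a warning); an
    empty list is an error.
    """
    if len(measurements) == 0:
        raise ValueError("aggregate_clefts needs at least one measurement")
    values = np.array([m.cleft_mean for m in measurements])
    n = len(values)
    if n == 1:
        warnings.warn("single cleft measurement: SD reported as 0.0", stacklevel=2)
        return float(values[0]), 0.0, 1
    return float(values.mean()), float(values.std(ddof=1)), n


# ---------------------------------------------------------------------------
# PSD area estimate
# ---------------------------------------------------------------------------

def estimate_psd_area(sa_preaz: float, l_psd: float, l_preaz: float) -> float:
    """PSD area from the PreAZ area scaled by the outline perimeter ratio."""
    if sa_preaz < 0 or l_psd < 0:
        raise ValueError("areas and lengths must be non-negative")
    if l_preaz <= 0:
        raise ValueError("l_preaz must be > 0 (undefined perimeter ratio)")
    return sa_preaz * l_psd / l_preaz


# ---------------------------------------------------------------------------
# PreAZ band measurement
# ---------------------------------------------------------------------------

def _cyclic_runs(mask: np.ndarray) -> list[np.ndarray]:
    """Index runs of consecutive True values in a cyclic boolean mask."""
    n = len(mask)
    if mask.all():
        return [np.arange(n)]
    if not mask.any():
        return []
    # rotate so the mask starts on a False
    start = int(np.flatnonzero(~mask)[0])
    rot = np.roll(mask, -start)
    runs: list[np.ndarray] = []
    i = 0
    while i < n:
        if rot[i]:
            j = i
            while j < n and rot[j]:
                j += 1
            runs.append((np.arange(i, j) + start) % n)
            i = j
        else:
            i += 1
    return runs


def _open_band_area(a: np.ndarray, b: np.ndarray) -> float:
    """Area of the ruled triangle band between two open 3D polylines."""
    m = 33
    a3 = np.column_stack([resample_open(a[:, :2], m), np.full(m, a[0, 2])])
    b3 = np.column_stack([resample_open(b[:, :2], m), np.full(m, b[0, 2])])
    # orientation: pair endpoints the cheaper way round
    straight = np.linalg.norm(a3[0] - b3[0]) + np.linalg.norm(a3[-1] - b3[-1])
    flipped = np.linalg.norm(a3[0] - b3[-1]) + np.linalg.norm(a3[-1] - b3[0])
    if flipped < straight:
        b3 = b3[::-1]
    t1 = 0.5 * np.linalg.norm(
        np.cross(a3[1:] - a3[:-1], b3[1:] - a3[:-1]), axis=1
    ).sum()
    t2 = 0.5 * np.linalg.norm(
        np.cross(b3[1:] - a3[:-1], b3[:-1] - a3[:-1]), axis=1
    ).sum()
    return float(t1 + t2)


def _polyline_len(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def measure_preaz(
    stack: SectionStack,
    bouton_id: str,
    preaz_id: str,
    coincidence_nm: float = DEFAULT_COINCIDENCE_NM,
) -> tuple[float, float]:
    """Measure (sa_preaz nm^2, l_preaz nm) for one PreAZ of one bouton.

    ``l_preaz`` is the summed trace length of the PreAZ outlines across
    sections.  ``sa_preaz`` is the area of the band stitched over the
    membrane sub-arcs within ``coincidence_nm`` of the outline; if the
    outline never comes that close to the membrane the area is zero and a
    warning is emitted.
    """
    zs = stack.section_z()
    secs = stack.section_by_index()
    preaz_by_sec: dict[int, list[Contour]] = {}
    for c in stack.contours_for(preaz_id):
        preaz_by_sec.setdefault(c.section_index, []).append(c)
    if not preaz_by_sec:
        raise ValueError(f"no contours found for PreAZ {preaz_id!r}")

    membrane_by_sec = {
        c.section_index: c
        for c in stack.contours_for(bouton_id)
        if c.role == "bouton_membrane" and c.closed
    }

    l_preaz = sum(
        _polyline_len(c.points) for cs in preaz_by_sec.values() for c in cs
    )

    step = max(min(stack.pixel_size_xy, 2.0), 0.5)
    per_section: list[tuple[int, float, list[np.ndarray]]] = []  # (idx, z, runs)
    for idx in sorted(preaz_by_sec):
        membrane = membrane_by_sec.get(idx)
        if membrane is None:
            warnings.warn(
                f"PreAZ {preaz_id!r} on section {idx} has no bouton membrane "
                f"contour for {bouton_id!r}; section skipped",
                stacklevel=2,
            )
            continue
        n = max(64, int(np.ceil(membrane.length / step)))
        dense = resample_closed(membrane.points, n)
        pts = shapely.points(dense)
        mask = np.zeros(n, dtype=bool)
        for c in preaz_by_sec[idx]:
            if len(c.points) < 2:
                continue
            line = LineString(c.points)
            d = shapely.distance(pts, line)
            # covered membrane: the perpendicular foot lies on the outline
            # (not beyond its ends) within the coincidence distance
            t = shapely.line_locate_point(line, pts)
            mask |= (d <= coincidence_nm) & (t > 1e-6) & (t < line.length - 1e-6)
        runs = [dense[r] for r in _cyclic_runs(mask) if len(r) >= 2]
        per_section.append((idx, zs[idx], runs))

    covered = [(idx, z, runs) for idx, z, runs in per_section if runs]
    if not covered:
        warnings.warn(
            f"PreAZ {preaz_id!r} is farther than {coincidence_nm:.0f} nm from the "
            f"membrane of {bouton_id!r} on every section; sa_preaz = 0",
            stacklevel=2,
        )
        return 0.0, l_preaz

    sa = 0.0
    # bands between consecutive covered sections (gaps bridged directly)
    for (i0, z0, runs0), (i1, z1, runs1) in zip(covered, covered[1:]):
        if len(runs0) == 1 and len(runs1) == 1:
            a = np.column_stack([runs0[0], np.full(len(runs0[0]), z0)])
            b = np.column_stack([runs1[0], np.full(len(runs1[0]), z1)])
            sa += _open_band_area(a, b)
        else:
            # fragmented density: ruled-band area from the trapezoid rule
            l0 = sum(_polyline_len(r) for r in runs0)
            l1 = sum(_polyline_len(r) for r in runs1)
            sa += 0.5 * (l0 + l1) * abs(z1 - z0)
    # half-thickness flanges at the two end sections
    first_idx, _, first_runs = covered[0]
    last_idx, _, last_runs = covered[-1]
    sa += sum(_polyline_len(r) for r in first_runs) * 0.5 * secs[first_idx].thickness
    sa += sum(_polyline_len(r) for r in last_runs) * 0.5 * secs[last_idx].thickness
    return float(sa), float(l_preaz)


# ---------------------------------------------------------------------------
# AZ shape classification
# ---------------------------------------------------------------------------

def classify_az_shape(
    stack: SectionStack,
    preaz_id: str,
    ring_hole_fraction: float = RING_HOLE_AREA_FRACTION,
    solidity_threshold: float = HORSESHOE_SOLIDITY,
) -> str:
    """Classify the en-face projected PreAZ patch: macular/perforated/horseshoe/ring.

    The outlines (embedded at their section z) are projected onto the patch's
    best-fit plane — the en-face view — so that the curvature of the bouton
    wall does not masquerade as concavity.  Each projected outline is dilated
    by half its section thickness (plus one pixel, so adjacent-section
    footprints fuse) and the pieces are unioned.  A simply connected patch is
    macular unless its convex-hull solidity falls below
    ``solidity_threshold`` (horseshoe).  A patch with exactly one enclosed
    hole covering more than ``ring_hole_fraction`` of the filled patch is a
    ring; any other enclosed holes (or a fragmented projection) mean
    perforated.
    """
    contours = stack.contours_for(preaz_id)
    if not contours:
        raise ValueError(f"no contours found for PreAZ {preaz_id!r}")
    secs = stack.section_by_index()
    zs = stack.section_center_z()

    pts3 = np.vstack(
        [
            np.column_stack(
                [c.points, np.full(len(c.points), zs[c.section_index])]
            )
            for c in contours
        ]
    )
    centroid = pts3.mean(axis=0)
    _, _, vt = np.linalg.svd(pts3 - centroid, full_matrices=False)
    plane = vt[:2]  # the two highest-variance directions: the en-face plane

    pieces = []
    for c in contours:
        radius = 0.5 * secs[c.section_index].thickness + stack.pixel_size_xy
        p3 = np.column_stack(
            [c.points, np.full(len(c.points), zs[c.section_index])]
        )
        p2 = (p3 - centroid) @ plane.T
        if len(p2) >= 2:
            geom = LineString(p2)
        else:
            geom = Point(p2[0])
        pieces.append(geom.buffer(radius))
    patch = unary_union(pieces)
    if patch.geom_type == "MultiPolygon":
        return "perforated"
    holes = list(patch.interiors)
    filled = Polygon(patch.exterior).area
    if holes:
        hole_areas = [Polygon(h).area for h in holes]
        if len(holes) == 1 and hole_areas[0] > ring_hole_fraction * filled:
            return "ring"
        return "perforated"
    solidity = patch.area / patch.convex_hull.area
    if solidity < solidity_threshold:
        return "horseshoe"
    return "macular"


# ---------------------------------------------------------------------------
# per-AZ record
# ---------------------------------------------------------------------------

@dataclass
class AZMeasurement:
    """Morphometry of one active zone.

    By construction ``sa_psd * l_preaz == sa_preaz * l_psd`` (the PSD area is
    the perimeter-ratio estimate, not an independent reconstruction).
    """

    az_id: str
    bouton_id: str
    l_preaz: float
    l_psd: float
    sa_preaz: float
    sa_psd: float
    shape: str
    n_sections_spanned: int
    cleft: CleftMeasurement | None = None


def measure_az(
    stack: SectionStack,
    bouton_id: str,
    preaz_id: str,
    psd_id: str | None = None,
    cleft: CleftMeasurement | None = None,
    coincidence_nm: float = DEFAULT_COINCIDENCE_NM,
) -> AZMeasurement:
    """Measure one AZ end-to-end: PreAZ band, PSD estimate, shape class.

    Without a traced PSD outline the PSD length and area are reported as 0
    with a warning (the perimeter-ratio estimate needs both outlines).
    """
    sa_preaz, l_preaz = measure_preaz(stack, bouton_id, preaz_id, coincidence_nm)
    sections = {c.section_index for c in stack.contours_for(preaz_id)}
    if psd_id is not None:
        l_psd = sum(_polyline_len(c.points) for c in stack.contours_for(psd_id))
    else:
        warnings.warn(
            f"AZ {preaz_id!r}: no PSD outline given; sa_psd reported as 0",
            stacklevel=2,
        )
        l_psd = 0.0
    sa_psd = estimate_psd_area(sa_preaz, l_psd, l_preaz) if l_preaz > 0 else 0.0
    shape = classify_az_shape(stack, preaz_id)
    return AZMeasurement(
        az_id=preaz_id,
        bouton_id=bouton_id,
        l_preaz=l_preaz,
        l_psd=l_psd,
        sa_preaz=sa_preaz,
        sa_psd=sa_psd,
        shape=shape,
        n_sections_spanned=len(sections),
        cleft=cleft,
    )


def az_table(measurements: Iterable[AZMeasurement]):
    """Per-AZ measurements as a pandas DataFrame (one row per AZ)."""
    import pandas as pd

    rows = []
    for m in measurements:
        row = {
            "az_id": m.az_id,
            "bouton_id": m.bouton_id,
            "l_preaz_nm": m.l_preaz,
            "l_psd_nm": m.l_psd,
            "sa_preaz_nm2": m.sa_preaz,
            "sa_psd_nm2": m.sa_psd,
            "shape": m.shape,
            "n_sections_spanned": m.n_sections_spanned,
            "cleft_lateral_1_nm": m.cleft.lateral_1 if m.cleft else np.nan,
            "cleft_lateral_2_nm": m.cleft.lateral_2 if m.cleft else np.nan,
            "cleft_center_nm": m.cleft.center if m.cleft else np.nan,
            "cleft_mean_nm": m.cleft.cleft_mean if m.cleft else np.nan,
            "cleft_sd_nm": m.cleft.cleft_sd if m.cleft else np.nan,
        }
        rows.append(row)
    return pd.DataFrame(rows)
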