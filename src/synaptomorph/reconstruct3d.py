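"""Contour-to-mesh stitching and surface/volume measurement.

A bouton traced as one closed contour per section is turned into a watertight
triangulated surface by connecting consecutive contours with a triangle band
and capping the first and last contours with planar fans.  The band
correspondence is the cyclic vertex alignment (after arc-length resampling of
both contours to a common vertex count) that minimizes total band area, the
standard objective for stitching parallel planar cross sections.

Sections on which the object was not traced (lost sections, annotation gaps)
are bridged directly: the band simply spans the larger z gap.
"""

from __future__ import annotations

import numpy as np

from .contour_io import Contour, SectionStack, SurfaceMesh

__all__ = [
    "UnsupportedTopologyError",
    "stitch_mesh",
    "mesh_surface_area",
    "mesh_volume",
    "check_bouton_completeness",
    "resample_closed",
]

#: An end contour whose area is below this fraction of the object's maximum
#: cross-section counts as a terminal taper for the completeness check.
TAPER_AREA_FRACTION = 0.25


class UnsupportedTopologyError(ValueError):
    """Raised for contour topologies the v1 stitcher does not handle."""


def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _ensure_ccw(points: np.ndarray) -> np.ndarray:
    return points if _signed_area(points) >= 0 else points[::-1]


def resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polygon to ``n`` vertices equally spaced in arc length.

    The first output vertex coincides with ``points[0]``; the closing vertex
    is not repeated.
    """
    pts = np.asarray(points, dtype=float)
    loop = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(loop, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate contour with zero perimeter")
    targets = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(targets, s, loop[:, 0])
    out[:, 1] = np.interp(targets, s, loop[:, 1])
    return out


def resample_open(points: np.ndarray, n: int) -> np.ndarray:
    """Resample an open polyline to ``n`` vertices equally spaced in arc length."""
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return np.repeat(pts[:1], n, axis=0)
    targets = np.linspace(0.0, total, n)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(targets, s, pts[:, 0])
    out[:, 1] = np.interp(targets, s, pts[:, 1])
    return out


def _tri_areas(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=-1)


def _best_cyclic_offset(lower: np.ndarray, upper: np.ndarray) -> int:
    """Cyclic offset of ``upper`` minimizing the stitched band area."""
    n = len(lower)
    lo_next = np.roll(lower, -1, axis=0)
    best_k, best_cost = 0, np.inf
    for k in range(n):
        up = np.roll(upper, -k, axis=0)
        up_next = np.roll(up, -1, axis=0)
        cost = _tri_areas(lower, lo_next, up_next).sum()
        cost += _tri_areas(lower, up_next, up).sum()
        if cost < best_cost:
            best_cost, best_k = cost, k
    return best_k


def _band_triangles(i0: int, i1: int, n: int) -> np.ndarray:
    """Index triples stitching vertex blocks ``i0..i0+n`` and ``i1..i1+n``."""
    i = np.arange(n)
    j = (i + 1) % n
    lower, lower_next = i0 + i, i0 + j
    upper, upper_next = i1 + i, i1 + j
    t1 = np.column_stack([lower, lower_next, upper_next])
    t2 = np.column_stack([lower, upper_next, upper])
    return np.vstack([t1, t2])


def stitch_mesh(stack: SectionStack, object_id: str) -> SurfaceMesh:
    """Reconstruct a watertight surface from an object's closed contours.

    Requires at least two closed contours on two distinct sections and at
    most one contour per section (branching objects are rejected).  The first
    and last contours are capped by planar centroid fans at their section
    planes, so the returned mesh bounds a volume.
    """
    by_section: dict[int, list[Contour]] = {}
    for c in stack.contours_for(object_id):
        if not c.closed:
            continue
        by_section.setdefault(c.section_index, []).append(c)
    if not by_section:
        raise ValueError(f"no closed contours found for object {object_id!r}")
    for idx, cs in by_section.items():
        if len(cs) > 1:
            raise UnsupportedTopologyError(
                f"object {object_id!r} has {len(cs)} contours on section {idx}; "
                "branching topology is not supported"
            )
    if len(by_section) < 2:
        raise ValueError(
            f"object {object_id!r} appears on a single section; need >= 2 to stitch"
        )

    zs = stack.section_z()
    order = sorted(by_section)
    contours = [by_section[i][0] for i in order]
    z_levels = [zs[i] for i in order]

    # common vertex count tied to acquisition resolution
    n = max(
        32,
        max(
            int(np.ceil(c.length / max(stack.pixel_size_xy, 1e-9))) for c in contours
        ),
    )
    rings = [resample_closed(_ensure_ccw(c.points), n) for c in contours]

    vertices: list[np.ndarray] = []
    for ring, z in zip(rings, z_levels):
        vertices.append(np.column_stack([ring, np.full(n, z)]))

    # align each ring to its predecessor by minimal band area
    for k in range(1, len(vertices)):
        off = _best_cyclic_offset(vertices[k - 1], vertices[k])
        vertices[k] = np.roll(vertices[k], -off, axis=0)

    verts = np.vstack(vertices)
    tris = [
        _band_triangles(n * (k - 1), n * k, n) for k in range(1, len(vertices))
    ]

    # planar caps: fan from the contour centroid, oriented outward
    bottom_c = vertices[0].mean(axis=0)
    top_c = vertices[-1].mean(axis=0)
    verts = np.vstack([verts, bottom_c, top_c])
    ib, it = len(verts) - 2, len(verts) - 1
    i = np.arange(n)
    j = (i + 1) % n
    tris.append(np.column_stack([np.full(n, ib), j, i]))  # bottom, normal -z
    base = n * (len(vertices) - 1)
    tris.append(np.column_stack([np.full(n, it), base + i, base + j]))  # top, +z

    mesh = SurfaceMesh(verts, np.vstack(tris), watertight=True)
    return mesh


def mesh_surface_area(mesh: SurfaceMesh) -> float:
    """Total triangle area of the mesh (nm^2)."""
    v = mesh.vertices
    t = mesh.triangles
    return float(_tri_areas(v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]).sum())


def mesh_volume(mesh: SurfaceMesh) -> float:
    """Enclosed volume (nm^3) by the divergence theorem.

    Requires a watertight mesh; the signed sum of tetrahedron volumes against
    the origin is orientation-corrected to a positive value.
    """
    if not mesh.watertight:
        raise ValueError("mesh_volume requires a watertight mesh")
    v = mesh.vertices
    t = mesh.triangles
    a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    signed = np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0
    return float(abs(signed))


def check_bouton_completeness(stack: SectionStack, object_id: str) -> str:
    """Classify a bouton's reconstruction completeness within the series.

    Returns ``"incomplete"`` when the object touches the first or last
    section of the stack (the series does not contain it fully),
    ``"complete_en_passant"`` when its cross-section tapers below
    :data:`TAPER_AREA_FRACTION` of the maximum at both ends inside the stack,
    and ``"complete_end_terminal"`` when it tapers at exactly one end.  An
    object strictly inside the stack that tapers at neither end cannot be
    certified and is reported ``"incomplete"``.
    """
    contours = [c for c in stack.contours_for(object_id) if c.role == "bouton_membrane"]
    if not contours:
        raise ValueError(f"no bouton_membrane contours for object {object_id!r}")
    by_section: dict[int, float] = {}
    for c in contours:
        by_section[c.section_index] = by_section.get(c.section_index, 0.0) + c.area
    order = sorted(by_section)
    stack_indices = [s.index for s in stack.sections]
    if order[0] <= stack_indices[0] or order[-1] >= stack_indices[-1]:
        return "incomplete"
    areas = np.array([by_section[i] for i in order])
    amax = areas.max()
    taper_first = areas[0] < TAPER_AREA_FRACTION * amax
    taper_last = areas[-1] < TAPER_AREA_FRACTION * amax
    if taper_first and taper_last:
        return "complete_en_passant"
    if taper_first or taper_last:
        return "complete_end_terminal"
    return "incomplete"
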