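"""Annotation data model and plain-text I/O for serial-section synapse annotations.

The atomic unit of annotation is a planar contour (a closed membrane outline
or an open trace along a membrane specialization) drawn on a single ultrathin
section, plus circular vesicle marks.  A :class:`SectionStack` bundles the
ordered sections of one series together with acquisition geometry (per-section
thickness and in-plane pixel size, both in nanometres).

Conventions
-----------
* All coordinates are nanometres.  The in-plane origin is the lower-left
  corner of a section with y pointing up.
* The z coordinate of section ``i`` is the cumulative sum of the thicknesses
  of the sections listed before it.  Sections lost during cutting should be
  kept in the file as empty ``S`` records so that z bookkeeping stays honest.
* The on-disk format (``.syn``) is line oriented UTF-8 text so that fixtures
  stay diffable; see :func:`read_stack` for the grammar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from shapely.geometry import LineString

__all__ = [
    "ROLES",
    "VESICLE_KINDS",
    "MODALITIES",
    "CLEAR_SV_DIAMETER_RANGE",
    "ParseError",
    "ValidationError",
    "Contour",
    "VesicleMark",
    "Section",
    "SectionStack",
    "SurfaceMesh",
    "read_stack",
    "write_stack",
    "export_mesh",
]

ROLES = frozenset(
    {
        "bouton_membrane",
        "preaz",
        "psd",
        "mitochondrion",
        "dendrite",
        "spine",
        "astrocyte",
    }
)
VESICLE_KINDS = frozenset({"clear", "dense_core"})
MODALITIES = frozenset({"tem", "fibsem", "tomogram"})

#: Expected diameter range for small clear synaptic vesicles (nm).  Marks
#: outside this range are accepted with a warning, never rejected.
CLEAR_SV_DIAMETER_RANGE = (20.0, 80.0)

MESH_FORMATS = ("obj", "ply", "stl")


class ParseError(ValueError):
    """Raised when a ``.syn`` file is syntactically malformed."""


class ValidationError(ValueError):
    """Raised when an annotation violates a structural invariant."""


def _shoelace(points: np.ndarray) -> float:
    """Signed area of a closed polygon given as an (n, 2) vertex array."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _polyline_length(points: np.ndarray, closed: bool) -> float:
    if len(points) < 2:
        return 0.0
    d = np.linalg.norm(np.diff(points, axis=0), axis=1).sum()
    if closed:
        d += float(np.linalg.norm(points[-1] - points[0]))
    return float(d)


def _dedup_consecutive(points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    if len(points) < 2:
        return points
    keep = np.ones(len(points), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(points, axis=0), axis=1) > tol
    return points[keep]


@dataclass
class Contour:
    """A planar polyline on one section, tagged with the structure it outlines.

    ``closed`` contours trace full membranes (bouton, mitochondrion, ...);
    open contours trace membrane specializations (PreAZ, PSD) along a short
    stretch of membrane.  Points are normalized on construction: consecutive
    duplicates are dropped and a closed contour that repeats its first point
    as its last loses the repetition.
    """

    section_index: int
    role: str
    object_id: str
    points: np.ndarray
    closed: bool

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError(
                f"contour {self.object_id!r}: points must be an (n, 2) array"
            )
        pts = _dedup_consecutive(pts)
        if self.closed and len(pts) > 1 and np.linalg.norm(pts[0] - pts[-1]) <= 1e-9:
            pts = pts[:-1]
        self.points = pts

    # -- geometry ---------------------------------------------------------
    @property
    def length(self) -> float:
        """Trace length (nm); includes the closing segment for closed contours."""
        return _polyline_length(self.points, self.closed)

    @property
    def area(self) -> float:
        """Unsigned enclosed area (nm^2); zero for open contours."""
        return abs(_shoelace(self.points)) if self.closed else 0.0

    def validate(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(
                f"contour {self.object_id!r}: unknown role {self.role!r}"
            )
        if self.section_index < 0:
            raise ValidationError(
                f"contour {self.object_id!r}: negative section index"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValidationError(
                f"contour {self.object_id!r}: non-finite coordinates"
            )
        if self.closed:
            if len(self.points) < 3:
                raise ValidationError(
                    f"contour {self.object_id!r}: closed contour needs >= 3 points"
                )
            if self.area <= 0.0:
                raise ValidationError(
                    f"contour {self.object_id!r}: closed contour has zero area"
                )
            loop = LineString(np.vstack([self.points, self.points[:1]]))
            if not loop.is_simple:
                raise ValidationError(
                    f"contour {self.object_id!r}: closed contour self-intersects"
                )
        else:
            if len(self.points) < 2:
                raise ValidationError(
                    f"contour {self.object_id!r}: open contour needs >= 2 points"
                )


@dataclass
class VesicleMark:
    """A circular vesicle annotation: center and diameter on one section.

    ``object_id`` names the parent bouton (all marks of one bouton's vesicle
    cloud share it).  ``docked`` carries the optional tomography annotation;
    ``None`` means "not assessed".
    """

    section_index: int
    object_id: str
    center: np.ndarray
    diameter: float
    kind: str = "clear"
    docked: bool | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(2)
        self.diameter = float(self.diameter)

    def validate(self) -> None:
        if self.kind not in VESICLE_KINDS:
            raise ValidationError(
                f"vesicle mark in {self.object_id!r}: unknown kind {self.kind!r}"
            )
        if not np.all(np.isfinite(self.center)) or not np.isfinite(self.diameter):
            raise ValidationError(
                f"vesicle mark in {self.object_id!r}: non-finite values"
            )
        if self.diameter <= 0:
            raise ValidationError(
                f"vesicle mark in {self.object_id!r}: diameter must be > 0"
            )

    @property
    def diameter_in_range(self) -> bool:
        lo, hi = CLEAR_SV_DIAMETER_RANGE
        return self.kind != "clear" or lo <= self.diameter <= hi


@dataclass
class Section:
    """One ultrathin section: index, thickness (nm) and its annotations."""

    index: int
    thickness: float
    contours: list[Contour] = field(default_factory=list)
    vesicle_marks: list[VesicleMark] = field(default_factory=list)


@dataclass
class SectionStack:
    """An ordered series of sections with acquisition geometry metadata."""

    sections: list[Section] = field(default_factory=list)
    pixel_size_xy: float = 5.0
    modality: str = "tem"
    provenance: str = ""

    # -- queries ----------------------------------------------------------
    def section_z(self) -> dict[int, float]:
        """z (nm) of each section plane: cumulative preceding thicknesses."""
        z, out = 0.0, {}
        for sec in self.sections:
            out[sec.index] = z
            z += sec.thickness
        return out

    def section_center_z(self) -> dict[int, float]:
        """z (nm) of each section's mid-plane."""
        zs = self.section_z()
        return {s.index: zs[s.index] + 0.5 * s.thickness for s in self.sections}

    def section_by_index(self) -> dict[int, Section]:
        return {s.index: s for s in self.sections}

    def contours_for(self, object_id: str) -> list[Contour]:
        return [
            c
            for sec in self.sections
            for c in sec.contours
            if c.object_id == object_id
        ]

    def object_ids(self, role: str | None = None) -> list[str]:
        seen: dict[str, None] = {}
        for sec in self.sections:
            for c in sec.contours:
                if role is None or c.role == role:
                    seen.setdefault(c.object_id, None)
        return list(seen)

    def marks_for(self, object_id: str, kind: str | None = None) -> list[VesicleMark]:
        return [
            m
            for sec in self.sections
            for m in sec.vesicle_marks
            if m.object_id == object_id and (kind is None or m.kind == kind)
        ]

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.pixel_size_xy <= 0:
            raise ValidationError("pixel_size_xy must be > 0")
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        last = None
        for sec in self.sections:
            if last is not None and sec.index <= last:
                raise ValidationError(
                    f"section indices must strictly increase (at {sec.index})"
                )
            last = sec.index
            if not (sec.thickness > 0):
                raise ValidationError(
                    f"section {sec.index}: thickness must be > 0"
                )
        roles: dict[str, str] = {}
        for sec in self.sections:
            for c in sec.contours:
                c.validate()
                if c.section_index != sec.index:
                    raise ValidationError(
                        f"contour {c.object_id!r}: section_index "
                        f"{c.section_index} stored under section {sec.index}"
                    )
                prev = roles.setdefault(c.object_id, c.role)
                if prev != c.role:
                    raise ValidationError(
                        f"object {c.object_id!r} has contours of mixed roles "
                        f"({prev!r} and {c.role!r})"
                    )
        n_out_of_range = 0
        for sec in self.sections:
            for m in sec.vesicle_marks:
                m.validate()
                if m.section_index != sec.index:
                    raise ValidationError(
                        f"vesicle mark in {m.object_id!r}: section_index "
                        f"{m.section_index} stored under section {sec.index}"
                    )
                if not m.diameter_in_range:
                    n_out_of_range += 1
        if n_out_of_range:
            lo, hi = CLEAR_SV_DIAMETER_RANGE
            warnings.warn(
                f"{n_out_of_range} clear vesicle mark(s) have diameters outside "
                f"the expected {lo:.0f}-{hi:.0f} nm (profiles accepted)",
                stacklevel=2,
            )


@dataclass
class SurfaceMesh:
    """A triangulated surface in nm: vertex array (n, 3) and index triples."""

    vertices: np.ndarray
    triangles: np.ndarray
    watertight: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def as_trimesh(self) -> "trimesh.Trimesh":
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.triangles, process=False
        )


# ---------------------------------------------------------------------------
# .syn reader / writer
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    # shortest representation that round-trips exactly
    return repr(float(x))


def read_stack(path: str | Path) -> SectionStack:
    """Read and validate a ``.syn`` annotation file.

    Grammar (whitespace separated, one record per line)::

        #pixel_size_xy <nm>
        #modality <tem|fibsem|tomogram>
        #provenance <free text>
        S <index> <thickness_nm>
        C <section> <role> <object_id> <closed:0|1> x1,y1 x2,y2 ...
        V <section> <object_id> <kind> <cx>,<cy> <diameter_nm> [docked:0|1]

    Other lines starting with ``#`` are comments.  ``C`` and ``V`` records
    must follow the ``S`` record of the section they reference.
    """
    path = Path(path)
    stack = SectionStack(sections=[])
    sections: dict[int, Section] = {}

    def fail(lineno: int, msg: str) -> None:
        raise ParseError(f"{path.name}:{lineno}: {msg}")

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                head = line[1:].split(maxsplit=1)
                if not head:
                    continue
                key = head[0]
                rest = head[1] if len(head) > 1 else ""
                if key == "pixel_size_xy":
                    try:
                        stack.pixel_size_xy = float(rest)
                    except ValueError:
                        fail(lineno, f"bad pixel_size_xy {rest!r}")
                elif key == "modality":
                    stack.modality = rest.strip()
                elif key == "provenance":
                    stack.provenance = rest
                continue
            tok = line.split()
            kind = tok[0]
            try:
                if kind == "S":
                    if len(tok) != 3:
                        fail(lineno, "S record needs: S <index> <thickness>")
                    idx, thick = int(tok[1]), float(tok[2])
                    if idx in sections:
                        fail(lineno, f"duplicate section {idx}")
                    sec = Section(index=idx, thickness=thick)
                    sections[idx] = sec
                    stack.sections.append(sec)
                elif kind == "C":
                    if len(tok) < 6:
                        fail(lineno, "C record too short")
                    sec_idx = int(tok[1])
                    if sec_idx not in sections:
                        fail(lineno, f"contour references undeclared section {sec_idx}")
                    role, object_id = tok[2], tok[3]
                    closed = tok[4] not in ("0", "false")
                    pts = np.array(
                        [[float(v) for v in p.split(",")] for p in tok[5:]]
                    )
                    sections[sec_idx].contours.append(
                        Contour(sec_idx, role, object_id, pts, closed)
                    )
                elif kind == "V":
                    if len(tok) not in (6, 7):
                        fail(lineno, "V record needs 6 or 7 fields")
                    sec_idx = int(tok[1])
                    if sec_idx not in sections:
                        fail(lineno, f"vesicle references undeclared section {sec_idx}")
                    object_id, vkind = tok[2], tok[3]
                    cx, cy = (float(v) for v in tok[4].split(","))
                    diameter = float(tok[5])
                    docked: bool | None = None
                    if len(tok) == 7:
                        if not tok[6].startswith("docked:"):
                            fail(lineno, f"unexpected field {tok[6]!r}")
                        docked = tok[6].split(":", 1)[1] == "1"
                    sections[sec_idx].vesicle_marks.append(
                        VesicleMark(sec_idx, object_id, (cx, cy), diameter, vkind, docked)
                    )
                else:
                    fail(lineno, f"unknown record type {kind!r}")
            except ParseError:
                raise
            except (ValueError, IndexError) as exc:
                fail(lineno, f"malformed record ({exc})")

    stack.sections.sort(key=lambda s: s.index)
    stack.validate()
    return stack


def write_stack(stack: SectionStack, path: str | Path) -> Path:
    """Write a stack to ``path`` in ``.syn`` format.

    ``write_stack`` followed by :func:`read_stack` reproduces the stack
    exactly (coordinates are written with full float precision).
    """
    path = Path(path)
    lines = [f"#pixel_size_xy {_fmt(stack.pixel_size_xy)}", f"#modality {stack.modality}"]
    if stack.provenance:
        lines.append(f"#provenance {stack.provenance}")
    for sec in stack.sections:
        lines.append(f"S {sec.index} {_fmt(sec.thickness)}")
        for c in sec.contours:
            pts = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in c.points)
            lines.append(
                f"C {sec.index} {c.role} {c.object_id} {1 if c.closed else 0} {pts}"
            )
        for m in sec.vesicle_marks:
            rec = (
                f"V {sec.index} {m.object_id} {m.kind} "
                f"{_fmt(m.center[0])},{_fmt(m.center[1])} {_fmt(m.diameter)}"
            )
            if m.docked is not None:
                rec += f" docked:{1 if m.docked else 0}"
            lines.append(rec)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def export_mesh(mesh: SurfaceMesh, path: str | Path, format: str = "obj") -> Path:
    """Export a surface mesh to OBJ, PLY (ascii) or STL.

    Vertex order and count are preserved for OBJ and PLY; STL stores bare
    triangles, so re-imports only recover vertices after merging.
    """
    if format not in MESH_FORMATS:
        raise ValueError(f"unknown mesh format {format!r}; use one of {MESH_FORMATS}")
    if mesh.n_vertices == 0 or mesh.n_triangles == 0:
        raise ValueError("cannot export an empty mesh")
    path = Path(path)
    tm = mesh.as_trimesh()
    if format == "ply":
        data = tm.export(file_type="ply", encoding="ascii")
    else:
        data = tm.export(file_type=format)
    if isinstance(data, bytes):
        path.write_bytes(data)
    else:
        path.write_text(data)
    return path
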