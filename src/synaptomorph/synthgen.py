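"""Synthetic ground-truth scenes and a serial-section slicer.

A scene is an analytically defined synaptic bouton — an ellipsoid membrane
carrying one to three active-zone patches, a cloud of clear synaptic
vesicles with prescribed pool membership, dense-core vesicles, docked
vesicles and a mitochondrion.  The slicer cuts the scene into a
:class:`~synaptomorph.contour_io.SectionStack` the way an ultramicrotome and
annotator would produce one: every surface is intersected with each section's
central plane, contours are polygonized at the acquisition pixel size and
quantized to the pixel grid, and a vesicle yields a circular mark on the
section whose central plane cuts it, with the chord diameter at that plane.

Because the scene is analytic, every estimator in the package has an exact
reference: surface area and volume (closed form / high-order quadrature),
PreAZ patch area (quadrature), per-vesicle membrane-to-PreAZ distances and
pool labels (recorded at placement), dense-core and docked identities, and
cleft width readings.

The slicing model is deliberately simple and honest about its losses: a
vesicle whose chord at every central plane is smaller than the visibility
threshold produces no mark (small vesicles can be missed), and dense-core
vesicles larger than one section produce marks on consecutive sections
(realistic double counts for the dedup rule to remove).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import LineString, Point

from .contour_io import Contour, Section, SectionStack, VesicleMark

__all__ = [
    "SceneSpec",
    "SectionParams",
    "VesicleParams",
    "AZPatch",
    "SceneVesicle",
    "Scene",
    "GroundTruth",
    "FeasibilityError",
    "make_scene",
    "slice_scene",
    "slice_tomogram",
    "make_stack",
]

#: Profiles with an in-plane chord below this diameter (nm) are too faint to
#: annotate at a 5 nm pixel size and produce no mark.
MIN_MARK_DIAMETER = 10.0


class FeasibilityError(ValueError):
    """Raised when a scene specification cannot be realised geometrically."""


@dataclass
class VesicleParams:
    """Clear-vesicle cloud parameters.

    ``pool_fractions`` are the target fractions over the five distance bands
    (<=10, 10-20, 20-60, 60-200, >200 nm); they must sum to 1.  Counts per
    band are assigned exactly (largest-remainder rounding), not sampled.
    """

    n_total: int = 500
    diameter_mean: float = 40.0
    diameter_sd: float = 5.0
    pool_fractions: tuple[float, float, float, float, float] = (
        0.02,
        0.03,
        0.10,
        0.35,
        0.50,
    )
    resting_max_nm: float = 450.0
    #: Undocked vesicles keep at least this membrane-to-PreAZ distance (nm):
    #: membrane attachment is a distinct state reserved for docked vesicles.
    min_undocked_distance_nm: float = 4.0


@dataclass
class SectionParams:
    """Acquisition geometry: section thickness (nm) and in-plane pixel size."""

    thickness_mean: float = 55.0
    thickness_jitter: float = 5.0
    pixel_size: float = 5.0
    modality: str = "tem"


@dataclass
class SceneSpec:
    """Parameters of one synthetic bouton scene.

    Defaults emulate a mid-sized neocortical bouton: an ellipsoid of about
    4.5 um^2 surface area, one 60 degree active-zone patch of ~0.2 um^2, a
    ~22 nm cleft, and a 500-vesicle cloud — with TEM-style 55 +- 5 nm
    sections at 5 nm pixels.
    """

    seed: int = 1
    bouton_semi_axes: tuple[float, float, float] = (700.0, 600.0, 500.0)
    n_az: int = 1
    az_arc_deg: float = 60.0
    az_z_halfheight: float = 140.0
    cleft_width: float = 22.0
    cleft_sd: float = 1.0
    vesicles: VesicleParams = field(default_factory=VesicleParams)
    n_dcv: int = 5
    n_docked: int = 4
    n_mitochondria: int = 1
    section: SectionParams = field(default_factory=SectionParams)

    def validate(self) -> None:
        a, b, c = self.bouton_semi_axes
        if min(a, b, c) <= 0:
            raise FeasibilityError("bouton semi-axes must be positive")
        if not 1 <= self.n_az <= 3:
            raise FeasibilityError("n_az must be 1..3")
        if abs(sum(self.vesicles.pool_fractions) - 1.0) > 1e-9:
            raise FeasibilityError("pool_fractions must sum to 1")
        if self.cleft_width <= 0:
            raise FeasibilityError("cleft_width must be positive")
        if self.az_z_halfheight >= c:
            raise FeasibilityError("AZ z extent must fit inside the bouton")


@dataclass
class AZPatch:
    """An active-zone patch on the bouton wall.

    The patch is the band of the ellipsoid surface with cross-section
    parameter angle psi within ``psi_halfwidth`` of ``psi_center`` and z in
    ``[z_min, z_max]``.
    """

    patch_id: str
    psi_center: float
    psi_halfwidth: float
    z_min: float
    z_max: float


@dataclass
class SceneVesicle:
    vesicle_id: str
    center: np.ndarray  # (3,) nm
    diameter: float
    kind: str  # clear | dense_core
    pool: str | None
    true_distance: float  # nm, membrane to PreAZ in the vesicle's mid-plane
    docked: bool = False
    az_index: int | None = None


@dataclass
class Scene:
    spec: SceneSpec
    semi_axes: tuple[float, float, float]
    patches: list[AZPatch]
    vesicles: list[SceneVesicle]          # clear, incl. docked
    dcvs: list[SceneVesicle]
    mitochondria: list[tuple[np.ndarray, tuple[float, float, float]]]
    bouton_id: str = "b0"


@dataclass
class GroundTruth:
    """Exact quantities of a scene, plus slicing provenance.

    ``pool_counts`` are per-bin counts over all clear vesicles (docked ones
    included; they sit at distance 0).  ``mark_sources`` is filled by the
    slicer: ``(section_index, position_in_section) -> vesicle_id`` for every
    emitted mark, letting tests separate "not recovered" from "never
    visible".
    """

    surface_area: float
    volume: float
    sa_preaz: list[float]
    pool_counts: dict[str, int]
    true_distances: dict[str, float]
    vesicle_pools: dict[str, str]
    dcv_ids: list[str]
    docked_ids: list[str]
    cleft_triples: list[tuple[float, float, float]]
    mark_sources: dict[tuple[int, int], str] = field(default_factory=dict)

    def visible_ids(self) -> set[str]:
        return set(self.mark_sources.values())


# ---------------------------------------------------------------------------
# analytic ellipsoid geometry
# ---------------------------------------------------------------------------

def _cross_section_scale(z: float, c: float) -> float:
    return float(np.sqrt(max(0.0, 1.0 - (z / c) ** 2)))


def _ellipse_point(a2: float, b2: float, psi: np.ndarray) -> np.ndarray:
    return np.column_stack([a2 * np.cos(psi), b2 * np.sin(psi)])


def _ellipse_inward_normal(a2: float, b2: float, psi: float) -> np.ndarray:
    n = np.array([np.cos(psi) / a2, np.sin(psi) / b2])
    return -n / np.linalg.norm(n)


def ellipsoid_surface_area(a: float, b: float, c: float, order: int = 200) -> float:
    """Ellipsoid surface area by Gauss-Legendre quadrature (high order)."""
    xt, wt = np.polynomial.legendre.leggauss(order)
    theta = 0.5 * np.pi * (xt + 1.0)
    wtheta = 0.5 * np.pi * wt
    phi = np.pi * (xt + 1.0)
    wphi = np.pi * wt
    st, ct = np.sin(theta), np.cos(theta)
    sp, cp = np.sin(phi), np.cos(phi)
    # |r_theta x r_phi| = sin(theta) * sqrt((bc st cp)^2 + (ac st sp)^2 + (ab ct)^2)
    st2 = st[:, None] ** 2
    integrand = st[:, None] * np.sqrt(
        (b * c) ** 2 * st2 * cp[None, :] ** 2
        + (a * c) ** 2 * st2 * sp[None, :] ** 2
        + (a * b) ** 2 * (ct[:, None] ** 2)
    )
    return float(wtheta @ integrand @ wphi)


def patch_surface_area(
    a: float, b: float, c: float, patch: AZPatch, order: int = 120
) -> float:
    """Exact area (quadrature) of an AZ patch band on the ellipsoid."""
    xt, wt = np.polynomial.legendre.leggauss(order)
    z = 0.5 * (patch.z_max - patch.z_min) * xt + 0.5 * (patch.z_max + patch.z_min)
    wz = 0.5 * (patch.z_max - patch.z_min) * wt
    psi0, hw = patch.psi_center, patch.psi_halfwidth
    psi = hw * xt + psi0
    wpsi = hw * wt
    k = np.sqrt(np.clip(1.0 - (z / c) ** 2, 0.0, None))  # (order,)
    # surface element for r(psi, z) = (a k cos, b k sin, z):
    # |r_psi x r_z| = sqrt(b^2 k^2 cos^2 + a^2 k^2 sin^2 + a^2 b^2 z^2 / c^4)
    cos2 = np.cos(psi)[None, :] ** 2
    sin2 = np.sin(psi)[None, :] ** 2
    k2 = (k**2)[:, None]
    integrand = np.sqrt(
        b**2 * k2 * cos2 + a**2 * k2 * sin2 + (a * b) ** 2 * (z[:, None] / c**2) ** 2
    )
    return float(wz @ integrand @ wpsi)


def _patch_arc(
    scene: Scene, patch: AZPatch, z: float, step_nm: float = 2.0
) -> np.ndarray:
    """Polyline of the PreAZ outline at height z (unquantized)."""
    a, b, c = scene.semi_axes
    k = _cross_section_scale(z, c)
    a2, b2 = a * k, b * k
    arc_len = patch.psi_halfwidth * 2 * max(a2, b2)
    n = max(8, int(np.ceil(arc_len / step_nm)) + 1)
    psi = np.linspace(
        patch.psi_center - patch.psi_halfwidth,
        patch.psi_center + patch.psi_halfwidth,
        n,
    )
    return _ellipse_point(a2, b2, psi)


def _true_distance(scene: Scene, patch: AZPatch, center: np.ndarray, radius: float) -> float:
    """Membrane-to-PreAZ distance in the vesicle's own mid-plane (nm)."""
    z = float(center[2])
    zc = float(np.clip(z, patch.z_min, patch.z_max))
    arc = _patch_arc(scene, patch, zc)
    dz = z - zc
    d2 = LineString(arc).distance(Point(center[:2]))
    return max(0.0, float(np.hypot(d2, dz)) - radius)


def _inside_ellipsoid(center: np.ndarray, axes, margin: float) -> bool:
    a, b, c = axes
    x, y, z = center
    return (x / (a - margin)) ** 2 + (y / (b - margin)) ** 2 + (
        z / (c - margin)
    ) ** 2 <= 1.0


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------

_POOL_BANDS = {
    "rrp_p10": (0.0, 10.0),
    "rrp_p20": (10.0, 20.0),
    "interzone_20_60": (20.0, 60.0),
    "rp_60_200": (60.0, 200.0),
    "resting_gt200": (200.0, None),
}
_POOL_ORDER = tuple(_POOL_BANDS)


def _largest_remainder_counts(fractions, n: int) -> list[int]:
    raw = np.asarray(fractions, dtype=float) * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in range(short):
        counts[order[i]] += 1
    return counts.tolist()


def _assign_band(distance: float) -> str:
    if distance <= 10.0:
        return "rrp_p10"
    if distance <= 20.0:
        return "rrp_p20"
    if distance <= 60.0:
        return "interzone_20_60"
    if distance <= 200.0:
        return "rp_60_200"
    return "resting_gt200"


def make_scene(spec: SceneSpec) -> tuple[Scene, GroundTruth]:
    """Build a deterministic scene and its exact ground truth from a spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    a, b, c = spec.bouton_semi_axes

    # active-zone patches evenly spaced in parameter angle
    psi_start = rng.uniform(0.0, 2 * np.pi)
    hw = np.deg2rad(spec.az_arc_deg) / 2.0
    patches = []
    for i in range(spec.n_az):
        z_mid = rng.uniform(-0.2, 0.2) * spec.az_z_halfheight
        patches.append(
            AZPatch(
                patch_id=f"az{i}",
                psi_center=float(psi_start + i * 2 * np.pi / spec.n_az),
                psi_halfwidth=float(hw),
                z_min=float(z_mid - spec.az_z_halfheight),
                z_max=float(z_mid + spec.az_z_halfheight),
            )
        )

    scene = Scene(
        spec=spec,
        semi_axes=spec.bouton_semi_axes,
        patches=patches,
        vesicles=[],
        dcvs=[],
        mitochondria=[],
    )

    # feasibility: vesicle cloud must fit in the bouton with room to spare
    vp = spec.vesicles
    volume = 4.0 / 3.0 * np.pi * a * b * c
    cloud_volume = (vp.n_total + spec.n_docked) * (
        np.pi / 6.0 * (vp.diameter_mean + 3 * vp.diameter_sd) ** 3
    )
    if cloud_volume > 0.25 * volume:
        raise FeasibilityError(
            f"{vp.n_total} vesicles of ~{vp.diameter_mean:.0f} nm do not fit "
            "inside the bouton"
        )

    def sample_diameter() -> float:
        return float(np.clip(rng.normal(vp.diameter_mean, vp.diameter_sd), 20.0, 80.0))

    def place_vesicle(pool: str, vid: str, docked: bool = False) -> SceneVesicle:
        lo, hi = _POOL_BANDS[pool]
        hi_eff = vp.resting_max_nm if hi is None else hi
        for _ in range(500):
            patch = patches[int(rng.integers(len(patches)))]
            diameter = sample_diameter()
            r = 0.5 * diameter
            if docked:
                d_target = 0.0
            else:
                d_target = rng.uniform(max(lo, vp.min_undocked_distance_nm), hi_eff)
            inset = 0.15 * (patch.z_max - patch.z_min)
            z = rng.uniform(patch.z_min + inset, patch.z_max - inset)
            psi = rng.uniform(
                patch.psi_center - 0.7 * patch.psi_halfwidth,
                patch.psi_center + 0.7 * patch.psi_halfwidth,
            )
            k = _cross_section_scale(z, c)
            a2, b2 = a * k, b * k
            p = _ellipse_point(a2, b2, np.array([psi]))[0]
            n_in = _ellipse_inward_normal(a2, b2, psi)
            center = np.array(
                [p[0] + n_in[0] * (d_target + r), p[1] + n_in[1] * (d_target + r), z]
            )
            # near-wall placements along the inward normal are safe because
            # the vesicle radius is far below the bouton's minimal radius of
            # curvature; only deep placements need the far-wall margin test
            if d_target >= 50.0 and not _inside_ellipsoid(center, (a, b, c), margin=r):
                continue
            tau = _true_distance(scene, patch, center, r)
            if docked:
                tau = 0.0
            elif _assign_band(tau) != pool or tau < vp.min_undocked_distance_nm:
                continue
            if docked and any(
                np.linalg.norm(center - v.center) < r + 0.5 * v.diameter + 10.0
                for v in scene.vesicles
                if v.docked
            ):
                continue
            return SceneVesicle(
                vesicle_id=vid,
                center=center,
                diameter=diameter,
                kind="clear",
                pool=_assign_band(tau),
                true_distance=tau,
                docked=docked,
                az_index=patches.index(patch),
            )
        raise FeasibilityError(f"could not place vesicle {vid!r} in pool {pool!r}")

    counts = _largest_remainder_counts(vp.pool_fractions, vp.n_total)
    vid = 0
    for pool, n_pool in zip(_POOL_ORDER, counts):
        for _ in range(n_pool):
            scene.vesicles.append(place_vesicle(pool, f"sv{vid:04d}"))
            vid += 1
    docked_ids = []
    for i in range(spec.n_docked):
        v = place_vesicle("rrp_p10", f"dk{i:03d}", docked=True)
        scene.vesicles.append(v)
        docked_ids.append(v.vesicle_id)

    # dense-core vesicles: anywhere inside, mutually separated so that the
    # dedup rule can never merge two distinct DCVs
    dcv_ids = []
    for i in range(spec.n_dcv):
        for _ in range(500):
            diameter = rng.uniform(50.0, 90.0)
            r = 0.5 * diameter
            center = rng.uniform(-1.0, 1.0, size=3) * np.array([a, b, c]) * 0.8
            if not _inside_ellipsoid(center, (a, b, c), margin=r + 5.0):
                continue
            if any(
                np.linalg.norm(center - d.center) < 150.0 for d in scene.dcvs
            ):
                continue
            dcv = SceneVesicle(
                vesicle_id=f"dcv{i:02d}",
                center=center,
                diameter=diameter,
                kind="dense_core",
                pool=None,
                true_distance=float("nan"),
            )
            scene.dcvs.append(dcv)
            dcv_ids.append(dcv.vesicle_id)
            break
        else:
            raise FeasibilityError("could not place dense-core vesicles")

    # mitochondria: small ellipsoids tucked toward the bouton center
    for i in range(spec.n_mitochondria):
        axes_m = (0.3 * a, 0.2 * b, 0.2 * c)
        center_m = np.array([-0.35 * a, 0.0, 0.1 * c]) + rng.normal(0, 10.0, 3)
        scene.mitochondria.append((center_m, axes_m))

    # cleft width readings at the two lateral edges and the center per AZ
    cleft_triples = [
        tuple(rng.normal(spec.cleft_width, spec.cleft_sd, 3).tolist())
        for _ in patches
    ]

    truth = GroundTruth(
        surface_area=ellipsoid_surface_area(a, b, c),
        volume=float(volume),
        sa_preaz=[patch_surface_area(a, b, c, p) for p in patches],
        pool_counts={
            p: sum(1 for v in scene.vesicles if v.pool == p) for p in _POOL_ORDER
        },
        true_distances={v.vesicle_id: v.true_distance for v in scene.vesicles},
        vesicle_pools={v.vesicle_id: v.pool for v in scene.vesicles},
        dcv_ids=dcv_ids,
        docked_ids=docked_ids,
        cleft_triples=cleft_triples,
    )
    return scene, truth


# ---------------------------------------------------------------------------
# slicing
# ---------------------------------------------------------------------------

def _quantize(points: np.ndarray, pixel: float) -> np.ndarray:
    return np.round(points / pixel) * pixel


def _ellipse_contour(
    cx: float, cy: float, a2: float, b2: float, z_unused: float, pixel: float
) -> np.ndarray | None:
    if min(a2, b2) < 2.0 * pixel:
        return None  # profile too small to trace
    h = ((a2 - b2) / (a2 + b2)) ** 2
    perimeter = np.pi * (a2 + b2) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
    n = max(32, int(np.ceil(perimeter / pixel)))
    psi = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([cx + a2 * np.cos(psi), cy + b2 * np.sin(psi)])
    return _quantize(pts, pixel)


def slice_scene(
    scene: Scene,
    section: SectionParams | None = None,
    *,
    rng: np.random.Generator | int | None = None,
    margin_sections: int = 3,
    z_window: tuple[float, float] | None = None,
    min_mark_diameter: float = MIN_MARK_DIAMETER,
    include: set[str] | None = None,
    truth: GroundTruth | None = None,
) -> SectionStack:
    """Cut a scene into an annotated section stack.

    Section thicknesses are drawn per section (mean +- jitter); the grid's
    phase relative to the scene is random, so whether a small vesicle is cut
    by any central plane is a matter of luck, as it is at the microtome.
    When ``truth`` is given, the provenance of every emitted vesicle mark is
    recorded in ``truth.mark_sources``.
    """
    spec = scene.spec
    if section is None:
        section = spec.section
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if include is None:
        include = {"bouton", "preaz", "psd", "mito", "vesicles"}

    a, b, c = scene.semi_axes
    t_mean, t_sd = section.thickness_mean, section.thickness_jitter
    pixel = section.pixel_size

    if z_window is None:
        z_lo = -c - margin_sections * t_mean - rng.uniform(0.0, t_mean)
        z_hi = c + margin_sections * t_mean
    else:
        z_lo, z_hi = z_window

    thicknesses: list[float] = []
    total = 0.0
    while total < z_hi - z_lo:
        t = float(np.clip(rng.normal(t_mean, t_sd), max(1.0, t_mean - 4 * t_sd), t_mean + 4 * t_sd)) if t_sd > 0 else t_mean
        thicknesses.append(t)
        total += t

    stack = SectionStack(
        sections=[],
        pixel_size_xy=pixel,
        modality=section.modality,
        provenance=f"synthgen seed={spec.seed} modality={section.modality}",
    )

    z_bottom = z_lo
    for idx, t in enumerate(thicknesses):
        sec = Section(index=idx, thickness=t)
        zc = z_bottom + 0.5 * t

        if "bouton" in include and abs(zc) < c:
            k = _cross_section_scale(zc, c)
            pts = _ellipse_contour(0.0, 0.0, a * k, b * k, zc, pixel)
            if pts is not None:
                try:
                    contour = Contour(idx, "bouton_membrane", scene.bouton_id, pts, True)
                    contour.validate()
                    sec.contours.append(contour)
                except Exception:
                    pass  # grid-degenerate sliver; skip like an annotator would

        for p_i, patch in enumerate(scene.patches):
            if not (patch.z_min <= zc <= patch.z_max) or abs(zc) >= c:
                continue
            arc = _patch_arc(scene, patch, zc, step_nm=max(pixel, 1.0))
            if "preaz" in include:
                pts = _quantize(arc, pixel)
                try:
                    contour = Contour(idx, "preaz", patch.patch_id, pts, False)
                    contour.validate()
                    sec.contours.append(contour)
                except Exception:
                    pass
            if "psd" in include:
                k = _cross_section_scale(zc, c)
                a2, b2 = a * k, b * k
                normals = np.column_stack(
                    [
                        arc[:, 0] / a2**2,
                        arc[:, 1] / b2**2,
                    ]
                )
                normals /= np.linalg.norm(normals, axis=1)[:, None]
                psd_pts = _quantize(arc + spec.cleft_width * normals, pixel)
                try:
                    contour = Contour(idx, "psd", f"psd{p_i}", psd_pts, False)
                    contour.validate()
                    sec.contours.append(contour)
                except Exception:
                    pass

        if "mito" in include:
            for m_i, (center_m, axes_m) in enumerate(scene.mitochondria):
                dz = zc - center_m[2]
                if abs(dz) >= axes_m[2]:
                    continue
                km = np.sqrt(1.0 - (dz / axes_m[2]) ** 2)
                pts = _ellipse_contour(
                    center_m[0], center_m[1], axes_m[0] * km, axes_m[1] * km, zc, pixel
                )
                if pts is not None:
                    try:
                        contour = Contour(idx, "mitochondrion", f"mito{m_i}", pts, True)
                        contour.validate()
                        sec.contours.append(contour)
                    except Exception:
                        pass

        if "vesicles" in include:
            for v in list(scene.vesicles) + list(scene.dcvs):
                r = 0.5 * v.diameter
                dz = zc - v.center[2]
                if abs(dz) >= r:
                    continue
                chord = 2.0 * float(np.sqrt(r**2 - dz**2))
                if chord < min_mark_diameter:
                    continue
                center2 = _quantize(v.center[:2], pixel)
                mark = VesicleMark(
                    section_index=idx,
                    object_id=scene.bouton_id,
                    center=center2,
                    diameter=round(chord, 1),
                    kind=v.kind,
                    docked=True if v.docked else None,
                )
                sec.vesicle_marks.append(mark)
                if truth is not None:
                    truth.mark_sources[(idx, len(sec.vesicle_marks) - 1)] = (
                        v.vesicle_id
                    )

        stack.sections.append(sec)
        z_bottom += t

    stack.validate()
    return stack


def slice_tomogram(
    scene: Scene,
    patch_index: int = 0,
    *,
    thickness: float = 2.0,
    pixel_size: float = 1.0,
    pad_nm: float = 30.0,
    rng: np.random.Generator | int | None = None,
    truth: GroundTruth | None = None,
) -> SectionStack:
    """Slice a thin tomographic volume around one AZ patch.

    Emulates the 200-300 nm re-sectioned tomogram used to count docked
    vesicles: virtual sections a few nm thick, fine pixels, and only the
    PreAZ outline plus vesicle marks annotated.
    """
    patch = scene.patches[patch_index]
    window = (patch.z_min - pad_nm, patch.z_max + pad_nm)
    params = SectionParams(
        thickness_mean=thickness,
        thickness_jitter=0.0,
        pixel_size=pixel_size,
        modality="tomogram",
    )
    return slice_scene(
        scene,
        params,
        rng=rng,
        z_window=window,
        include={"preaz", "vesicles"},
        truth=truth,
    )


def make_stack(
    spec: SceneSpec | None = None, **slice_kwargs
) -> tuple[SectionStack, GroundTruth, Scene]:
    """Convenience: build a scene from a spec and slice it in one call."""
    if spec is None:
        spec = SceneSpec()
    scene, truth = make_scene(spec)
    stack = slice_scene(scene, truth=truth, **slice_kwargs)
    return stack, truth, scene
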