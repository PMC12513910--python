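"""Analytic stack builders shared across tests.

These construct section stacks directly from closed-form geometry (squares,
circles, cylinder walls) so that tests of the reconstruction and measurement
code have oracles that are independent of the package's own scene generator.
"""

from __future__ import annotations

import numpy as np

from synaptomorph.contour_io import Contour, Section, SectionStack, VesicleMark


def square(side: float, cx: float = 0.0, cy: float = 0.0) -> np.ndarray:
    h = side / 2.0
    return np.array(
        [[cx - h, cy - h], [cx + h, cy - h], [cx + h, cy + h], [cx - h, cy + h]]
    )


def circle(r: float, n: int = 128, cx: float = 0.0, cy: float = 0.0) -> np.ndarray:
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])


def arc(r: float, deg: float, n: int = 64, psi0: float = 0.0) -> np.ndarray:
    half = np.deg2rad(deg) / 2.0
    t = np.linspace(psi0 - half, psi0 + half, n)
    return np.column_stack([r * np.cos(t), r * np.sin(t)])


def build_stack(sections, pixel_size: float = 5.0, modality: str = "tem") -> SectionStack:
    """sections: iterable of (index, thickness, [Contour], [VesicleMark])."""
    secs = [
        Section(index=i, thickness=t, contours=list(cs), vesicle_marks=list(ms))
        for i, t, cs, ms in sections
    ]
    stack = SectionStack(sections=secs, pixel_size_xy=pixel_size)
    stack.modality = modality
    stack.validate()
    return stack


def box_stack(side: float = 200.0, thickness: float = 50.0, n: int = 2) -> SectionStack:
    secs = [
        (i, thickness, [Contour(i, "bouton_membrane", "b0", square(side), True)], [])
        for i in range(n)
    ]
    return build_stack(secs)


def sphere_stack(
    radius: float = 500.0,
    thickness: float = 50.0,
    pixel_size: float = 5.0,
    object_id: str = "s0",
) -> SectionStack:
    """Slice a sphere analytically: circle contours at section mid-planes."""
    sections = []
    z0 = -radius - thickness
    n_sec = int(np.ceil((2 * radius + 2 * thickness) / thickness))
    for i in range(n_sec):
        zm = z0 + (i + 0.5) * thickness
        cs = []
        if abs(zm) < radius:
            r = float(np.sqrt(radius**2 - zm**2))
            if r > 2 * pixel_size:
                npts = max(32, int(np.ceil(2 * np.pi * r / pixel_size)))
                cs = [Contour(i, "bouton_membrane", object_id, circle(r, npts), True)]
        sections.append((i, thickness, cs, []))
    return build_stack(sections, pixel_size)


def cylinder_patch_stack(
    radius: float = 400.0,
    thickness: float = 50.0,
    n_sections: int = 4,
    arc_deg: float = 60.0,
    cleft: float | None = None,
    skip_sections: tuple[int, ...] = (),
) -> SectionStack:
    """Cylinder wall with a PreAZ arc traced exactly on the membrane.

    Optionally adds a parallel PSD outline offset outward by ``cleft`` and
    omits the membrane contour on ``skip_sections`` (gap bridging tests).
    """
    sections = []
    for i in range(n_sections):
        cs = []
        if i not in skip_sections:
            npts = max(64, int(np.ceil(2 * np.pi * radius / 5.0)))
            cs.append(Contour(i, "bouton_membrane", "b0", circle(radius, npts), True))
        cs.append(Contour(i, "preaz", "az0", arc(radius, arc_deg), False))
        if cleft is not None:
            cs.append(Contour(i, "psd", "psd0", arc(radius + cleft, arc_deg), False))
        sections.append((i, thickness, cs, []))
    return build_stack(sections)
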