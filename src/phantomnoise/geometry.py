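"""Orientation algebra, point-group symmetry, view grids and error metrics.

Conventions used throughout the package:

* Euler angles are intrinsic ZYZ (phi, theta, psi, degrees):
  R = Rz(phi) @ Ry(theta) @ Rz(psi).
* The rotation takes reference-frame coordinates to particle-frame
  coordinates; the view vector is R applied to +z, so it is independent
  of the in-plane angle psi.
* Shifts (dx, dy) are in pixels, applied to the projection after rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Orientation",
    "SymmetryGroup",
    "ViewGrid",
    "symmetry_operators",
    "view_grid",
    "random_orientations",
    "orientation_errors",
]

_Z = np.array([0.0, 0.0, 1.0])


@dataclass
class Orientation:
    """A rigid particle pose: rotation (unit quaternion) plus 2D shift."""

    rotation: Rotation
    shift: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        self.shift = np.asarray(self.shift, dtype=float)
        if self.shift.shape != (2,):
            raise ValueError("shift must be (dx, dy)")
        q = self.rotation.as_quat()
        if abs(np.linalg.norm(q) - 1.0) > 1e-9:
            raise ValueError("rotation quaternion must be unit norm")

    @classmethod
    def identity(cls) -> "Orientation":
        return cls(Rotation.identity())

    @classmethod
    def from_euler(cls, phi: float, theta: float, psi: float, shift=(0.0, 0.0)) -> "Orientation":
        """Build from intrinsic ZYZ Euler angles in degrees."""
        return cls(Rotation.from_euler("ZYZ", [phi, theta, psi], degrees=True), np.asarray(shift, float))

    @classmethod
    def from_view(cls, view, psi: float = 0.0, shift=(0.0, 0.0)) -> "Orientation":
        """Build from a unit view vector plus in-plane angle (degrees)."""
        view = np.asarray(view, float)
        view = view / np.linalg.norm(view)
        theta = np.degrees(np.arccos(np.clip(view[2], -1, 1)))
        phi = np.degrees(np.arctan2(view[1], view[0])) if theta > 1e-9 else 0.0
        return cls.from_euler(phi, theta, psi, shift)

    @property
    def euler(self) -> np.ndarray:
        """(phi, theta, psi) in degrees, theta in [0, 180]."""
        import warnings

        with warnings.catch_warnings():
            # at theta = 0/180 the split between phi and psi is arbitrary;
            # scipy's choice (psi -> 0) is a valid decomposition
            warnings.simplefilter("ignore", UserWarning)
            ang = self.rotation.as_euler("ZYZ", degrees=True)
        if ang[1] < 0:  # scipy may return theta in [-180, 0]; fold to [0, 180]
            ang = np.array([ang[0] + 180.0, -ang[1], ang[2] + 180.0])
        ang[0] %= 360.0
        ang[2] %= 360.0
        return ang

    @property
    def view(self) -> np.ndarray:
        return self.rotation.apply(_Z)

    @property
    def quaternion(self) -> np.ndarray:
        """Unit quaternion as (w, x, y, z)."""
        x, y, z, w = self.rotation.as_quat()
        return np.array([w, x, y, z])


@dataclass
class SymmetryGroup:
    """A proper point group: Schoenflies label plus its rotation operators."""

    label: str
    operators: Rotation  # stacked; identity first

    @property
    def order(self) -> int:
        return len(self.operators)


_EXPECTED_ORDER = {"T": 12, "O": 24, "I": 60}


def symmetry_operators(label: str) -> SymmetryGroup:
    """All proper rotations of a point group (C_n, D_n, T, O, I), identity first."""
    label = label.strip()
    name = label.upper()
    try:
        if name == "C1":
            ops = Rotation.identity(1)
        else:
            ops = Rotation.create_group(name)
    except (ValueError, KeyError) as exc:
        raise ValueError(
            f"unknown symmetry label {label!r}; supported: C1, Cn, Dn, T, O, I"
        ) from exc
    # put the identity first, deterministic order for the rest
    angles = ops.magnitude()
    order = np.argsort(angles, kind="stable")
    ops = ops[order]
    if name.startswith("C") and name[1:].isdigit():
        expected = int(name[1:])
    elif name.startswith("D") and name[1:].isdigit():
        expected = 2 * int(name[1:])
    else:
        expected = _EXPECTED_ORDER.get(name)
    if expected is not None and len(ops) != expected:
        raise ValueError(f"group {label}: got {len(ops)} operators, expected {expected}")
    return SymmetryGroup(name, ops)


@dataclass
class ViewGrid:
    """Unit view vectors covering the asymmetric unit at a given angular step."""

    views: np.ndarray  # (M, 3)
    angular_step: float  # degrees

    def __len__(self) -> int:
        return len(self.views)

    def orientations(self) -> list[Orientation]:
        return [Orientation.from_view(v) for v in self.views]


def _canonical_orbit_member(orbit: np.ndarray) -> np.ndarray:
    """Deterministic representative of a symmetry orbit of view vectors.

    Highest z first (smallest theta), then lowest azimuth phi in [0, 360).
    For C_n / D_n this reproduces the usual asymmetric-unit boundaries
    (phi in [0, 360/n), D_n additionally theta <= 90 deg); for the
    polyhedral groups it selects one valid fundamental domain.
    """
    z = np.round(orbit[:, 2], 6)
    phi = np.degrees(np.arctan2(orbit[:, 1], orbit[:, 0])) % 360.0
    phi = np.round(phi, 6) % 360.0
    key = np.lexsort((phi, -z))
    return orbit[key[0]]


def in_asymmetric_unit(view: np.ndarray, group: SymmetryGroup, tol: float = 1e-6) -> bool:
    if group.order == 1:
        return True
    orbit = group.operators.apply(view)
    rep = _canonical_orbit_member(orbit)
    return bool(np.linalg.norm(rep - view) < tol)


def view_grid(group: SymmetryGroup, angular_step: float) -> ViewGrid:
    """Near-equal-area view sampling filtered to the asymmetric unit.

    Theta rings at multiples of the step; on each ring the phi spacing is
    step / sin(theta) so the arc length between neighbours is constant;
    the poles enter once.
    """
    if not 0 < angular_step <= 90:
        raise ValueError("angular_step must be in (0, 90] degrees")
    step = float(angular_step)
    views = [np.array([0.0, 0.0, 1.0])]
    n_rings = int(round(180.0 / step))
    for i in range(1, n_rings + 1):
        theta = i * step
        if theta >= 180.0 - 1e-9:
            views.append(np.array([0.0, 0.0, -1.0]))
            break
        st = np.sin(np.radians(theta))
        n_phi = max(1, int(np.ceil(360.0 * st / step)))
        phis = np.arange(n_phi) * (360.0 / n_phi)
        ct = np.cos(np.radians(theta))
        for phi in phis:
            views.append(
                np.array(
                    [st * np.cos(np.radians(phi)), st * np.sin(np.radians(phi)), ct]
                )
            )
    views = np.array(views)
    if group.order > 1:
        keep = [in_asymmetric_unit(v, group) for v in views]
        views = views[np.array(keep)]
    return ViewGrid(views, step)


def random_orientations(n: int, rng: np.random.Generator) -> list[Orientation]:
    """n orientations uniform over SO(3) (normalized 4D Gaussian quaternions)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return [Orientation(Rotation.from_quat(qi)) for qi in q]


def _twist_about_z_deg(rot: Rotation) -> float:
    """Magnitude of the twist component of a rotation about the z axis."""
    x, y, z, w = rot.as_quat()
    if w < 0:
        z, w = -z, -w
    if abs(z) < 1e-15 and abs(w) < 1e-15:
        return 180.0
    ang = np.degrees(2.0 * np.arctan2(z, w))
    ang = (ang + 180.0) % 360.0 - 180.0
    return abs(ang)


def orientation_errors(
    truth: Orientation, estimate: Orientation, group: SymmetryGroup
) -> tuple[float, float, float]:
    """(view_error deg, inplane_error deg, shift_error px), symmetry-minimized.

    The symmetry operator applied to the truth is the one minimizing the
    total rotation angle between the poses; the view error is the angle
    between view vectors, the in-plane error is the twist of the residual
    rotation about the view axis (swing-twist decomposition).
    """
    best_angle = np.inf
    best_rel = None
    for g in group.operators:
        rel = (g * truth.rotation).inv() * estimate.rotation
        ang = rel.magnitude()
        if ang < best_angle:
            best_angle = ang
            best_rel = rel
    view_err = np.degrees(
        np.arccos(np.clip(np.dot(best_rel.apply(_Z), _Z), -1.0, 1.0))
    )
    inplane_err = _twist_about_z_deg(best_rel)
    shift_err = float(np.linalg.norm(truth.shift - estimate.shift))
    return float(view_err), float(inplane_err), shift_err
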