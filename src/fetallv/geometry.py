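"""Axisymmetric truncated-ellipsoid left-ventricular meshes.

The LV is idealised as a thick-walled truncated prolate spheroid.  In prolate
spheroidal coordinates with focal length ``d`` the long axis is

    x = d cosh(lambda) cos(mu),   (y, z) = d sinh(lambda) sin(mu) (cos phi, sin phi)

with ``mu = 0`` at the apex and the base plane at ``mu_base`` (120 degrees by
default), normal to the long axis.  The endocardial and epicardial surfaces
are surfaces of constant ``lambda`` truncated at a common base plane.

The mesh is a structured grid of 5 longitudinal x 4 transmural bicubic
Hermite elements (1 circumferential element, swept analytically), i.e. the
30-node / 20-element reference topology.  Internally only the meridian-plane
fields ``R(xi1, xi2)`` (distance from the long axis, mm) and ``Z(xi1, xi2)``
(position along the long axis, mm) are stored; all quantities of an
axisymmetric configuration follow from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .hermite import HermiteGrid, gauss_legendre_01

__all__ = [
    "KPA_PER_MMHG",
    "ProlateCoords",
    "GeometryParams",
    "HermiteMesh",
    "FiberField",
    "LVMetrics",
    "ShapeVariantSpec",
    "InfeasibleGeometryError",
    "build_lv_mesh",
    "assign_fiber_field",
    "lv_metrics",
    "make_shape_variant",
    "cavity_volume",
    "wall_volume",
    "measure_echo_dimensions",
]

KPA_PER_MMHG = 0.133322  # 1 mmHg in kPa; 0.75 kPa is 5.63 mmHg

# Reference topology: 5 longitudinal x 4 transmural elements.
N_LONG, N_TRANS = 5, 4

# Default transmural fiber helix angles (degrees from circumferential).
ENDO_ANGLE_DEG = 83.0
EPI_ANGLE_DEG = -37.0


class InfeasibleGeometryError(ValueError):
    """Raised when requested dimensions cannot form a valid truncated ellipsoid."""


@dataclass(frozen=True)
class ProlateCoords:
    """A point in prolate spheroidal coordinates."""

    lambda_: float  # transmural coordinate, > 0
    mu: float  # longitudinal coordinate, radians, 0 at apex
    phi: float  # circumferential coordinate, radians
    focal_length: float  # mm

    def __post_init__(self):
        if self.lambda_ <= 0 or self.focal_length <= 0:
            raise ValueError("lambda_ and focal_length must be positive")
        if not (0 <= self.mu < np.pi):
            raise ValueError("mu must lie in [0, pi)")

    def to_cartesian(self) -> np.ndarray:
        """(x, y, z) in mm with x along the long axis."""
        d, lam, mu, phi = self.focal_length, self.lambda_, self.mu, self.phi
        return np.array(
            [
                d * np.cosh(lam) * np.cos(mu),
                d * np.sinh(lam) * np.sin(mu) * np.cos(phi),
                d * np.sinh(lam) * np.sin(mu) * np.sin(phi),
            ]
        )


@dataclass(frozen=True)
class GeometryParams:
    """Unloaded truncated-ellipsoid dimensions.

    ``long_axis`` is the inner apex-to-base length (mm), ``short_axis`` the
    inner equatorial diameter (mm), ``wall_thickness`` the equatorial
    transmural thickness (mm) and ``base_truncation_mu`` the longitudinal
    truncation angle (radians).
    """

    long_axis: float
    short_axis: float
    wall_thickness: float
    base_truncation_mu: float = 2.0 * np.pi / 3.0

    def __post_init__(self):
        if min(self.long_axis, self.short_axis, self.wall_thickness) <= 0:
            raise InfeasibleGeometryError("all dimensions must be positive")
        # hypertrophic walls thicker than the cavity radius remain valid
        # truncated ellipsoids; reject only degenerate thickness
        if self.wall_thickness >= self.short_axis:
            raise InfeasibleGeometryError(
                f"wall thickness {self.wall_thickness} mm must be smaller than "
                f"the inner short-axis diameter {self.short_axis} mm"
            )
        if not (np.pi / 2.0 < self.base_truncation_mu < np.pi):
            raise InfeasibleGeometryError("base truncation must lie in (pi/2, pi)")

    # -- closed-form ellipsoid parameters --------------------------------
    @property
    def inner_semi_long(self) -> float:
        """Inner long semi-axis a = d cosh(lambda_endo)."""
        return self.long_axis / (1.0 - np.cos(self.base_truncation_mu))

    @property
    def inner_semi_short(self) -> float:
        return self.short_axis / 2.0

    @property
    def focal_length(self) -> float:
        a, b = self.inner_semi_long, self.inner_semi_short
        if a <= b:
            raise InfeasibleGeometryError(
                "inner surface is not prolate (long semi-axis <= short semi-axis)"
            )
        return float(np.sqrt(a * a - b * b))

    @property
    def lambda_endo(self) -> float:
        return float(np.arcsinh(self.inner_semi_short / self.focal_length))

    @property
    def lambda_epi(self) -> float:
        d = self.focal_length
        return float(np.arcsinh(np.sinh(self.lambda_endo) + self.wall_thickness / d))

    def cavity_volume_closed_form(self) -> float:
        """Analytic cavity volume of the truncated inner ellipsoid (uL)."""
        c = np.cos(self.base_truncation_mu)
        a, b = self.inner_semi_long, self.inner_semi_short
        return float(np.pi * a * b * b * (2.0 / 3.0 - c + c**3 / 3.0))


@dataclass
class LVMetrics:
    """Scalar measurements of an LV configuration."""

    cavity_volume: float  # uL
    wall_volume: float  # uL
    long_axis: float  # mm, inner apex-to-base
    short_axis: float  # mm, inner equatorial diameter
    wall_thickness: float  # mm, equatorial
    gestational_age: float | None = None  # weeks
    load_state: Literal["unloaded", "end_diastole"] = "unloaded"

    def __post_init__(self):
        if min(
            self.cavity_volume,
            self.wall_volume,
            self.long_axis,
            self.short_axis,
            self.wall_thickness,
        ) <= 0:
            raise ValueError("all LV metrics must be strictly positive")


@dataclass(frozen=True)
class ShapeVariantSpec:
    """A shape perturbation of the reference unloaded geometry."""

    mode: Literal["wall_thickness_scale", "aspect_ratio_scale"]
    scale: float  # fractional change, e.g. +0.30 for a 30% thicker wall
    preserve_unloaded_cavity_volume: bool = True


class HermiteMesh:
    """30-node / 20-element axisymmetric bicubic-Hermite LV mesh.

    ``dofs`` has shape ``(6, 5, 2, 4)``: node grid (longitudinal x transmural),
    field (R, Z), and per-node Hermite DOFs (value, d/dxi1, d/dxi2, mixed).
    """

    grid = HermiteGrid(N_LONG, N_TRANS)

    def __init__(
        self,
        dofs: np.ndarray,
        focal_length: float,
        mu_base: float,
        params: GeometryParams | None = None,
        endo_angle: float = ENDO_ANGLE_DEG,
        epi_angle: float = EPI_ANGLE_DEG,
    ):
        dofs = np.asarray(dofs, dtype=float)
        if dofs.shape != (N_LONG + 1, N_TRANS + 1, 2, 4):
            raise ValueError(f"expected dofs shape (6, 5, 2, 4), got {dofs.shape}")
        self.dofs = dofs
        self.focal_length = float(focal_length)
        self.mu_base = float(mu_base)
        self.params = params
        self.endo_angle = float(endo_angle)
        self.epi_angle = float(epi_angle)

    # -- topology ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.grid.n_nodes  # 30

    @property
    def n_elements(self) -> int:
        return self.grid.n_elements  # 20 (x 1 circumferential)

    @property
    def dofs_r(self) -> np.ndarray:
        return self.grid.flatten(self.dofs[:, :, 0, :])

    @property
    def dofs_z(self) -> np.ndarray:
        return self.grid.flatten(self.dofs[:, :, 1, :])

    def copy(self) -> "HermiteMesh":
        return HermiteMesh(
            self.dofs.copy(),
            self.focal_length,
            self.mu_base,
            self.params,
            self.endo_angle,
            self.epi_angle,
        )

    def with_dofs(self, dofs_r: np.ndarray, dofs_z: np.ndarray) -> "HermiteMesh":
        dofs = np.stack(
            [self.grid.unflatten(dofs_r), self.grid.unflatten(dofs_z)], axis=2
        )
        return HermiteMesh(
            dofs, self.focal_length, self.mu_base, None, self.endo_angle, self.epi_angle
        )

    def scaled(self, factor: float) -> "HermiteMesh":
        """Uniform isotropic scaling of the geometry (all lengths x factor)."""
        out = self.copy()
        out.dofs = out.dofs * factor
        out.focal_length *= factor
        out.params = None
        return out

    # -- evaluation -------------------------------------------------------
    def _split_element(self, element_id: int) -> tuple[int, int]:
        if not (0 <= element_id < self.n_elements):
            raise ValueError(f"element_id must be in [0, {self.n_elements})")
        return element_id // N_TRANS, element_id % N_TRANS

    def meridian(self, element_id: int, s, t, d1: int = 0, d2: int = 0):
        """Evaluate (R, Z) (or a global parametric derivative) on an element."""
        e1, e2 = self._split_element(element_id)
        op = self.grid.operator(e1, e2, s, t, d1=d1, d2=d2)
        return op @ self.dofs_r, op @ self.dofs_z

    def evaluate_field(self, element_id: int, local_coords) -> np.ndarray:
        """Physical position (x, y, z) in mm at element-local ``(s, t, u)``.

        ``s`` runs apex->base, ``t`` endo->epi, ``u`` is the circumferential
        fraction (``phi = 2 pi u``, linear interpolation over the single
        circumferential element).
        """
        s, t, u = (float(c) for c in local_coords)
        if not (0 <= u <= 1):
            raise ValueError("local coordinates must lie in [0, 1]")
        r, z = self.meridian(element_id, s, t)
        phi = 2.0 * np.pi * u
        return np.array([z[0], r[0] * np.cos(phi), r[0] * np.sin(phi)])

    def interpolate(self, nodal_field: np.ndarray, element_id: int, s, t,
                    d1: int = 0, d2: int = 0):
        """Interpolate an arbitrary scalar Hermite field on this topology."""
        e1, e2 = self._split_element(element_id)
        op = self.grid.operator(e1, e2, s, t, d1=d1, d2=d2)
        return op @ self.grid.flatten(nodal_field)

    # -- measurement helpers ----------------------------------------------
    def surface_line(self, xi2: float, n: int = 601):
        """(R, Z) sampled densely along a transmural level xi2 in {0, 1}."""
        e2 = 0 if xi2 == 0 else N_TRANS - 1
        t = 0.0 if xi2 == 0 else 1.0
        xs = np.linspace(0.0, 1.0, n)
        e1 = np.minimum((xs * N_LONG).astype(int), N_LONG - 1)
        s = xs * N_LONG - e1
        op = self.grid.operator(e1, e2, s, t)
        return op @ self.dofs_r, op @ self.dofs_z

    def check_jacobian(self) -> float:
        """Smallest in-plane Jacobian determinant at the 3x3x3 quadrature."""
        e1, e2, s, t, _ = self.grid.quadrature(3)
        a11 = self.grid.operator(e1, e2, s, t, d1=1) @ self.dofs_r
        a12 = self.grid.operator(e1, e2, s, t, d2=1) @ self.dofs_r
        a21 = self.grid.operator(e1, e2, s, t, d1=1) @ self.dofs_z
        a22 = self.grid.operator(e1, e2, s, t, d2=1) @ self.dofs_z
        det = a11 * a22 - a12 * a21
        r = self.grid.operator(e1, e2, s, t) @ self.dofs_r
        # orientation: (xi1 x xi2) sweep must have consistent sign and R > 0
        return float(np.min(np.abs(det))) if np.all(det * det[0] > 0) and np.all(r > 0) else -1.0


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _meridian_map(params: GeometryParams):
    """Analytic meridian map (xi1, xi2) -> (R, Z) and its derivatives.

    Layers of constant xi2 interpolate lambda linearly between endo and epi;
    every layer is truncated at the common base plane, so the longitudinal
    range mu_max depends on xi2.
    """
    d = params.focal_length
    lam_e, lam_p = params.lambda_endo, params.lambda_epi
    dlam = lam_p - lam_e
    x_base = params.inner_semi_long * np.cos(params.base_truncation_mu)

    def fields(xi1, xi2):
        lam = lam_e + xi2 * dlam
        ch, sh = np.cosh(lam), np.sinh(lam)
        u = x_base / (d * ch)
        mumax = np.arccos(u)
        du = -x_base * sh * dlam / (d * ch * ch)
        dmumax = -du / np.sqrt(1.0 - u * u)
        mu = xi1 * mumax
        smu, cmu = np.sin(mu), np.cos(mu)
        R = d * sh * smu
        Z = d * ch * cmu
        dmu_d1 = mumax
        dmu_d2 = xi1 * dmumax
        dR1 = d * sh * cmu * dmu_d1
        dR2 = d * ch * smu * dlam + d * sh * cmu * dmu_d2
        dZ1 = -d * ch * smu * dmu_d1
        dZ2 = d * sh * cmu * dlam - d * ch * smu * dmu_d2
        # mixed derivatives d2/dxi1 dxi2
        dR12 = d * (
            ch * dlam * cmu * mumax
            - sh * smu * dmu_d2 * mumax
            + sh * cmu * dmumax
        )
        dZ12 = -d * (
            sh * dlam * smu * mumax
            + ch * cmu * dmu_d2 * mumax
            + ch * smu * dmumax
        )
        return R, Z, dR1, dR2, dZ1, dZ2, dR12, dZ12

    return fields


def build_lv_mesh(params: GeometryParams) -> HermiteMesh:
    """Construct the 30-node / 20-element truncated-ellipsoid mesh.

    The inner surface reproduces ``params.long_axis`` / ``params.short_axis``
    and the equatorial transmural distance equals ``params.wall_thickness``
    (all exactly, by the closed-form inversion to ellipsoid parameters).

    Raises
    ------
    InfeasibleGeometryError
        For degenerate dimensions or a non-positive geometric Jacobian.
    """
    fields = _meridian_map(params)
    xi1 = np.linspace(0.0, 1.0, N_LONG + 1)[:, None]
    xi2 = np.linspace(0.0, 1.0, N_TRANS + 1)[None, :]
    R, Z, dR1, dR2, dZ1, dZ2, dR12, dZ12 = fields(xi1, xi2)
    dofs = np.empty((N_LONG + 1, N_TRANS + 1, 2, 4))
    dofs[:, :, 0, 0], dofs[:, :, 0, 1] = R, dR1
    dofs[:, :, 0, 2], dofs[:, :, 0, 3] = dR2, dR12
    dofs[:, :, 1, 0], dofs[:, :, 1, 1] = Z, dZ1
    dofs[:, :, 1, 2], dofs[:, :, 1, 3] = dZ2, dZ12
    # exact pole conditions on the axis
    dofs[0, :, 0, 0] = 0.0  # R = 0
    dofs[0, :, 0, 2] = 0.0  # dR/dxi2 = 0
    dofs[0, :, 1, 1] = 0.0  # dZ/dxi1 = 0 (smooth cap)
    dofs[0, :, 1, 3] = 0.0
    mesh = HermiteMesh(dofs, params.focal_length, params.base_truncation_mu, params)
    if mesh.check_jacobian() <= 0:
        raise InfeasibleGeometryError("geometric Jacobian is not positive everywhere")
    return mesh


# ---------------------------------------------------------------------------
# fiber field
# ---------------------------------------------------------------------------

@dataclass
class FiberField:
    """Rule-based helical fiber field at a set of material points.

    ``frames`` has shape ``(n, 3, 3)``; columns are the fiber ``f``,
    cross-fiber-in-wall ``c`` and radial ``r`` unit vectors expressed in the
    local cylindrical basis ``(e_R, e_Z, e_phi)``.
    """

    endo_angle: float  # degrees at endocardium
    epi_angle: float  # degrees at epicardium
    angles: np.ndarray  # degrees, per point
    frames: np.ndarray  # (n, 3, 3)
    depth: np.ndarray = field(default=None, repr=False)  # normalized transmural t


def fiber_frames_at(mesh: HermiteMesh, e1, e2, s, t,
                    endo_angle: float, epi_angle: float) -> FiberField:
    """Fiber frames at arbitrary in-plane points of the mesh."""
    grid = mesh.grid
    dR1 = grid.operator(e1, e2, s, t, d1=1) @ mesh.dofs_r
    dZ1 = grid.operator(e1, e2, s, t, d1=1) @ mesh.dofs_z
    dR2 = grid.operator(e1, e2, s, t, d2=1) @ mesh.dofs_r
    dZ2 = grid.operator(e1, e2, s, t, d2=1) @ mesh.dofs_z
    # in-wall longitudinal unit vector (meridian tangent, apex->base)
    norm1 = np.hypot(dR1, dZ1)
    lR, lZ = dR1 / norm1, dZ1 / norm1
    # transmural unit vector: meridian normal oriented endo->epi
    nR, nZ = lZ, -lR
    flip = np.sign(nR * dR2 + nZ * dZ2)
    nR, nZ = nR * flip, nZ * flip
    depth = (np.broadcast_to(np.atleast_1d(e2), np.shape(norm1)) +
             np.broadcast_to(np.atleast_1d(t), np.shape(norm1))) / N_TRANS
    ang = np.deg2rad(endo_angle * (1.0 - depth) + epi_angle * depth)
    ca, sa = np.cos(ang), np.sin(ang)
    n = norm1.size
    frames = np.zeros((n, 3, 3))
    # fiber: cos(a) e_phi + sin(a) e_l
    frames[:, 0, 0], frames[:, 1, 0], frames[:, 2, 0] = sa * lR, sa * lZ, ca
    # radial: wall normal
    frames[:, 0, 2], frames[:, 1, 2] = nR, nZ
    # cross-fiber: r x f (right-handed f, c, r)
    frames[:, :, 1] = np.cross(frames[:, :, 2], frames[:, :, 0])
    return FiberField(endo_angle, epi_angle, np.rad2deg(ang), frames, depth)


def assign_fiber_field(
    mesh: HermiteMesh,
    endo_angle: float = ENDO_ANGLE_DEG,
    epi_angle: float = EPI_ANGLE_DEG,
    ngauss: int = 3,
) -> FiberField:
    """Fiber frames at the standard in-plane quadrature points.

    The helix angle varies linearly with normalized transmural depth
    (endocardium ``endo_angle`` to epicardium ``epi_angle``).
    """
    for a in (endo_angle, epi_angle):
        if not (-90.0 < a <= 90.0):
            raise ValueError("helix angles must lie in (-90, 90] degrees")
    mesh.endo_angle, mesh.epi_angle = float(endo_angle), float(epi_angle)
    e1, e2, s, t, _ = mesh.grid.quadrature(ngauss)
    return fiber_frames_at(mesh, e1, e2, s, t, endo_angle, epi_angle)


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

_BQ_N = 6  # Gauss points per element edge for the surface volume integral


def cavity_volume(mesh: HermiteMesh) -> float:
    """Endocardial cavity volume (uL) closed by the base plane.

    Solid-of-revolution integral ``pi * integral R^2 (-dZ/dxi1) dxi1`` along
    the endocardium; the base plane is normal to the axis so contributes
    nothing.
    """
    e1, e2, s, t, w = mesh.grid.boundary_quadrature(0.0, _BQ_N)
    r = mesh.grid.operator(e1, e2, s, t) @ mesh.dofs_r
    dz = mesh.grid.operator(e1, e2, s, t, d1=1) @ mesh.dofs_z
    return float(np.pi * np.sum(w * r * r * (-dz)))


def outer_volume(mesh: HermiteMesh) -> float:
    """Volume enclosed by the epicardium and the base plane (uL)."""
    e1, e2, s, t, w = mesh.grid.boundary_quadrature(1.0, _BQ_N)
    r = mesh.grid.operator(e1, e2, s, t) @ mesh.dofs_r
    dz = mesh.grid.operator(e1, e2, s, t, d1=1) @ mesh.dofs_z
    return float(np.pi * np.sum(w * r * r * (-dz)))


def wall_volume(mesh: HermiteMesh, ngauss: int = 5) -> float:
    """Myocardial wall volume (uL) by in-plane quadrature of the solid sweep."""
    e1, e2, s, t, w = mesh.grid.quadrature(ngauss)
    g = mesh.grid
    a11 = g.operator(e1, e2, s, t, d1=1) @ mesh.dofs_r
    a12 = g.operator(e1, e2, s, t, d2=1) @ mesh.dofs_r
    a21 = g.operator(e1, e2, s, t, d1=1) @ mesh.dofs_z
    a22 = g.operator(e1, e2, s, t, d2=1) @ mesh.dofs_z
    r = g.operator(e1, e2, s, t) @ mesh.dofs_r
    det = np.abs(a11 * a22 - a12 * a21)
    return float(2.0 * np.pi * np.sum(w * r * det))


def lv_metrics(
    mesh: HermiteMesh,
    load_state: Literal["unloaded", "end_diastole"] = "unloaded",
    gestational_age: float | None = None,
) -> LVMetrics:
    """Measure cavity/wall volumes and LA, SA, WT of a configuration.

    The long axis is the inner apex-to-base distance, the short axis the
    maximal inner diameter, and the wall thickness is measured at the
    equatorial level as the difference of maximal outer and inner radii.
    """
    if mesh.check_jacobian() <= 0:
        raise InfeasibleGeometryError("mesh contains inverted elements")
    r_in, z_in = mesh.surface_line(0)
    r_out, _ = mesh.surface_line(1)
    la = float(z_in[0] - z_in[-1])
    sa = float(2.0 * np.max(r_in))
    wt = float(np.max(r_out) - np.max(r_in))
    return LVMetrics(
        cavity_volume=cavity_volume(mesh),
        wall_volume=wall_volume(mesh),
        long_axis=la,
        short_axis=sa,
        wall_thickness=wt,
        gestational_age=gestational_age,
        load_state=load_state,
    )


def measure_echo_dimensions(mesh: HermiteMesh) -> dict[str, float]:
    """Six planar dimensions as measured on a four-chamber echo view.

    Widths are diameters at the basal plane and at the mid (equatorial)
    level; lengths are apex-to-base on the endo- and epicardial surfaces.
    """
    r_in, z_in = mesh.surface_line(0)
    r_out, z_out = mesh.surface_line(1)
    return {
        "inner_width_base": float(2.0 * r_in[-1]),
        "outer_width_base": float(2.0 * r_out[-1]),
        "inner_width_mid": float(2.0 * np.max(r_in)),
        "outer_width_mid": float(2.0 * np.max(r_out)),
        "inner_length": float(z_in[0] - z_in[-1]),
        "outer_length": float(z_out[0] - z_in[-1]),
    }


# ---------------------------------------------------------------------------
# shape variants
# ---------------------------------------------------------------------------

def make_shape_variant(mesh: HermiteMesh, spec: ShapeVariantSpec) -> HermiteMesh:
    """Perturb wall thickness or aspect ratio of an unloaded reference mesh.

    Wall-thickness variants move the epicardial surface only (uniform change
    of the epicardial lambda), leaving the cavity untouched.  Aspect-ratio
    variants rescale LA:SA by ``1 + scale``; with the preserve flag the
    overall size factor ``(1 + scale)**(-1/3)`` keeps the cavity volume exact
    (cavity volume is proportional to LA * SA^2 at fixed truncation).
    """
    if mesh.params is None:
        raise ValueError(
            "shape variants require a mesh built from GeometryParams "
            "(an undeformed reference configuration)"
        )
    p = mesh.params
    if spec.scale == 0:
        return mesh.copy()
    if spec.mode == "wall_thickness_scale":
        newp = replace(p, wall_thickness=p.wall_thickness * (1.0 + spec.scale))
    elif spec.mode == "aspect_ratio_scale":
        alpha = (1.0 + spec.scale) ** (-1.0 / 3.0) if spec.preserve_unloaded_cavity_volume else 1.0
        newp = replace(
            p,
            long_axis=p.long_axis * alpha * (1.0 + spec.scale),
            short_axis=p.short_axis * alpha,
        )
    else:
        raise ValueError(f"unknown variant mode {spec.mode!r}")
    out = build_lv_mesh(newp)
    out.endo_angle, out.epi_angle = mesh.endo_angle, mesh.epi_angle
    return out
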