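"""Strain-driven multiplicative growth of the fetal LV.

Growth is kinematic: at every quadrature point a diagonal growth tensor in
the local fiber frame, ``Fg = diag(F_ff, F_cc, F_rr)``, multiplies the
elastic deformation (``F = Fe Fg``).  Sarcomere addition in series (fiber
direction, predominantly circumferential) is driven by the end-diastolic
fiber strain; addition in parallel (cross-fiber, transversely isotropic:
``F_cc = F_rr``) by the maximal cross-fiber principal strain.  Because only
end-diastole is simulated, the cycle-maximal strains are the end-diastolic
strains.

Each branch follows a saturating sigmoid of the stimulus ``s`` (strain above
its setpoint):

    dF = 1 + dt * f_max / (1 + exp(-k (s - s50)))     for s > 0,
    dF = 1                                            otherwise,

applied weekly at constant end-diastolic pressure.  The grown unloaded
configuration is obtained from a zero-load elastic equilibrium solve that
resolves the (generally incompatible) pointwise growth into a smooth mesh;
residual stresses are not carried over, so the grown configuration is
treated as the new stress-free reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import HermiteMesh, cavity_volume, fiber_frames_at, lv_metrics, wall_volume
from .materials import PassiveMaterial
from .mechanics import (
    BoundaryConditions,
    ConvergenceError,
    DeformedState,
    SolverSettings,
    _System,
    inflate,
)


def _free_dofs(bc):
    """Free-DOF mask of the reference topology (cached per anchor mode)."""
    from .geometry import GeometryParams, build_lv_mesh
    from .materials import PassiveMaterial as _PM

    key = (bc or BoundaryConditions()).longitudinal_anchor
    if key not in _free_dofs._cache:
        ref = build_lv_mesh(GeometryParams(16.0, 8.0, 2.0))
        sysr = _System(ref, _PM(), SolverSettings(), bc or BoundaryConditions())
        _free_dofs._cache[key] = sysr.free
    return _free_dofs._cache[key]


_free_dofs._cache = {}

__all__ = [
    "GrowthParams",
    "GrowthState",
    "GrowthTrajectory",
    "NormativeTrajectory",
    "growth_stimuli",
    "growth_increment",
    "apply_growth",
    "simulate_growth",
    "calibrate_growth_rate",
]


@dataclass(frozen=True)
class GrowthParams:
    """Rate constants of the two growth branches.

    Rates are per week; stimuli and setpoints are Green strains.  ``s_f50`` /
    ``s_t50`` default to None, meaning "set to the reference model's mean
    end-diastolic strain during rate calibration" (half-maximal activation
    at the reference operating point).
    """

    f_ff_max: float = 0.1  # 1/week, fiber branch (calibrated)
    k_f: float = 30.0  # sigmoid slope, 1/strain
    s_f50: float | None = None  # half-activation strain
    e_f_set: float = 0.0  # homeostatic setpoint strain
    f_t_max: float = 0.1  # 1/week, transverse branch (calibrated)
    k_t: float = 30.0
    s_t50: float | None = None
    e_t_set: float = 0.0
    growth_dt: float = 1.0  # weeks
    limit_min: float = 0.67  # per-step clamp on each component
    limit_max: float = 1.5
    transverse_stimulus: str = "principal"  # or "cc"

    def __post_init__(self):
        if self.f_ff_max < 0 or self.f_t_max < 0 or self.growth_dt <= 0:
            raise ValueError("growth rates must be >= 0 and dt > 0")
        if not (self.limit_min < 1.0 < self.limit_max):
            raise ValueError("growth limits must bracket 1")

    def with_rate_scale(self, gamma: float) -> "GrowthParams":
        """Rescale both branch rates, preserving their ratio."""
        ratio = self.f_t_max / self.f_ff_max if self.f_ff_max > 0 else 1.0
        return replace(self, f_ff_max=float(gamma), f_t_max=float(gamma * ratio))

    def with_branch_ratio(self, ratio: float) -> "GrowthParams":
        """Set the transverse-to-fiber maximal-rate ratio."""
        return replace(self, f_t_max=float(self.f_ff_max * ratio))


@dataclass
class GrowthState:
    """Cumulative per-quadrature-point growth tensor components."""

    F_ff: np.ndarray
    F_cc: np.ndarray
    F_rr: np.ndarray

    @classmethod
    def identity(cls, n: int) -> "GrowthState":
        return cls(np.ones(n), np.ones(n), np.ones(n))


@dataclass(frozen=True)
class NormativeTrajectory:
    """Normative end-diastolic volume versus gestational age.

    Piecewise log-linear (exponential) interpolation through the anchor
    points; the defaults span mid-gestation to term (1.1 mL at 22 weeks to
    8.3 mL at 40 weeks).
    """

    anchors: tuple = ((22.0, 1100.0), (40.0, 8300.0))  # (weeks, uL)

    def __post_init__(self):
        ages = [a for a, _ in self.anchors]
        vols = [v for _, v in self.anchors]
        if len(self.anchors) < 2 or sorted(ages) != list(ages):
            raise ValueError("need >= 2 anchors with increasing ages")
        if any(v2 <= v1 for v1, v2 in zip(vols, vols[1:])):
            raise ValueError("normative EDV must strictly increase with age")

    def edv(self, age) -> np.ndarray:
        ages = np.array([a for a, _ in self.anchors])
        logv = np.log([v for _, v in self.anchors])
        return np.exp(np.interp(age, ages, logv))


@dataclass
class GrowthTrajectory:
    """Weekly record of a growth simulation."""

    data: pd.DataFrame  # per age: volumes (uL), dimensions (mm), stimuli
    direction: str  # "forward" | "reverse"
    meshes: list = field(default_factory=list)  # unloaded mesh per recorded age
    final_state: DeformedState | None = None
    growth_state: "GrowthState | None" = None  # cumulative growth tensor

    def at_age(self, age: float) -> pd.Series:
        i = (self.data["age"] - age).abs().idxmin()
        return self.data.loc[i]


# ---------------------------------------------------------------------------
# stimuli and increments
# ---------------------------------------------------------------------------

def growth_stimuli(state: DeformedState, params: GrowthParams):
    """Per-point growth stimuli from a converged end-diastolic state.

    Fiber stimulus: ``E_ff - e_f_set``.  Transverse stimulus: the maximal
    principal strain of the cross-fiber block ``[[E_cc, E_cr], [E_rc, E_rr]]``
    (or plain ``E_cc``), minus its setpoint.
    """
    E = state.E_fiber
    s_f = E[:, 0, 0] - params.e_f_set
    if params.transverse_stimulus == "principal":
        ecc, err, ecr = E[:, 1, 1], E[:, 2, 2], E[:, 1, 2]
        e_t = 0.5 * (ecc + err) + np.sqrt(0.25 * (ecc - err) ** 2 + ecr * ecr)
    elif params.transverse_stimulus == "cc":
        e_t = E[:, 1, 1]
    else:
        raise ValueError("transverse_stimulus must be 'principal' or 'cc'")
    return s_f, e_t - params.e_t_set


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def growth_increment(stimuli, params: GrowthParams, dt: float | None = None):
    """Multiplicative per-step growth updates ``(dF_ff, dF_cc, dF_rr)``.

    Each branch is a saturating sigmoid of its stimulus; non-positive
    stimuli fall in the dead band (no growth).  The transverse branch drives
    both cross-fiber and radial components (transverse isotropy).
    """
    s_f, s_t = stimuli
    dt = params.growth_dt if dt is None else float(dt)
    if dt <= 0:
        raise ValueError("growth time step must be positive")
    if params.s_f50 is None or params.s_t50 is None:
        raise ValueError("half-activation strains are unset; calibrate first")
    dff = np.where(
        s_f > 0, 1.0 + dt * params.f_ff_max * _sigmoid(params.k_f * (s_f - params.s_f50)), 1.0
    )
    dft = np.where(
        s_t > 0, 1.0 + dt * params.f_t_max * _sigmoid(params.k_t * (s_t - params.s_t50)), 1.0
    )
    dff = np.clip(dff, params.limit_min, params.limit_max)
    dft = np.clip(dft, params.limit_min, params.limit_max)
    return dff, dft.copy(), dft.copy()


# ---------------------------------------------------------------------------
# growth kinematics
# ---------------------------------------------------------------------------

def apply_growth(
    mesh: HermiteMesh,
    updates,
    mat: PassiveMaterial,
    settings: SolverSettings | None = None,
    bc: BoundaryConditions | None = None,
    warm: tuple | None = None,
):
    """Grow the unloaded mesh by per-point multiplicative updates.

    ``updates`` are ``(dF_ff, dF_cc, dF_rr)`` at the standard quadrature
    points.  The incompatible pointwise growth is resolved by an elastic
    equilibrium solve at zero external load with elastic deformation
    ``Fe = F Fg^{-1}``; the converged configuration is returned as the new
    (approximately stress-free) reference mesh.

    Returns ``(grown_mesh, diagnostics)`` where the diagnostics report the
    wall-volume change against the volume integral of ``det Fg``.
    """
    from .mechanics import _newton_al

    settings = settings or SolverSettings()
    bc = bc or BoundaryConditions()
    dff, dfc, dfr = (np.asarray(a, dtype=float) for a in updates)
    if np.allclose([dff, dfc, dfr], 1.0, atol=1e-14):
        return mesh.copy(), {"wall_ratio": 1.0, "det_integral_ratio": 1.0}
    e1, e2, s, t, w = mesh.grid.quadrature(settings.quadrature)
    frames = fiber_frames_at(mesh, e1, e2, s, t, mesh.endo_angle, mesh.epi_angle).frames

    def system_for(alpha: float) -> _System:
        inv_diag = np.zeros((e1.size, 3, 3))
        inv_diag[:, 0, 0] = dff ** -alpha
        inv_diag[:, 1, 1] = dfc ** -alpha
        inv_diag[:, 2, 2] = dfr ** -alpha
        g_inv = frames @ inv_diag @ np.swapaxes(frames, 1, 2)
        return _System(mesh, mat, settings, bc, g_inv)

    def predictor(alpha: float) -> np.ndarray:
        # similarity scaling about the (fixed) base plane by the mean linear
        # growth starts Newton close to the grown equilibrium
        sys0 = system_for(alpha)
        scale = float(np.mean((dff * dfc * dfr) ** alpha)) ** (1.0 / 3.0)
        z_base = float(mesh.dofs[-1, 0, 1, 0])
        u = sys0.u0 * scale
        u[sys0.ndoff:: 4] += (1.0 - scale) * z_base
        x0 = u[sys0.free].copy()
        # initialise multipliers to cancel the predictor's volumetric
        # stress (the similarity guess violates det Fe = 1 pointwise)
        from .mechanics import _det3

        J0 = _det3(sys0.kinematics(u))
        sys0.pe = -sys0.multiplier_update(J0)
        return sys0, x0

    # warm start from the previous step's growth displacement, if given
    if warm is not None:
        du_prev, pe_prev = warm
        sys_w = system_for(1.0)
        u_guess = sys_w.u0 + du_prev
        x_w = u_guess[sys_w.free].copy()
        sys_w.pe = pe_prev.copy()
        x_new, _, hist, ok = _newton_al(sys_w, x_w, 0.0, settings)
        if ok:
            u = sys_w.full_u(x_new)
            grown = mesh.with_dofs(u[: sys_w.ndoff], u[sys_w.ndoff:])
            grown.endo_angle, grown.epi_angle = mesh.endo_angle, mesh.epi_angle
            grown.params = None
            if grown.check_jacobian() > 0:
                det_ratio = float(
                    np.sum(sys_w.dv * dff * dfc * dfr) / sys_w.wall_volume0
                )
                return grown, {
                    "wall_ratio": wall_volume(grown) / wall_volume(mesh),
                    "det_integral_ratio": det_ratio,
                    "du": u - sys_w.u0,
                    "pe": sys_w.pe.copy(),
                }

    # continuation in the growth exponent for strongly incompatible updates
    alpha_done, dalpha = 0.0, 1.0
    sys, x = predictor(1.0)
    pe = sys.pe.copy()
    while True:
        alpha = min(1.0, alpha_done + dalpha)
        if alpha_done > 0:
            sys_a = system_for(alpha)
            sys_a.pe, x_try = pe.copy(), x
        else:
            sys_a, x_try = predictor(alpha)
        x_new, _, hist, ok = _newton_al(sys_a, x_try, 0.0, settings)
        if ok:
            alpha_done, x, pe = alpha, x_new, sys_a.pe.copy()
            if alpha_done >= 1.0:
                sys = sys_a
                break
            dalpha = min(1.0 - alpha_done, 2.0 * dalpha)
        else:
            dalpha *= 0.5
            if dalpha < 1.0 / 32.0:
                raise ConvergenceError(
                    f"grown-equilibrium solve failed at growth fraction "
                    f"{alpha_done + dalpha:.3f}", hist,
                )

    u = sys.full_u(x)
    grown = mesh.with_dofs(u[: sys.ndoff], u[sys.ndoff:])
    grown.endo_angle, grown.epi_angle = mesh.endo_angle, mesh.epi_angle
    grown.params = None
    if grown.check_jacobian() <= 0:
        raise ConvergenceError("growth produced an inverted element")
    # mass-kinematics consistency: dV_wall = integral of det(Fg)
    det_ratio = float(np.sum(sys.dv * dff * dfc * dfr) / sys.wall_volume0)
    wall_ratio = wall_volume(grown) / wall_volume(mesh)
    return grown, {
        "wall_ratio": wall_ratio,
        "det_integral_ratio": det_ratio,
        "du": u - sys.u0,
        "pe": sys.pe.copy(),
    }


# ---------------------------------------------------------------------------
# growth loop
# ---------------------------------------------------------------------------

def simulate_growth(
    mesh: HermiteMesh,
    mat: PassiveMaterial,
    params: GrowthParams,
    edp: float,
    age_start: float = 22.0,
    age_end: float = 40.0,
    direction: str | None = None,
    settings: SolverSettings | None = None,
    bc: BoundaryConditions | None = None,
    store_meshes: bool = True,
) -> GrowthTrajectory:
    """Grow the LV from ``age_start`` to ``age_end`` at constant EDP.

    Weekly loop: inflate to EDP, evaluate stimuli from the end-diastolic
    strains, form the multiplicative increment (inverted for reverse-in-time
    runs), regenerate the grown unloaded configuration, repeat.  Records
    end-diastolic metrics at every age.
    """
    if age_end == age_start:
        raise ValueError("age_end must differ from age_start")
    settings = settings or SolverSettings()
    reverse = age_end < age_start
    if direction is None:
        direction = "reverse" if reverse else "forward"
    dt = params.growth_dt
    n_steps = int(round(abs(age_end - age_start) / dt))
    ages = age_start + np.sign(age_end - age_start) * dt * np.arange(n_steps + 1)

    rows = []
    meshes = []
    cur = mesh
    x_warm = pe_warm = grow_warm = None
    state = None
    cum = None  # cumulative growth components, accumulated per step
    for i, age in enumerate(ages):
        try:
            state = inflate(cur, mat, edp, bc, settings, x0=x_warm, pe0=pe_warm)
        except Exception as err:
            raise type(err)(
                f"growth loop failed at gestational age {age:.1f} weeks: {err}"
            ) from err
        x_warm, pe_warm = state.x, state.hydrostatic
        met = state.metrics(age)
        s_f, s_t = growth_stimuli(state, params)
        rows.append(
            {
                "age": float(age),
                "cavity_volume": met.cavity_volume,
                "wall_volume": met.wall_volume,
                "long_axis": met.long_axis,
                "short_axis": met.short_axis,
                "wall_thickness": met.wall_thickness,
                "unloaded_cavity_volume": cavity_volume(cur),
                "mean_fiber_stimulus": float(np.mean(s_f)),
                "mean_transverse_stimulus": float(np.mean(s_t)),
            }
        )
        if store_meshes:
            meshes.append(cur)
        if i == n_steps:
            break
        dff, dfc, dfr = growth_increment((s_f, s_t), params, dt)
        if reverse:
            dff, dfc, dfr = 1.0 / dff, 1.0 / dfc, 1.0 / dfr
        if cum is None:
            cum = GrowthState.identity(dff.size)
        cum = GrowthState(cum.F_ff * dff, cum.F_cc * dfc, cum.F_rr * dfr)
        cur, _diag = apply_growth(
            cur, (dff, dfc, dfr), mat, settings, bc, warm=grow_warm
        )
        grow_warm = (_diag.get("du"), _diag.get("pe"))
        if grow_warm[0] is None:
            grow_warm = None
        # warm-start the next inflation from the current ED configuration
        # scaled by the linear growth factor (base plane anchored); the
        # cavity grows faster than the wall, so use the observed EDV ratio
        # once two weeks of history exist
        if x_warm is not None:
            if len(rows) >= 2:
                scale = (rows[-1]["cavity_volume"] / rows[-2]["cavity_volume"]) ** (
                    1.0 / 3.0
                )
            else:
                scale = _diag["wall_ratio"] ** (1.0 / 3.0)
            u_ed = np.concatenate([state.mesh.dofs_r, state.mesh.dofs_z])
            z_base = float(state.mesh.dofs[-1, 0, 1, 0])
            u_ed = u_ed * scale
            nd = state.mesh.grid.n_dof
            u_ed[nd::4] += (1.0 - scale) * z_base
            x_warm = u_ed[_free_dofs(bc)]
    data = pd.DataFrame(rows)
    return GrowthTrajectory(data, direction, meshes, state, cum)


# ---------------------------------------------------------------------------
# rate calibration
# ---------------------------------------------------------------------------

def calibrate_growth_rate(
    params: GrowthParams,
    normative: NormativeTrajectory,
    mesh: HermiteMesh,
    mat: PassiveMaterial,
    edp: float,
    age_start: float = 22.0,
    age_end: float = 40.0,
    settings: SolverSettings | None = None,
    rtol: float = 0.01,
    drift_tol: float = 0.02,
    max_runs: int = 14,
) -> tuple[GrowthParams, GrowthTrajectory]:
    """Calibrate the growth-rate scale to the normative EDV trajectory.

    The sigmoid shapes and the branch ratio are held fixed; the overall
    rate scale is adjusted so the simulated EDV at ``age_end`` matches the
    normative value.  Half-activation strains left unset default to the
    reference model's mean end-diastolic strains at ``age_start``.
    Returns the frozen parameters and the calibrated reference trajectory.
    """
    settings = settings or SolverSettings()
    state0 = inflate(mesh, mat, edp, None, settings)
    if params.s_f50 is None or params.s_t50 is None:
        s_f, s_t = growth_stimuli(state0, replace(params, s_f50=0.0, s_t50=0.0))
        params = replace(
            params,
            s_f50=params.s_f50 if params.s_f50 is not None else float(np.mean(s_f)),
            s_t50=params.s_t50 if params.s_t50 is not None else float(np.mean(s_t)),
        )
    target = float(normative.edv(age_end))
    v22 = state0.cavity_volume
    if abs(np.log(target / v22)) < 1e-6:  # flat normative curve: no growth
        return params.with_rate_scale(0.0), simulate_growth(
            mesh, mat, params.with_rate_scale(0.0), edp, age_start, age_end,
            settings=settings,
        )

    def run(log_gamma, log_ratio):
        p = params.with_rate_scale(np.exp(log_gamma)).with_branch_ratio(
            np.exp(log_ratio)
        )
        traj = simulate_growth(
            mesh, mat, p, edp, age_start, age_end, settings=settings,
            store_meshes=False,
        )
        d = traj.data
        verr = float(np.log(d["cavity_volume"].iloc[-1] / target))
        ar = d["long_axis"] / d["short_axis"]
        drift = float(np.log(ar.iloc[-1] / ar.iloc[0]))
        return verr, drift, p, traj

    # Calibrate the overall rate scale so the terminal EDV matches the
    # normative value (secant on the log scale; terminal volume increases
    # monotonically with the rate).  The transverse-to-fiber branch ratio
    # is a fixed a-priori constant of the law (equal maxima by default):
    # with the published branch constants unavailable there is no
    # independent constraint to identify it, and the terminal dimensions
    # remain emergent predictions.
    r_needed = np.log(target / v22) / abs(age_end - age_start)
    # the sigmoid operates above half activation at the reference strains,
    # so the needed scale is roughly half the required volumetric rate
    a = float(np.log(max(r_needed / 2.0, 1e-4)))

    def evaluate(lg):
        verr, drift, p, traj = run(lg, np.log(params.f_t_max / params.f_ff_max))
        return verr, p, traj

    fa, pa, ta = evaluate(a)
    best = (abs(fa), pa, ta, fa)
    # first secant step from the log-log volume sensitivity (~1.5)
    b = float(np.clip(a - fa / 1.5, a - 0.5, a + 0.5))
    for _ in range(max_runs - 1):
        if best[0] < rtol:
            break
        fb, pb, tb = evaluate(b)
        if abs(fb) < best[0]:
            best = (abs(fb), pb, tb, fb)
        if fb == fa:
            break
        a, fa, b = b, fb, float(np.clip(b - fb * (b - a) / (fb - fa), b - 0.6, b + 0.6))
    if abs(best[3]) > np.log(1.05):
        raise RuntimeError(
            f"growth-rate calibration did not reach the normative EDV: "
            f"relative error {np.expm1(best[3]):.2%} at {age_end} weeks"
        )
    return best[1], best[2]
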