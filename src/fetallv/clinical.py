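"""Patient-specific workflow and scenario experiments.

The clinical pipeline turns six-planar fetal echocardiographic LV
dimensions into an axisymmetric end-diastolic mesh, estimates its unloaded
configuration under normal material properties and preload, and predicts
later-gestation size by running the frozen reference growth law.  The
scenario runners reproduce the model experiments: sensitivity of birth
size to mid-gestation ventricular filling and to LV shape (wall thickness
and length-to-width ratio) at preserved unloaded volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .geometry import (
    GeometryParams,
    HermiteMesh,
    InfeasibleGeometryError,
    LVMetrics,
    ShapeVariantSpec,
    build_lv_mesh,
    cavity_volume,
    lv_metrics,
    make_shape_variant,
    measure_echo_dimensions,
)
from .growth import GrowthParams, GrowthTrajectory, simulate_growth
from .materials import PassiveMaterial
from .mechanics import BoundaryConditions, SolverSettings, inflate, unload

__all__ = [
    "EchoMeasurements",
    "PatientPrediction",
    "SensitivityResult",
    "fit_patient_mesh",
    "predict_patient_growth",
    "filling_sensitivity",
    "shape_sensitivity",
    "find_edp_for_filling",
]

ECHO_FIELDS = (
    "inner_width_base",
    "outer_width_base",
    "inner_width_mid",
    "outer_width_mid",
    "inner_length",
    "outer_length",
)


@dataclass(frozen=True)
class EchoMeasurements:
    """Six planar end-diastolic LV dimensions from a four-chamber view (mm)."""

    gestational_age: float  # weeks
    inner_width_base: float
    outer_width_base: float
    inner_width_mid: float
    outer_width_mid: float
    inner_length: float
    outer_length: float
    uncertainty: float | None = None  # fractional measurement uncertainty

    def __post_init__(self):
        dims = [getattr(self, f) for f in ECHO_FIELDS]
        if min(dims) <= 0 or self.gestational_age <= 0:
            raise ValueError("all dimensions and the age must be positive")
        for inner, outer in (
            ("inner_width_base", "outer_width_base"),
            ("inner_width_mid", "outer_width_mid"),
            ("inner_length", "outer_length"),
        ):
            if getattr(self, inner) >= getattr(self, outer):
                raise ValueError(f"{outer} must exceed {inner}")

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in ECHO_FIELDS}


@dataclass
class PatientPrediction:
    """End-to-end patient-specific growth prediction."""

    ed_mesh: HermiteMesh  # fitted end-diastolic mesh at the first time point
    unloaded_mesh: HermiteMesh
    predicted: LVMetrics  # at the target age
    fit_residuals: dict[str, float]  # mm, per measurement
    trajectory: GrowthTrajectory | None = None


@dataclass
class SensitivityResult:
    """Scenario grid and fitted linear slopes of a sensitivity experiment."""

    table: pd.DataFrame  # one row per scenario
    slopes: dict  # % outcome change per +10% perturbation
    fit_residual: dict = field(default_factory=dict)
    load_mode: str | None = None


# ---------------------------------------------------------------------------
# echo fitting
# ---------------------------------------------------------------------------

def fit_patient_mesh(
    echo: EchoMeasurements,
) -> tuple[HermiteMesh, dict[str, float]]:
    """Least-squares fit of the truncated-ellipsoid family to six dimensions.

    Free parameters are the inner long axis, inner short axis and wall
    thickness of the end-diastolic configuration.  Returns the fitted mesh
    and the per-measurement residuals (model minus measurement, mm).
    """
    meas = echo.as_dict()
    target = np.array([meas[f] for f in ECHO_FIELDS])

    def predict(p):
        la, sa, wt = p
        try:
            mesh = build_lv_mesh(GeometryParams(la, sa, wt))
        except InfeasibleGeometryError:
            return None
        d = measure_echo_dimensions(mesh)
        return np.array([d[f] for f in ECHO_FIELDS])

    def residuals(p):
        pred = predict(p)
        if pred is None:
            return np.full(len(ECHO_FIELDS), 1e3)
        return pred - target

    la0 = meas["inner_length"]
    sa0 = meas["inner_width_mid"]
    wt0 = max(0.5 * (meas["outer_width_mid"] - meas["inner_width_mid"]), 0.3)
    wt0 = min(wt0, 0.45 * sa0)
    sol = least_squares(
        residuals,
        x0=[la0, sa0, wt0],
        bounds=([1.0, 1.0, 0.2], [80.0, 40.0, 15.0]),
        xtol=1e-10,
        ftol=1e-12,
    )
    mesh = build_lv_mesh(GeometryParams(*sol.x))
    pred = measure_echo_dimensions(mesh)
    res = {f: float(pred[f] - meas[f]) for f in ECHO_FIELDS}
    return mesh, res


def predict_patient_growth(
    echo: EchoMeasurements,
    target_age: float,
    mat: PassiveMaterial,
    growth_params: GrowthParams,
    edp: float = 0.75,
    settings: SolverSettings | None = None,
    bc: BoundaryConditions | None = None,
) -> PatientPrediction:
    """Patient pipeline: fit -> unload -> grow with frozen reference constants.

    The unloaded configuration is estimated with the normal material and the
    normal gestational EDP (configurable); growth runs from the echo age to
    ``target_age`` with the calibrated reference growth parameters
    unchanged.
    """
    ed_mesh, res = fit_patient_mesh(echo)
    if target_age == echo.gestational_age:
        met = lv_metrics(ed_mesh, "end_diastole", target_age)
        return PatientPrediction(ed_mesh, ed_mesh.copy(), met, res)
    if target_age < echo.gestational_age:
        raise ValueError("target age must not precede the measurement age")
    unloaded = unload(ed_mesh, mat, edp, bc, settings)
    traj = simulate_growth(
        unloaded, mat, growth_params, edp, echo.gestational_age, target_age,
        settings=settings, bc=bc, store_meshes=False,
    )
    last = traj.data.iloc[-1]
    met = LVMetrics(
        cavity_volume=last["cavity_volume"],
        wall_volume=last["wall_volume"],
        long_axis=last["long_axis"],
        short_axis=last["short_axis"],
        wall_thickness=last["wall_thickness"],
        gestational_age=float(last["age"]),
        load_state="end_diastole",
    )
    return PatientPrediction(ed_mesh, unloaded, met, res, traj)


# ---------------------------------------------------------------------------
# scenario experiments
# ---------------------------------------------------------------------------

def find_edp_for_filling(
    mesh: HermiteMesh,
    mat: PassiveMaterial,
    target_filling: float,
    p0: float = 0.75,
    rtol: float = 5e-3,
    settings: SolverSettings | None = None,
    max_iterations: int = 20,
):
    """Solve for the EDP whose filling volume (EDV - V0) hits a target (uL).

    Secant iteration on log pressure; filling volume increases strictly
    with pressure.  Returns ``(pressure_kPa, DeformedState)``.
    """
    if target_filling <= 0:
        raise ValueError("target filling volume must be positive")

    state = {}

    def f(logp):
        st = inflate(
            mesh, mat, float(np.exp(logp)), settings=settings,
            x0=state.get("x"), pe0=state.get("pe"),
        )
        state["x"], state["pe"] = st.x, st.hydrostatic
        return float(np.log(st.filling_volume / target_filling)), st

    a = np.log(p0)
    fa, sta = f(a)
    best = (abs(fa), a, sta)
    b = a + (-0.3 if fa > 0 else 0.3)
    for _ in range(max_iterations):
        if best[0] < rtol:
            break
        fb, stb = f(b)
        if abs(fb) < best[0]:
            best = (abs(fb), b, stb)
        if fb == fa:
            break
        a, fa, b = b, fb, float(np.clip(b - fb * (b - a) / (fb - fa), b - 1.0, b + 1.0))
    if best[0] > np.log(1.02):
        raise RuntimeError(
            f"could not reach target filling {target_filling:.0f} uL "
            f"(best relative error {np.expm1(best[0]):.2%})"
        )
    return float(np.exp(best[1])), best[2]


def _through_origin_slope(x, y):
    """OLS slope through the origin and its residual RMS."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    slope = float(np.sum(x * y) / np.sum(x * x))
    resid = float(np.sqrt(np.mean((y - slope * x) ** 2)))
    return slope, resid


def filling_sensitivity(
    reference_mesh: HermiteMesh,
    mat: PassiveMaterial,
    growth_params: GrowthParams,
    reduction_fractions=(0.10, 0.20, 0.25, 0.30),
    edp_ref: float = 0.75,
    age_start: float = 22.0,
    target_age: float = 40.0,
    settings: SolverSettings | None = None,
    reference_trajectory: GrowthTrajectory | None = None,
) -> SensitivityResult:
    """Effect of reduced mid-gestation ventricular filling on birth size.

    Each scenario lowers the EDP on the same unloaded mesh until the filling
    volume (EDV - V0) is reduced by the stated fraction, then grows to
    ``target_age`` at that constant EDP with frozen growth constants.
    Reports % changes in 40-week cavity and wall volume and the fitted
    linear slopes per 10% filling reduction.
    """
    for f_ in reduction_fractions:
        if not (-0.5 < f_ < 0.5):
            raise ValueError("reduction fractions must lie in (-0.5, 0.5)")
    if reference_trajectory is None:
        reference_trajectory = simulate_growth(
            reference_mesh, mat, growth_params, edp_ref, age_start, target_age,
            settings=settings, store_meshes=False,
        )
    ref_end = reference_trajectory.data.iloc[-1]
    st_ref = inflate(reference_mesh, mat, edp_ref, settings=settings)
    fill_ref = st_ref.filling_volume

    rows = [
        {
            "reduction": 0.0,
            "edp": edp_ref,
            "filling_volume": fill_ref,
            "cavity_volume_40": ref_end["cavity_volume"],
            "wall_volume_40": ref_end["wall_volume"],
            "cavity_change_pct": 0.0,
            "wall_change_pct": 0.0,
        }
    ]
    for f_ in reduction_fractions:
        if f_ == 0:
            continue
        target = (1.0 - f_) * fill_ref
        edp_f, _st = find_edp_for_filling(
            reference_mesh, mat, target, p0=edp_ref, settings=settings
        )
        traj = simulate_growth(
            reference_mesh, mat, growth_params, edp_f, age_start, target_age,
            settings=settings, store_meshes=False,
        )
        end = traj.data.iloc[-1]
        rows.append(
            {
                "reduction": f_,
                "edp": edp_f,
                "filling_volume": _st.filling_volume,
                "cavity_volume_40": end["cavity_volume"],
                "wall_volume_40": end["wall_volume"],
                "cavity_change_pct": 100.0
                * (end["cavity_volume"] / ref_end["cavity_volume"] - 1.0),
                "wall_change_pct": 100.0
                * (end["wall_volume"] / ref_end["wall_volume"] - 1.0),
            }
        )
    table = pd.DataFrame(rows)
    sub = table[table["reduction"] != 0]
    x = -100.0 * sub["reduction"].to_numpy()  # % filling change (negative)
    cav_slope, cav_res = _through_origin_slope(x, sub["cavity_change_pct"])
    wall_slope, wall_res = _through_origin_slope(x, sub["wall_change_pct"])
    # report as % decrease per 10% filling decrease (positive numbers)
    slopes = {
        "cavity_pct_per_10pct_filling": 10.0 * cav_slope,
        "wall_pct_per_10pct_filling": 10.0 * wall_slope,
    }
    return SensitivityResult(
        table, slopes, {"cavity": cav_res, "wall": wall_res}, load_mode="filling"
    )


_SHAPE_VARIANTS = {
    "wall_thickness_scale": ("thin", "thick"),
    "aspect_ratio_scale": ("ShortWide", "TallNarrow"),
}


def shape_sensitivity(
    reference_mesh: HermiteMesh,
    mat: PassiveMaterial,
    growth_params: GrowthParams,
    wt_scales=(-0.30, -0.10, 0.10, 0.30),
    ar_scales=(-0.20, -0.10, 0.10, 0.20),
    load_mode: str = "constant_preload",
    edp_ref: float = 0.75,
    filling_ref: float | None = None,
    age_start: float = 22.0,
    target_age: float = 40.0,
    settings: SolverSettings | None = None,
    reference_trajectory: GrowthTrajectory | None = None,
) -> SensitivityResult:
    """Effect of mid-gestation LV shape on birth cavity volume.

    Wall-thickness and aspect-ratio variants are built at preserved unloaded
    cavity volume, loaded either at constant preload (EDP) or at constant
    filling volume relative to unloaded, and grown with frozen constants.
    Slopes are % cavity-volume change at ``target_age`` per +10% shape
    change.
    """
    if load_mode not in ("constant_preload", "constant_filling"):
        raise ValueError("load_mode must be constant_preload or constant_filling")
    if reference_trajectory is None:
        reference_trajectory = simulate_growth(
            reference_mesh, mat, growth_params, edp_ref, age_start, target_age,
            settings=settings, store_meshes=False,
        )
    ref_cav40 = float(reference_trajectory.data["cavity_volume"].iloc[-1])
    if load_mode == "constant_filling" and filling_ref is None:
        filling_ref = inflate(
            reference_mesh, mat, edp_ref, settings=settings
        ).filling_volume

    rows = []
    for mode, scales in (
        ("wall_thickness_scale", wt_scales),
        ("aspect_ratio_scale", ar_scales),
    ):
        for scale in scales:
            variant = make_shape_variant(
                reference_mesh, ShapeVariantSpec(mode, scale, True)
            )
            if load_mode == "constant_preload":
                edp = edp_ref
            else:
                edp, _ = find_edp_for_filling(
                    variant, mat, filling_ref, p0=edp_ref, settings=settings
                )
            traj = simulate_growth(
                variant, mat, growth_params, edp, age_start, target_age,
                settings=settings, store_meshes=False,
            )
            cav40 = float(traj.data["cavity_volume"].iloc[-1])
            wall40 = float(traj.data["wall_volume"].iloc[-1])
            rows.append(
                {
                    "mode": mode,
                    "scale": scale,
                    "edp": edp,
                    "cavity_volume_40": cav40,
                    "wall_volume_40": wall40,
                    "cavity_change_pct": 100.0 * (cav40 / ref_cav40 - 1.0),
                }
            )
    table = pd.DataFrame(rows)
    slopes, resid = {}, {}
    for mode, key in (
        ("wall_thickness_scale", "cavity_pct_per_10pct_wt"),
        ("aspect_ratio_scale", "cavity_pct_per_10pct_ar"),
    ):
        sub = table[table["mode"] == mode]
        sl, rs = _through_origin_slope(
            100.0 * sub["scale"].to_numpy(), sub["cavity_change_pct"].to_numpy()
        )
        slopes[key] = 10.0 * sl
        resid[key] = rs
    return SensitivityResult(table, slopes, resid, load_mode=load_mode)
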