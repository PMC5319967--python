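"""Model/Results facade over the fetal LV growth pipeline.

``FetalLVGrowthModel`` bundles the reference unloaded geometry with the
end-diastolic constraints and the normative volumetric trajectory;
``fit()`` performs the two calibrations the pipeline requires — the passive
stress scale against the end-diastolic (pressure, volume) pair, and the
growth-rate scale against the normative EDV curve — and returns a
``FetalLVGrowthResults`` carrying the calibrated constants, the reference
growth trajectory and diagnostics.  Simulation, patient prediction and the
sensitivity experiments hang off the results object, always reusing the
frozen calibrated constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clinical import (
    EchoMeasurements,
    PatientPrediction,
    SensitivityResult,
    filling_sensitivity,
    predict_patient_growth,
    shape_sensitivity,
)
from .geometry import GeometryParams, HermiteMesh, build_lv_mesh, cavity_volume
from .growth import (
    GrowthParams,
    GrowthTrajectory,
    NormativeTrajectory,
    calibrate_growth_rate,
    simulate_growth,
)
from .materials import PassiveMaterial
from .mechanics import (
    BoundaryConditions,
    DeformedState,
    SolverSettings,
    calibrate_passive_stiffness,
    inflate,
)
from .selection import rmsd_to_regression

__all__ = [
    "REFERENCE_EDP_KPA",
    "REFERENCE_EDV_UL",
    "REFERENCE_FILLING_UL",
    "reference_geometry",
    "FetalLVGrowthModel",
    "FetalLVGrowthResults",
]

# End-diastolic constraints of the reference 22-week model: median clinical
# EDP and EDV, and the filling volume at a 0.75 kPa preload.
REFERENCE_EDP_KPA = 0.75  # = 5.63 mmHg
REFERENCE_EDV_UL = 1020.0
REFERENCE_FILLING_UL = 383.0
_REFERENCE_WT_MM = 3.0  # unloaded wall thickness, morphometric mid-range
_REFERENCE_LA_SA = 2.0  # unloaded length-to-width ratio


def geometry_from_volume(
    cavity_volume_ul: float,
    aspect_ratio: float,
    wall_thickness: float = _REFERENCE_WT_MM,
) -> GeometryParams:
    """Unloaded dimensions from a target cavity volume and LA:SA ratio.

    The truncated-ellipsoid cavity volume is
    ``V = pi LA SA^2 (1 - c)(2 + c) / 12`` with ``c = cos(mu_base)``, so a
    volume and a ratio determine both dimensions in closed form.
    """
    c = np.cos(GeometryParams(16.0, 8.0, 2.0).base_truncation_mu)
    shape = np.pi * aspect_ratio * (1.0 - c) * (2.0 + c) / 12.0
    sa = (cavity_volume_ul / shape) ** (1.0 / 3.0)
    return GeometryParams(aspect_ratio * sa, sa, wall_thickness)


def reference_geometry(aspect_ratio: float = _REFERENCE_LA_SA) -> GeometryParams:
    """Reference unloaded geometry implied by the end-diastolic constraints.

    The unloaded cavity volume equals EDV minus the filling volume (637 uL);
    the starting unloaded LA:SA ratio of 2 is subsequently refined during
    fitting so that the *end-diastolic* dimensions reproduce the clinical
    ratio (18 mm / 9 mm at 22 weeks).
    """
    return geometry_from_volume(
        REFERENCE_EDV_UL - REFERENCE_FILLING_UL, aspect_ratio
    )


class FetalLVGrowthModel:
    """Strain-driven finite-element growth model of the fetal left ventricle.

    Parameters
    ----------
    geometry : GeometryParams, optional
        Unloaded mid-gestation geometry (defaults to the reference model).
    ed_targets : dict, optional
        End-diastolic constraints ``{"edp": kPa, "edv": uL}``.
    normative : NormativeTrajectory, optional
        EDV-versus-age curve for growth-rate calibration.
    material, growth : starting parameter sets (calibrated by ``fit``).
    """

    def __init__(
        self,
        geometry: GeometryParams | None = None,
        ed_targets: dict | None = None,
        normative: NormativeTrajectory | None = None,
        material: PassiveMaterial | None = None,
        growth: GrowthParams | None = None,
        settings: SolverSettings | None = None,
        bc: BoundaryConditions | None = None,
        age_start: float = 22.0,
        age_end: float = 40.0,
    ):
        self.geometry = geometry or reference_geometry()
        self.ed_targets = dict(
            ed_targets or {"edp": REFERENCE_EDP_KPA, "edv": REFERENCE_EDV_UL}
        )
        self.normative = normative or NormativeTrajectory()
        self.material0 = material or PassiveMaterial()
        self.growth0 = growth or GrowthParams()
        self.settings = settings or SolverSettings()
        self.bc = bc or BoundaryConditions()
        self.age_start = age_start
        self.age_end = age_end
        self._default_geometry = geometry is None
        self.mesh = build_lv_mesh(self.geometry)

    @classmethod
    def from_dimensions(
        cls, long_axis: float, short_axis: float, wall_thickness: float, **kw
    ) -> "FetalLVGrowthModel":
        return cls(GeometryParams(long_axis, short_axis, wall_thickness), **kw)

    def fit(
        self,
        calibrate_stiffness: bool = True,
        calibrate_growth: bool = True,
        calibrate_geometry: bool | None = None,
    ) -> "FetalLVGrowthResults":
        """Calibrate the reference model and run the growth simulation.

        Three nested calibrations, mirroring how the reference model is
        constrained: the unloaded aspect ratio so the end-diastolic shape
        matches the clinical LA:SA (only when fitting the built-in
        reference geometry), the passive stress scale so the end-diastolic
        (pressure, volume) pair is reproduced, and the growth rate/branch
        ratio against the normative volumetric trajectory.
        """
        if calibrate_geometry is None:
            calibrate_geometry = self._default_geometry and calibrate_stiffness
        if calibrate_geometry:
            material, ed_state = self._calibrate_geometry()
        elif calibrate_stiffness:
            material, ed_state = calibrate_passive_stiffness(
                self.mesh, self.ed_targets, self.material0, self.bc, self.settings
            )
        else:
            material = self.material0
            ed_state = inflate(
                self.mesh, material, self.ed_targets["edp"], self.bc, self.settings
            )
        if calibrate_growth:
            growth, trajectory = calibrate_growth_rate(
                self.growth0, self.normative, self.mesh, material,
                self.ed_targets["edp"], self.age_start, self.age_end,
                settings=self.settings,
            )
        else:
            growth = self.growth0
            trajectory = simulate_growth(
                self.mesh, material, growth, self.ed_targets["edp"],
                self.age_start, self.age_end, settings=self.settings, bc=self.bc,
            )
        return FetalLVGrowthResults(self, material, growth, ed_state, trajectory)

    def _calibrate_geometry(self, rtol: float = 0.01, max_iterations: int = 6):
        """Refine the unloaded LA:SA so the ED shape hits the clinical ratio.

        The end-diastolic configuration is rounder than the unloaded one
        (inflation widens the ventricle), so the unloaded ratio that yields
        the clinical end-diastolic LA:SA (default 18/9) is found by a small
        secant iteration; the cavity-volume constraint V0 = EDV - filling
        is preserved exactly by the closed-form dimension update and the
        stress scale is recalibrated at every step.
        """
        target_ar = self.ed_targets.get("ed_long_axis", 18.0) / self.ed_targets.get(
            "ed_short_axis", 9.0
        )
        v0 = cavity_volume(self.mesh)
        wt = self.geometry.wall_thickness

        def trial(log_ar):
            geo = geometry_from_volume(v0, float(np.exp(log_ar)), wt)
            mesh = build_lv_mesh(geo)
            material, st = calibrate_passive_stiffness(
                mesh, self.ed_targets, self.material0, self.bc, self.settings
            )
            met = st.metrics()
            return (
                float(np.log((met.long_axis / met.short_axis) / target_ar)),
                geo, mesh, material, st,
            )

        a = float(np.log(self.geometry.long_axis / self.geometry.short_axis))
        fa, *out_a = trial(a)
        best = (abs(fa), a, out_a)
        b = a - fa  # ED ratio responds nearly one-to-one in the log
        for _ in range(max_iterations):
            if best[0] < rtol:
                break
            fb, *out_b = trial(b)
            if abs(fb) < best[0]:
                best = (abs(fb), b, out_b)
            if fb == fa:
                break
            a, fa, b = b, fb, float(np.clip(b - fb * (b - a) / (fb - fa), b - 0.5, b + 0.5))
        _, _, (geo, mesh, material, st) = best
        self.geometry, self.mesh = geo, mesh
        return material, st


@dataclass
class FetalLVGrowthResults:
    """Calibrated model constants, reference trajectory and diagnostics."""

    model: FetalLVGrowthModel
    material: PassiveMaterial
    growth_params: GrowthParams
    ed_state: DeformedState
    reference_trajectory: GrowthTrajectory
    _cache: dict = field(default_factory=dict, repr=False)

    # -- diagnostics ------------------------------------------------------
    @property
    def unloaded_cavity_volume(self) -> float:
        return cavity_volume(self.model.mesh)

    @property
    def edv(self) -> float:
        return self.ed_state.cavity_volume

    @property
    def filling_volume(self) -> float:
        return self.ed_state.filling_volume

    def rmsd_to_normative(self) -> float:
        """RMSD (uL) between simulated EDV and the normative curve."""
        d = self.reference_trajectory.data
        return rmsd_to_regression(
            d["cavity_volume"], self.model.normative.edv(d["age"])
        )

    def summary(self) -> str:
        d = self.reference_trajectory.data
        end = d.iloc[-1]
        g = self.geometry_table()
        lines = [
            "        Fetal LV growth model: calibrated reference",
            "=" * 60,
            f"Unloaded geometry        LA {self.model.geometry.long_axis:6.2f} mm   "
            f"SA {self.model.geometry.short_axis:5.2f} mm   WT {self.model.geometry.wall_thickness:4.2f} mm",
            f"Unloaded cavity volume   {self.unloaded_cavity_volume:8.1f} uL",
            f"Passive stress scale C   {self.material.C:8.4f} kPa   "
            f"(b_f {self.material.b_f:.2f}, b_t {self.material.b_t:.2f}, b_fs {self.material.b_fs:.2f})",
            f"End-diastole @ {self.ed_state.pressure:4.2f} kPa  "
            f"EDV {self.edv:7.1f} uL   filling {self.filling_volume:6.1f} uL",
            f"Growth rate scale        {self.growth_params.f_ff_max:8.4f} /week   "
            f"(k {self.growth_params.k_f:.0f}, s50 f/t "
            f"{self.growth_params.s_f50:.3f}/{self.growth_params.s_t50:.3f})",
            "-" * 60,
            f"Reference growth {d['age'].iloc[0]:.0f} -> {end['age']:.0f} weeks:",
            f"  EDV        {d['cavity_volume'].iloc[0]:7.1f} -> {end['cavity_volume']:8.1f} uL",
            f"  long axis  {d['long_axis'].iloc[0]:7.2f} -> {end['long_axis']:8.2f} mm",
            f"  short axis {d['short_axis'].iloc[0]:7.2f} -> {end['short_axis']:8.2f} mm",
            f"  wall vol   {d['wall_volume'].iloc[0]:7.1f} -> {end['wall_volume']:8.1f} uL",
            f"  RMSD to normative EDV  {self.rmsd_to_normative():7.1f} uL "
            f"({100 * self.rmsd_to_normative() / end['cavity_volume']:.1f}% of term EDV)",
            "=" * 60,
        ]
        return "\n".join(lines)

    def geometry_table(self) -> pd.DataFrame:
        return self.reference_trajectory.data

    # -- simulation and experiments (frozen constants) --------------------
    def simulate(self, age_start: float, age_end: float, edp: float | None = None,
                 mesh: HermiteMesh | None = None, **kw) -> GrowthTrajectory:
        return simulate_growth(
            mesh if mesh is not None else self.model.mesh,
            self.material,
            self.growth_params,
            self.model.ed_targets["edp"] if edp is None else edp,
            age_start,
            age_end,
            settings=self.model.settings,
            bc=self.model.bc,
            **kw,
        )

    def predict_patient(
        self, echo: EchoMeasurements, target_age: float, edp: float | None = None
    ) -> PatientPrediction:
        return predict_patient_growth(
            echo, target_age, self.material, self.growth_params,
            self.model.ed_targets["edp"] if edp is None else edp,
            self.model.settings, self.model.bc,
        )

    def filling_sensitivity(self, reduction_fractions=(0.10, 0.20, 0.25, 0.30),
                            **kw) -> SensitivityResult:
        return filling_sensitivity(
            self.model.mesh, self.material, self.growth_params,
            reduction_fractions, self.model.ed_targets["edp"],
            self.model.age_start, self.model.age_end,
            settings=self.model.settings,
            reference_trajectory=self.reference_trajectory, **kw,
        )

    def shape_sensitivity(self, load_mode: str = "constant_preload",
                          **kw) -> SensitivityResult:
        return shape_sensitivity(
            self.model.mesh, self.material, self.growth_params,
            load_mode=load_mode, edp_ref=self.model.ed_targets["edp"],
            age_start=self.model.age_start, target_age=self.model.age_end,
            settings=self.model.settings,
            reference_trajectory=self.reference_trajectory, **kw,
        )

    def plot_growth(self, ax=None):
        """EDV and dimension growth curves against the normative EDV."""
        import matplotlib.pyplot as plt

        d = self.reference_trajectory.data
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        ax.plot(d["age"], d["cavity_volume"] / 1000.0, "k-", label="model EDV")
        ages = np.linspace(d["age"].iloc[0], d["age"].iloc[-1], 100)
        ax.plot(ages, self.model.normative.edv(ages) / 1000.0, "k--",
                label="normative EDV")
        ax.set_xlabel("gestational age (weeks)")
        ax.set_ylabel("end-diastolic volume (mL)")
        ax2 = ax.twinx()
        ax2.plot(d["age"], d["long_axis"], "b-", label="long axis")
        ax2.plot(d["age"], d["short_axis"], "r-", label="short axis")
        ax2.set_ylabel("dimension (mm)")
        ax.legend(loc="upper left")
        ax2.legend(loc="lower right")
        return ax
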