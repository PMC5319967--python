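"""Synthetic fixtures: echo measurement sets and candidate-geometry tables.

These generators stand in for clinical inputs so that every pipeline stage
is testable without data downloads: echocardiographic dimension sets are
measured from known ground-truth meshes with controllable multiplicative
noise, and candidate tables emulate the role of the original cohort of
idealised geometries sampled within clinical ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clinical import EchoMeasurements
from .geometry import GeometryParams, HermiteMesh, build_lv_mesh, measure_echo_dimensions
from .selection import PREGROWTH_PARAMETERS, CandidateTable

__all__ = [
    "DEFAULT_PARAMETER_RANGES",
    "generate_synthetic_echo",
    "generate_candidate_table",
]

# Clinical-range bounds for the seven mid-gestation constraining parameters
# (dimensions mm, EDV uL, EDP kPa).  Spans chosen to bracket the reported
# 22-week medians used to constrain the reference model.
DEFAULT_PARAMETER_RANGES: dict[str, tuple[float, float]] = {
    "unloaded_sa": (6.5, 10.0),
    "unloaded_la": (13.0, 20.0),
    "wall_thickness": (2.0, 4.0),
    "loaded_sa": (8.0, 11.5),
    "loaded_la": (16.0, 22.0),
    "edv": (800.0, 1250.0),
    "edp": (0.55, 0.95),
}


def generate_synthetic_echo(
    truth_mesh: HermiteMesh,
    noise_fraction: float = 0.0,
    seed: int | np.random.Generator = 0,
    gestational_age: float = 22.0,
) -> tuple[EchoMeasurements, dict[str, float]]:
    """Six-planar echo measurements of a known mesh with multiplicative noise.

    Each dimension is perturbed by ``(1 + noise_fraction * N(0, 1))``.
    Returns the measurements and the noise-free truth record for recovery
    tests.  Identical seeds give identical output.
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    truth = measure_echo_dimensions(truth_mesh)
    noisy = {
        k: float(v * (1.0 + noise_fraction * rng.standard_normal()))
        for k, v in truth.items()
    }
    # preserve the outer > inner orderings the measurement protocol guarantees
    noisy["outer_width_base"] = max(noisy["outer_width_base"], noisy["inner_width_base"] * 1.01)
    noisy["outer_width_mid"] = max(noisy["outer_width_mid"], noisy["inner_width_mid"] * 1.01)
    noisy["outer_length"] = max(noisy["outer_length"], noisy["inner_length"] * 1.01)
    echo = EchoMeasurements(
        gestational_age=gestational_age,
        uncertainty=noise_fraction,
        **noisy,
    )
    return echo, truth


def generate_candidate_table(
    n_candidates: int = 24,
    parameter_ranges: dict | None = None,
    seed: int | np.random.Generator = 0,
) -> CandidateTable:
    """Sample feasible candidate geometries within clinical parameter ranges.

    Every constraining parameter of every candidate lies within its stated
    range; the attached reference means/SDs are the range midpoints and a
    quarter of the range span (so all z-scores are bounded by 2).
    """
    ranges = dict(DEFAULT_PARAMETER_RANGES, **(parameter_ranges or {}))
    missing = set(PREGROWTH_PARAMETERS) - set(ranges)
    if missing:
        raise ValueError(f"ranges missing for {sorted(missing)}")
    for k, (lo, hi) in ranges.items():
        if hi < lo:
            raise ValueError(f"empty feasible region for {k!r}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    cols = list(PREGROWTH_PARAMETERS)
    rows = {
        c: rng.uniform(ranges[c][0], ranges[c][1], size=n_candidates) for c in cols
    }
    values = pd.DataFrame(rows, index=pd.RangeIndex(1, n_candidates + 1, name="model"))
    means = pd.Series({c: 0.5 * (ranges[c][0] + ranges[c][1]) for c in cols})
    spans = pd.Series({c: (ranges[c][1] - ranges[c][0]) for c in cols})
    sds = (spans / 4.0).where(spans > 0, 1.0)
    return CandidateTable(values=values, means=means, sds=sds)


def reference_truth_mesh() -> HermiteMesh:
    """A mid-gestation-sized truth mesh for echo-recovery fixtures."""
    return build_lv_mesh(GeometryParams(18.0, 9.2, 2.6))
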