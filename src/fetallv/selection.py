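"""Candidate-geometry optimisation by cumulative z-scores.

Candidate idealised LV geometries are scored against reference clinical
statistics: for each constraining parameter the z-score is the absolute
deviation from the reference mean in units of its standard deviation.
Pregrowth scores cover the seven constraining parameters at mid-gestation
(unloaded SA, LA, WT; loaded SA, LA; EDV; EDP); postgrowth scores
accumulate the dimension errors over the growth interval.  The candidate
with the lowest total cumulative score is selected as the reference model.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "PREGROWTH_PARAMETERS",
    "POSTGROWTH_PARAMETERS",
    "CandidateTable",
    "ZScoreReport",
    "parameter_z_scores",
    "cumulative_z",
    "rmsd_to_regression",
    "load_packaged_zscores",
]

PREGROWTH_PARAMETERS = (
    "unloaded_sa",
    "unloaded_la",
    "wall_thickness",
    "loaded_sa",
    "loaded_la",
    "edv",
    "edp",
)
POSTGROWTH_PARAMETERS = ("post_sa", "post_la")


@dataclass
class CandidateTable:
    """Candidate parameter values with reference means and SDs.

    ``values`` is indexed by candidate id with one column per scored
    parameter; ``means`` / ``sds`` are Series over the same columns.
    """

    values: pd.DataFrame
    means: pd.Series
    sds: pd.Series

    def __post_init__(self):
        cols = list(self.values.columns)
        for name, s in (("means", self.means), ("sds", self.sds)):
            missing = set(cols) - set(s.index)
            if missing:
                raise ValueError(f"{name} missing for parameters {sorted(missing)}")
        if (self.sds[cols] <= 0).any():
            raise ValueError("every scored parameter needs a positive SD")


@dataclass
class ZScoreReport:
    """Per-candidate cumulative scores and the selected candidate."""

    scores: pd.DataFrame  # per-candidate per-parameter z-scores
    pregrowth: pd.Series
    postgrowth: pd.Series
    total: pd.Series
    selected_id: int


def parameter_z_scores(candidates: CandidateTable) -> pd.DataFrame:
    """Absolute z-score of every candidate parameter: |value - mean| / SD."""
    cols = list(candidates.values.columns)
    mu = candidates.means[cols]
    sd = candidates.sds[cols]
    return (candidates.values - mu).abs() / sd


def cumulative_z(scores: pd.DataFrame) -> ZScoreReport:
    """Sum z-scores into pregrowth, postgrowth and total; select the argmin.

    Ties break toward the lowest candidate id.  Raises on missing entries.
    """
    if scores.isna().any().any():
        raise ValueError("score matrix contains missing entries")
    pre_cols = [c for c in scores.columns if c in PREGROWTH_PARAMETERS]
    post_cols = [c for c in scores.columns if c in POSTGROWTH_PARAMETERS]
    pre = scores[pre_cols].sum(axis=1)
    post = scores[post_cols].sum(axis=1)
    total = pre + post
    # idxmin is first-occurrence on ties: lowest id wins for sorted indices
    selected = int(total.sort_index().idxmin())
    return ZScoreReport(scores, pre, post, total, selected)


def rmsd_to_regression(model_series, regression_series) -> float:
    """Root-mean-square deviation between model values and a regression fit.

    ``sqrt(sum((V_model - V_regression)^2) / n_data)``; units preserved.
    """
    m = np.asarray(model_series, dtype=float)
    r = np.asarray(regression_series, dtype=float)
    if m.shape != r.shape or m.ndim != 1 or m.size < 1:
        raise ValueError("series must be equal-length 1-D with n >= 1")
    return float(np.sqrt(np.mean((m - r) ** 2)))


def load_packaged_zscores() -> pd.DataFrame:
    """The packaged candidate z-score table (24 idealised geometries).

    Pre-computed absolute z-scores of the seven mid-gestation constraining
    parameters and the cumulative postgrowth dimension scores, indexed by
    candidate id.
    """
    with resources.files("fetallv.data").joinpath("table1_zscores.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    return df.set_index("model")
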