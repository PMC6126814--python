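"""Quantitative phenotype utilities: ruler calibration, halo areas, reporter RLU.

The flagellar hook grows to a length set by the FliK molecular ruler; over
engineered ruler variants with controlled hooks the relation is linear at
about 0.2 nm of hook per amino acid of ruler.  Motility-plate halo areas are
normalized to the wild-type reference per plate/batch, and luciferase
reporter output is growth-corrected into relative light units (RLU).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .simulate import HookMeasurementSet

__all__ = ["RulerFit", "fit_ruler", "normalize_halos", "compute_rlu"]

log = logging.getLogger(__name__)


@dataclass
class RulerFit:
    """OLS fit of hook length (nm) against ruler length (amino acids)."""

    slope: float            # nm per amino acid
    intercept: float        # nm
    r_squared: float
    residuals: np.ndarray   # per fitted point, nm
    n_points: int
    controlled_only: bool = True
    per_mutant_means: bool = True


def fit_ruler(measurements: HookMeasurementSet, controlled_only: bool = True,
              per_mutant_means: bool = True) -> RulerFit:
    """Ordinary least squares of hook length on FliK ruler length.

    By default the per-mutant mean hook lengths enter the regression (one
    point per distinct ruler length) and mutants flagged uncontrolled are
    excluded; set ``per_mutant_means=False`` to regress on raw measurements.
    """
    data = measurements.data
    if controlled_only:
        data = data[data["controlled"]]
        if data.empty:
            raise ValueError("no controlled records to fit")
    if data["flik_length"].nunique() < 2:
        raise ValueError("need >= 2 distinct ruler lengths")
    if per_mutant_means:
        data = (data.groupby("flik_length", as_index=False)["hook_length"].mean())
    X = sm.add_constant(data["flik_length"].to_numpy(float))
    res = sm.OLS(data["hook_length"].to_numpy(float), X).fit()
    return RulerFit(slope=float(res.params[1]), intercept=float(res.params[0]),
                    r_squared=float(res.rsquared) if len(data) > 2 else 1.0,
                    residuals=np.asarray(res.resid), n_points=int(len(data)),
                    controlled_only=controlled_only,
                    per_mutant_means=per_mutant_means)


def normalize_halos(table: pd.DataFrame, reference_strain: str,
                    batch_col: str = None) -> pd.DataFrame:
    """Normalize motility halo/disk areas to the reference strain.

    ``table`` needs columns ``strain`` and ``area``; each area is divided by
    the mean area of ``reference_strain`` within the same batch (column
    ``batch_col`` if given, otherwise the whole table is one batch).  Batches
    missing the reference are kept but flagged (``normalized_area`` NaN,
    ``reference_missing`` True) rather than silently dropped.
    """
    if "strain" not in table.columns or "area" not in table.columns:
        raise ValueError("table needs 'strain' and 'area' columns")
    out = table.copy()
    if batch_col is None:
        out["_batch"] = 0
        batch_col_eff = "_batch"
    else:
        batch_col_eff = batch_col
    out["normalized_area"] = np.nan
    out["reference_missing"] = False
    for _, idx in out.groupby(batch_col_eff).groups.items():
        sub = out.loc[idx]
        ref = sub.loc[sub["strain"] == reference_strain, "area"]
        if ref.empty:
            out.loc[idx, "reference_missing"] = True
            log.warning("batch without reference strain %r flagged", reference_strain)
            continue
        out.loc[idx, "normalized_area"] = sub["area"] / ref.mean()
    if batch_col is None:
        out = out.drop(columns="_batch")
    return out


def compute_rlu(light, od_t0, od_tn):
    """Relative light units: RLU = light · OD(t=0)/OD(t=n).

    Dividing by the relative growth corrects reporter output for culture
    density changes between induction and measurement.
    """
    od_tn = np.asarray(od_tn, float)
    if np.any(od_tn <= 0):
        raise ValueError("OD at measurement time must be > 0")
    return np.asarray(light, float) * np.asarray(od_t0, float) / od_tn
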