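"""Reference-based subpopulation gating.

The AXL+/cKIT+ (double-positive) subpopulation is defined relative to a
reference microenvironment in which expression of both receptors is
suppressed — spots whose backbone is COL4 alone.  Each marker's gate is
mean + k*SD of the per-cell mean intensity over all reference cells
(sample SD, n-1 denominator; k defaults to 1).  A cell is positive for a
marker when its intensity is strictly above the gate; ties are negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .design import Design, MicroenvironmentCondition

__all__ = [
    "MARKERS",
    "GateModel",
    "GatingError",
    "col4_alone",
    "fit_gate",
    "call_cells",
    "summarize_spots",
    "summarize_conditions",
]

logger = logging.getLogger(__name__)

MARKERS = ("axl", "ckit")


class GatingError(ValueError):
    pass


def col4_alone(condition: MicroenvironmentCondition) -> bool:
    """Default reference selector: backbone is exactly COL4, no factors."""
    return condition.ecm_backbone == frozenset({"COL4"}) and not condition.soluble_factors


def col4_containing(condition: MicroenvironmentCondition) -> bool:
    """Looser selector: any condition whose backbone contains COL4."""
    return "COL4" in condition.ecm_backbone


@dataclass
class GateModel:
    """Per-marker positivity thresholds learned from reference cells."""

    mu_ref: dict[str, float]
    sigma_ref: dict[str, float]
    k: float = 1.0
    n_ref: int = 0
    reference_condition_ids: tuple[str, ...] = ()
    thresholds: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.thresholds = {
            m: self.mu_ref[m] + self.k * self.sigma_ref[m] for m in self.mu_ref
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": list(self.mu_ref),
                "mu_ref": [self.mu_ref[m] for m in self.mu_ref],
                "sigma_ref": [self.sigma_ref[m] for m in self.mu_ref],
                "k": self.k,
                "threshold": [self.thresholds[m] for m in self.mu_ref],
                "n_ref": self.n_ref,
            }
        )


def fit_gate(
    cells: pd.DataFrame,
    design: Design,
    reference_selector: Callable[[MicroenvironmentCondition], bool] = col4_alone,
    k: float = 1.0,
    min_ref_cells: int = 50,
    markers: tuple[str, ...] = MARKERS,
) -> GateModel:
    """Learn mean + k*SD gates from reference-condition cells.

    ``cells`` is the per-cell table with ``condition_id`` and
    ``mean_<marker>`` columns on the background-subtracted scale.
    """
    ref_ids = tuple(
        c.condition_id for c in design.conditions if reference_selector(c)
    )
    ref = cells[cells["condition_id"].isin(ref_ids)]
    if len(ref) < min_ref_cells:
        raise GatingError(
            f"only {len(ref)} reference cells (conditions {list(ref_ids)}); "
            f"need at least {min_ref_cells}"
        )
    mu = {m: float(ref[f"mean_{m}"].mean()) for m in markers}
    sigma = {m: float(ref[f"mean_{m}"].std(ddof=1)) for m in markers}
    return GateModel(
        mu_ref=mu,
        sigma_ref=sigma,
        k=k,
        n_ref=len(ref),
        reference_condition_ids=ref_ids,
    )


def call_cells(cells: pd.DataFrame, gate: GateModel) -> pd.DataFrame:
    """Add boolean positivity calls; strictly-above-gate counts positive."""
    out = cells.copy()
    for m in gate.thresholds:
        out[f"{m}_pos"] = out[f"mean_{m}"] > gate.thresholds[m]
    pos_cols = [f"{m}_pos" for m in gate.thresholds]
    out["double_pos"] = out[pos_cols].all(axis=1)
    return out


def summarize_spots(called: pd.DataFrame) -> pd.DataFrame:
    """Per-spot aggregates of the called cell table.

    Returns one row per spot: cell count, double-positive count and
    fraction, mean marker intensities in the double-positive subset and
    in the ungated population, mean eccentricity and solidity.
    """
    rows = []
    for (spot_index, condition_id), grp in called.groupby(
        ["spot_index", "condition_id"], sort=True
    ):
        n = len(grp)
        dp = grp[grp["double_pos"]]
        row = {
            "spot_index": spot_index,
            "condition_id": condition_id,
            "n_cells": n,
            "n_double_positive": len(dp),
            "fraction_dp": len(dp) / n if n else np.nan,
        }
        for m in MARKERS:
            row[f"mean_{m}_dp"] = float(dp[f"mean_{m}"].mean()) if len(dp) else np.nan
            row[f"mean_{m}_all"] = float(grp[f"mean_{m}"].mean()) if n else np.nan
        row["mean_eccentricity"] = float(grp["eccentricity"].mean()) if n else np.nan
        row["mean_solidity"] = float(grp["solidity"].mean()) if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


#: Fixed feature order of the per-condition phenotype vector.
PHENOTYPE_FEATURES = [
    "fraction_dp",
    "mean_axl_dp",
    "mean_ckit_dp",
    "mean_axl_all",
    "mean_ckit_all",
    "n_cells",
    "mean_eccentricity",
    "mean_solidity",
]


def summarize_conditions(spots: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-condition means over usable spots.

    Spots with zero cells are excluded (count logged, reported in
    ``n_spots_excluded``); a condition left with no usable spots yields a
    flagged all-NaN row rather than being dropped.
    """
    rows = []
    for condition_id, grp in spots.groupby("condition_id", sort=True):
        usable = grp[grp["n_cells"] > 0]
        n_excluded = len(grp) - len(usable)
        if n_excluded:
            logger.info(
                "condition %s: excluded %d empty spots", condition_id, n_excluded
            )
        row = {
            "condition_id": condition_id,
            "n_spots_used": len(usable),
            "n_spots_excluded": n_excluded,
            "flagged": len(usable) == 0,
        }
        for feat in PHENOTYPE_FEATURES:
            row[feat] = float(usable[feat].mean()) if len(usable) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
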