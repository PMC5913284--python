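"""Downstream assay calculators: qPCR fold change, 4PL dose-response, EdU.

* relative qPCR quantification by the 2^(-ddCt) method:
  dCt = Ct(gene) - mean Ct(control genes, same sample),
  ddCt = dCt(sample) - dCt(control sample), fold = 2^(-ddCt);
* four-parameter logistic (4PL) dose-response fitting,
  y = a + (b - a) / (1 + (x/c)^d), with IC50 = c (the midpoint dose);
* EdU incorporation: percent proliferating cells per condition relative
  to a control condition, with an unpaired t-test on replicate percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "AssayError",
    "DoseResponseFit",
    "fold_change",
    "fit_4pl",
    "predict_4pl",
    "ic50",
    "edu_tolerance",
]


class AssayError(ValueError):
    pass


# ---------------------------------------------------------------------------
# 2^(-ddCt)
# ---------------------------------------------------------------------------

def fold_change(
    ct_table: pd.DataFrame,
    control_genes: set[str] | list[str],
    control_sample: str,
) -> pd.DataFrame:
    """Per-(sample, gene) fold expression by the 2^(-ddCt) method.

    ``ct_table`` has columns sample, gene, ct.  Control genes are
    averaged arithmetically within each sample; the control sample's
    folds are exactly 1 for every gene by construction.
    """
    required = {"sample", "gene", "ct"}
    if not required <= set(ct_table.columns):
        raise AssayError(f"ct table needs columns {sorted(required)}")
    df = ct_table.copy()
    if df.duplicated(["sample", "gene"]).any():
        dup = df[df.duplicated(["sample", "gene"])][["sample", "gene"]]
        raise AssayError(f"duplicate (sample, gene) rows: {dup.values.tolist()}")
    if not np.isfinite(df["ct"]).all() or (df["ct"] <= 0).any():
        raise AssayError("Ct values must be finite and > 0")
    control_genes = set(control_genes)
    if control_sample not in set(df["sample"]):
        raise AssayError(f"control sample {control_sample!r} not in table")

    ctrl_means = {}
    for sample, grp in df.groupby("sample"):
        present = set(grp["gene"]) & control_genes
        if present != control_genes:
            missing = sorted(control_genes - present)
            raise AssayError(f"sample {sample!r} is missing control genes {missing}")
        ctrl_means[sample] = grp[grp["gene"].isin(control_genes)]["ct"].mean()

    df["dct"] = df["ct"] - df["sample"].map(ctrl_means)
    ref = df[df["sample"] == control_sample].set_index("gene")["dct"]
    missing_genes = set(df["gene"]) - set(ref.index)
    if missing_genes:
        raise AssayError(
            f"control sample {control_sample!r} lacks genes {sorted(missing_genes)}"
        )
    df["ddct"] = df["dct"] - df["gene"].map(ref)
    df["fold"] = np.power(2.0, -df["ddct"])
    return df[["sample", "gene", "ct", "dct", "ddct", "fold"]]


# ---------------------------------------------------------------------------
# 4PL dose-response
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseFit:
    a: float  # lower asymptote (response as dose -> infinity when d > 0)
    b: float  # upper asymptote (response as dose -> 0)
    c: float  # inflection dose = IC50
    d: float  # Hill slope
    rss: float
    converged: bool
    degenerate: bool = False

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return predict_4pl(x, self.a, self.b, self.c, self.d)


def predict_4pl(x, a: float, b: float, c: float, d: float):
    """y = a + (b - a) / (1 + (x/c)^d), evaluated stably in log-dose."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        ratio = np.exp(d * (np.log(x) - np.log(c)))
    return a + (b - a) / (1.0 + ratio)


def fit_4pl(
    doses: np.ndarray,
    responses: np.ndarray,
    n_starts: int = 3,
    min_points: int = 5,
) -> DoseResponseFit:
    """Least-squares 4PL fit; the dose axis is handled in log space.

    Initialization: a = min(y), b = max(y), c = geometric mean dose,
    d = 1; up to ``n_starts`` perturbed restarts on failure.  A response
    range indistinguishable from noise (flat data) is flagged degenerate.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(x) != len(y):
        raise AssayError("doses and responses differ in length")
    if len(x) < min_points:
        raise AssayError(f"need >= {min_points} dose points, got {len(x)}")
    if (x <= 0).any():
        raise AssayError("doses must be > 0")

    logc0 = float(np.mean(np.log(x)))
    span = float(y.max() - y.min())
    degenerate = span < 1e-3 * max(abs(y).max(), 1e-12)

    def residuals(theta):
        a, b, logc, d = theta
        return predict_4pl(x, a, b, np.exp(logc), d) - y

    best = None
    rng = np.random.default_rng(7)
    for start in range(n_starts):
        theta0 = np.array([y.min(), y.max(), logc0, 1.0])
        if start > 0:
            theta0 = theta0 + rng.normal(0, [0.1 * span + 1e-6, 0.1 * span + 1e-6, 0.5, 0.5])
        try:
            sol = optimize.least_squares(residuals, theta0, method="lm", max_nfev=5000)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if np.all(np.isfinite(sol.x)) and (best is None or rss < best[1]):
            best = (sol, rss)
        if best is not None and best[1] < 1e-20:
            break
    if best is None:
        raise AssayError("4PL fit failed to converge from all starts")
    sol, rss = best
    a, b, logc, d = sol.x
    fit = DoseResponseFit(
        a=float(a), b=float(b), c=float(np.exp(logc)), d=float(d),
        rss=rss, converged=bool(sol.success), degenerate=degenerate,
    )
    if not np.isfinite([fit.a, fit.b, fit.c, fit.d]).all() or fit.c <= 0:
        raise AssayError(f"4PL fit produced non-finite or invalid parameters: {fit}")
    return fit


def ic50(fit: DoseResponseFit) -> float:
    """The midpoint (inflection) dose of a 4PL fit."""
    return fit.c


# ---------------------------------------------------------------------------
# EdU proliferation
# ---------------------------------------------------------------------------

def edu_tolerance(
    counts: pd.DataFrame,
    control_label: str,
) -> pd.DataFrame:
    """Per-condition EdU+ percentage and ratio vs the control condition.

    ``counts`` has columns condition, positive, total (one row per
    replicate).  Returns one row per condition with the mean and SD of
    replicate percentages, the ratio of mean percentage to the control's,
    and the unpaired two-sided t-test p-value vs the control replicates.
    """
    required = {"condition", "positive", "total"}
    if not required <= set(counts.columns):
        raise AssayError(f"counts table needs columns {sorted(required)}")
    if (counts["total"] <= 0).any():
        raise AssayError("totals must be > 0")
    df = counts.copy()
    df["pct"] = 100.0 * df["positive"] / df["total"]
    if control_label not in set(df["condition"]):
        raise AssayError(f"control condition {control_label!r} not present")
    ctrl = df[df["condition"] == control_label]["pct"].to_numpy()
    rows = []
    for condition, grp in df.groupby("condition", sort=True):
        pct = grp["pct"].to_numpy()
        if condition == control_label:
            p = 1.0
        else:
            p = float(stats.ttest_ind(pct, ctrl, equal_var=False).pvalue)
        rows.append(
            {
                "condition": condition,
                "n_replicates": len(pct),
                "pct_mean": float(pct.mean()),
                "pct_sd": float(pct.std(ddof=1)) if len(pct) > 1 else np.nan,
                "relative_to_control": float(pct.mean() / ctrl.mean()),
                "t_p_vs_control": p,
            }
        )
    return pd.DataFrame(rows)
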