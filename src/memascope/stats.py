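"""Effect decoupling, post-hoc contrasts, clustering and embedding.

The central model is a binomial GLM with logit link on per-spot
double-positive counts:

    logit P(cell is AXL+/cKIT+) = alpha + sum_j beta_j * ECM_j
                                        + sum_k gamma_k * factor_k

with one indicator per ECM backbone level (reference level COL4 dropped)
and one indicator per soluble factor (baseline = factor absent).  Because
components co-occur combinatorially across spots, the fit decouples their
marginal contributions on the log-odds scale.

Post-hoc pairwise comparisons among ECM levels (and factor-vs-baseline
comparisons) use a single-step max-|z| family-wise adjustment over the
estimated coefficient covariance — the standard generalization of Tukey's
HSD to GLM coefficients.

Condition-level phenotype structure is explored with z-score hierarchical
clustering and a t-SNE embedding of the standardized phenotype vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .design import Design

__all__ = [
    "GLMFit",
    "SeparationError",
    "StatsError",
    "build_design_matrix",
    "fit_component_glm",
    "posthoc_contrasts",
    "rank_factor_effects",
    "compare_lines",
    "zscore_cluster",
    "embed_conditions",
]

logger = logging.getLogger(__name__)

_ADJ_DRAWS = 100_000
_ADJ_SEED = 20260101  # fixed internal stream: adjusted p-values are deterministic


class StatsError(ValueError):
    pass


class SeparationError(StatsError):
    """Quasi-complete separation: the MLE diverges.

    Refit with ``fit_component_glm(..., method="firth")`` for a
    bias-reduced (Jeffreys-penalized) estimate.
    """


@dataclass
class GLMFit:
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    llf: float
    dispersion: float
    nobs: int
    ecm_levels: list[str]
    ecm_reference: str
    factor_names: list[str]
    method: str = "mle"
    converged: bool = True

    @property
    def coef_frame(self) -> pd.DataFrame:
        z = self.params / self.bse
        from scipy.stats import norm

        return pd.DataFrame(
            {
                "term": self.params.index,
                "estimate": self.params.values,
                "se": self.bse.values,
                "z": z.values,
                "p": 2 * norm.sf(np.abs(z.values)),
            }
        )


def build_design_matrix(
    spots: pd.DataFrame,
    design: Design,
    ecm_reference: str = "COL4",
    min_factor_spots: int = 2,
) -> tuple[pd.DataFrame, np.ndarray, list[str], list[str]]:
    """Spot-level design matrix with ECM-level and factor indicators.

    Returns (X, endog, ecm_levels, factor_names); endog is the two-column
    (successes, failures) array.  Factors observed on fewer than
    ``min_factor_spots`` spots are excluded with a warning (their
    coefficient would be unidentifiable noise).
    """
    usable = spots[spots["n_cells"] > 0].reset_index(drop=True)
    if usable.empty:
        raise StatsError("no usable spots (all have zero cells)")
    cond = {c.condition_id: c for c in design.conditions}
    unknown = set(usable["condition_id"]) - cond.keys()
    if unknown:
        raise StatsError(f"spots reference unknown conditions: {sorted(unknown)[:5]}")

    ecm_label = usable["condition_id"].map(
        lambda cid: "+".join(sorted(cond[cid].ecm_backbone))
    )
    levels = sorted(ecm_label.unique())
    if ecm_reference not in levels:
        ecm_reference = levels[0]
    level_counts = ecm_label.value_counts()
    if len(levels) < 2 or (level_counts >= 2).sum() < 2:
        raise StatsError(
            f"need >=2 ECM levels with >=2 spots each, got {level_counts.to_dict()}"
        )

    factor_spots: dict[str, np.ndarray] = {}
    for f in sorted({f for c in cond.values() for f in c.soluble_factors}):
        ind = usable["condition_id"].map(lambda cid: f in cond[cid].soluble_factors)
        if ind.sum() == 0:
            continue
        if ind.sum() < min_factor_spots:
            logger.warning(
                "factor %s present on only %d spot(s); excluded from model", f, ind.sum()
            )
            continue
        factor_spots[f] = ind.to_numpy(dtype=float)

    X = pd.DataFrame({"Intercept": np.ones(len(usable))})
    ecm_levels_used = [lv for lv in levels if lv != ecm_reference]
    for lv in ecm_levels_used:
        X[f"ecm[{lv}]"] = (ecm_label == lv).to_numpy(dtype=float)
    for f, ind in factor_spots.items():
        X[f"factor[{f}]"] = ind
    endog = np.column_stack(
        [
            usable["n_double_positive"].to_numpy(float),
            (usable["n_cells"] - usable["n_double_positive"]).to_numpy(float),
        ]
    )
    return X, endog, [ecm_reference] + ecm_levels_used, list(factor_spots)


def _firth_logit(
    X: np.ndarray, successes: np.ndarray, failures: np.ndarray, max_iter: int = 200, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, float]:
    """Bias-reduced binomial logit via Jeffreys-prior penalized scoring.

    The score is adjusted by the hat-diagonal term (Firth's correction),
    which keeps estimates finite under separation.
    """
    n = successes + failures
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = n * mu * (1.0 - mu)
        W = np.clip(w, 1e-12, None)
        XtWX = X.T @ (X * W[:, None])
        cov = np.linalg.inv(XtWX)
        # hat diagonal of the weighted LS problem
        h = np.einsum("ij,jk,ik->i", X * np.sqrt(W)[:, None], cov, X * np.sqrt(W)[:, None])
        score = X.T @ (successes - n * mu + h * (0.5 - mu))
        step = cov @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    ll = float(np.sum(successes * np.log(mu + 1e-300) + failures * np.log(1 - mu + 1e-300)))
    W = np.clip(n * mu * (1 - mu), 1e-12, None)
    cov = np.linalg.inv(X.T @ (X * W[:, None]))
    return beta, cov, ll


def fit_component_glm(
    spots: pd.DataFrame,
    design: Design,
    ecm_reference: str = "COL4",
    method: str = "mle",
) -> GLMFit:
    """Fit the binomial logit GLM of double-positive counts on components.

    ``method="mle"`` uses the standard IRLS maximum-likelihood fit and
    raises :class:`SeparationError` when the fit diverges;
    ``method="firth"`` uses the bias-reduced Jeffreys-penalized fit,
    which stays finite under separation.
    """
    X, endog, ecm_levels, factor_names = build_design_matrix(
        spots, design, ecm_reference=ecm_reference
    )
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise StatsError(
            f"design matrix rank-deficient ({rank} < {X.shape[1]}); "
            "check for aliased components"
        )
    terms = list(X.columns)
    if method == "firth":
        beta, cov, ll = _firth_logit(X.to_numpy(), endog[:, 0], endog[:, 1])
        params = pd.Series(beta, index=terms)
        covdf = pd.DataFrame(cov, index=terms, columns=terms)
        bse = pd.Series(np.sqrt(np.diag(cov)), index=terms)
        mu = 1 / (1 + np.exp(-(X.to_numpy() @ beta)))
        n = endog.sum(axis=1)
        pearson = np.sum((endog[:, 0] - n * mu) ** 2 / np.clip(n * mu * (1 - mu), 1e-12, None))
        df_resid = max(len(n) - len(terms), 1)
        return GLMFit(
            params=params, bse=bse, cov_params=covdf, llf=ll,
            dispersion=float(pearson / df_resid), nobs=len(n),
            ecm_levels=ecm_levels, ecm_reference=ecm_levels[0],
            factor_names=factor_names, method="firth",
        )

    model = sm.GLM(endog, X, family=sm.families.Binomial())
    res = model.fit()
    if (not res.converged) or np.any(np.abs(res.params) > 15) or np.any(
        ~np.isfinite(res.bse)
    ):
        raise SeparationError(
            "binomial GLM shows (quasi-)complete separation or non-convergence; "
            'refit with method="firth" for a bias-reduced estimate'
        )
    mu = res.fittedvalues
    n = endog.sum(axis=1)
    df_resid = max(res.df_resid, 1)
    dispersion = float(res.pearson_chi2 / df_resid)
    return GLMFit(
        params=res.params,
        bse=res.bse,
        cov_params=pd.DataFrame(res.cov_params(), index=terms, columns=terms),
        llf=float(res.llf),
        dispersion=dispersion,
        nobs=len(n),
        ecm_levels=ecm_levels,
        ecm_reference=ecm_levels[0],
        factor_names=factor_names,
    )


def _singlestep_adjust(
    estimates: np.ndarray, ses: np.ndarray, cov: np.ndarray, draws: int = _ADJ_DRAWS
) -> np.ndarray:
    """Single-step max-|z| adjusted p-values over a contrast family.

    p_i = P(max_j |Z_j| >= |t_i|) with Z ~ MVN(0, correlation of the
    contrast estimates), evaluated by seeded Monte Carlo.
    """
    t = np.abs(estimates / ses)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    corr = (corr + corr.T) / 2
    # sample via eigendecomposition: contrast covariances are typically singular
    vals, vecs = np.linalg.eigh(corr)
    vals = np.clip(vals, 0.0, None)
    A = vecs * np.sqrt(vals)
    rng = np.random.default_rng(_ADJ_SEED)
    z = rng.standard_normal((draws, corr.shape[0])) @ A.T
    maxabs = np.max(np.abs(z), axis=1)
    return np.array([(maxabs >= ti).mean() for ti in t])


def posthoc_contrasts(
    fit: GLMFit, factor: str = "ecm_backbone", alpha: float = 0.05
) -> pd.DataFrame:
    """All pairwise ECM-level contrasts with family-wise adjustment.

    Output mirrors the familiar contrast-table layout: pair label
    ("A-B" = level A minus level B on the logit scale), estimate,
    standard error, adjusted p, significance flag at ``alpha``.
    """
    if factor != "ecm_backbone":
        raise StatsError(f"unsupported contrast factor {factor!r}")
    levels = sorted(fit.ecm_levels)
    if len(levels) < 2:
        raise StatsError("need at least 2 ECM levels for contrasts")
    terms = list(fit.params.index)

    def level_vec(lv: str) -> np.ndarray:
        v = np.zeros(len(terms))
        if lv != fit.ecm_reference:
            v[terms.index(f"ecm[{lv}]")] = 1.0
        return v

    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
    C = np.array([level_vec(a) - level_vec(b) for a, b in pairs])
    V = fit.cov_params.to_numpy()
    est = C @ fit.params.to_numpy()
    cov_c = C @ V @ C.T
    se = np.sqrt(np.diag(cov_c))
    p_adj = _singlestep_adjust(est, se, cov_c)
    return pd.DataFrame(
        {
            "pair": [f"{a}-{b}" for a, b in pairs],
            "estimate": est,
            "se": se,
            "adjusted_p": p_adj,
            "significant": p_adj < alpha,
        }
    )


def rank_factor_effects(fit: GLMFit, alpha: float = 0.05) -> pd.DataFrame:
    """Soluble factors ranked by estimated log-odds effect vs factor-absent.

    The factor coefficients are each a contrast against the factor-absent
    baseline; the family-wise adjustment runs over the whole factor
    family.  Sorted by estimate, descending.
    """
    terms = list(fit.params.index)
    fterms = [f"factor[{f}]" for f in fit.factor_names]
    if not fterms:
        raise StatsError("model contains no factor terms")
    idx = [terms.index(t) for t in fterms]
    est = fit.params.to_numpy()[idx]
    V = fit.cov_params.to_numpy()[np.ix_(idx, idx)]
    se = np.sqrt(np.diag(V))
    p_adj = _singlestep_adjust(est, se, V)
    out = pd.DataFrame(
        {
            "factor": fit.factor_names,
            "estimate": est,
            "se": se,
            "adjusted_p": p_adj,
            "significant": p_adj < alpha,
        }
    )
    return out.sort_values("estimate", ascending=False).reset_index(drop=True)


@dataclass
class LineComparison:
    diff_variance: float
    lr_stat: float
    lr_df: int
    lr_p: float


def compare_lines(
    spots_a: pd.DataFrame,
    spots_b: pd.DataFrame,
    design: Design,
    ecm_reference: str = "COL4",
) -> LineComparison:
    """Compare two cell lines' microenvironment response profiles.

    Two statistics (the underlying dispersion summary of the original
    analysis is not uniquely defined, so both are reported):

    * ``diff_variance`` — variance across matched conditions of the
      difference in per-condition double-positive fractions;
    * a likelihood-ratio test for a line x ECM-class interaction in the
      joint spot-level binomial GLM (null: the two lines share one
      microenvironment response profile up to a line offset).
    """
    conds_a = set(spots_a["condition_id"])
    conds_b = set(spots_b["condition_id"])
    if conds_a != conds_b:
        diff = sorted(conds_a ^ conds_b)
        raise StatsError(f"condition sets differ; symmetric difference: {diff[:10]}")

    def cond_fracs(spots: pd.DataFrame) -> pd.Series:
        g = spots[spots["n_cells"] > 0].groupby("condition_id")
        return g.apply(
            lambda d: (d["n_double_positive"] / d["n_cells"]).mean(),
            include_groups=False,
        )

    fa, fb = cond_fracs(spots_a), cond_fracs(spots_b)
    common = fa.index.intersection(fb.index)
    diff_var = float((fa[common] - fb[common]).var(ddof=1))

    def stack(with_interaction: bool):
        frames = []
        for line, spots in (("A", spots_a), ("B", spots_b)):
            X, endog, _, _ = build_design_matrix(spots, design, ecm_reference)
            X = X.copy()
            X["line[B]"] = 1.0 if line == "B" else 0.0
            frames.append((X, endog))
        cols = sorted(set(frames[0][0].columns) | set(frames[1][0].columns))
        Xs = [f[0].reindex(columns=cols, fill_value=0.0) for f in frames]
        X = pd.concat(Xs, ignore_index=True)
        endog = np.vstack([f[1] for f in frames])
        if with_interaction:
            for col in [c for c in cols if c.startswith("ecm[")]:
                X[f"line[B]:{col}"] = X["line[B]"] * X[col]
        return X, endog

    lls = {}
    dfs = {}
    for label, inter in (("null", False), ("full", True)):
        X, endog = stack(inter)
        res = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        lls[label] = float(res.llf)
        dfs[label] = X.shape[1]
    lr = max(0.0, 2 * (lls["full"] - lls["null"]))
    df = dfs["full"] - dfs["null"]
    from scipy.stats import chi2

    p = float(chi2.sf(lr, df)) if df > 0 else 1.0
    return LineComparison(diff_variance=diff_var, lr_stat=lr, lr_df=df, lr_p=p)


def zscore_cluster(
    matrix: pd.DataFrame,
    axis: int = 0,
    distance: str = "euclidean",
    linkage_method: str = "average",
) -> dict:
    """Z-score a condition x feature matrix and cluster rows hierarchically.

    ``axis=0`` standardizes each column (feature) over rows.  Constant
    features are dropped with a warning; an all-constant matrix is an
    error.  Rows are pre-sorted by index so leaf order is deterministic.
    Returns a dict with keys ``z`` (DataFrame), ``linkage``, ``leaf_order``
    (index labels in dendrogram order), and ``cut`` (callable n_clusters ->
    label Series).
    """
    if len(matrix) < 2:
        raise StatsError("need at least 2 rows to cluster")
    m = matrix.sort_index()
    mean = m.mean(axis=axis)
    sd = m.std(axis=axis, ddof=1)
    if axis == 0:
        keep = sd > 0
        if not keep.any():
            raise StatsError("all features constant; nothing to standardize")
        if (~keep).any():
            logger.warning("dropping constant features: %s", list(sd.index[~keep]))
        z = (m.loc[:, keep] - mean[keep]) / sd[keep]
    else:
        keep = sd > 0
        if not keep.any():
            raise StatsError("all rows constant; nothing to standardize")
        z = m.loc[keep].sub(mean[keep], axis=0).div(sd[keep], axis=0)
    Z = hierarchy.linkage(pdist(z.to_numpy(), metric=distance), method=linkage_method)
    leaves = hierarchy.leaves_list(Z)
    leaf_order = list(z.index[leaves])

    def cut(n_clusters: int) -> pd.Series:
        labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
        return pd.Series(labels, index=z.index, name="cluster")

    return {"z": z, "linkage": Z, "leaf_order": leaf_order, "cut": cut}


def embed_conditions(
    phenotypes: pd.DataFrame,
    perplexity: float = 30.0,
    seed: int = 0,
    max_iter: int = 1000,
) -> pd.DataFrame:
    """t-SNE embedding of standardized condition phenotype vectors.

    Requires at least ``3 * perplexity`` conditions (t-SNE's neighborhood
    size); features are z-scored first, initialization is PCA, and the
    seed fixes the embedding exactly.  Returns a DataFrame indexed like
    ``phenotypes`` with columns x, y.
    """
    from sklearn.manifold import TSNE

    n = len(phenotypes)
    if n < 3 * perplexity:
        raise StatsError(
            f"{n} conditions < 3 x perplexity ({perplexity}); "
            f"lower perplexity to <= {n / 3:.0f}"
        )
    X = phenotypes.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xz = (X - mean) / sd
    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=seed,
        max_iter=max_iter,
        method="exact" if n < 200 else "barnes_hut",
        n_jobs=1,
    )
    coords = ts.fit_transform(Xz)
    return pd.DataFrame(coords, columns=["x", "y"], index=phenotypes.index)
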