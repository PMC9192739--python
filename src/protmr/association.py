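"""Protein-outcome association stage.

Study-wide sex/age-adjusted logistic screening of every analyte against a
staged disease outcome, quantile (quintile/quartile) profiling with a
top-vs-bottom marginal contrast, Fisher-exact module enrichment, and module
eigenprotein (first/second principal component) scores.

Multiple testing is Bonferroni at the level of unique protein-encoding
genes, not analytes: several aptamers can target the same gene product, and
0.05 divided by the gene count is what reproduces the study-wide threshold
(with 4137 genes, 1.21e-5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import logit_fit
from .simulate import ProteinMatrix, binary_outcome

__all__ = [
    "bonferroni_threshold",
    "logistic_screen",
    "QuantileProfile",
    "quantile_bins",
    "quantile_profile",
    "EnrichmentResult",
    "module_enrichment",
    "eigenprotein",
]


def bonferroni_threshold(n_genes: int, alpha: float = 0.05) -> float:
    """Study-wide significance threshold: alpha over the unique gene count."""
    if n_genes < 1:
        raise ValueError("need at least one gene")
    return alpha / n_genes


def logistic_screen(proteins: ProteinMatrix, phen: pd.DataFrame, outcome: str,
                    covariates: tuple[str, ...] = ("age", "sex"),
                    alpha: float = 0.05) -> pd.DataFrame:
    """Sex/age-adjusted logistic regression of every analyte on one outcome.

    Returns one record per analyte: ``beta`` (log OR per SD), ``se``, ``p``,
    ``p_adj`` (gene-count Bonferroni, capped at 1), case/control counts,
    ``significant`` (p below alpha / unique genes) and a ``converged`` flag.
    Missing protein values are dropped case-wise per analyte. Outcomes with
    fewer than 2 cases (or controls) are rejected.
    """
    if proteins.state != "transformed":
        raise ValueError("logistic_screen expects transformed protein data")
    y_all = binary_outcome(phen, outcome)
    if (y_all == 1).sum() < 2 or (y_all == 0).sum() < 2:
        raise ValueError(f"outcome {outcome!r} has fewer than 2 cases/controls")
    n_genes = proteins.annotation["gene"].nunique()
    thresh = bonferroni_threshold(n_genes, alpha)
    cov = phen.loc[proteins.values.index, list(covariates)]

    rows = []
    for aid in proteins.values.columns:
        x = proteins.values[aid]
        df = pd.concat([y_all, x.rename("_x"), cov], axis=1).dropna()
        y = df[outcome].to_numpy(dtype=float)
        ncase, nctrl = int(y.sum()), int(len(y) - y.sum())
        beta = se = p = np.nan
        ok = False
        if ncase >= 2 and nctrl >= 2 and df["_x"].nunique() > 1:
            X = np.column_stack([np.ones(len(df)), df["_x"].to_numpy(),
                                 df[list(covariates)].to_numpy(dtype=float)])
            b, s, ok = logit_fit(X, y)
            if ok and np.isfinite(s[1]) and s[1] > 0:
                beta, se = float(b[1]), float(s[1])
                p = 2.0 * stats.norm.sf(abs(beta / se))
            else:
                ok = False
        rows.append({"analyte": aid, "outcome": outcome, "beta": beta,
                     "se": se, "p": p,
                     "p_adj": min(1.0, p * n_genes) if np.isfinite(p) else np.nan,
                     "n_cases": ncase, "n_controls": nctrl,
                     "significant": bool(np.isfinite(p) and p < thresh),
                     "converged": bool(ok)})
    out = pd.DataFrame(rows).set_index("analyte")
    out.attrs["threshold"] = thresh
    out.attrs["n_genes"] = n_genes
    return out


def quantile_bins(x: pd.Series, q: int) -> pd.Series:
    """Rank-based equal-size bins 1..q; sizes differ by at most one.

    Ties are broken by stable sample order after ranking, so the assignment
    is deterministic. Example: values 1..10 with q=5 map to
    (1,1,2,2,3,3,4,4,5,5).
    """
    obs = x.dropna()
    if obs.nunique() < q:
        raise ValueError("protein has fewer distinct values than bins")
    order = np.argsort(obs.to_numpy(), kind="stable")
    bins = np.empty(len(obs), dtype=int)
    for b, chunk in enumerate(np.array_split(np.arange(len(obs)), q), start=1):
        bins[order[chunk]] = b
    out = pd.Series(np.nan, index=x.index)
    out[obs.index] = bins
    return out


@dataclass
class QuantileProfile:
    """Per-bin log-odds profile of one analyte against one outcome."""

    analyte: str
    outcome: str
    q: int
    bin_logodds: pd.DataFrame        # columns: logodds, lo, hi (95% CI) per bin
    slope: float                     # log OR per bin, bins coded 1..q
    slope_ci: tuple[float, float]
    slope_p: float
    contrast: float                  # q-th vs 1st bin marginal difference
    contrast_ci: tuple[float, float]
    contrast_p: float


def quantile_profile(protein: pd.Series, phen: pd.DataFrame, outcome: str,
                     q: int = 5, covariates: tuple[str, ...] = ("age", "sex"),
                     analyte: str = "") -> QuantileProfile:
    """Quantile-as-factor and quantile-as-continuous logistic profiles.

    The categorical model treats bins as factor levels (bin 1 reference) and
    reports per-bin predicted log odds at mean covariate values with 95%
    CIs; the continuous model codes bins 1..q numerically. The top-vs-bottom
    contrast is the marginal (model-based) difference between the q-th and
    reference bins, i.e. the q-th bin dummy coefficient; the reference bin
    contrast is exactly zero by construction.
    """
    if q not in (4, 5):
        raise ValueError("q must be 4 (quartiles) or 5 (quintiles)")
    y_all = binary_outcome(phen, outcome)
    bins = quantile_bins(protein, q)
    df = pd.concat([y_all, bins.rename("_bin"),
                    phen[list(covariates)]], axis=1).dropna()
    y = df[outcome].to_numpy(dtype=float)
    C = df[list(covariates)].to_numpy(dtype=float)
    Cc = C - C.mean(axis=0)  # center so bin terms are at mean covariates
    Cc = Cc[:, Cc.std(axis=0) > 0]  # a constant covariate carries no model

    # categorical model: intercept + dummies for bins 2..q + covariates
    D = np.column_stack([(df["_bin"] == b).to_numpy(dtype=float)
                         for b in range(2, q + 1)])
    Xcat = np.column_stack([np.ones(len(df)), D, Cc])
    b_cat, se_cat, ok1 = logit_fit(Xcat, y)
    if not ok1:
        raise ValueError("categorical quantile model did not converge")
    z = stats.norm.ppf(0.975)
    # covariance for linear predictions per bin
    mu = 1.0 / (1.0 + np.exp(-(Xcat @ b_cat)))
    H = Xcat.T @ (Xcat * (mu * (1 - mu))[:, None])
    cov_b = np.linalg.inv(H)
    rows = []
    for b in range(1, q + 1):
        vec = np.zeros(Xcat.shape[1])
        vec[0] = 1.0
        if b > 1:
            vec[b - 1] = 1.0
        est = float(vec @ b_cat)
        sd = float(np.sqrt(vec @ cov_b @ vec))
        rows.append({"bin": b, "logodds": est, "lo": est - z * sd,
                     "hi": est + z * sd})
    bin_logodds = pd.DataFrame(rows).set_index("bin")

    # top-vs-bottom marginal contrast = q-th bin dummy coefficient
    cvec = np.zeros(Xcat.shape[1])
    cvec[q - 1] = 1.0
    contrast = float(cvec @ b_cat)
    csd = float(np.sqrt(cvec @ cov_b @ cvec))
    contrast_p = 2.0 * stats.norm.sf(abs(contrast / csd)) if csd > 0 else np.nan

    # continuous coding 1..q
    Xcont = np.column_stack([np.ones(len(df)), df["_bin"].to_numpy(dtype=float), Cc])
    b_con, se_con, ok2 = logit_fit(Xcont, y)
    if not ok2:
        raise ValueError("continuous quantile model did not converge")
    slope, ssd = float(b_con[1]), float(se_con[1])
    slope_p = 2.0 * stats.norm.sf(abs(slope / ssd)) if ssd > 0 else np.nan

    return QuantileProfile(
        analyte=analyte or (protein.name or ""), outcome=outcome, q=q,
        bin_logodds=bin_logodds,
        slope=slope, slope_ci=(slope - z * ssd, slope + z * ssd), slope_p=slope_p,
        contrast=contrast, contrast_ci=(contrast - z * csd, contrast + z * csd),
        contrast_p=contrast_p)


@dataclass
class EnrichmentResult:
    """2x2 Fisher-exact enrichment of hits within a module."""

    table: np.ndarray                # [[hits_in, hits_out], [non_in, non_out]]
    odds_ratio: float
    p: float
    degenerate: bool = False


def module_enrichment(hits: set, module: set, universe: set) -> EnrichmentResult:
    """Two-sided Fisher exact test of hit enrichment in a module.

    The table partitions the universe by (hit, in-module); the reported OR
    is the sample odds ratio ad/bc. Empty hits or module give a degenerate
    table returned with a flag rather than an error.
    """
    hits, module, universe = set(hits), set(module), set(universe)
    if not hits <= universe or not module <= universe:
        raise ValueError("hits and module must be subsets of the universe")
    a = len(hits & module)
    b = len(hits - module)
    c = len(module - hits)
    d = len(universe - hits - module)
    table = np.array([[a, b], [c, d]])
    if min(len(hits), len(module)) == 0:
        return EnrichmentResult(table, np.nan, 1.0, degenerate=True)
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(table, float(odds), float(p))


def eigenprotein(proteins: ProteinMatrix, module: set, n_components: int = 1,
                 max_missing: float = 0.5) -> pd.DataFrame:
    """Module eigenprotein: first (and optionally second) PC score per sample.

    Computed from the standardized module submatrix (missing values mean-
    imputed for the decomposition); each component is sign-fixed to
    correlate positively with the module mean profile. Samples missing more
    than ``max_missing`` of the module's analytes get a missing score.
    """
    module = [a for a in proteins.values.columns if a in set(module)]
    if len(module) < 2:
        raise ValueError("module must contain at least two measured analytes")
    sub = proteins.values[module]
    frac_missing = sub.isna().mean(axis=1)
    X = sub.to_numpy(dtype=float)
    col_mean = np.nanmean(X, axis=0)
    col_sd = np.nanstd(X, axis=0)
    col_sd[col_sd == 0] = 1.0
    Z = (X - col_mean) / col_sd
    Z = np.where(np.isnan(Z), 0.0, Z)
    U, s, Vt = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)
    mean_profile = Z.mean(axis=1)
    out = {}
    for k in range(n_components):
        score = U[:, k] * s[k]
        if np.corrcoef(score, mean_profile)[0, 1] < 0:
            score = -score
        out[f"PC{k + 1}"] = score
    res = pd.DataFrame(out, index=sub.index)
    res[frac_missing > max_missing] = np.nan
    res.attrs["explained_variance_ratio"] = (s**2 / (s**2).sum())[:n_components]
    res.attrs["loadings"] = pd.DataFrame(
        Vt[:n_components].T, index=module,
        columns=[f"PC{k + 1}" for k in range(n_components)])
    return res
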