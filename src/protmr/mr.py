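"""Two-sample Mendelian randomization for correlated cis instruments.

Implements the full causal-inference stage: cis-window instrument
selection with a window-wide Bonferroni threshold and greedy LD clumping,
allele harmonization with proxy substitution, the generalized weighted
least squares (GWLS) causal estimator for correlated instruments, the Wald
ratio for single instruments, weighted-median and MR-Egger sensitivity
estimators, Benjamini-Hochberg FDR adjustment, and the two-step
sensitivity gate that promotes an estimate to causal-candidate status.

The GWLS estimator combines per-variant exposure effects beta_X (SD units)
and outcome effects beta_Y (log odds ratios) through the weighting matrix
Sigma with entries rho_ij * sigma_Yi * sigma_Yj, where rho is the signed LD
correlation between instruments:

    theta_hat = (beta_X' Sigma^-1 beta_X)^-1  beta_X' Sigma^-1 beta_Y
    se(theta_hat) = alpha * sqrt((beta_X' Sigma^-1 beta_X)^-1)

with alpha = max(1, sqrt(MSE)) and MSE the Sigma^-1-weighted residual
quadratic form divided by (M - 1), so a good fit never deflates the SE.
Exposure-side standard errors are carried but not used by the estimators
(the no-measurement-error first-order convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import GenotypeMatrix

__all__ = [
    "MRConfig", "InstrumentSet", "MREstimate", "ld_matrix",
    "make_instrument_set", "select_instruments", "harmonize_and_proxy",
    "gwls_estimate", "wald_ratio", "weighted_median", "mr_egger",
    "bh_adjust", "sensitivity_gate", "mr_all_methods",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(str(ea).upper()) == str(oa).upper()


@dataclass(frozen=True)
class MRConfig:
    """Tunable parameters of the MR stage.

    ``p_b`` is not stored: it is always 0.05 / N with N the number of
    variants in the cis window. ``null_dist`` selects the reference
    distribution for the causal P ("normal", or "t" with M-1 df).
    """

    window_halfwidth: int = 500_000
    clump_r2: float = 0.2
    proxy_r2: float = 0.8
    fdr_level: float = 0.05
    null_dist: str = "normal"
    palindromic_maf: float = 0.42
    wm_bootstrap: int = 1000
    wm_seed: int = 0
    ridge_eps: float = 1e-6

    def __post_init__(self):
        for name in ("clump_r2", "proxy_r2", "fdr_level"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.window_halfwidth <= 0:
            raise ValueError("window halfwidth must be positive")
        if self.null_dist not in ("normal", "t"):
            raise ValueError("null_dist must be 'normal' or 't'")


@dataclass
class InstrumentSet:
    """Harmonized instruments for one protein.

    ``table`` is indexed by variant id with columns
    ``chrom pos ea oa beta_x se_x beta_y se_y maf`` (beta_y/se_y NaN until
    harmonized); ``ld`` is the signed LD correlation matrix in table order.
    ``window`` retains the full cis-window exposure statistics for proxy
    search; ``dropped`` logs variants removed during harmonization.
    """

    analyte: str
    gene: dict
    table: pd.DataFrame
    ld: np.ndarray
    p_b: float
    n_window: int
    window: pd.DataFrame | None = None
    dropped: list = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.table)

    @property
    def untestable(self) -> bool:
        return self.m == 0

    def validate(self):
        if self.m:
            if not np.allclose(self.ld, self.ld.T) or \
                    not np.allclose(np.diag(self.ld), 1.0):
                raise ValueError("LD matrix must be symmetric with unit diagonal")
            if np.any(np.abs(self.ld) > 1.0 + 1e-12):
                raise ValueError("LD entries must lie in [-1, 1]")


@dataclass
class MREstimate:
    """Causal-effect record for one analyte and one estimator."""

    analyte: str
    method: str                      # gwls | wald | weighted_median | egger
    theta: float
    se: float
    p: float
    m: int
    fdr: float | None = None
    mse: float = np.nan
    alpha: float = np.nan
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None
    gate: str = "not_tested"
    note: str = ""


# --------------------------------------------------------------------------
# LD helpers
# --------------------------------------------------------------------------

def ld_matrix(genotypes: GenotypeMatrix, variants) -> np.ndarray:
    """Signed empirical dosage correlation among ``variants``."""
    G = genotypes.dosages[list(variants)].to_numpy(dtype=float)
    sd = G.std(axis=0)
    if np.any(sd == 0):
        bad = [v for v, s in zip(variants, sd) if s == 0]
        raise ValueError(f"monomorphic variants in LD source: {bad}")
    return np.corrcoef(G, rowvar=False).reshape(len(sd), len(sd))


def make_instrument_set(analyte: str, beta_x, se_x, beta_y, se_y,
                        ld=None) -> InstrumentSet:
    """Build a harmonized ``InstrumentSet`` directly from effect arrays
    (identity LD unless given); convenient for fixtures and summary-level
    analyses."""
    beta_x = np.asarray(beta_x, dtype=float)
    m = len(beta_x)
    table = pd.DataFrame({
        "chrom": 1, "pos": np.arange(m) + 1, "ea": "A", "oa": "G",
        "beta_x": beta_x, "se_x": np.asarray(se_x, dtype=float),
        "beta_y": np.asarray(beta_y, dtype=float),
        "se_y": np.asarray(se_y, dtype=float),
        "maf": np.nan,
    }, index=[f"snp{i}" for i in range(m)])
    ld = np.eye(m) if ld is None else np.asarray(ld, dtype=float)
    out = InstrumentSet(analyte=analyte, gene={}, table=table, ld=ld,
                        p_b=np.nan, n_window=m)
    out.validate()
    return out


# --------------------------------------------------------------------------
# instrument selection and harmonization
# --------------------------------------------------------------------------

def select_instruments(exposure: pd.DataFrame, gene: dict, config: MRConfig,
                       ld_source: GenotypeMatrix) -> InstrumentSet:
    """Select clumped cis instruments for one protein.

    Restricts the exposure statistics to the gene's cis window, computes the
    window-wide threshold P_b = 0.05 / N (N = variants in the window),
    greedily clumps by ascending P (a retained index variant removes any
    later variant with r^2 >= ``clump_r2`` within 1 Mb), and finally prunes
    survivors with P >= P_b. An empty survivor set marks the analyte
    untestable rather than raising.
    """
    lo = gene["start"] - config.window_halfwidth
    hi = gene["end"] + config.window_halfwidth
    window = exposure[(exposure["chrom"] == gene["chrom"])
                      & (exposure["pos"] >= lo) & (exposure["pos"] <= hi)].copy()
    n_window = len(window)
    empty = InstrumentSet(analyte=str(gene.get("analyte", gene.get("gene", ""))),
                          gene=dict(gene), table=window.iloc[0:0],
                          ld=np.empty((0, 0)), p_b=np.nan, n_window=n_window,
                          window=window)
    if n_window == 0:
        return empty
    p_b = 0.05 / n_window
    cand = window.dropna(subset=["beta", "se", "p"]).sort_values(
        "p", kind="stable")
    usable = [v for v in cand.index
              if v in ld_source.dosages.columns
              and ld_source.dosages[v].std() > 0]
    cand = cand.loc[usable]
    if cand.empty:
        return replace(empty, p_b=p_b)

    R = ld_matrix(ld_source, list(cand.index))
    pos = cand["pos"].to_numpy()
    kept: list[int] = []
    for i in range(len(cand)):
        clumped = any(abs(pos[i] - pos[j]) <= 1_000_000
                      and R[i, j] ** 2 >= config.clump_r2 for j in kept)
        if not clumped:
            kept.append(i)
    survivors = cand.iloc[kept]
    survivors = survivors[survivors["p"] < p_b]
    if survivors.empty:
        return replace(empty, p_b=p_b)

    table = survivors.rename(columns={"beta": "beta_x", "se": "se_x"})
    table = table[["chrom", "pos", "ea", "oa", "beta_x", "se_x", "p"]].copy()
    table["beta_y"] = np.nan
    table["se_y"] = np.nan
    mafs = ld_source.variants["maf"] if "maf" in ld_source.variants else None
    table["maf"] = [float(mafs[v]) if mafs is not None and v in mafs else np.nan
                    for v in table.index]
    ld = ld_matrix(ld_source, list(table.index))
    out = InstrumentSet(analyte=empty.analyte, gene=dict(gene), table=table,
                        ld=ld, p_b=p_b, n_window=n_window, window=window)
    out.validate()
    return out


def _align_outcome(exp_ea, exp_oa, orec) -> float | None:
    """Outcome beta aligned to the exposure effect allele; None if alleles
    are inconsistent."""
    if orec["ea"] == exp_ea and orec["oa"] == exp_oa:
        return float(orec["beta"])
    if orec["ea"] == exp_oa and orec["oa"] == exp_ea:
        return -float(orec["beta"])
    # strand flip
    cea, coa = _COMPLEMENT.get(str(orec["ea"]).upper()), \
        _COMPLEMENT.get(str(orec["oa"]).upper())
    if cea == exp_ea and coa == exp_oa:
        return float(orec["beta"])
    if cea == exp_oa and coa == exp_ea:
        return -float(orec["beta"])
    return None


def harmonize_and_proxy(instruments: InstrumentSet, outcome: pd.DataFrame,
                        ld_source: GenotypeMatrix,
                        config: MRConfig) -> InstrumentSet:
    """Align outcome effects to exposure effect alleles; substitute proxies.

    Outcome betas are sign-flipped on allele swaps. Palindromic (A/T, C/G)
    instruments with MAF above the ambiguity threshold are dropped with a
    log entry. An instrument missing from the outcome set is replaced by its
    best in-window proxy with r^2 > ``proxy_r2`` that is present in the
    outcome set, with the exposure effect re-estimated at the proxy (so
    both samples refer to the same physical variant); instruments with no
    qualifying proxy are dropped. The LD matrix is rebuilt for the final
    set.
    """
    if instruments.untestable:
        return instruments
    rows = []
    dropped = list(instruments.dropped)
    window = instruments.window if instruments.window is not None \
        else instruments.table
    used = set()
    for vid, rec in instruments.table.iterrows():
        target = vid
        trec = rec
        if vid not in outcome.index:
            proxy = _best_proxy(vid, rec, window, outcome, ld_source, config)
            if proxy is None:
                dropped.append((vid, "no_outcome_record_no_proxy"))
                continue
            target = proxy
            wrec = window.loc[proxy]
            trec = pd.Series({"chrom": wrec["chrom"], "pos": wrec["pos"],
                              "ea": wrec["ea"], "oa": wrec["oa"],
                              "beta_x": wrec["beta"], "se_x": wrec["se"],
                              "p": wrec["p"], "maf": np.nan})
            if "maf" in ld_source.variants and proxy in ld_source.variants.index:
                trec["maf"] = float(ld_source.variants.loc[proxy, "maf"])
        if target in used:
            dropped.append((vid, "proxy_already_used"))
            continue
        if _is_palindromic(trec["ea"], trec["oa"]):
            maf = trec.get("maf", np.nan)
            if not np.isfinite(maf) or maf > config.palindromic_maf:
                dropped.append((target, "palindromic_ambiguous"))
                continue
        beta_y = _align_outcome(trec["ea"], trec["oa"], outcome.loc[target])
        if beta_y is None:
            dropped.append((target, "allele_mismatch"))
            continue
        row = dict(trec)
        row["variant"] = target
        row["beta_y"] = beta_y
        row["se_y"] = float(outcome.loc[target, "se"])
        rows.append(row)
        used.add(target)

    if not rows:
        return replace(instruments, table=instruments.table.iloc[0:0],
                       ld=np.empty((0, 0)), dropped=dropped)
    table = pd.DataFrame(rows).set_index("variant")
    ld = ld_matrix(ld_source, list(table.index))
    out = replace(instruments, table=table, ld=ld, dropped=dropped)
    out.validate()
    return out


def _best_proxy(vid: str, rec: pd.Series, window: pd.DataFrame,
                outcome: pd.DataFrame, ld_source: GenotypeMatrix,
                config: MRConfig) -> str | None:
    if vid not in ld_source.dosages.columns:
        return None
    g0 = ld_source.dosages[vid].to_numpy(dtype=float)
    best, best_r2 = None, config.proxy_r2
    for cand in window.index:
        if cand == vid or cand not in outcome.index \
                or cand not in ld_source.dosages.columns:
            continue
        if not np.isfinite(window.loc[cand, "beta"]):
            continue
        g1 = ld_source.dosages[cand].to_numpy(dtype=float)
        if g1.std() == 0:
            continue
        r2 = float(np.corrcoef(g0, g1)[0, 1]) ** 2
        if r2 > best_r2:
            best, best_r2 = cand, r2
    return best


# --------------------------------------------------------------------------
# estimators
# --------------------------------------------------------------------------

def _causal_p(theta: float, se: float, m: int, config: MRConfig) -> float:
    if se <= 0 or not np.isfinite(se):
        return np.nan
    z = theta / se
    if config.null_dist == "t" and m >= 2:
        return 2.0 * stats.t.sf(abs(z), m - 1)
    return 2.0 * stats.norm.sf(abs(z))


def _weight_matrix(instruments: InstrumentSet, config: MRConfig):
    rho = instruments.ld.copy()
    if np.linalg.eigvalsh(rho).min() < 1e-8:
        rho = rho + config.ridge_eps * np.eye(len(rho))
    sy = instruments.table["se_y"].to_numpy(dtype=float)
    sigma = rho * np.outer(sy, sy)
    cond = np.linalg.cond(sigma)
    if cond > 1e6:
        raise np.linalg.LinAlgError(
            f"weighting matrix singular beyond regularization "
            f"(condition number {cond:.3g})")
    return sigma


def gwls_estimate(instruments: InstrumentSet,
                  config: MRConfig = MRConfig()) -> MREstimate:
    """Generalized weighted least squares causal estimate.

    With M = 1 this collapses exactly to the Wald ratio (alpha fixed to 1,
    normal null). With rho = I it equals the classical inverse-variance-
    weighted estimate. The SE carries alpha = max(1, sqrt(MSE)), so
    residual heterogeneity inflates but never deflates uncertainty.
    """
    m = instruments.m
    if m == 0:
        raise ValueError("no instruments (analyte untestable)")
    bx = instruments.table["beta_x"].to_numpy(dtype=float)
    by = instruments.table["beta_y"].to_numpy(dtype=float)
    if np.any(~np.isfinite(by)):
        raise ValueError("outcome effects not harmonized")
    if m == 1:
        est = wald_ratio(instruments.table.iloc[0], config)
        return replace(est, analyte=instruments.analyte, method="gwls",
                       mse=0.0, alpha=1.0)
    sigma = _weight_matrix(instruments, config)
    sinv_bx = np.linalg.solve(sigma, bx)
    sinv_by = np.linalg.solve(sigma, by)
    info = float(bx @ sinv_bx)
    theta = float(bx @ sinv_by) / info
    resid = by - bx * theta
    mse = float(resid @ np.linalg.solve(sigma, resid)) / (m - 1)
    alpha = max(1.0, float(np.sqrt(mse)))
    se = alpha * float(np.sqrt(1.0 / info))
    return MREstimate(analyte=instruments.analyte, method="gwls",
                      theta=theta, se=se, p=_causal_p(theta, se, m, config),
                      m=m, mse=mse, alpha=alpha)


def wald_ratio(instrument: pd.Series,
               config: MRConfig = MRConfig()) -> MREstimate:
    """Single-instrument Wald ratio theta = beta_Y / beta_X.

    The SE is the first-order delta-method value sigma_Y / |beta_X|;
    P is two-sided normal. beta_X = 0 is undefined and rejected.
    """
    bx = float(instrument["beta_x"])
    if bx == 0.0 or not np.isfinite(bx):
        raise ValueError("Wald ratio undefined for beta_X = 0")
    theta = float(instrument["beta_y"]) / bx
    se = float(instrument["se_y"]) / abs(bx)
    p = 2.0 * stats.norm.sf(abs(theta / se)) if se > 0 else np.nan
    return MREstimate(analyte=str(instrument.get("analyte", "")),
                      method="wald", theta=theta, se=se, p=p, m=1,
                      mse=0.0, alpha=1.0)


def _weighted_median_point(theta_j: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta_j)
    th = theta_j[order]
    wn = w[order] / w.sum()
    s = np.cumsum(wn) - 0.5 * wn
    k = int(np.searchsorted(s, 0.5))
    if k == 0:
        return float(th[0])
    if k >= len(th):
        return float(th[-1])
    return float(th[k - 1] + (th[k] - th[k - 1])
                 * (0.5 - s[k - 1]) / (s[k] - s[k - 1]))


def weighted_median(instruments: InstrumentSet,
                    config: MRConfig = MRConfig()) -> MREstimate:
    """Weighted median of per-instrument ratio estimates.

    Weights are inverse variances of the ratios (sigma_Y^2 / beta_X^2,
    first order); the 50% weighted quantile is linearly interpolated, so up
    to half the weight may come from invalid instruments without moving the
    estimate arbitrarily. The SE is a parametric bootstrap
    (``config.wm_bootstrap`` resamples of beta_X and beta_Y from their
    reported normal sampling distributions, seeded by ``config.wm_seed``);
    P is two-sided normal.
    """
    m = instruments.m
    if m < 3:
        raise ValueError("weighted median needs at least 3 instruments")
    bx = instruments.table["beta_x"].to_numpy(dtype=float)
    by = instruments.table["beta_y"].to_numpy(dtype=float)
    sx = instruments.table["se_x"].to_numpy(dtype=float)
    sy = instruments.table["se_y"].to_numpy(dtype=float)
    theta_j = by / bx
    w = bx**2 / sy**2
    theta = _weighted_median_point(theta_j, w)
    rng = np.random.default_rng(config.wm_seed)
    boots = np.empty(config.wm_bootstrap)
    for b in range(config.wm_bootstrap):
        bxs = bx + sx * rng.standard_normal(m)
        bys = by + sy * rng.standard_normal(m)
        bxs[bxs == 0] = 1e-12
        boots[b] = _weighted_median_point(bys / bxs, bxs**2 / sy**2)
    se = float(boots.std(ddof=1))
    p = 2.0 * stats.norm.sf(abs(theta / se)) if se > 0 else np.nan
    return MREstimate(analyte=instruments.analyte, method="weighted_median",
                      theta=theta, se=se, p=p, m=m)


def mr_egger(instruments: InstrumentSet,
             config: MRConfig = MRConfig()) -> MREstimate:
    """MR-Egger regression: weighted regression of beta_Y on beta_X with an
    intercept measuring directional pleiotropy.

    Instruments are oriented so beta_X >= 0 (the standard Egger
    convention), weights are 1 / sigma_Y^2, and inference is classical WLS
    with the residual scale estimated on M - 2 degrees of freedom, so the
    intercept P (t, M - 2 df) is exactly calibrated under no pleiotropy.
    All-equal beta_X leaves the slope unidentifiable and is rejected.
    """
    m = instruments.m
    if m < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    bx = instruments.table["beta_x"].to_numpy(dtype=float).copy()
    by = instruments.table["beta_y"].to_numpy(dtype=float).copy()
    sy = instruments.table["se_y"].to_numpy(dtype=float)
    flip = bx < 0
    bx[flip] *= -1.0
    by[flip] *= -1.0
    if np.ptp(bx) == 0:
        raise ValueError("all beta_X equal: Egger slope unidentifiable")
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(m), bx])
    WX = X * w[:, None]
    xtx = X.T @ WX
    coef = np.linalg.solve(xtx, WX.T @ by)
    resid = by - X @ coef
    s2 = float(resid @ (resid * w)) / (m - 2)
    cov = s2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    tvals = coef / se
    p_slope = 2.0 * stats.t.sf(abs(tvals[1]), m - 2)
    p_int = 2.0 * stats.t.sf(abs(tvals[0]), m - 2)
    return MREstimate(analyte=instruments.analyte, method="egger",
                      theta=float(coef[1]), se=float(se[1]), p=float(p_slope),
                      m=m, egger_intercept=float(coef[0]),
                      egger_intercept_p=float(p_int))


# --------------------------------------------------------------------------
# multiple testing and the sensitivity gate
# --------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("P-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def sensitivity_gate(gwls: MREstimate, wm: MREstimate | None,
                     egger: MREstimate | None,
                     config: MRConfig = MRConfig()) -> MREstimate:
    """Two-step sensitivity gate applied to a FDR-significant GWLS estimate.

    not_tested if the GWLS FDR is at or above the level (or too few
    instruments to run the sensitivity estimators); failed_step1 if the
    weighted median disagrees in sign or has P >= 0.05; failed_step2 if the
    Egger slope disagrees in sign or the Egger intercept P <= 0.05;
    causal_candidate otherwise. A missing sensitivity estimate where M
    permits one is a pipeline ordering bug and is rejected.
    """
    if gwls.fdr is None:
        raise ValueError("gwls estimate must carry a BH-adjusted FDR")
    for other in (wm, egger):
        if other is not None and other.analyte != gwls.analyte:
            raise ValueError("sensitivity estimates refer to another analyte")
    if gwls.fdr >= config.fdr_level:
        return replace(gwls, gate="not_tested")
    if gwls.m < 3:
        if wm is not None or egger is not None:
            raise ValueError("sensitivity estimates present despite M < 3")
        return replace(gwls, gate="not_tested", note="sensitivity_untestable")
    if wm is None or egger is None:
        raise ValueError("missing sensitivity estimate despite M >= 3")
    if np.sign(wm.theta) != np.sign(gwls.theta) or not wm.p < 0.05:
        return replace(gwls, gate="failed_step1")
    if np.sign(egger.theta) != np.sign(gwls.theta) \
            or not egger.egger_intercept_p > 0.05:
        return replace(gwls, gate="failed_step2")
    return replace(gwls, gate="causal_candidate")


def mr_all_methods(instruments: InstrumentSet,
                   config: MRConfig = MRConfig()) -> dict[str, MREstimate | None]:
    """GWLS plus sensitivity estimators for one harmonized instrument set.

    Returns ``{"gwls": ..., "weighted_median": ..., "egger": ...}`` with the
    sensitivity entries None when M < 3 (single- and two-instrument sets
    cannot support them).
    """
    out: dict[str, MREstimate | None] = {
        "gwls": gwls_estimate(instruments, config),
        "weighted_median": None, "egger": None}
    if instruments.m >= 3:
        out["weighted_median"] = weighted_median(instruments, config)
        try:
            out["egger"] = mr_egger(instruments, config)
        except ValueError:
            out["egger"] = None
    return out
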