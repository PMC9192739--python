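"""Synthetic two-sample proteogenomic cohort generator.

Generates LD-structured genotypes, genetically regulated correlated serum
proteins, and a staged binary disease under a known causal model, so that
every downstream stage of the pipeline (association screen, pQTL scan,
predictor selection, Mendelian randomization) has a parameter-recovery
test against recorded ground truth.

Model
-----
* Genotypes: per LD block, a latent multivariate Gaussian is thresholded at
  the MAF-determined quantile once per haplotype and the two haplotypes are
  summed, which preserves Hardy-Weinberg proportions while controlling the
  signed dosage correlation within the block. Blocks are mutually
  independent.
* Proteins: each analyte is a sum of per-allele genetic effects (in SD
  units), a coregulation-module latent factor, an optional shared
  confounder loading, and independent Gaussian noise, with the noise
  variance chosen so the analyte has (theoretical) unit variance.
* Disease: a logistic model on protein levels, direct (pleiotropic) variant
  effects, the confounder, and age/sex. Staged severity labels are assigned
  among cases by configurable multinomial proportions; a follow-up visit
  supplies progression labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import linear_scan, logistic_scan

__all__ = [
    "LDBlock",
    "SimulationConfig",
    "GenotypeMatrix",
    "ProteinMatrix",
    "TrueParams",
    "SimulatedCohort",
    "SimulatedStudy",
    "simulate_genotypes",
    "simulate_proteins",
    "simulate_outcome",
    "simulate_cohorts",
    "compute_summary_stats",
    "binary_outcome",
    "OUTCOME_NAMES",
]

# logit-probit scaling constant (16*sqrt(3)/(15*pi))**2, used to keep the
# marginal case fraction at its target when the linear predictor carries
# random terms
_C2 = (16.0 * np.sqrt(3.0) / (15.0 * np.pi)) ** 2


# --------------------------------------------------------------------------
# configuration and containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LDBlock:
    """One linkage-disequilibrium block of variants.

    ``r`` is the target signed pairwise *dosage* correlation within the
    block (exchangeable); MAFs are drawn uniformly from ``maf_range``.
    """

    n_variants: int
    r: float = 0.0
    maf_range: tuple[float, float] = (0.1, 0.5)
    chrom: int | None = None

    def __post_init__(self):
        if self.n_variants < 1:
            raise ValueError("block needs at least one variant")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("MAFs must lie in (0, 1)")
        if not abs(self.r) < 1.0:
            raise ValueError("target |r| must be < 1")


@dataclass
class SimulationConfig:
    """Full specification of one simulated two-sample study.

    The seed fully determines all outputs; the exposure and outcome samples
    share the variant map (MAFs, LD structure) but no individuals.
    """

    n_exposure: int = 5000
    n_outcome: int = 5000
    blocks: Sequence[LDBlock] = field(default_factory=lambda: [LDBlock(10, 0.5, (0.2, 0.4))])
    n_proteins: int = 20
    n_modules: int = 2
    module_r: float = 0.3
    cis_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    trans_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    causal_thetas: Mapping[str, float] = field(default_factory=dict)
    direct_snp_effects: Mapping[str, float] = field(default_factory=dict)
    confounder_protein_loadings: Mapping[str, float] = field(default_factory=dict)
    confounder_disease_effect: float = 0.0
    baseline_prevalence: float = 0.05
    age_effect: float = 0.05       # log-odds per year (centered)
    sex_effect: float = 0.1        # log-odds, female vs male (centered)
    age_mean: float = 76.6
    age_sd: float = 5.6
    age_range: tuple[float, float] = (67.0, 96.0)
    female_fraction: float = 0.573
    # staged-severity proportions among cases (early : late echoes 1755:272;
    # late splits into GA-pure / nAMD-without-GA / GA-plus-nAMD 112:89:71)
    stage_weights: tuple[float, float] = (1755.0, 272.0)
    early_b_fraction: float = 1054.0 / 1755.0
    late_subtype_weights: tuple[float, float, float] = (112.0, 89.0, 71.0)
    followup_fraction: float = 0.592
    progression_rate: float = 0.13
    progression_effects: Mapping[str, float] = field(default_factory=dict)
    progression_subtype_ga: float = 0.5
    emit_raw: bool = False         # emit log-normal raw-scale proteins
    seed: int = 0

    def __post_init__(self):
        if self.n_exposure < 2 or self.n_outcome < 2:
            raise ValueError("need at least two subjects per sample")
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if not 0.0 <= self.module_r < 1.0:
            raise ValueError("module correlation must lie in [0, 1)")
        if self.n_modules < 1 or self.n_proteins < 1:
            raise ValueError("need at least one protein and one module")
        vids = set(self._variant_ids())
        pids = set(self.protein_ids())
        for name, mapping in (("cis_effects", self.cis_effects),
                              ("trans_effects", self.trans_effects)):
            for pid, eff in mapping.items():
                if pid not in pids:
                    raise ValueError(f"{name}: unknown protein {pid!r}")
                for vid in eff:
                    if vid not in vids:
                        raise ValueError(f"{name}: unknown variant {vid!r}")
        for pid in list(self.causal_thetas) + list(self.confounder_protein_loadings) \
                + list(self.progression_effects):
            if pid not in pids:
                raise ValueError(f"unknown protein {pid!r}")
        for vid in self.direct_snp_effects:
            if vid not in vids:
                raise ValueError(f"direct_snp_effects: unknown variant {vid!r}")

    def _variant_ids(self) -> list[str]:
        return [f"b{bi}v{vi}" for bi, blk in enumerate(self.blocks)
                for vi in range(blk.n_variants)]

    def protein_ids(self) -> list[str]:
        return [f"P{i:04d}" for i in range(self.n_proteins)]


@dataclass
class GenotypeMatrix:
    """Samples x variants allele-dosage table with variant metadata.

    ``dosages`` holds counts of the effect allele in {0, 1, 2};
    ``variants`` is indexed by variant id with columns
    ``chrom, pos, ea, oa, maf``.
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self):
        if not self.variants.index.is_unique:
            raise ValueError("variant identifiers must be unique")
        vals = self.dosages.to_numpy()
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 2:
            raise ValueError("dosages must lie in [0, 2]")
        for _, grp in self.variants.groupby("chrom"):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("positions must increase within a chromosome")


@dataclass
class ProteinMatrix:
    """Samples x analytes abundance table with analyte->gene annotation.

    ``annotation`` is indexed by analyte id with columns
    ``gene, chrom, start, end`` (and ``module`` when simulated).
    ``state`` records the transform stage (``raw`` or ``transformed``).
    ``confounder`` and ``standardized`` (simulation only) carry the shared
    latent per sample and, for raw-scale emission, the underlying
    standardized levels the disease model acts on.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame
    state: str = "raw"
    confounder: np.ndarray | None = None
    standardized: pd.DataFrame | None = None

    def __post_init__(self):
        if not self.values.columns.is_unique:
            raise ValueError("analyte ids must be unique")
        missing = set(self.values.columns) - set(self.annotation.index)
        if missing:
            raise ValueError(f"analytes without annotation: {sorted(missing)[:5]}")


@dataclass(frozen=True)
class TrueParams:
    """Immutable record of every effect realized in one simulation run."""

    maf: pd.Series
    cis_betas: dict
    trans_betas: dict
    thetas: dict
    direct_effects: dict
    confounder_loadings: dict
    confounder_disease_effect: float
    disease_intercept: float


@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix
    proteins: ProteinMatrix
    phenotypes: pd.DataFrame


@dataclass
class SimulatedStudy:
    exposure: SimulatedCohort
    outcome: SimulatedCohort
    params: TrueParams


# --------------------------------------------------------------------------
# LD machinery
# --------------------------------------------------------------------------

def _allele_corr_bounds(p1: float, p2: float) -> tuple[float, float]:
    """Frechet bounds on the correlation of two Bernoulli alleles."""
    denom = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    hi = (min(p1, p2) - p1 * p2) / denom
    lo = (max(0.0, p1 + p2 - 1.0) - p1 * p2) / denom
    return lo, hi


def _bvn_cdf(t1: float, t2: float, rho: float) -> float:
    return float(stats.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]).cdf([t1, t2]))


def _latent_corr(p1: float, p2: float, target: float) -> float:
    """Latent-Gaussian correlation producing allele (= dosage) correlation
    ``target`` after thresholding at the MAF quantiles."""
    if target == 0.0:
        return 0.0
    lo, hi = _allele_corr_bounds(p1, p2)
    if not lo + 1e-9 < target < hi - 1e-9:
        raise ValueError(
            f"target dosage correlation {target:.3f} infeasible for MAFs "
            f"({p1:.3f}, {p2:.3f}); attainable range is ({lo:.3f}, {hi:.3f})")
    t1, t2 = stats.norm.ppf(p1), stats.norm.ppf(p2)
    denom = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))

    def f(rho):
        return (_bvn_cdf(t1, t2, rho) - p1 * p2) / denom - target

    from scipy.optimize import brentq
    return float(brentq(f, -0.9999, 0.9999, xtol=1e-10))


def _nearest_corr(L: np.ndarray) -> np.ndarray:
    """Clip eigenvalues to keep the latent matrix positive definite."""
    w, V = np.linalg.eigh(L)
    if w.min() > 1e-8:
        return L
    w = np.clip(w, 1e-8, None)
    L2 = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(L2))
    return L2 / np.outer(d, d)


@dataclass(frozen=True)
class _VariantMap:
    """Deterministic variant metadata shared by both samples."""

    variants: pd.DataFrame        # chrom pos ea oa maf block
    latent_chol: list[np.ndarray]
    thresholds: list[np.ndarray]


def _build_variant_map(config: SimulationConfig, rng: np.random.Generator) -> _VariantMap:
    rows, chols, thrs = [], [], []
    for bi, blk in enumerate(config.blocks):
        chrom = blk.chrom if blk.chrom is not None else bi + 1
        lo, hi = blk.maf_range
        mafs = rng.uniform(lo, hi, size=blk.n_variants)
        m = blk.n_variants
        L = np.eye(m)
        for i in range(m):
            for j in range(i + 1, m):
                L[i, j] = L[j, i] = _latent_corr(mafs[i], mafs[j], blk.r)
        L = _nearest_corr(L)
        chols.append(np.linalg.cholesky(L))
        thrs.append(stats.norm.ppf(mafs))
        for vi in range(m):
            rows.append({"variant": f"b{bi}v{vi}", "chrom": chrom,
                         "pos": 1_000_000 + 20_000 * vi, "ea": "A", "oa": "G",
                         "maf": mafs[vi], "block": bi})
    variants = pd.DataFrame(rows).set_index("variant")
    return _VariantMap(variants, chols, thrs)


def _sample_genotypes(vmap: _VariantMap, config: SimulationConfig, n: int,
                      rng: np.random.Generator) -> GenotypeMatrix:
    cols = []
    for chol, thr in zip(vmap.latent_chol, vmap.thresholds):
        m = chol.shape[0]
        z = rng.standard_normal((2, n, m)) @ chol.T
        dosage = (z < thr).sum(axis=0).astype(float)
        cols.append(dosage)
    dosages = pd.DataFrame(np.hstack(cols), columns=vmap.variants.index,
                           index=[f"s{i}" for i in range(n)])
    return GenotypeMatrix(dosages, vmap.variants.copy())


def simulate_genotypes(config: SimulationConfig, n: int,
                       seed: int | None = None) -> GenotypeMatrix:
    """Draw ``n`` subjects' dosages under the configured LD-block model.

    Within-block signed dosage correlation approximates each block's target,
    across-block correlation is zero by construction, and genotype class
    frequencies follow Hardy-Weinberg at the drawn MAF (the two haplotypes
    are thresholded independently). An infeasible target correlation for the
    drawn MAFs raises ``ValueError`` with the attainable range.
    """
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    c_map, c_draw = ss.spawn(2)
    vmap = _build_variant_map(config, np.random.default_rng(c_map))
    return _sample_genotypes(vmap, config, n, np.random.default_rng(c_draw))


# --------------------------------------------------------------------------
# proteins
# --------------------------------------------------------------------------

def _theoretical_dosage_cov(vmap_variants: pd.DataFrame, config: SimulationConfig,
                            vids: list[str]) -> np.ndarray:
    """Target covariance of the selected dosages (used for the variance
    budget, not for sampling)."""
    sub = vmap_variants.loc[vids]
    k = len(vids)
    cov = np.zeros((k, k))
    for i in range(k):
        pi = sub["maf"].iloc[i]
        cov[i, i] = 2 * pi * (1 - pi)
        for j in range(i + 1, k):
            pj = sub["maf"].iloc[j]
            if sub["block"].iloc[i] == sub["block"].iloc[j]:
                r = config.blocks[int(sub["block"].iloc[i])].r
                cov[i, j] = cov[j, i] = 2 * r * np.sqrt(
                    pi * (1 - pi) * pj * (1 - pj))
    return cov


def simulate_proteins(genotypes: GenotypeMatrix, config: SimulationConfig,
                      seed: int | None = None) -> ProteinMatrix:
    """Generate analyte levels from the configured genetic architecture.

    Each protein is a sum of per-allele genetic effects (SD units), its
    module latent factor (loading sqrt(module_r)), an optional confounder
    loading, and independent noise scaled so the theoretical variance is 1.
    Raises ``ValueError`` when the configured variance shares exceed 1.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = len(genotypes.dosages)
    pids = config.protein_ids()
    modules = {pid: i % config.n_modules for i, pid in enumerate(pids)}
    factors = rng.standard_normal((n, config.n_modules))
    confounder = rng.standard_normal(n)
    G = genotypes.dosages.to_numpy()
    vindex = {v: i for i, v in enumerate(genotypes.dosages.columns)}
    maf = genotypes.variants["maf"]
    Gc = G - 2.0 * maf.to_numpy()[None, :]

    X = np.empty((n, len(pids)))
    load_mod = np.sqrt(config.module_r)
    for k, pid in enumerate(pids):
        effects: dict[str, float] = {}
        effects.update(config.cis_effects.get(pid, {}))
        for v, b in config.trans_effects.get(pid, {}).items():
            effects[v] = effects.get(v, 0.0) + b
        var_gen = 0.0
        genetic = np.zeros(n)
        if effects:
            vids = list(effects)
            betas = np.array([effects[v] for v in vids])
            cov = _theoretical_dosage_cov(genotypes.variants, config, vids)
            var_gen = float(betas @ cov @ betas)
            genetic = Gc[:, [vindex[v] for v in vids]] @ betas
        c_load = config.confounder_protein_loadings.get(pid, 0.0)
        var_noise = 1.0 - var_gen - config.module_r - c_load**2
        if var_noise < 0:
            raise ValueError(
                f"protein {pid}: configured variance shares sum to "
                f"{1 - var_noise:.3f} > 1")
        X[:, k] = (genetic + load_mod * factors[:, modules[pid]]
                   + c_load * confounder
                   + np.sqrt(var_noise) * rng.standard_normal(n))

    ann_rows = []
    far_pos = 500_000_000
    for k, pid in enumerate(pids):
        cis = config.cis_effects.get(pid, {})
        if cis:
            v0 = next(iter(cis))
            vrow = genotypes.variants.loc[v0]
            chrom, start = int(vrow["chrom"]), int(vrow["pos"]) - 25_000
            end = int(vrow["pos"]) + 25_000
        else:
            chrom, start, end = 1, far_pos + 100_000 * k, far_pos + 100_000 * k + 20_000
        ann_rows.append({"analyte": pid, "gene": f"G{k}", "chrom": chrom,
                         "start": max(start, 1), "end": end,
                         "module": modules[pid]})
    annotation = pd.DataFrame(ann_rows).set_index("analyte")

    std = pd.DataFrame(X, index=genotypes.dosages.index, columns=pids)
    if config.emit_raw:
        raw = np.exp(0.5 * X + 2.0)  # log-normal raw-scale intensities
        values = pd.DataFrame(raw, index=std.index, columns=pids)
        return ProteinMatrix(values, annotation, state="raw",
                             confounder=confounder, standardized=std)
    return ProteinMatrix(std, annotation, state="transformed",
                         confounder=confounder)


# --------------------------------------------------------------------------
# phenotypes / outcome
# --------------------------------------------------------------------------

def _phenotype_base(config: SimulationConfig, n: int,
                    rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = config.age_range
    a, b = (lo - config.age_mean) / config.age_sd, (hi - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                              size=n, random_state=rng)
    sex = (rng.random(n) < config.female_fraction).astype(int)
    return pd.DataFrame({"age": age, "sex": sex},
                        index=[f"s{i}" for i in range(n)])


def simulate_outcome(proteins: ProteinMatrix, genotypes: GenotypeMatrix,
                     phen_base: pd.DataFrame, config: SimulationConfig,
                     seed: int | None = None) -> pd.DataFrame:
    """Draw the staged binary disease from the configured logistic model.

    logit P(case) = intercept + sum(theta_p * protein_p)
                  + sum(direct variant effects) + confounder + age/sex terms.

    The intercept is calibrated (logit-probit approximation) so the marginal
    case fraction matches ``baseline_prevalence`` despite the random terms.
    Stage and subtype labels are assigned among cases by the configured
    multinomial proportions; a follow-up stage is drawn for the re-examined
    subset, with progression among baseline-early subjects optionally driven
    by configured protein effects.
    """
    if proteins.state == "raw":
        if proteins.standardized is None:
            raise ValueError("simulate_outcome needs standardized protein levels")
        levels = proteins.standardized
    else:
        levels = proteins.values
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    n = len(phen_base)
    lp = np.zeros(n)
    for pid, theta in config.causal_thetas.items():
        lp += theta * levels[pid].to_numpy()
    maf = genotypes.variants["maf"]
    for vid, d in config.direct_snp_effects.items():
        lp += d * (genotypes.dosages[vid].to_numpy() - 2.0 * maf[vid])
    if config.confounder_disease_effect and proteins.confounder is not None:
        lp += config.confounder_disease_effect * proteins.confounder
    lp += config.age_effect * (phen_base["age"].to_numpy() - phen_base["age"].mean())
    lp += config.sex_effect * (phen_base["sex"].to_numpy() - phen_base["sex"].mean())

    v_extra = float(np.var(lp))
    intercept = float(stats.logistic.ppf(config.baseline_prevalence)
                      * np.sqrt(1.0 + _C2 * v_extra))
    prob = 1.0 / (1.0 + np.exp(-(intercept + lp)))
    case = rng.random(n) < prob

    stage = np.full(n, "none", dtype=object)
    early_b = np.zeros(n, dtype=bool)
    subtype = np.full(n, "none", dtype=object)
    idx_cases = np.flatnonzero(case)
    w_early, w_late = config.stage_weights
    is_late = rng.random(len(idx_cases)) < w_late / (w_early + w_late)
    stage[idx_cases[~is_late]] = "early"
    stage[idx_cases[is_late]] = "late"
    early_idx = idx_cases[~is_late]
    early_b[early_idx[rng.random(len(early_idx)) < config.early_b_fraction]] = True
    late_idx = idx_cases[is_late]
    wt = np.asarray(config.late_subtype_weights, dtype=float)
    sub_draw = rng.choice(["GA_pure", "nAMD", "GA_plus_nAMD"], size=len(late_idx),
                          p=wt / wt.sum())
    subtype[late_idx] = sub_draw

    reexamined = rng.random(n) < config.followup_fraction
    followup = np.full(n, "", dtype=object)
    followup[reexamined] = stage[reexamined]
    prog_lp = np.full(n, stats.logistic.ppf(config.progression_rate))
    for pid, eff in config.progression_effects.items():
        prog_lp += eff * levels[pid].to_numpy()
    cand = reexamined & (stage == "early")
    progressed = cand & (rng.random(n) < 1.0 / (1.0 + np.exp(-prog_lp)))
    followup[progressed] = "late"
    followup_subtype = np.full(n, "none", dtype=object)
    followup_subtype[progressed] = np.where(
        rng.random(progressed.sum()) < config.progression_subtype_ga,
        "GA_pure", "nAMD")
    followup_subtype[reexamined & (stage == "late")] = subtype[reexamined & (stage == "late")]

    phen = phen_base.copy()
    phen["stage"] = stage
    phen["early_scheme_b"] = early_b
    phen["late_subtype"] = subtype
    phen["reexamined"] = reexamined
    phen["followup_stage"] = followup
    phen["followup_subtype"] = followup_subtype
    phen.attrs["disease_intercept"] = intercept
    return phen


OUTCOME_NAMES = ("amd_any", "amd_early_A", "amd_early_B", "amd_late",
                 "ga_pure", "namd", "progression_ga")


def binary_outcome(phen: pd.DataFrame, name: str) -> pd.Series:
    """Binary outcome vector for one staged definition; excluded subjects NaN.

    Controls are stage ``none`` subjects; early/late definitions exclude the
    other case stratum, mirroring case-vs-none contrasts. ``progression_ga``
    restricts to re-examined baseline-early (stricter scheme) subjects and
    codes progression to pure GA at follow-up.
    """
    stage = phen["stage"]
    out = pd.Series(np.nan, index=phen.index, name=name)
    if name == "amd_any":
        out[:] = (stage != "none").astype(float)
    elif name == "amd_early_A":
        out[stage == "none"] = 0.0
        out[stage == "early"] = 1.0
    elif name == "amd_early_B":
        out[stage == "none"] = 0.0
        out[(stage == "early") & phen["early_scheme_b"]] = 1.0
    elif name == "amd_late":
        out[stage == "none"] = 0.0
        out[stage == "late"] = 1.0
    elif name == "ga_pure":
        out[stage == "none"] = 0.0
        out[phen["late_subtype"] == "GA_pure"] = 1.0
    elif name == "namd":
        out[stage == "none"] = 0.0
        out[phen["late_subtype"].isin(["nAMD", "GA_plus_nAMD"])] = 1.0
    elif name == "progression_ga":
        cand = phen["reexamined"] & (stage == "early") & phen["early_scheme_b"]
        out[cand & (phen["followup_stage"] == "early")] = 0.0
        out[cand & (phen["followup_subtype"] == "GA_pure")] = 1.0
    else:
        raise ValueError(f"unknown outcome {name!r}; choose from {OUTCOME_NAMES}")
    return out


# --------------------------------------------------------------------------
# whole-study driver and summary statistics
# --------------------------------------------------------------------------

def simulate_cohorts(config: SimulationConfig) -> SimulatedStudy:
    """Generate the exposure and outcome samples of one two-sample study.

    The variant map (MAFs, LD) is drawn once; individuals, proteins and
    disease are drawn independently per sample. Identical configs (including
    the seed) give bit-identical output.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(7)
    rng_map = np.random.default_rng(seeds[0])
    vmap = _build_variant_map(config, rng_map)

    cohorts = []
    for n, s_geno, s_prot, s_phen in (
            (config.n_exposure, seeds[1], seeds[2], seeds[3]),
            (config.n_outcome, seeds[4], seeds[5], seeds[6])):
        rng_g = np.random.default_rng(s_geno)
        geno = _sample_genotypes(vmap, config, n, rng_g)
        prot = simulate_proteins(geno, config, seed=s_prot)
        rng_p = np.random.default_rng(s_phen)
        base = _phenotype_base(config, n, rng_p)
        phen = simulate_outcome(prot, geno, base, config,
                                seed=rng_p.integers(2**31))
        cohorts.append(SimulatedCohort(geno, prot, phen))

    params = TrueParams(
        maf=vmap.variants["maf"].copy(),
        cis_betas={p: dict(v) for p, v in config.cis_effects.items()},
        trans_betas={p: dict(v) for p, v in config.trans_effects.items()},
        thetas=dict(config.causal_thetas),
        direct_effects=dict(config.direct_snp_effects),
        confounder_loadings=dict(config.confounder_protein_loadings),
        confounder_disease_effect=config.confounder_disease_effect,
        disease_intercept=cohorts[1].phenotypes.attrs["disease_intercept"],
    )
    return SimulatedStudy(cohorts[0], cohorts[1], params)


def compute_summary_stats(genotypes: GenotypeMatrix, trait, covariates: pd.DataFrame
                          ) -> pd.DataFrame:
    """Per-variant additive-model association summary statistics.

    Continuous traits use linear regression (slope per effect allele);
    binary {0,1} traits use logistic regression, returning log-odds-ratio
    betas to match consortium GWAS scale. Columns:
    ``variant chrom pos ea oa beta se p n`` plus a ``flag`` column
    (``ok | monomorphic | non_converged``); monomorphic variants are
    flagged, not dropped. Deterministic given inputs.
    """
    if not isinstance(trait, pd.Series):
        trait = pd.Series(np.asarray(trait, dtype=float),
                          index=genotypes.dosages.index)
    df = pd.concat([trait.rename("_y"), covariates], axis=1)
    df = df.loc[genotypes.dosages.index]
    ids = df.index[df.notna().all(axis=1)]
    y = df.loc[ids, "_y"].to_numpy(dtype=float)
    G = genotypes.dosages.loc[ids].to_numpy(dtype=float)
    Cmat = np.column_stack([np.ones(len(ids)),
                            df.loc[ids, list(covariates.columns)].to_numpy(dtype=float)])

    binary = set(np.unique(y)) <= {0.0, 1.0}
    if binary:
        beta, se, p, mono, conv = logistic_scan(G, y, Cmat)
        flag = np.where(mono, "monomorphic",
                        np.where(conv, "ok", "non_converged"))
    else:
        beta, se, p, mono = linear_scan(G, y, Cmat)
        flag = np.where(mono, "monomorphic", "ok")

    meta = genotypes.variants
    return pd.DataFrame({
        "variant": meta.index, "chrom": meta["chrom"].to_numpy(),
        "pos": meta["pos"].to_numpy(), "ea": meta["ea"].to_numpy(),
        "oa": meta["oa"].to_numpy(), "beta": beta, "se": se, "p": p,
        "n": len(y), "flag": flag,
    }).set_index("variant")
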