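"""Per-variant additive-model pQTL scan with cis/trans labeling.

Associates every genotype dosage with every protein analyte by sex/age-
adjusted linear regression, labels each record cis or trans by position
relative to the analyte's encoding gene (gene body plus a +-500 kb window,
closed interval, 1-based coordinates), and exports exposure summary
statistics per analyte for the Mendelian randomization engine.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._glm import linear_scan
from .simulate import GenotypeMatrix, ProteinMatrix

__all__ = ["CIS_WINDOW", "classify_cis_trans", "snp_protein_scan",
           "exposure_stats"]

CIS_WINDOW = 500_000  # halfwidth around the gene body, bp


def classify_cis_trans(variant: pd.Series, gene: pd.Series,
                       window_halfwidth: int = CIS_WINDOW) -> str:
    """Label a variant cis or trans relative to a gene locus.

    cis iff the variant is on the gene's chromosome with position inside
    ``[start - halfwidth, end + halfwidth]`` (closed interval); anything
    else, including another chromosome, is trans. Missing gene coordinates
    give ``undetermined``.
    """
    if pd.isna(gene.get("chrom")) or pd.isna(gene.get("start")) or pd.isna(gene.get("end")):
        return "undetermined"
    if variant["chrom"] != gene["chrom"]:
        return "trans"
    lo = gene["start"] - window_halfwidth
    hi = gene["end"] + window_halfwidth
    return "cis" if lo <= variant["pos"] <= hi else "trans"


def snp_protein_scan(genotypes: GenotypeMatrix, proteins: ProteinMatrix,
                     covariates: pd.DataFrame,
                     p_threshold: float = 1e-6) -> pd.DataFrame:
    """Additive-model linear regression of every variant on every analyte.

    Returns one record per variant x analyte with summary-statistic fields
    (``beta se p n``), the cis/trans label, and ``reportable`` set where the
    P-value falls below ``p_threshold``. Monomorphic variants are flagged
    and skipped (NaN estimates). Missing protein values are dropped
    case-wise per analyte; the scan is deterministic and invariant to
    analyte ordering.
    """
    if proteins.state != "transformed":
        raise ValueError("snp_protein_scan expects transformed protein data")
    shared = genotypes.dosages.index.intersection(proteins.values.index)
    if len(shared) == 0:
        raise ValueError("no shared sample ids between genotypes and proteins")
    G_all = genotypes.dosages.loc[shared]
    cov = covariates.loc[shared]
    meta = genotypes.variants

    frames = []
    for aid in proteins.values.columns:
        x = proteins.values.loc[shared, aid]
        obs = x.notna() & cov.notna().all(axis=1)
        y = x[obs].to_numpy(dtype=float)
        G = G_all.loc[obs.index[obs]].to_numpy(dtype=float)
        C = np.column_stack([np.ones(len(y)),
                             cov.loc[obs.index[obs]].to_numpy(dtype=float)])
        beta, se, p, mono = linear_scan(G, y, C)
        gene = proteins.annotation.loc[aid]
        labels = [classify_cis_trans(meta.loc[v], gene) for v in meta.index]
        frames.append(pd.DataFrame({
            "analyte": aid, "variant": meta.index,
            "chrom": meta["chrom"].to_numpy(), "pos": meta["pos"].to_numpy(),
            "ea": meta["ea"].to_numpy(), "oa": meta["oa"].to_numpy(),
            "beta": beta, "se": se, "p": p, "n": len(y),
            "regulatory": labels,
            "flag": np.where(mono, "monomorphic", "ok"),
            "reportable": np.where(np.isfinite(p), p < p_threshold, False),
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["analyte", "chrom", "pos"], kind="stable") \
              .reset_index(drop=True)


def exposure_stats(scan: pd.DataFrame, analyte: str) -> pd.DataFrame:
    """Exposure summary statistics for one analyte, MR-engine layout
    (``variant chrom pos ea oa beta se p n`` indexed by variant)."""
    sub = scan[scan["analyte"] == analyte]
    if sub.empty:
        raise KeyError(f"analyte {analyte!r} not present in scan")
    return sub[["variant", "chrom", "pos", "ea", "oa", "beta", "se", "p", "n"]] \
        .set_index("variant")
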