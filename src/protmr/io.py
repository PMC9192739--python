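"""Plain-text readers and writers for the pipeline's tables.

Everything is tab-separated text: dosage matrices (plus an optional
minimal VCF rendering), protein matrices with their analyte annotation,
phenotype tables, and per-variant summary statistics with the fixed header
``variant chrom pos ea oa beta se p n``. Ground-truth parameters are
written as a flat key-value file.
"""

from __future__ import annotations

import dataclasses
import json

import pandas as pd
import yaml

from .simulate import GenotypeMatrix, ProteinMatrix, SimulationConfig, LDBlock, TrueParams

__all__ = [
    "write_summary_stats", "read_summary_stats",
    "write_genotypes", "read_genotypes", "write_vcf",
    "write_proteins", "read_proteins",
    "write_phenotypes", "read_phenotypes",
    "write_true_params", "load_run_config",
]

SUMMARY_COLUMNS = ["variant", "chrom", "pos", "ea", "oa", "beta", "se", "p", "n"]


def write_summary_stats(stats: pd.DataFrame, path) -> None:
    df = stats.reset_index() if stats.index.name == "variant" else stats.copy()
    df[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_summary_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"summary-statistics file lacks columns {sorted(missing)}")
    return df.set_index("variant")


def write_genotypes(geno: GenotypeMatrix, dosage_path, variant_path) -> None:
    geno.dosages.to_csv(dosage_path, sep="\t", index_label="sample")
    geno.variants.to_csv(variant_path, sep="\t", index_label="variant")


def read_genotypes(dosage_path, variant_path) -> GenotypeMatrix:
    dosages = pd.read_csv(dosage_path, sep="\t", index_col="sample")
    variants = pd.read_csv(variant_path, sep="\t", index_col="variant")
    return GenotypeMatrix(dosages, variants)


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Minimal unphased diploid VCF (GT only) for hard-call dosages."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    samples = list(geno.dosages.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for vid, row in geno.variants.iterrows():
            calls = [gt_map[int(round(d))] for d in geno.dosages[vid]]
            # the counted (effect) allele is written as ALT
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{vid}\t{row['oa']}\t"
                     f"{row['ea']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


def write_proteins(prot: ProteinMatrix, values_path, annotation_path) -> None:
    prot.values.to_csv(values_path, sep="\t", index_label="sample")
    prot.annotation.to_csv(annotation_path, sep="\t", index_label="analyte")


def read_proteins(values_path, annotation_path,
                  state: str = "raw") -> ProteinMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="sample")
    annotation = pd.read_csv(annotation_path, sep="\t", index_col="analyte")
    return ProteinMatrix(values, annotation, state=state)


def write_phenotypes(phen: pd.DataFrame, path) -> None:
    phen.to_csv(path, sep="\t", index_label="sample")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


def write_true_params(params: TrueParams, path) -> None:
    """Flat key-value rendering of the realized simulation ground truth."""
    with open(path, "w") as fh:
        for f in dataclasses.fields(params):
            val = getattr(params, f.name)
            if isinstance(val, pd.Series):
                for k, v in val.items():
                    fh.write(f"{f.name}.{k}\t{v}\n")
            elif isinstance(val, dict):
                fh.write(f"{f.name}\t{json.dumps(val)}\n")
            else:
                fh.write(f"{f.name}\t{val}\n")


def load_run_config(path) -> SimulationConfig:
    """Build a SimulationConfig from a YAML run-configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    blocks = [LDBlock(n_variants=b["n_variants"], r=b.get("r", 0.0),
                      maf_range=tuple(b.get("maf_range", (0.1, 0.5))),
                      chrom=b.get("chrom"))
              for b in raw.pop("blocks", [])]
    if blocks:
        raw["blocks"] = blocks
    for key in ("maf_range", "stage_weights", "late_subtype_weights", "age_range"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return SimulationConfig(**raw)
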