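"""Readers and writers for the pipeline's plain-text formats.

Dialects:

* protein TSV — rows = samples, first column ``sample_id``, one column per
  protein, empty cell = missing;
* phenotype TSV — ``sample_id``, age, sex, outcome and survival columns;
* genotype TSV — rows = variants with id/chrom/pos/effect_allele/
  other_allele followed by one dosage column per sample;
* minimal VCF 4.2 — biallelic sites with a GT FORMAT field;
* GWAS summary statistics TSV — CHR, POS, ID, EA, OA, EAF, BETA, SE, P, N;
* MR instrument TSV — SNP, EA, OA, beta_exp, se_exp, beta_out, se_out;
* truth/manifest JSON.

VCF reading uses cyvcf2 when installed and falls back to a small text
parser for plain (uncompressed) VCFs otherwise; both paths apply the same
policy: multiallelic records are skipped with a warning, missing genotypes
are mean-imputed per variant with a logged count, and variants with more
than 10% missing genotypes are dropped (consistent with the protein-side
QC threshold).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .synthgen import Cohort, GenotypeMatrix, Truth

__all__ = [
    "write_protein_tsv", "read_protein_tsv",
    "write_phenotype_tsv", "read_phenotype_tsv",
    "write_cohort", "read_cohort",
    "write_genotype_tsv", "write_vcf", "read_genotypes",
    "write_truth_json", "write_sumstats_tsv",
]

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


def write_protein_tsv(cohort: Cohort, path: str | Path) -> None:
    cohort.proteins.to_csv(path, sep="\t", na_rep="", float_format=FLOAT_FMT)


def read_protein_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    df.columns.name = "protein_id"
    return df


def write_phenotype_tsv(cohort: Cohort, path: str | Path) -> None:
    cohort.phenotypes.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_phenotype_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_cohort(cohort: Cohort, outdir: str | Path, prefix: str = "cohort") -> None:
    outdir = Path(outdir)
    write_protein_tsv(cohort, outdir / f"{prefix}_proteins.tsv")
    write_phenotype_tsv(cohort, outdir / f"{prefix}_phenotypes.tsv")


def read_cohort(proteins_path: str | Path, phenotypes_path: str | Path) -> Cohort:
    proteins = read_protein_tsv(proteins_path)
    phenotypes = read_phenotype_tsv(phenotypes_path)
    proteins = proteins.loc[phenotypes.index]
    return Cohort(phenotypes=phenotypes, proteins=proteins)


def write_genotype_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    meta = genotypes.variants.rename(
        columns={"chrom": "chrom", "pos": "pos"}
    )
    dosage = pd.DataFrame(
        genotypes.dosage.T, columns=genotypes.sample_ids,
        index=meta.index,
    )
    pd.concat([meta, dosage], axis=1).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def _read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["id", "chrom", "pos", "effect_allele", "other_allele"]
    meta = df[meta_cols].copy()
    meta["chrom"] = meta["chrom"].astype(str)
    sample_cols = [c for c in df.columns if c not in meta_cols]
    dosage = df[sample_cols].to_numpy(dtype=float).T
    return GenotypeMatrix(meta, dosage, pd.Index(sample_cols, name="sample_id"))


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Minimal biallelic VCF 4.2 with GT genotypes.

    Dosages are rounded to the nearest integer genotype; ALT is the effect
    allele so that the ALT count reproduces the dosage on re-reading.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(genotypes.sample_ids),
    ]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    for j, (_, row) in enumerate(genotypes.variants.iterrows()):
        counts = np.clip(np.rint(genotypes.dosage[:, j]), 0, 2).astype(int)
        gts = "\t".join(gt_map[c] for c in counts)
        lines.append(
            f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['other_allele']}\t"
            f"{row['effect_allele']}\t.\tPASS\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _vcf_records_cyvcf2(path: str):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for rec in vcf:
        if len(rec.ALT) != 1:
            logger.warning("VCF: skipping multiallelic record %s", rec.ID or rec.POS)
            continue
        gts = rec.genotypes  # [a0, a1, phased]
        counts = np.array(
            [a0 + a1 if a0 >= 0 and a1 >= 0 else -1 for a0, a1, *_ in gts],
            dtype=float,
        )
        yield (str(rec.CHROM), int(rec.POS), rec.ID or f"{rec.CHROM}:{rec.POS}",
               rec.REF, rec.ALT[0], counts), samples


def _vcf_records_text(path: str):
    samples = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 10 or fields[8:9] == []:
                    raise ValueError("malformed VCF header (no samples)")
                samples = fields[9:]
                continue
            if samples is None:
                raise ValueError("malformed VCF: data before #CHROM header")
            f = line.split("\t")
            chrom, pos, vid, ref, alt = f[0], int(f[1]), f[2], f[3], f[4]
            if "," in alt:
                logger.warning("VCF: skipping multiallelic record %s", vid)
                continue
            fmt = f[8].split(":")
            gt_idx = fmt.index("GT")
            counts = []
            for s in f[9:]:
                gt = s.split(":")[gt_idx].replace("|", "/")
                if "." in gt:
                    counts.append(-1.0)
                else:
                    counts.append(float(sum(int(a) for a in gt.split("/"))))
            yield (chrom, pos, vid, ref, alt, np.array(counts)), samples


def read_genotypes(
    path: str | Path, format: str | None = None, max_missing: float = 0.10
) -> GenotypeMatrix:
    """Load a genotype matrix from TSV or VCF.

    Dosage is the count of effect (ALT) alleles. Missing genotypes are
    mean-imputed per variant (count logged); variants with more than
    ``max_missing`` missing genotypes are dropped.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix == ".vcf" else "tsv"
    if format == "tsv":
        return _read_genotype_tsv(path)
    if format != "vcf":
        raise ValueError(f"unknown genotype format {format!r}")

    try:
        import cyvcf2  # noqa: F401

        records = _vcf_records_cyvcf2(str(path))
    except ImportError:
        records = _vcf_records_text(str(path))

    rows, dosages, samples = [], [], None
    n_imputed = 0
    try:
        parsed = list(records)
    except ValueError:
        raise
    except Exception as exc:  # cyvcf2 raises its own error types
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    for (chrom, pos, vid, ref, alt, counts), samp in parsed:
        samples = samp
        miss = counts < 0
        if miss.mean() > max_missing:
            logger.warning("VCF: dropping %s (%.0f%% missing genotypes)",
                           vid, 100 * miss.mean())
            continue
        if miss.any():
            n_imputed += int(miss.sum())
            counts = counts.copy()
            counts[miss] = counts[~miss].mean()
        rows.append(
            {"id": vid, "chrom": chrom, "pos": pos,
             "effect_allele": alt, "other_allele": ref}
        )
        dosages.append(counts)
    if n_imputed:
        logger.info("VCF: mean-imputed %d missing genotypes", n_imputed)
    if samples is None:
        raise ValueError("VCF contained no usable records")
    meta = pd.DataFrame(rows)
    return GenotypeMatrix(
        meta, np.array(dosages).T, pd.Index(samples, name="sample_id")
    )


def write_truth_json(truth: Truth, path: str | Path) -> None:
    payload = {
        "latent_bioage": truth.latent_bioage.tolist(),
        "age_slopes": truth.age_slopes.tolist(),
        "sex_effects": truth.sex_effects.tolist(),
        "baseline_means": truth.baseline_means.tolist(),
        "variant_effects": {
            str(v): {str(p): e for p, e in eff.items()}
            for v, eff in truth.variant_effects.items()
        },
        "mortality_loghr_per_year": truth.mortality_loghr_per_year,
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def read_carrier_sets_tsv(path: str | Path) -> dict[str, set[str]]:
    """Gene -> qualifying-variant carrier sets from a two-column TSV
    (gene, sample_id; one row per carrier)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "sample_id"} <= set(df.columns):
        raise ValueError("carrier TSV needs 'gene' and 'sample_id' columns")
    return {g: set(sub["sample_id"]) for g, sub in df.groupby("gene")}


def read_mr_tsv(path: str | Path) -> pd.DataFrame:
    """Instrument-level MR summary statistics
    (SNP, EA, OA, beta_exp, se_exp, beta_out, se_out)."""
    df = pd.read_csv(path, sep="\t")
    required = {"SNP", "EA", "OA", "beta_exp", "se_exp", "beta_out", "se_out"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"MR TSV lacks columns: {sorted(missing)}")
    return df


def write_sumstats_tsv(assoc: pd.DataFrame, path: str | Path) -> None:
    out = assoc.rename(
        columns={
            "chrom": "CHR", "pos": "POS", "id": "ID", "ea": "EA", "oa": "OA",
            "eaf": "EAF", "beta": "BETA", "se": "SE", "p": "P", "n": "N",
        }
    )[["CHR", "POS", "ID", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]]
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
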