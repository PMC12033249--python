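"""Protein-matrix QC and imputation.

Two steps, in a fixed order: drop samples with more than 10% of proteins
missing, then drop proteins with more than 10% missingness across the
*remaining* samples, then replace what is left with sex-specific means.
The thresholds are strict inequalities (a sample at exactly 10% is kept),
and the sample filter runs first — on edge cases reversing the order
changes which proteins survive, so the order is part of the contract.
"""

from __future__ import annotations

import logging

import pandas as pd

from .synthgen import Cohort

__all__ = ["qc_filter", "impute_missing", "EmptyCohortError", "ImputationError"]

logger = logging.getLogger(__name__)


class EmptyCohortError(ValueError):
    """All samples or all proteins were removed by QC."""


class ImputationError(ValueError):
    """A protein cannot be imputed within a sex stratum."""


def qc_filter(
    cohort: Cohort,
    max_sample_missing: float = 0.10,
    max_protein_missing: float = 0.10,
) -> Cohort:
    """Drop high-missingness samples, then high-missingness proteins.

    Sample missingness is the fraction of proteins missing for that sample;
    protein missingness is recomputed on the retained samples only. Both
    filters are strict: a fraction exactly at the threshold is retained.
    The returned cohort records the dropped sample and protein IDs.
    """
    mask = cohort.missing_mask
    sample_frac = mask.mean(axis=1)
    keep_samples = sample_frac <= max_sample_missing
    if not keep_samples.any():
        raise EmptyCohortError("sample QC removed every sample")

    mask2 = mask.loc[keep_samples]
    protein_frac = mask2.mean(axis=0)
    keep_proteins = protein_frac <= max_protein_missing
    if not keep_proteins.any():
        raise EmptyCohortError("protein QC removed every protein")

    dropped_samples = list(cohort.sample_ids[~keep_samples])
    dropped_proteins = list(cohort.protein_ids[~keep_proteins])
    logger.info(
        "QC: dropped %d/%d samples (>%0.0f%% missing), then %d/%d proteins",
        len(dropped_samples), len(cohort.sample_ids), 100 * max_sample_missing,
        len(dropped_proteins), len(cohort.protein_ids),
    )
    return Cohort(
        phenotypes=cohort.phenotypes.loc[keep_samples].copy(),
        proteins=cohort.proteins.loc[keep_samples, keep_proteins].copy(),
        dropped_samples=cohort.dropped_samples + dropped_samples,
        dropped_proteins=cohort.dropped_proteins + dropped_proteins,
        imputed_mask=cohort.imputed_mask,
    )


def impute_missing(cohort: Cohort) -> Cohort:
    """Fill remaining missing values with sex-specific observed means.

    The imputed value for protein p in stratum s is the mean of the observed
    values of p among samples of sex s; observed entries are never touched.
    A protein with no observed value in a stratum that needs it is an error
    (QC should have removed such proteins).
    """
    proteins = cohort.proteins.copy()
    mask = cohort.missing_mask
    if not mask.to_numpy().any():
        return Cohort(
            cohort.phenotypes.copy(), proteins,
            list(cohort.dropped_samples), list(cohort.dropped_proteins),
            imputed_mask=mask.copy(),
        )
    sex = cohort.phenotypes["sex"]
    for stratum in sex.unique():
        rows = sex == stratum
        block = proteins.loc[rows]
        needs = block.isna().any(axis=0)
        if not needs.any():
            continue
        means = block.loc[:, needs].mean(axis=0, skipna=True)
        dead = means.index[means.isna()]
        if len(dead):
            raise ImputationError(
                f"protein(s) {list(dead)} fully missing among {stratum} samples"
            )
        proteins.loc[rows, needs] = block.loc[:, needs].fillna(means)
    assert not proteins.isna().to_numpy().any()
    return Cohort(
        cohort.phenotypes.copy(), proteins,
        list(cohort.dropped_samples), list(cohort.dropped_proteins),
        imputed_mask=mask.copy(),
    )


def qc_report(cohort: Cohort) -> dict:
    """Summary of what QC removed, suitable for JSON logging."""
    return {
        "n_samples": int(cohort.n_samples),
        "n_proteins": int(len(cohort.protein_ids)),
        "n_dropped_samples": len(cohort.dropped_samples),
        "n_dropped_proteins": len(cohort.dropped_proteins),
        "dropped_samples": list(cohort.dropped_samples),
        "dropped_proteins": list(cohort.dropped_proteins),
        "n_imputed": int(cohort.imputed_mask.to_numpy().sum())
        if cohort.imputed_mask is not None
        else None,
    }
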