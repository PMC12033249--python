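"""Synthetic plasma-proteomics cohorts with planted genetic and aging structure.

The generator emulates the statistical skeleton of a large biobank proteomics
study: a panel of log2-scale relative protein abundances (NPX-like units)
measured on tens of thousands of adults, where

* a subset of proteins drift linearly with age,
* proteins differ systematically between sexes,
* a latent per-person "biological age" offset ``b`` (years) shifts every
  age-responsive protein as if the person were ``age + b`` years old, and
  also drives disease risk and mortality,
* planted variants act as cis-pQTLs (one strong target) or broad trans
  factors (many weak targets), and
* values go missing completely at random, with designated high-missingness
  samples and proteins to exercise downstream QC.

Every generated dataset carries a :class:`Truth` record with the planted
parameters so that recovery can be tested; the analysis stages never see it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlantedVariant",
    "SimConfig",
    "Cohort",
    "GenotypeMatrix",
    "Truth",
    "MRTruth",
    "simulate_cohort",
    "simulate_mr_summary",
    "classification_scenario",
]

VariantKind = Literal["cis_pqtl", "widespread", "null"]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class PlantedVariant:
    """A variant with a declared effect on the proteome.

    ``cis_pqtl`` variants have exactly one target protein; ``widespread``
    variants have at least ten; ``null`` variants have none and exist to
    probe false-positive behaviour.
    """

    index: int
    maf: float
    kind: VariantKind
    target_proteins: tuple[int, ...] = ()
    effect_sizes: tuple[float, ...] = ()  # NPX per effect allele

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ConfigurationError(f"maf must be in (0, 0.5], got {self.maf}")
        if len(self.target_proteins) != len(self.effect_sizes):
            raise ConfigurationError("target_proteins and effect_sizes length mismatch")
        if self.kind == "cis_pqtl" and len(self.target_proteins) != 1:
            raise ConfigurationError("cis_pqtl variant must have exactly one target")
        if self.kind == "widespread" and len(self.target_proteins) < 10:
            raise ConfigurationError("widespread variant must have >= 10 targets")
        if self.kind == "null" and self.target_proteins:
            raise ConfigurationError("null variant must have no targets")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the generative model.

    Defaults describe a mid-life cohort (ages 40-70) in which half the panel
    is age-responsive with slopes of SD 0.02 NPX/year, the latent biological
    age offset has SD 3 years, and per-protein residual noise has SD 0.5 NPX
    — i.e. a single protein is a weak age predictor but a few hundred
    together support a clock with a 2-3 year error, mirroring the regime of
    published plasma clocks.
    """

    n_samples: int = 1000
    n_proteins: int = 100
    n_variants: int = 50
    age_range: tuple[float, float] = (40.0, 70.0)
    frac_age_proteins: float = 0.5
    age_slope_sd: float = 0.02  # NPX per year
    sex_effect_sd: float = 0.3  # NPX
    noise_sd: float = 0.5  # NPX
    latent_bioage_sd: float = 3.0  # years (tau)
    planted_variants: tuple[PlantedVariant, ...] = ()
    background_maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate_base: float = 0.02
    n_high_missing_samples: int = 0
    n_high_missing_proteins: int = 0
    high_missing_rate: float = 0.15
    mortality_loghr_per_year: float = 0.1  # log-hazard per year of b
    baseline_hazard: float = 0.02  # events per year at b = 0
    followup_years: float = 14.0
    age_slope_overrides: tuple[tuple[int, float], ...] = ()  # (protein idx, NPX/year)
    disease_logit_intercept: float = -6.0
    disease_logit_per_year_age: float = 0.05
    disease_logit_per_year_b: float = 0.08
    ld_block_size: int = 1  # >1 switches on AR(1) block LD
    ld_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_proteins, self.n_variants) < 1:
            raise ConfigurationError("n_samples, n_proteins, n_variants must be >= 1")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError("age_range lower bound must be below upper")
        for name in ("frac_age_proteins", "missing_rate_base", "high_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for pv in self.planted_variants:
            if not 0 <= pv.index < self.n_variants:
                raise ConfigurationError(f"planted variant index {pv.index} out of range")
            for t in pv.target_proteins:
                if not 0 <= t < self.n_proteins:
                    raise ConfigurationError(f"planted target protein {t} out of range")
        for idx, _ in self.age_slope_overrides:
            if not 0 <= idx < self.n_proteins:
                raise ConfigurationError(f"slope override protein {idx} out of range")


@dataclass
class Cohort:
    """Samples with phenotypes and a proteins-by-samples abundance matrix.

    ``proteins`` is samples x proteins in log2 abundance units with missing
    entries as NaN; the boolean ``missing_mask`` property flags them
    explicitly. ``phenotypes`` holds age (years), sex ('female'/'male'),
    binary and continuous outcomes, and right-censored survival fields.
    """

    phenotypes: pd.DataFrame
    proteins: pd.DataFrame
    dropped_samples: list[str] = field(default_factory=list)
    dropped_proteins: list[str] = field(default_factory=list)
    imputed_mask: pd.DataFrame | None = None

    @property
    def sample_ids(self) -> pd.Index:
        return self.phenotypes.index

    @property
    def protein_ids(self) -> pd.Index:
        return self.proteins.columns

    @property
    def n_samples(self) -> int:
        return len(self.phenotypes)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.proteins.isna()

    def __post_init__(self) -> None:
        if not self.proteins.index.equals(self.phenotypes.index):
            raise ValueError("protein matrix rows must match phenotype sample ids")


@dataclass
class GenotypeMatrix:
    """Biallelic dosages (samples x variants, values in [0, 2])."""

    variants: pd.DataFrame  # columns: id, chrom, pos, effect_allele, other_allele
    dosage: np.ndarray
    sample_ids: pd.Index

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError("dosage shape inconsistent with sample/variant counts")
        if self.dosage.size and (self.dosage.min() < 0 or self.dosage.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def variant_ids(self) -> pd.Index:
        return pd.Index(self.variants["id"])

    def eaf(self) -> np.ndarray:
        return self.dosage.mean(axis=0) / 2.0

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_ids.get_indexer(keep)
        if (idx < 0).any():
            raise KeyError("sample ids missing from genotype matrix")
        return GenotypeMatrix(self.variants.copy(), self.dosage[idx], pd.Index(keep))


@dataclass
class Truth:
    """Planted ground truth for a simulated cohort (never used in analysis)."""

    latent_bioage: np.ndarray  # b_i, years
    age_slopes: np.ndarray  # a_p, NPX/year
    sex_effects: np.ndarray  # s_p, NPX
    baseline_means: np.ndarray  # mu_p, NPX
    variant_effects: dict[int, dict[int, float]]  # variant idx -> {protein idx: NPX/allele}
    planted_variants: tuple[PlantedVariant, ...]
    mortality_loghr_per_year: float


@dataclass
class MRTruth:
    slope: float
    pleiotropy_intercept: float


def _draw_genotypes(rng: np.random.Generator, n: int, mafs: np.ndarray,
                    block_size: int, rho: float) -> np.ndarray:
    """Hardy-Weinberg dosages; optional AR(1) block LD on latent gaussians."""
    m = len(mafs)
    if block_size <= 1 or rho == 0.0:
        return rng.binomial(2, mafs, size=(n, m)).astype(float)
    # Two haplotypes per person: correlated gaussians thresholded at the
    # allele-frequency quantile, giving pairwise dosage LD within blocks.
    from scipy.stats import norm

    thresh = norm.ppf(mafs)
    dosage = np.zeros((n, m))
    for _hap in range(2):
        z = np.empty((n, m))
        for start in range(0, m, block_size):
            stop = min(start + block_size, m)
            width = stop - start
            e = rng.standard_normal((n, width))
            z[:, start] = e[:, 0]
            for j in range(1, width):
                z[:, start + j] = rho * z[:, start + j - 1] + np.sqrt(1 - rho**2) * e[:, j]
        dosage += (z < thresh)
    return dosage


def simulate_cohort(config: SimConfig) -> tuple[Cohort, GenotypeMatrix, Truth]:
    """Generate a cohort, genotypes and the planted truth.

    Generative model, per sample i / protein p / variant v::

        age_i ~ Uniform(age_range)
        sex_i ~ Bernoulli(0.5)
        b_i   ~ Normal(0, tau^2)                       (latent bioage offset)
        g_iv  ~ Binomial(2, maf_v)                     (HWE; optional block LD)
        x_ip  = mu_p + a_p (age_i + b_i) + s_p 1[male_i]
                + sum_v gamma_vp g_iv + eps_ip,  eps ~ Normal(0, noise_sd^2)

    Survival time is exponential with hazard ``h0 exp(theta b_i)``,
    right-censored at ``followup_years``; the binary disease indicator uses a
    logistic link on age and b. Missingness is MCAR at the base rate, with
    designated rows/columns pushed above the 10% QC threshold.

    Fully deterministic given ``config.seed``. Independent named random
    streams are used for sample draws, protein parameters, genotypes, noise,
    survival, outcomes and missingness, so that e.g. the protein panel's
    slopes do not depend on the sample size and shortening follow-up
    recensors the same event times.
    """
    streams = np.random.SeedSequence(config.seed).spawn(7)
    rng_sample, rng_prot, rng_geno, rng_noise, rng_surv, rng_out, rng_miss = (
        np.random.default_rng(s) for s in streams
    )
    n, p, m = config.n_samples, config.n_proteins, config.n_variants

    sample_ids = pd.Index([f"S{i:06d}" for i in range(n)], name="sample_id")
    protein_ids = pd.Index([f"PROT{j:04d}" for j in range(p)], name="protein_id")

    age = rng_sample.uniform(*config.age_range, size=n)
    male = rng_sample.integers(0, 2, size=n)
    b = rng_sample.normal(0.0, config.latent_bioage_sd, size=n)

    # Protein model parameters (depend only on seed and panel size)
    mu = rng_prot.normal(0.0, 0.5, size=p)
    n_age = int(round(config.frac_age_proteins * p))
    age_prot = rng_prot.choice(p, size=n_age, replace=False)
    slopes = np.zeros(p)
    slopes[age_prot] = rng_prot.normal(0.0, config.age_slope_sd, size=n_age)
    for idx, slope in config.age_slope_overrides:
        slopes[idx] = slope  # designated marker proteins (e.g. a GDF15-like slope)
    sex_eff = rng_prot.normal(0.0, config.sex_effect_sd, size=p)

    # Genotypes: planted variants keep their configured MAF
    mafs = rng_geno.uniform(*config.background_maf_range, size=m)
    for pv in config.planted_variants:
        mafs[pv.index] = pv.maf
    dosage = _draw_genotypes(rng_geno, n, mafs, config.ld_block_size, config.ld_rho)

    gamma = {}  # variant idx -> {protein idx: effect}
    for pv in config.planted_variants:
        gamma[pv.index] = dict(zip(pv.target_proteins, pv.effect_sizes))

    bio_age = age + b
    x = (
        mu[None, :]
        + np.outer(bio_age, slopes)
        + np.outer(male, sex_eff)
        + rng_noise.normal(0.0, config.noise_sd, size=(n, p))
    )
    for v, effects in gamma.items():
        for prot, eff in effects.items():
            x[:, prot] += eff * dosage[:, v]

    # Survival: exponential draw first (independent of followup_years so that
    # shortening follow-up only recensors the same event times)
    hazard = config.baseline_hazard * np.exp(config.mortality_loghr_per_year * b)
    t_event = rng_surv.exponential(1.0 / hazard)
    event = t_event <= config.followup_years
    surv_time = np.minimum(t_event, config.followup_years)

    logit = (
        config.disease_logit_intercept
        + config.disease_logit_per_year_age * age
        + config.disease_logit_per_year_b * b
    )
    disease = rng_out.random(n) < 1.0 / (1.0 + np.exp(-logit))
    cont_outcome = 0.2 * b + rng_out.normal(0.0, 1.0, size=n)

    # MCAR missingness + designated high-missingness rows/columns.  The
    # high-missing proteins are made missing only among ordinary samples so
    # that they still exceed 10% after the high-missing samples are removed.
    mask = rng_miss.random((n, p)) < config.missing_rate_base
    hi_s = rng_miss.choice(n, size=config.n_high_missing_samples, replace=False)
    hi_p = rng_miss.choice(p, size=config.n_high_missing_proteins, replace=False)
    if config.n_high_missing_samples:
        mask[hi_s, :] |= rng_miss.random((len(hi_s), p)) < config.high_missing_rate
    if config.n_high_missing_proteins:
        ordinary = np.setdiff1d(np.arange(n), hi_s)
        mask[np.ix_(ordinary, hi_p)] |= (
            rng_miss.random((len(ordinary), len(hi_p))) < config.high_missing_rate
        )
    # Guarantee the designated rows/columns actually exceed the 10% QC
    # threshold (the Bernoulli draw only does so in expectation).
    need_row = int(np.floor(0.10 * p)) + 1
    for i in hi_s:
        short = need_row - int(mask[i].sum())
        if short > 0:
            candidates = np.flatnonzero(~mask[i])
            mask[i, rng_miss.choice(candidates, size=short, replace=False)] = True
    if config.n_high_missing_proteins:
        ordinary = np.setdiff1d(np.arange(n), hi_s)
        need_col = int(np.floor(0.10 * len(ordinary))) + 1
        for j in hi_p:
            col = mask[ordinary, j]
            short = need_col - int(col.sum())
            if short > 0:
                candidates = ordinary[~col]
                mask[rng_miss.choice(candidates, size=short, replace=False), j] = True
    x = x.astype(float)
    x[mask] = np.nan

    phenotypes = pd.DataFrame(
        {
            "age": age,
            "sex": np.where(male == 1, "male", "female"),
            "disease": disease.astype(int),
            "cont_outcome": cont_outcome,
            "survival_time": surv_time,
            "event": event.astype(int),
        },
        index=sample_ids,
    )
    proteins = pd.DataFrame(x, index=sample_ids, columns=protein_ids)

    variants = pd.DataFrame(
        {
            "id": [f"var{v:05d}" for v in range(m)],
            "chrom": ["1"] * m,
            "pos": np.arange(1, m + 1) * 100_000,  # 1-based bp, strictly increasing
            "effect_allele": ["A"] * m,
            "other_allele": ["G"] * m,
        }
    )
    genotypes = GenotypeMatrix(variants, dosage, sample_ids)

    truth = Truth(
        latent_bioage=b,
        age_slopes=slopes,
        sex_effects=sex_eff,
        baseline_means=mu,
        variant_effects=gamma,
        planted_variants=config.planted_variants,
        mortality_loghr_per_year=config.mortality_loghr_per_year,
    )
    return Cohort(phenotypes, proteins), genotypes, truth


def simulate_mr_summary(
    n_instruments: int,
    true_slope: float,
    pleiotropy_intercept: float = 0.0,
    se_scale: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, MRTruth]:
    """Instrument-level two-sample MR summary statistics with known truth.

    Exposure effects are drawn half-normal (all positive, the orientation the
    Egger model requires); outcome effects follow
    ``beta_Y = intercept + slope * beta_X + Normal(0, se_Y^2)`` with
    per-instrument outcome SEs ``se_Y = se_scale * Uniform(0.5, 1.5)``.
    With ``se_scale = 0`` the draw is noiseless and reported outcome SEs fall
    back to 1 so that weights stay defined.
    """
    if n_instruments < 3:
        raise ValueError("need at least 3 instruments (Egger requires >= 3)")
    rng = np.random.default_rng(seed)
    beta_exp = np.abs(rng.normal(0.0, 0.1, size=n_instruments))
    beta_exp = np.maximum(beta_exp, 1e-3)  # avoid degenerate zero-strength instruments
    se_exp = rng.uniform(0.01, 0.03, size=n_instruments)
    se_out = se_scale * rng.uniform(0.5, 1.5, size=n_instruments)
    noise = rng.standard_normal(n_instruments) * se_out
    beta_out = pleiotropy_intercept + true_slope * beta_exp + noise
    se_out_reported = np.where(se_out > 0, se_out, 1.0)

    mr = pd.DataFrame(
        {
            "SNP": [f"rs{i:05d}" for i in range(n_instruments)],
            "EA": ["A"] * n_instruments,
            "OA": ["G"] * n_instruments,
            "beta_exp": beta_exp,
            "se_exp": se_exp,
            "beta_out": beta_out,
            "se_out": se_out_reported,
        }
    )
    return mr, MRTruth(slope=true_slope, pleiotropy_intercept=pleiotropy_intercept)


def classification_scenario(
    seed: int,
    n_samples: int = 3000,
    n_proteins: int = 300,
    n_variants: int = 20,
) -> SimConfig:
    """Study design for the signal-classification experiment.

    Plants two genome-wide-detectable variants in a 3000-sample, 300-protein
    cohort:

    * a **cis-pQTL** (variant 2) with a single target — the panel's most
      age-responsive protein, whose slope is pinned to 0.12 NPX/year (a
      GDF15-like strongly aging marker, heavily weighted by the clock) —
      shifted by 1.2 NPX per allele;
    * a **widespread trans** factor (variant 10) nudging the next 60 most
      age-responsive proteins by 0.04 NPX per allele each, aligned with each
      protein's aging direction, so the aggregate effect on proteomic age is
      genome-wide significant while individual protein effects sit mostly
      below the pQTL detection threshold.

    Both MAFs are 0.3. Effect sizes were fixed by a pilot power calculation
    at these sample sizes (aggregate |z| ~ 6-8 for both variants; per-target
    pQTL |z| ~ 2 for the widespread variant, ~ 25 for the cis target).
    """
    # Reproduce the slope assignment simulate_cohort will make (the protein
    # parameter stream is independent of sample size), so targets can be
    # chosen among genuinely age-responsive proteins.
    probe = SimConfig(
        n_samples=2, n_proteins=n_proteins, n_variants=n_variants, seed=seed
    )
    _, _, probe_truth = simulate_cohort(probe)
    slopes = probe_truth.age_slopes

    cis_target = int(np.argmax(np.abs(slopes)))
    cis_sign = float(np.sign(slopes[cis_target]) or 1.0)
    order = np.argsort(-np.abs(slopes))
    trans_targets = [int(j) for j in order[1:61]]
    trans_effects = [0.04 * float(np.sign(slopes[j])) for j in trans_targets]

    cis = PlantedVariant(
        index=2, maf=0.3, kind="cis_pqtl",
        target_proteins=(cis_target,),
        effect_sizes=(1.2 * cis_sign,),
    )
    widespread = PlantedVariant(
        index=10, maf=0.3, kind="widespread",
        target_proteins=tuple(trans_targets),
        effect_sizes=tuple(trans_effects),
    )
    return SimConfig(
        n_samples=n_samples,
        n_proteins=n_proteins,
        n_variants=n_variants,
        planted_variants=(cis, widespread),
        age_slope_overrides=((cis_target, 0.12 * cis_sign),),
        missing_rate_base=0.01,
        seed=seed,
    )
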