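"""Forward simulators: read-count evidence at known tumor fraction, and
clinical cohorts with planted burden structure.

The sequencing simulator is the exact forward model of the estimation
formulas: at tumor fraction ``t``, a clonal mutation under LOH has expected
VAF ``t/(2-t)``; a mutation on a diploid heterozygous background has expected
VAF ``t/2``; a heterozygous SNP on a single-copy-deleted gene has allele
probability ``1/(2-t)`` (or its complement, per parental allele); a deleted
gene's depth log-ratio is ``log2((2-t)/2)``; an AR gain of ``k`` extra copies
is ``log2((2+k*t)/2)``. Read counts are binomial at a per-entity depth drawn
from a negative binomial around the target coverage (capture variability).

The cohort simulator plants a single latent "disease burden" factor z ~ N(0,1)
per patient. The ctDNA-fraction label is a left-censored logit-normal
transform of z (point mass of undetectable samples plus a right-skewed tail,
bounded by 1); burden markers are monotone transforms of correlated latents,
with the hemoglobin loading negative. Binary features are thresholded latents
at a configured prevalence. Missingness is completely at random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ValidationError
from .types import CohortTable, FeatureSpec, GeneCopyNumber, GermlineSNP, SomaticMutation

__all__ = [
    "ReadSimConfig",
    "CohortSimConfig",
    "FeatureSimSpec",
    "DEFAULT_FEATURE_SIMS",
    "DEFAULT_FEATURES",
    "simulate_sequencing_sample",
    "simulate_clinical_cohort",
]


@dataclass(frozen=True)
class ReadSimConfig:
    """Configuration of one simulated cfDNA sample.

    ``deleted_genes`` lists (gene, n_snps) pairs: each gene receives a
    deletion log-ratio and that many heterozygous SNPs. ``ar_gain_copies``
    is the number of extra AR copies when ``include_ar_gain`` is set
    (default 6, i.e. ~8 total copies as typical for AR-gained mCRPC).
    """

    true_fraction: float = 0.3
    n_loh_mutations: int = 5
    n_diploid_mutations: int = 2
    depth: float = 2000.0
    depth_dispersion: float = 20.0
    deleted_genes: tuple[tuple[str, int], ...] = (("TP53", 6), ("RB1", 8))
    n_neutral_genes: int = 4
    include_ar_gain: bool = False
    ar_gain_copies: float = 6.0
    log_ratio_noise_sd: float = 0.05
    sample_id: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_fraction <= 1.0:
            raise ValidationError("true_fraction must lie in [0,1]")
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        if min(self.n_loh_mutations, self.n_diploid_mutations, self.n_neutral_genes) < 0:
            raise ValidationError("counts must be non-negative")


def _draw_depths(rng: np.random.Generator, n: int, mean: float, dispersion: float) -> np.ndarray:
    if n == 0:
        return np.zeros(0, dtype=int)
    p = dispersion / (dispersion + mean)
    return np.maximum(1, rng.negative_binomial(dispersion, p, size=n))


def simulate_sequencing_sample(
    cfg: ReadSimConfig,
) -> tuple[list[SomaticMutation], list[GermlineSNP], list[GeneCopyNumber], dict]:
    """Draw one sample's mutation, SNP and copy-number tables plus truth.

    Fully reproducible from ``cfg.seed``; the truth record carries the true
    fraction and the expected value of every simulated quantity.
    """
    rng = np.random.default_rng(cfg.seed)
    t = cfg.true_fraction
    sid = cfg.sample_id
    noise = cfg.log_ratio_noise_sd

    p_loh = t / (2.0 - t)
    p_dip = t / 2.0
    hsaf = 1.0 / (2.0 - t)
    del_lr = math.log2((2.0 - t) / 2.0)
    gain_lr = math.log2((2.0 + cfg.ar_gain_copies * t) / 2.0)

    mutations: list[SomaticMutation] = []
    pos = 1000

    depths = _draw_depths(rng, cfg.n_loh_mutations, cfg.depth, cfg.depth_dispersion)
    for j, d in enumerate(depths):
        alt = int(rng.binomial(d, p_loh))
        lr = del_lr + rng.normal(0.0, noise)
        mutations.append(
            SomaticMutation(
                sample_id=sid,
                gene=f"LOHMUT{j + 1}",
                chrom=str(1 + j % 22),
                pos=pos + j,
                ref_count=int(d) - alt,
                alt_count=alt,
                vaf=alt / d,
                gene_log_ratio=lr,
            )
        )

    depths = _draw_depths(rng, cfg.n_diploid_mutations, cfg.depth, cfg.depth_dispersion)
    for j, d in enumerate(depths):
        alt = int(rng.binomial(d, p_dip))
        lr = rng.normal(0.0, noise)
        mutations.append(
            SomaticMutation(
                sample_id=sid,
                gene=f"DIPMUT{j + 1}",
                chrom=str(1 + j % 22),
                pos=pos + 500 + j,
                ref_count=int(d) - alt,
                alt_count=alt,
                vaf=alt / d,
                gene_log_ratio=lr,
            )
        )

    snps: list[GermlineSNP] = []
    copy_number: list[GeneCopyNumber] = []
    for g, (gene, n_snps) in enumerate(cfg.deleted_genes):
        copy_number.append(
            GeneCopyNumber(
                sample_id=sid,
                gene=gene,
                log_ratio=del_lr + rng.normal(0.0, noise),
            )
        )
        depths = _draw_depths(rng, n_snps, cfg.depth, cfg.depth_dispersion)
        for j, d in enumerate(depths):
            # retained parental allele chosen at random per SNP
            p = hsaf if rng.random() < 0.5 else 1.0 - hsaf
            alt = int(rng.binomial(d, p))
            snps.append(
                GermlineSNP(
                    sample_id=sid,
                    gene=gene,
                    chrom=str(1 + g % 22),
                    pos=pos + 2000 + 100 * g + j,
                    ref_count=int(d) - alt,
                    alt_count=alt,
                )
            )

    for j in range(cfg.n_neutral_genes):
        copy_number.append(
            GeneCopyNumber(
                sample_id=sid,
                gene=f"NEUT{j + 1}",
                log_ratio=rng.normal(0.0, noise),
            )
        )
    if cfg.include_ar_gain:
        copy_number.append(
            GeneCopyNumber(
                sample_id=sid,
                gene="AR",
                log_ratio=gain_lr + rng.normal(0.0, noise),
                is_ar=True,
            )
        )

    truth = {
        "sample_id": sid,
        "true_fraction": t,
        "expected_loh_vaf": p_loh,
        "expected_diploid_vaf": p_dip,
        "expected_hsaf": hsaf,
        "expected_deletion_log_ratio": del_lr,
        "expected_ar_gain_log_ratio": gain_lr if cfg.include_ar_gain else None,
        "seed": cfg.seed,
    }
    return mutations, snps, copy_number, truth


# ---------------------------------------------------------------------------
# clinical cohort


@dataclass(frozen=True)
class FeatureSimSpec:
    """How one clinical feature is generated from the latent burden.

    ``loading`` is the correlation between the feature's own latent and the
    burden factor (sign included). Continuous features are mapped through a
    monotone transform: log-normal around ``center`` with log-scale
    ``spread`` for right-skewed serum markers, or linear for hemoglobin.
    Binary features are 1 when the latent exceeds the quantile implied by
    ``prevalence``. ``target_spearman`` records the rank correlation with
    the label that the loading was calibrated to imply.
    """

    spec: FeatureSpec
    loading: float
    target_spearman: float
    transform: str = "lognormal"  # lognormal | linear | threshold
    center: float = 1.0
    spread: float = 1.0
    prevalence: float = 0.5


def _loading_for(rho_s: float) -> float:
    """Latent correlation implying Spearman ``rho_s`` between monotone
    transforms of a bivariate normal pair (inverse of the classical
    Pearson-Spearman relation rho_s = (6/pi) asin(rho/2))."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


DEFAULT_FEATURE_SIMS: dict[str, FeatureSimSpec] = {
    "cfdna_conc": FeatureSimSpec(
        FeatureSpec("cfdna_conc", "continuous", monotone=1),
        loading=_loading_for(0.55), target_spearman=0.55,
        transform="lognormal", center=14.0, spread=1.0,
    ),
    "psa": FeatureSimSpec(
        FeatureSpec("psa", "continuous", monotone=1),
        loading=_loading_for(0.40), target_spearman=0.40,
        transform="lognormal", center=26.0, spread=1.8,
    ),
    "ldh_uln": FeatureSimSpec(
        FeatureSpec("ldh_uln", "continuous", monotone=1),
        loading=_loading_for(0.41), target_spearman=0.41,
        transform="lognormal", center=0.80, spread=0.30,
    ),
    "alp_uln": FeatureSimSpec(
        FeatureSpec("alp_uln", "continuous", monotone=1),
        loading=_loading_for(0.35), target_spearman=0.35,
        transform="lognormal", center=0.85, spread=0.42,
    ),
    "hemoglobin": FeatureSimSpec(
        FeatureSpec("hemoglobin", "continuous", monotone=0),
        loading=-_loading_for(0.35), target_spearman=-0.35,
        transform="linear", center=130.0, spread=15.0,
    ),
    "liver_mets": FeatureSimSpec(
        FeatureSpec("liver_mets", "binary"),
        loading=0.45, target_spearman=0.25,
        transform="threshold", prevalence=0.12,
    ),
    "bone_mets_10plus": FeatureSimSpec(
        FeatureSpec("bone_mets_10plus", "binary"),
        loading=0.35, target_spearman=0.22,
        transform="threshold", prevalence=0.40,
    ),
    "ecog_2plus": FeatureSimSpec(
        FeatureSpec("ecog_2plus", "binary"),
        loading=0.30, target_spearman=0.15,
        transform="threshold", prevalence=0.14,
    ),
}

DEFAULT_FEATURES: tuple[str, ...] = tuple(DEFAULT_FEATURE_SIMS)


@dataclass(frozen=True)
class CohortSimConfig:
    """Configuration of a simulated clinical cohort.

    The label model is a left-censored logit-normal: raw fraction
    ``expit(label_mu + label_sigma * z)`` with everything below
    ``censor_floor`` reported as 0 (undetectable). Defaults give a median
    near 5%, roughly 36-38% undetectable and ~20% above 30%. ``loadings``
    overrides per-feature latent loadings (set all to 0 for a null cohort).
    """

    n_patients: int = 300
    features: tuple[str, ...] = DEFAULT_FEATURES
    label_mu: float = float(logit(0.05))
    label_sigma: float = 2.64
    censor_floor: float = 0.02
    missing_rate: float = 0.0
    loadings: Optional[dict[str, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must lie in [0,1)")
        unknown = set(self.features) - set(DEFAULT_FEATURE_SIMS)
        if unknown:
            raise ValidationError(f"unknown features: {sorted(unknown)}")


def simulate_clinical_cohort(cfg: CohortSimConfig) -> CohortTable:
    """Draw a cohort with burden-correlated features and censored labels.

    Byte-identical output for identical (config, seed); the ``truth`` frame
    carries the latent burden and the uncensored fraction per patient.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    z = rng.normal(size=n)

    raw = expit(cfg.label_mu + cfg.label_sigma * z)
    label = np.where(raw < cfg.censor_floor, 0.0, raw)

    data = {}
    specs: dict[str, FeatureSpec] = {}
    for name in cfg.features:
        sim = DEFAULT_FEATURE_SIMS[name]
        rho = sim.loading if cfg.loadings is None else cfg.loadings.get(name, sim.loading)
        rho = float(np.clip(rho, -0.999, 0.999))
        u = rho * z + math.sqrt(1.0 - rho * rho) * rng.normal(size=n)
        if sim.transform == "lognormal":
            values = sim.center * np.exp(sim.spread * u)
        elif sim.transform == "linear":
            values = sim.center + sim.spread * u
        else:  # threshold
            cut = float(_norm_ppf(1.0 - sim.prevalence))
            values = (u > cut).astype(float)
        data[name] = values
        specs[name] = sim.spec

    index = pd.Index([f"P{i + 1:04d}" for i in range(n)], name="patient_id")
    frame = pd.DataFrame(data, index=index, columns=list(cfg.features))

    if cfg.missing_rate > 0:
        mask = rng.random(size=frame.shape) < cfg.missing_rate
        frame = frame.mask(mask)

    truth = pd.DataFrame({"latent_burden": z, "uncensored_fraction": raw}, index=index)
    return CohortTable(
        data=frame,
        features=specs,
        label=pd.Series(label, index=index, name="ctdna_fraction"),
        truth=truth,
    )


def _norm_ppf(q: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(q))
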