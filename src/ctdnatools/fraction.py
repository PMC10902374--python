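"""Hierarchical estimation of circulating tumor DNA fraction (ctDNA%).

Plasma cell-free DNA is a mixture of tumor-derived fragments (fraction ``t``)
and normal, mostly leukocyte-derived DNA. Targeted panel sequencing yields
three convertible lines of evidence about ``t``:

1. **Somatic mutation VAFs.** Assuming every somatic mutation may sit in a
   region of loss-of-heterozygosity (LOH) — the conservative worst case,
   since concurrent loss of the wild-type allele inflates VAF — a clonal
   mutation at tumor fraction ``t`` has expected VAF ``t / (2 - t)``, hence
   ``t = 2 / (VAF^-1 + 1)``. Sampling noise is handled by replacing the
   observed VAF with a one-sided lower binomial confidence bound before
   inversion, and the maximum over eligible mutations (the one most likely
   truncal) is taken as the sample estimate.
2. **Allelic imbalance of germline heterozygous SNPs** on genes with
   log-ratio evidence of a single-copy deletion: the major-allele frequency
   is expected at ``1 / (2 - t)``, hence ``t = 2 - VAF^-1`` on the
   major-allele scale.
3. **Copy-number log-ratios alone** (qualitative fallback): a heterozygous
   deletion at fraction ``t`` shifts depth by ``log2((2 - t)/2)`` and a
   single-copy gain by ``log2((2 + t)/2)``; inverting the mean log-ratio of
   each class gives a coarse estimate when neither mutation nor SNP evidence
   is usable.

A sample whose only alteration is an androgen receptor (*AR*) gain is
assigned 5% ctDNA: an isolated AR gain visible on log-ratio data rules out
ctDNA < 2%, and 5% is the approximate detection floor for the high-level
(~7-8 copy) AR gains typical of castration-resistant prostate cancer.

Estimates are bucketed into prognostic categories: undetected (<2%),
low (2-30%, inclusive at 30%), and high (>30%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, ValidationError
from .types import GeneCopyNumber, GermlineSNP, SomaticMutation, is_autosome

__all__ = [
    "EstimatorConfig",
    "CtDNAEstimate",
    "vaf_to_fraction",
    "hsaf_to_fraction",
    "major_allele_frequency",
    "outlier_corrected_vaf",
    "mutation_based_estimate",
    "hsaf_based_estimate",
    "qualitative_fallback_estimate",
    "estimate_ctdna_fraction",
    "classify_fraction",
]


@dataclass(frozen=True)
class EstimatorConfig:
    """Thresholds of the estimation hierarchy.

    Defaults encode the published analysis settings: mutations on amplified
    genes (log-ratio >= 0.2) are ineligible, single-copy deletions are called
    in the log-ratio window [-0.7, -0.3], genes need >= 4 unique heterozygous
    SNPs for the allelic-imbalance estimate, the binomial correction treats
    the observed VAF as a 95% quantile outlier, detection/high thresholds are
    2% and 30%, and an isolated AR gain maps to 5%.
    """

    amp_lr_max: float = 0.2
    del_lr_low: float = -0.7
    del_lr_high: float = -0.3
    gain_lr_max: float = 0.58  # ~3 copies at purity 1; cap for "low-level" gains
    min_snps_per_gene: int = 4
    outlier_quantile: float = 0.95
    detect_threshold: float = 0.02
    high_threshold: float = 0.30
    ar_gain_fraction: float = 0.05
    concordance_tol: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 < self.detect_threshold < self.high_threshold < 1.0:
            raise ValidationError("need 0 < detect_threshold < high_threshold < 1")
        if not self.del_lr_low < self.del_lr_high < 0.0 < self.amp_lr_max:
            raise ValidationError("need del_lr_low < del_lr_high < 0 < amp_lr_max")
        if not 0.0 < self.outlier_quantile < 1.0:
            raise ValidationError("outlier_quantile must lie in (0,1)")
        if self.min_snps_per_gene < 1:
            raise ValidationError("min_snps_per_gene must be >= 1")


@dataclass(frozen=True)
class MutationEvidence:
    """Per-mutation detail: identifier, corrected VAF, implied fraction."""

    mutation_id: str
    corrected_vaf: float
    fraction: float
    log_ratio_missing: bool = False


@dataclass(frozen=True)
class GeneHSAFEvidence:
    """Per-gene detail: gene, median major-allele frequency, implied fraction."""

    gene: str
    median_maf: float
    fraction: float
    n_snps: int = 0


@dataclass
class CtDNAEstimate:
    """Output of the hierarchical estimator for one sample."""

    sample_id: str
    fraction: float
    tier: str  # mutation | hsaf | qualitative | ar_gain | undetected
    category: str  # undetected | low | high
    per_mutation: list[MutationEvidence] = field(default_factory=list)
    per_gene_hsaf: list[GeneHSAFEvidence] = field(default_factory=list)
    concordance_flag: Optional[bool] = None

    @property
    def n_eligible_mutations(self) -> int:
        return len(self.per_mutation)

    @property
    def n_eligible_genes(self) -> int:
        return len(self.per_gene_hsaf)


def _check_unit_interval(x: float, name: str) -> float:
    x = float(x)
    if not (0.0 <= x <= 1.0) or math.isnan(x):
        raise DomainError(f"{name} must lie in [0,1], got {x}")
    return x


def vaf_to_fraction(vaf: float) -> float:
    """Invert the LOH mixture model: ``t = 2 * VAF / (1 + VAF)``.

    Equivalent to ``2 / (VAF^-1 + 1)`` with the 0 limit handled; monotone
    increasing, mapping [0,1] onto [0,1].
    """
    vaf = _check_unit_interval(vaf, "vaf")
    return 2.0 * vaf / (1.0 + vaf)


def hsaf_to_fraction(hsaf: float) -> float:
    """Invert the allelic-imbalance model: ``t = 2 - 1/HSAF`` (floored at 0).

    ``hsaf`` is a major-allele frequency and must already lie in [0.5, 1];
    use :func:`major_allele_frequency` to fold a raw VAF first.
    """
    hsaf = float(hsaf)
    if not (0.5 <= hsaf <= 1.0) or math.isnan(hsaf):
        raise DomainError(
            f"hsaf must lie in [0.5,1] (major-allele scale), got {hsaf}"
        )
    return max(0.0, 2.0 - 1.0 / hsaf)


def major_allele_frequency(vaf: float) -> float:
    """Fold a VAF onto the major-allele scale: ``|0.5 - VAF| + 0.5``."""
    vaf = _check_unit_interval(vaf, "vaf")
    return abs(0.5 - vaf) + 0.5


def outlier_corrected_vaf(
    alt_count: int, depth: int, quantile: float = 0.95
) -> float:
    """Conservative VAF: treat the observed count as a ``quantile`` outlier.

    Returns the success probability ``p`` at which the observed mutant read
    count would sit at the upper ``quantile`` of a Binomial(depth, p), i.e.
    solves ``P(X >= alt_count | depth, p) = 1 - quantile``. This is the
    one-sided lower Clopper-Pearson bound, computed in closed form from the
    beta quantile function. Always <= the raw VAF; exactly 0 at zero counts.
    """
    if depth < 1:
        raise DomainError(f"depth must be >= 1, got {depth}")
    if not 0 <= alt_count <= depth:
        raise DomainError(f"need 0 <= alt_count <= depth, got {alt_count}/{depth}")
    if not 0.0 < quantile < 1.0:
        raise DomainError(f"quantile must lie in (0,1), got {quantile}")
    if alt_count == 0:
        return 0.0
    return float(stats.beta.ppf(1.0 - quantile, alt_count, depth - alt_count + 1))


def _mutation_id(m: SomaticMutation) -> str:
    return f"{m.gene}:{m.chrom}:{m.pos}"


def mutation_based_estimate(
    mutations: Sequence[SomaticMutation], cfg: EstimatorConfig = EstimatorConfig()
) -> Optional[tuple[float, list[MutationEvidence]]]:
    """Maximum outlier-corrected per-mutation fraction over eligible mutations.

    Eligible mutations are somatic-confirmed, autosomal, and lie on
    non-amplified host genes (log-ratio < ``amp_lr_max``; a missing log-ratio
    counts as non-amplified but is flagged in the evidence record). Returns
    None when nothing is eligible.
    """
    evidence: list[MutationEvidence] = []
    for m in mutations:
        if m.somatic_status != "somatic_confirmed":
            continue
        if not is_autosome(m.chrom):
            continue
        lr_missing = m.gene_log_ratio is None or not np.isfinite(m.gene_log_ratio)
        if not lr_missing and m.gene_log_ratio >= cfg.amp_lr_max:
            continue
        if m.depth == 0:
            continue
        cv = outlier_corrected_vaf(m.alt_count, m.depth, cfg.outlier_quantile)
        evidence.append(
            MutationEvidence(
                mutation_id=_mutation_id(m),
                corrected_vaf=cv,
                fraction=vaf_to_fraction(cv),
                log_ratio_missing=lr_missing,
            )
        )
    if not evidence:
        return None
    return max(e.fraction for e in evidence), evidence


def hsaf_based_estimate(
    snps: Sequence[GermlineSNP],
    cn: Sequence[GeneCopyNumber],
    cfg: EstimatorConfig = EstimatorConfig(),
) -> Optional[tuple[float, list[GeneHSAFEvidence]]]:
    """Allelic-imbalance estimate from SNPs on single-copy-deleted genes.

    For every gene whose log-ratio falls in the deletion window and that
    carries at least ``min_snps_per_gene`` unique heterozygous SNPs, the
    median major-allele frequency of its SNPs is pushed through
    ``t = 2 - 1/HSAF``; the overall estimate is the maximum over eligible
    genes. Returns None when no gene qualifies.
    """
    deleted = {
        rec.gene
        for rec in cn
        if cfg.del_lr_low <= rec.log_ratio <= cfg.del_lr_high
    }
    by_gene: dict[str, dict[tuple[str, int], GermlineSNP]] = {}
    for s in snps:
        if s.gene in deleted:
            by_gene.setdefault(s.gene, {})[(s.chrom, s.pos)] = s
    evidence: list[GeneHSAFEvidence] = []
    for gene in sorted(by_gene):
        unique_snps = list(by_gene[gene].values())
        if len(unique_snps) < cfg.min_snps_per_gene:
            continue
        mafs = [major_allele_frequency(s.vaf) for s in unique_snps]
        med = float(np.median(mafs))
        evidence.append(
            GeneHSAFEvidence(
                gene=gene,
                median_maf=med,
                fraction=hsaf_to_fraction(med),
                n_snps=len(unique_snps),
            )
        )
    if not evidence:
        return None
    return max(e.fraction for e in evidence), evidence


def qualitative_fallback_estimate(
    cn: Sequence[GeneCopyNumber], cfg: EstimatorConfig = EstimatorConfig()
) -> Optional[float]:
    """Coarse estimate from mean log-ratios of deletions and low-level gains.

    Deletions (window log-ratios) invert ``LR = log2((2 - t)/2)`` at the
    class mean; non-AR low-level gains (``amp_lr_max <= LR <= gain_lr_max``)
    invert ``LR = log2((2 + t)/2)``. The larger of the two inversions,
    clipped to [0,1], is returned; None when neither class is present. AR is
    excluded from the gain class because an isolated AR gain triggers its own
    heuristic tier.
    """
    del_lrs = [
        r.log_ratio for r in cn if cfg.del_lr_low <= r.log_ratio <= cfg.del_lr_high
    ]
    gain_lrs = [
        r.log_ratio
        for r in cn
        if not r.is_ar and cfg.amp_lr_max <= r.log_ratio <= cfg.gain_lr_max
    ]
    candidates: list[float] = []
    if del_lrs:
        candidates.append(2.0 - 2.0 ** (float(np.mean(del_lrs)) + 1.0))
    if gain_lrs:
        candidates.append(2.0 ** (float(np.mean(gain_lrs)) + 1.0) - 2.0)
    if not candidates:
        return None
    return float(np.clip(max(candidates), 0.0, 1.0))


def classify_fraction(
    fraction: float, cfg: EstimatorConfig = EstimatorConfig()
) -> str:
    """Bucket a fraction: [0, 2%) undetected, [2%, 30%] low, (30%, 1] high."""
    fraction = _check_unit_interval(fraction, "fraction")
    if fraction < cfg.detect_threshold:
        return "undetected"
    if fraction <= cfg.high_threshold:
        return "low"
    return "high"


def _single_sample_id(*groups: Iterable) -> Optional[str]:
    ids = {rec.sample_id for group in groups for rec in group}
    if len(ids) > 1:
        raise ValidationError(f"records from multiple samples: {sorted(ids)}")
    return ids.pop() if ids else None


def estimate_ctdna_fraction(
    mutations: Sequence[SomaticMutation] = (),
    snps: Sequence[GermlineSNP] = (),
    cn: Sequence[GeneCopyNumber] = (),
    cfg: EstimatorConfig = EstimatorConfig(),
    sample_id: Optional[str] = None,
) -> CtDNAEstimate:
    """Run the full estimation hierarchy on one sample's evidence.

    Tier order: mutation-based, then allelic-imbalance (HSAF), then the
    qualitative log-ratio fallback, then the isolated-AR-gain heuristic
    (5%), and finally undetected (fraction 0). When both mutation and HSAF
    estimates exist, ``concordance_flag`` records whether they agree within
    ``concordance_tol``; discordance is flagged, never auto-resolved.
    """
    inferred = _single_sample_id(mutations, snps, cn)
    if sample_id is None:
        sample_id = inferred if inferred is not None else "sample"

    mut = mutation_based_estimate(mutations, cfg)
    hsaf = hsaf_based_estimate(snps, cn, cfg)

    concordance: Optional[bool] = None
    if mut is not None and hsaf is not None:
        concordance = abs(mut[0] - hsaf[0]) <= cfg.concordance_tol

    per_mutation = mut[1] if mut is not None else []
    per_gene = hsaf[1] if hsaf is not None else []

    if mut is not None:
        fraction, tier = mut[0], "mutation"
    elif hsaf is not None:
        fraction, tier = hsaf[0], "hsaf"
    else:
        qual = qualitative_fallback_estimate(cn, cfg)
        if qual is not None and qual > 0.0:
            fraction, tier = qual, "qualitative"
        else:
            has_ar_gain = any(
                r.is_ar and r.log_ratio >= cfg.amp_lr_max for r in cn
            )
            if has_ar_gain:
                fraction, tier = cfg.ar_gain_fraction, "ar_gain"
            else:
                fraction, tier = 0.0, "undetected"

    return CtDNAEstimate(
        sample_id=sample_id,
        fraction=fraction,
        tier=tier,
        category=classify_fraction(fraction, cfg),
        per_mutation=per_mutation,
        per_gene_hsaf=per_gene,
        concordance_flag=concordance,
    )
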