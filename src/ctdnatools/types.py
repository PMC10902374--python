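"""Core record types shared across the estimator, simulators and predictors.

Coordinates are 1-based inclusive (VCF convention) in every table. Read counts
are raw integers; VAF is always recomputed from counts when counts are present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .errors import ValidationError

_AUTOSOMES = {str(i) for i in range(1, 23)}


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix; ``chrX`` and ``X`` are the same contig."""
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


def is_autosome(chrom: str) -> bool:
    return normalize_chrom(chrom) in _AUTOSOMES


@dataclass(frozen=True)
class SomaticMutation:
    """One somatic variant call with its host-gene copy-number context.

    ``gene_log_ratio`` is the log2 tumor/normal depth ratio of the gene the
    variant lies in (None when the panel gives no copy-number call there).
    ``somatic_status`` is the flag from upstream paired tumor/leukocyte
    calling; ``excluded`` encodes germline or clonal-hematopoiesis removal.
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref_count: int
    alt_count: int
    vaf: float
    gene_log_ratio: Optional[float] = None
    somatic_status: Literal["somatic_confirmed", "excluded"] = "somatic_confirmed"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValidationError(
                f"read counts must be non-negative, got ref={self.ref_count} "
                f"alt={self.alt_count}"
            )
        if not 0.0 <= self.vaf <= 1.0:
            raise ValidationError(f"vaf must lie in [0,1], got {self.vaf}")
        if self.somatic_status not in ("somatic_confirmed", "excluded"):
            raise ValidationError(f"unknown somatic_status {self.somatic_status!r}")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count


@dataclass(frozen=True)
class GermlineSNP:
    """One heterozygous germline SNP on a candidate-LOH gene."""

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValidationError("read counts must be non-negative")
        if self.ref_count + self.alt_count < 1:
            raise ValidationError("SNP must have at least one supporting read")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth


@dataclass(frozen=True)
class GeneCopyNumber:
    """Gene-level log2 depth ratio; ``is_ar`` marks the androgen receptor."""

    sample_id: str
    gene: str
    log_ratio: float
    is_ar: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.log_ratio):
            raise ValidationError(f"log_ratio must be finite, got {self.log_ratio}")


FeatureKind = Literal["continuous", "binary", "categorical"]


@dataclass(frozen=True)
class FeatureSpec:
    """Declaration of one clinical feature column.

    ``monotone`` is the sign of the constrained relationship between the
    feature and tumor burden (+1, -1, or 0 for unconstrained); it is consumed
    by the gradient-boosting models.
    """

    name: str
    kind: FeatureKind = "continuous"
    levels: tuple[str, ...] = ()
    monotone: int = 0

    def __post_init__(self) -> None:
        if self.kind == "categorical" and not self.levels:
            raise ValidationError(f"categorical feature {self.name!r} needs levels")
        if self.monotone not in (-1, 0, 1):
            raise ValidationError(f"monotone sign must be -1/0/+1, got {self.monotone}")


@dataclass
class CohortTable:
    """Patient-by-clinical-feature matrix with optional ctDNA-fraction labels.

    ``data`` is indexed by patient_id; every column is numeric (categoricals
    are stored as float level codes per ``features[...].levels``). Missing
    cells are NaN — the mask is ``data.isna()``. ``label`` holds the observed
    ctDNA fraction in [0,1] where measured (NaN elsewhere).
    """

    data: pd.DataFrame
    features: dict[str, FeatureSpec]
    label: Optional[pd.Series] = None
    truth: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(self.features):
            raise ValidationError(
                "data columns must match declared features in order: "
                f"{list(self.data.columns)} vs {list(self.features)}"
            )
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate patient_id {dup!r}")
        values = self.data.to_numpy(dtype=float)
        observed = ~np.isnan(values)
        if not np.isfinite(values[observed]).all():
            raise ValidationError("non-finite value in an observed cell")
        if self.label is not None:
            lab = self.label.to_numpy(dtype=float)
            ok = np.isnan(lab) | ((lab >= 0.0) & (lab <= 1.0))
            if not ok.all():
                bad = self.label.index[~ok][0]
                raise ValidationError(f"label_fraction outside [0,1] for {bad!r}")

    @property
    def n_patients(self) -> int:
        return len(self.data)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean frame, True where a cell is missing."""
        return self.data.isna()

    @property
    def feature_names(self) -> list[str]:
        return list(self.features)

    def monotone_signs(self) -> tuple[int, ...]:
        return tuple(self.features[name].monotone for name in self.features)

    def subset_rows(self, index) -> "CohortTable":
        return CohortTable(
            data=self.data.loc[index],
            features=self.features,
            label=None if self.label is None else self.label.loc[index],
        )

    def copy(self) -> "CohortTable":
        return CohortTable(
            data=self.data.copy(),
            features=dict(self.features),
            label=None if self.label is None else self.label.copy(),
            truth=None if self.truth is None else self.truth.copy(),
        )
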