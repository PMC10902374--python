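"""Readers and writers for the evidence tables and clinical cohort files.

All tables are UTF-8 text with "." as the decimal point and no thousands
separators. Coordinates are 1-based inclusive (VCF convention). TSV is the
canonical dialect for the three sequencing-evidence tables; somatic mutations
can additionally be ingested from a VCF with AD-style allele depths. The
clinical cohort is a CSV validated against a declared feature schema
(optionally loaded from YAML).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, ValidationError
from .types import CohortTable, FeatureSpec, GeneCopyNumber, GermlineSNP, SomaticMutation

logger = logging.getLogger(__name__)

_VAF_TOL = 1e-6

MUTATION_COLUMNS = ("sample_id", "gene", "chrom", "pos", "ref_count", "alt_count")
SNP_COLUMNS = ("sample_id", "gene", "chrom", "pos", "ref_count", "alt_count")
COPY_NUMBER_COLUMNS = ("sample_id", "gene", "log_ratio")


def _read_tsv(path: Union[str, Path], required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    return df


def _parse_int(value: str, column: str, row: int) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise ValidationError(
            f"row {row}: column {column!r} must be an integer, got {value!r}"
        ) from None


def _parse_float(value, column: str, row: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(
            f"row {row}: column {column!r} must be numeric, got {value!r}"
        ) from None


def _is_na(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or (
        isinstance(value, str) and value.strip() in ("", "NA", "NaN", "nan", ".")
    )


def read_mutation_table(
    path: Union[str, Path],
    dialect: str = "tsv",
    sample: Optional[str] = None,
) -> list[SomaticMutation]:
    """Read somatic mutations from TSV (canonical) or a VCF with AD fields.

    VAF is recomputed from counts; a supplied ``vaf`` column disagreeing with
    ``alt/(alt+ref)`` by more than 1e-6 raises (stale-column guard). For
    ``dialect="vcf"`` the ``sample`` selector is required.
    """
    if dialect == "vcf":
        return _read_mutation_vcf(path, sample)
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")

    df = _read_tsv(path, MUTATION_COLUMNS)
    records: list[SomaticMutation] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        ref = _parse_int(row.ref_count, "ref_count", i)
        alt = _parse_int(row.alt_count, "alt_count", i)
        if ref < 0 or alt < 0:
            raise ValidationError(f"row {i}: negative read count ({ref}, {alt})")
        supplied_vaf = getattr(row, "vaf", None)
        if alt + ref > 0:
            vaf = alt / (alt + ref)
            if not _is_na(supplied_vaf):
                sv = _parse_float(supplied_vaf, "vaf", i)
                if not 0.0 <= sv <= 1.0:
                    raise ValidationError(f"row {i}: vaf {sv} outside [0,1]")
                if abs(sv - vaf) > _VAF_TOL:
                    raise ValidationError(
                        f"row {i}: supplied vaf {sv} disagrees with counts "
                        f"({alt}/{alt + ref} = {vaf:.8f})"
                    )
        else:
            if _is_na(supplied_vaf):
                raise ValidationError(
                    f"row {i}: zero depth and no vaf column to fall back on"
                )
            vaf = _parse_float(supplied_vaf, "vaf", i)
            if not 0.0 <= vaf <= 1.0:
                raise ValidationError(f"row {i}: vaf {vaf} outside [0,1]")
        lr = getattr(row, "gene_log_ratio", None)
        log_ratio = None if _is_na(lr) else _parse_float(lr, "gene_log_ratio", i)
        status = getattr(row, "somatic_status", "somatic_confirmed")
        if _is_na(status):
            status = "somatic_confirmed"
        if status not in ("somatic_confirmed", "excluded"):
            raise ValidationError(f"row {i}: unknown somatic_status {status!r}")
        try:
            records.append(
                SomaticMutation(
                    sample_id=str(row.sample_id),
                    gene=str(row.gene),
                    chrom=str(row.chrom),
                    pos=_parse_int(row.pos, "pos", i),
                    ref_count=ref,
                    alt_count=alt,
                    vaf=vaf,
                    gene_log_ratio=log_ratio,
                    somatic_status=status,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
    if not records:
        logger.warning("%s: no mutation rows", Path(path).name)
    return records


def _read_mutation_vcf(path: Union[str, Path], sample: Optional[str]) -> list[SomaticMutation]:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - cyvcf2 is an optional extra
        raise ImportError("VCF ingestion requires cyvcf2") from exc
    if sample is None:
        raise ValueError("dialect='vcf' requires a sample selector")
    vcf = VCF(str(path))
    if sample not in vcf.samples:
        raise SchemaError(f"sample {sample!r} not present in VCF ({vcf.samples})")
    idx = vcf.samples.index(sample)
    records: list[SomaticMutation] = []
    for i, variant in enumerate(vcf, start=1):
        ad = variant.format("AD")
        if ad is None:
            raise SchemaError(f"variant {i}: VCF lacks per-sample AD field")
        ref, alt = int(ad[idx][0]), int(ad[idx][1])
        gene = variant.INFO.get("GENE", ".")
        lr = variant.INFO.get("GLR")
        status = variant.INFO.get("STATUS", "somatic_confirmed")
        if ref + alt == 0:
            raise ValidationError(f"variant {i}: zero allele depth for {sample}")
        records.append(
            SomaticMutation(
                sample_id=sample,
                gene=str(gene),
                chrom=str(variant.CHROM),
                pos=int(variant.POS),
                ref_count=ref,
                alt_count=alt,
                vaf=alt / (alt + ref),
                gene_log_ratio=None if lr is None else float(lr),
                somatic_status=str(status),
            )
        )
    return records


def read_snp_table(path: Union[str, Path]) -> list[GermlineSNP]:
    """Read heterozygous germline SNPs; duplicate (chrom,pos) per sample raises."""
    df = _read_tsv(path, SNP_COLUMNS)
    seen: set[tuple[str, str, int]] = set()
    records: list[GermlineSNP] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        pos = _parse_int(row.pos, "pos", i)
        key = (str(row.sample_id), str(row.chrom), pos)
        if key in seen:
            raise ValidationError(
                f"row {i}: duplicate SNP at {row.chrom}:{pos} for sample {row.sample_id}"
            )
        seen.add(key)
        try:
            records.append(
                GermlineSNP(
                    sample_id=str(row.sample_id),
                    gene=str(row.gene),
                    chrom=str(row.chrom),
                    pos=pos,
                    ref_count=_parse_int(row.ref_count, "ref_count", i),
                    alt_count=_parse_int(row.alt_count, "alt_count", i),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
    if not records:
        logger.warning("%s: no SNP rows", Path(path).name)
    return records


def read_copy_number_table(
    path: Union[str, Path], ar_gene: str = "AR"
) -> list[GeneCopyNumber]:
    """Read gene-level log-ratios; rows with NA log_ratio are dropped (logged)."""
    df = _read_tsv(path, COPY_NUMBER_COLUMNS)
    records: list[GeneCopyNumber] = []
    seen: set[tuple[str, str]] = set()
    n_dropped = 0
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if _is_na(row.log_ratio):
            n_dropped += 1
            continue
        key = (str(row.sample_id), str(row.gene))
        if key in seen:
            raise ValidationError(
                f"row {i}: duplicate copy-number record for {key[1]} in {key[0]}"
            )
        seen.add(key)
        lr = _parse_float(row.log_ratio, "log_ratio", i)
        if not np.isfinite(lr):
            raise ValidationError(f"row {i}: non-finite log_ratio")
        records.append(
            GeneCopyNumber(
                sample_id=str(row.sample_id),
                gene=str(row.gene),
                log_ratio=lr,
                is_ar=str(row.gene).upper() == ar_gene.upper(),
            )
        )
    if n_dropped:
        logger.warning(
            "%s: dropped %d rows with missing log_ratio", Path(path).name, n_dropped
        )
    return records


# ---------------------------------------------------------------------------
# clinical cohort


def load_schema(path: Union[str, Path]) -> dict[str, FeatureSpec]:
    """Load a clinical feature schema from YAML.

    Expected layout::

        features:
          cfdna_conc: {kind: continuous, monotone: 1}
          liver_mets: {kind: binary}
          site: {kind: categorical, levels: [bone, node, liver]}
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "features" not in raw:
        raise SchemaError("schema YAML must contain a 'features' mapping")
    specs: dict[str, FeatureSpec] = {}
    for name, entry in raw["features"].items():
        entry = entry or {}
        specs[name] = FeatureSpec(
            name=name,
            kind=entry.get("kind", "continuous"),
            levels=tuple(entry.get("levels", ())),
            monotone=int(entry.get("monotone", 0)),
        )
    return specs


def read_clinical_table(
    path: Union[str, Path],
    schema: dict[str, FeatureSpec],
    label_column: str = "ctdna_fraction",
    na_values: Sequence[str] = ("", "NA"),
) -> CohortTable:
    """Read a patient x clinical-feature CSV into a validated CohortTable.

    Missing cells (empty string or a declared sentinel) become NaN in the
    table — never imputed here. Categorical cells must match a declared
    level (stored as float level codes); duplicate patient_ids raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, dtype=str, keep_default_na=False, na_values=list(na_values)
    )
    if "patient_id" not in df.columns:
        raise SchemaError(f"{path.name}: missing required column 'patient_id'")
    for name in schema:
        if name not in df.columns:
            raise SchemaError(f"{path.name}: missing declared feature column {name!r}")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValidationError(f"duplicate patient_id {dup!r}")

    data = pd.DataFrame(index=pd.Index(df["patient_id"], name="patient_id"))
    for name, spec in schema.items():
        col = df[name]
        out = np.full(len(col), np.nan)
        for i, value in enumerate(col):
            if _is_na(value):
                continue
            if spec.kind == "categorical":
                if value not in spec.levels:
                    raise ValidationError(
                        f"row {i + 1}: undeclared level {value!r} for feature {name!r} "
                        f"(declared: {list(spec.levels)})"
                    )
                out[i] = spec.levels.index(value)
            elif spec.kind == "binary":
                v = _parse_float(value, name, i + 1)
                if v not in (0.0, 1.0):
                    raise ValidationError(
                        f"row {i + 1}: binary feature {name!r} must be 0/1, got {value!r}"
                    )
                out[i] = v
            else:
                out[i] = _parse_float(value, name, i + 1)
        data[name] = out

    label = None
    if label_column in df.columns:
        lab = np.full(len(df), np.nan)
        for i, value in enumerate(df[label_column]):
            if not _is_na(value):
                lab[i] = _parse_float(value, label_column, i + 1)
        label = pd.Series(lab, index=data.index, name=label_column)
    return CohortTable(data=data, features=dict(schema), label=label)


# ---------------------------------------------------------------------------
# writers (round-trip companions of the readers)


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    return repr(float(value))


def write_mutation_table(records: Sequence[SomaticMutation], path: Union[str, Path]) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "gene": m.gene,
            "chrom": m.chrom,
            "pos": m.pos,
            "ref_count": m.ref_count,
            "alt_count": m.alt_count,
            "vaf": repr(float(m.vaf)),
            "gene_log_ratio": _fmt(m.gene_log_ratio),
            "somatic_status": m.somatic_status,
        }
        for m in records
    ]
    cols = list(MUTATION_COLUMNS) + ["vaf", "gene_log_ratio", "somatic_status"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_snp_table(records: Sequence[GermlineSNP], path: Union[str, Path]) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "gene": s.gene,
            "chrom": s.chrom,
            "pos": s.pos,
            "ref_count": s.ref_count,
            "alt_count": s.alt_count,
        }
        for s in records
    ]
    pd.DataFrame(rows, columns=list(SNP_COLUMNS)).to_csv(path, sep="\t", index=False)


def write_copy_number_table(
    records: Sequence[GeneCopyNumber], path: Union[str, Path]
) -> None:
    rows = [
        {"sample_id": r.sample_id, "gene": r.gene, "log_ratio": repr(float(r.log_ratio))}
        for r in records
    ]
    pd.DataFrame(rows, columns=list(COPY_NUMBER_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def write_clinical_table(table: CohortTable, path: Union[str, Path]) -> None:
    """Write a CohortTable back to CSV (categorical codes mapped to levels)."""
    out = pd.DataFrame(index=table.data.index)
    for name, spec in table.features.items():
        col = table.data[name]
        if spec.kind == "categorical":
            out[name] = [
                "" if math.isnan(v) else spec.levels[int(v)] for v in col
            ]
        elif spec.kind == "binary":
            out[name] = ["" if math.isnan(v) else str(int(v)) for v in col]
        else:
            out[name] = ["" if math.isnan(v) else repr(float(v)) for v in col]
    if table.label is not None:
        out[table.label.name] = [
            "" if math.isnan(v) else repr(float(v)) for v in table.label
        ]
    out.to_csv(path, index=True)


def write_estimates(estimates, path: Union[str, Path]) -> None:
    """Write per-sample estimator output as TSV."""
    rows = [
        {
            "sample_id": e.sample_id,
            "fraction": repr(e.fraction),
            "tier": e.tier,
            "category": e.category,
            "n_eligible_mutations": e.n_eligible_mutations,
            "n_eligible_genes": e.n_eligible_genes,
            "concordance_flag": "NA" if e.concordance_flag is None else e.concordance_flag,
        }
        for e in estimates
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
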