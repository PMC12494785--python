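"""Canonical table dialects and readers/writers.

All pipeline tables are tab-separated with a one-line header; coordinates
are 1-based inclusive; VAF-like columns are fractions in [0, 1] internally.
A table may declare a ``vaf_units`` column with values ``fraction`` or
``percent``; percent values are normalized to fractions on read.  An
optional VCF adapter maps single-sample FORMAT fields (AF -> vaf, AD ->
alt_consensus_reads) onto the variants dialect.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError

SCHEMAS: dict[str, list[str]] = {
    "patients": ["patient_id", "arm", "os_months", "death_event", "age_years", "ecog",
                 "m_stage", "regimen", "ca19_9", "cea", "crp", "albumin"],
    "samples": ["patient_id", "sample_id", "timepoint", "days_from_baseline",
                "cfdna_conc", "assessable"],
    "variants": ["patient_id", "sample_id", "compartment", "timepoint", "chrom", "pos",
                 "ref", "alt", "gene", "vaf", "alt_consensus_reads", "n_callers",
                 "impact", "canonical", "detected_in_matched_normal", "kras_hotspot",
                 "confirmed_elsewhere"],
    "copy_states": ["patient_id", "chrom", "pos", "cn", "m", "amplified", "source"],
    "tissue_variants": ["patient_id", "sample_id", "compartment", "chrom", "pos", "ref",
                        "alt", "gene", "vaf", "n_callers", "impact",
                        "confirmed_elsewhere"],
    "workups": ["patient_id", "workup_id", "days_from_baseline", "disease_status"],
    "germline": ["patient_id", "sample_id", "compartment", "chrom", "pos", "ref", "alt",
                 "gene", "vaf", "impact", "gnomad_af", "clinvar_class",
                 "clinvar_conflict", "neoplastic_association",
                 "called_by_primary_caller"],
}

BOOL_COLUMNS = {
    "death_event", "assessable", "canonical", "detected_in_matched_normal",
    "kras_hotspot", "confirmed_elsewhere", "amplified", "clinvar_conflict",
    "neoplastic_association", "called_by_primary_caller", "truth_high",
    "exclude_from_search", "disomic_fallback",
}

VAF_COLUMNS = {"vaf", "normal_vaf", "gnomad_af", "ctdna_frac", "maf"}

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def _coerce_bool(series: pd.Series, column: str) -> pd.Series:
    if series.dtype == bool:
        return series
    def conv(x):
        if isinstance(x, (bool, np.bool_)):
            return bool(x)
        s = str(x).strip().lower()
        if s in _TRUE:
            return True
        if s in _FALSE:
            return False
        raise SchemaError(f"column {column!r}: cannot interpret {x!r} as a flag")
    return series.map(conv)


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read and validate one canonical TSV table.

    Required columns come from the named schema; unknown columns are
    preserved.  Flag columns are coerced to booleans and, when a
    ``vaf_units`` column is present, VAF-like columns are normalized to
    fractions.
    """
    if schema_name not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema_name!r}; known: {sorted(SCHEMAS)}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SCHEMAS[schema_name] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing} "
                          f"for schema {schema_name!r}")
    for col in df.columns:
        if col in BOOL_COLUMNS:
            df[col] = _coerce_bool(df[col], col)
    if "vaf_units" in df.columns:
        units = df["vaf_units"].astype(str).str.lower()
        bad = ~units.isin(["fraction", "percent"])
        if bad.any():
            raise SchemaError(f"{path.name}: vaf_units must be 'fraction' or 'percent', "
                              f"got {sorted(units[bad].unique())}")
        percent = units == "percent"
        for col in VAF_COLUMNS & set(df.columns):
            df.loc[percent, col] = df.loc[percent, col] / 100.0
        df = df.drop(columns=["vaf_units"])
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical TSV (deterministic byte-for-byte for a given frame)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")


def read_vcf_variants(path: str | Path, patient_id: str, sample_id: str,
                      compartment: str = "plasma", timepoint: str = "BL") -> pd.DataFrame:
    """Adapt a single-sample VCF to the variants dialect.

    FORMAT/AF maps to ``vaf`` and the alt count of FORMAT/AD to
    ``alt_consensus_reads``.  Annotation flags the dialect needs but a VCF
    lacks (impact, canonical, hotspot and confirmation flags) default to
    permissive values and should be overridden from curation tables.
    """
    from cyvcf2 import VCF  # optional dependency

    rows = []
    vcf = VCF(str(path))
    for rec in vcf:
        af = rec.format("AF")
        ad = rec.format("AD")
        vaf = float(af[0][0]) if af is not None else np.nan
        alt_reads = int(ad[0][-1]) if ad is not None else 0
        for alt in rec.ALT:
            rows.append([patient_id, sample_id, compartment, timepoint,
                         str(rec.CHROM), int(rec.POS), rec.REF, alt,
                         rec.INFO.get("GENE", ""), vaf, alt_reads, 1,
                         "moderate", True, False, False, False])
    return pd.DataFrame(rows, columns=SCHEMAS["variants"])
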