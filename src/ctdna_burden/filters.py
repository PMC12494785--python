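"""Variant-inclusion rules for tissue, germline and plasma call tables.

Three pure filters over pandas call tables:

* tissue somatic calls: concordance across callers, impact class and a VAF
  floor, with a rescue branch for variants corroborated in ctDNA or another
  tumor sample of the same patient;
* germline calls: caller, impact, VAF and population-frequency gates, plus
  the stricter clinical reporting subset (ClinVar pathogenic or likely
  pathogenic, conflict-free, neoplastic association);
* plasma (ctDNA) calls: duplex-consensus read support, matched-normal
  exclusion and canonical-transcript annotation, with a rescue branch for
  variants confirmed in tissue or another plasma sample of the patient, or
  sitting on KRAS hotspot codons (G12/G13/Q61), where sub-LOD support is
  accepted.

Boundary semantics follow the wording of the rules: "above 3%" and
"above 25%" are strict inequalities, "a minimum of five reads" is
inclusive.  All filters are idempotent, order-independent and monotone in
their thresholds.
"""

from __future__ import annotations

import logging

import pandas as pd

from .exceptions import DomainError

logger = logging.getLogger(__name__)

IMPACTS_KEPT = ("high", "moderate")


def _require_compartment(calls: pd.DataFrame, expected: str) -> None:
    if len(calls) and "compartment" in calls.columns:
        bad = calls.loc[calls["compartment"] != expected, "compartment"].unique()
        if len(bad):
            raise DomainError(
                f"expected only {expected!r} calls, found compartment(s) {list(bad)}"
            )


def filter_tissue_somatic(calls: pd.DataFrame, *, min_callers: int = 2,
                          min_vaf: float = 0.03) -> pd.DataFrame:
    """Tissue somatic inclusion rule.

    Keep a call iff it was made by ``min_callers`` or more callers, carries
    a high or moderate impact and a VAF strictly above ``min_vaf`` — or, to
    avoid manufacturing false heterogeneity, if the same variant was
    detected in ctDNA or another tumor sample of the patient
    (``confirmed_elsewhere``), in which case a single caller suffices but
    the impact requirement stands.
    """
    _require_compartment(calls, "tissue")
    if len(calls) == 0:
        return calls.copy()
    impact_ok = calls["impact"].isin(IMPACTS_KEPT)
    primary = (calls["n_callers"] >= min_callers) & impact_ok & (calls["vaf"] > min_vaf)
    rescue = calls["confirmed_elsewhere"].astype(bool) & (calls["n_callers"] >= 1) & impact_ok
    n_rescued = int((rescue & ~primary).sum())
    if n_rescued:
        logger.warning("tissue filter: %d call(s) rescued via cross-sample confirmation",
                       n_rescued)
    return calls[primary | rescue].copy()


def filter_germline(calls: pd.DataFrame, *, min_vaf: float = 0.25,
                    max_gnomad_af: float = 0.03) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Germline analysis and reporting sets.

    Analysis set: primary-caller calls with high/moderate impact, VAF
    strictly above ``min_vaf`` and a gnomAD allele frequency strictly below
    ``max_gnomad_af``.  Reported set: the analysis subset additionally
    classified pathogenic or likely pathogenic in ClinVar, without
    conflicting interpretations and with a neoplastic association.
    """
    _require_compartment(calls, "normal")
    if len(calls) == 0:
        return calls.copy(), calls.copy()
    if calls["gnomad_af"].isna().any():
        bad = calls.index[calls["gnomad_af"].isna()].tolist()
        raise DomainError(f"gnomad_af missing for row(s) {bad}; explicit nulls not allowed")
    analysis_mask = (
        calls["called_by_primary_caller"].astype(bool)
        & calls["impact"].isin(IMPACTS_KEPT)
        & (calls["vaf"] > min_vaf)
        & (calls["gnomad_af"] < max_gnomad_af)
    )
    analysis = calls[analysis_mask]
    reported = analysis[
        analysis["clinvar_class"].isin(("pathogenic", "likely_pathogenic"))
        & ~analysis["clinvar_conflict"].astype(bool)
        & analysis["neoplastic_association"].astype(bool)
    ]
    return analysis.copy(), reported.copy()


def filter_ctdna(calls: pd.DataFrame, *, min_consensus_reads: int = 5,
                 rescue_min_reads: int = 1, normal_override_vaf: float = 0.05,
                 normal_override_max_normal_vaf: float = 0.002) -> pd.DataFrame:
    """Plasma (ctDNA) inclusion rule.

    Keep a call iff it is supported by at least ``min_consensus_reads``
    duplex-consensus reads, shows no evidence in the matched normal and is
    annotated canonical — or, via the rescue branch, if it is confirmed in
    matched tumor tissue or another plasma sample of the same patient, or
    lies on a KRAS hotspot codon, with support down to ``rescue_min_reads``
    (the limit of detection is not modelled as a VAF, so corroborated
    variants are accepted on minimal consensus support).

    Matched-normal override: a variant with evidence in the normal sample
    is still retained when its plasma VAF exceeds ``normal_override_vaf``
    while the normal VAF stays below ``normal_override_max_normal_vaf`` —
    the trace in the normal is then more plausibly contamination or clonal
    hematopoiesis background than a germline or artifactual call.  The
    override requires a ``normal_vaf`` column; without it, normal-detected
    calls are always dropped.
    """
    _require_compartment(calls, "plasma")
    if len(calls) == 0:
        return calls.copy()
    in_normal = calls["detected_in_matched_normal"].astype(bool)
    if "normal_vaf" in calls.columns:
        override = (
            in_normal
            & (calls["vaf"] > normal_override_vaf)
            & (calls["normal_vaf"].fillna(1.0) < normal_override_max_normal_vaf)
        )
    else:
        override = pd.Series(False, index=calls.index)
    normal_clear = ~in_normal | override
    n_override = int(override.sum())
    if n_override:
        logger.warning("ctDNA filter: %d normal-detected call(s) retained via VAF override",
                       n_override)
    primary = (
        (calls["alt_consensus_reads"] >= min_consensus_reads)
        & normal_clear
        & calls["canonical"].astype(bool)
    )
    corroborated = calls["confirmed_elsewhere"].astype(bool) | calls["kras_hotspot"].astype(bool)
    rescue = corroborated & (calls["alt_consensus_reads"] >= rescue_min_reads) & normal_clear
    n_rescued = int((rescue & ~primary).sum())
    if n_rescued:
        logger.warning("ctDNA filter: %d sub-threshold call(s) rescued "
                       "(tissue/plasma confirmation or KRAS hotspot)", n_rescued)
    return calls[primary | rescue].copy()
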