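"""Plasma-tissue mutational concordance and temporal heterogeneity.

Per patient, all filtered variant calls are arranged into a presence matrix
(variant identity x sample) with cells ``detected`` / ``not_detected`` /
``not_assessable``.  Absences in a sample whose tumor content is below the
detectability floor cannot be distinguished from limited assay sensitivity,
so those cells are flagged ``not_assessable`` and never create
discrepancies.  Variant identity is the genomic change (chrom, pos, ref,
alt), keeping distinct variants in the same gene separate.

Patients enter the plasma-vs-tissue comparison only when at least one
plasma sample has a ctDNA fraction strictly above 2% (the floor is
configurable); discrepancies are then variants seen in one compartment and
absent from every assessable sample of the other.  Temporal heterogeneity
counts plasma-to-plasma disparities between timepoints after the same
abundance suppression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .exceptions import DomainError, SchemaError

DETECTED = "detected"
NOT_DETECTED = "not_detected"
NOT_ASSESSABLE = "not_assessable"

#: therapies approved in other solid cancers for alterations this panel
#: covers; emitted in reports for orientation only, no clinical authority
ACTIONABILITY = (
    ("KRAS", "G12C", "sotorasib"),
    ("BRCA1", None, "olaparib"),
    ("BRCA2", None, "olaparib"),
    ("PIK3CA", None, "alpelisib"),
)


def variant_key(row: pd.Series) -> str:
    return f"{row['gene']}|{row['chrom']}:{int(row['pos'])}:{row['ref']}>{row['alt']}"


@dataclass
class PresenceMatrix:
    """Variant-by-sample detection matrix for one patient."""

    patient_id: str
    matrix: pd.DataFrame = field(repr=False)  # rows: variant keys, cols: sample ids
    plasma_samples: list[str] = field(default_factory=list)
    tissue_samples: list[str] = field(default_factory=list)
    sample_fracs: dict[str, float] = field(default_factory=dict)
    detect_floor: float = 0.02


def build_presence_matrix(plasma_calls: pd.DataFrame, tissue_calls: pd.DataFrame,
                          samples: pd.DataFrame, patient_id: str,
                          detect_floor: float = 0.02) -> PresenceMatrix:
    """Assemble the union of filtered variants across both compartments.

    ``samples`` must be quantified plasma samples carrying ``ctdna_frac``;
    tissue tumor content is read from an optional ``tumor_fraction`` column
    on the tissue calls (absent means assessable).  Rows are ordered by
    (gene, coordinate), plasma columns by sampling day then tissue columns.
    """
    p = plasma_calls[plasma_calls["patient_id"] == patient_id]
    t = tissue_calls[tissue_calls["patient_id"] == patient_id] if len(tissue_calls) else tissue_calls
    srows = samples[samples["patient_id"] == patient_id]
    if "days_from_baseline" in srows.columns:
        srows = srows.sort_values("days_from_baseline")
    plasma_ids = list(srows["sample_id"])
    tissue_ids = sorted(t["sample_id"].unique()) if len(t) else []

    fracs: dict[str, float] = {}
    for _, s in srows.iterrows():
        fracs[s["sample_id"]] = float(s["ctdna_frac"]) if pd.notna(s["ctdna_frac"]) else float("nan")
    if len(t) and "tumor_fraction" in t.columns:
        for sid, d in t.groupby("sample_id"):
            fracs[sid] = float(d["tumor_fraction"].iloc[0])

    calls = pd.concat([p, t]) if len(t) else p.copy()
    if len(calls):
        dup = calls.assign(key=calls.apply(variant_key, axis=1))
        conflict = (dup.groupby(["key", "sample_id"])["vaf"].nunique() > 1)
        if conflict.any():
            raise SchemaError(
                f"conflicting VAFs for duplicate (variant, sample) rows: "
                f"{conflict[conflict].index.tolist()}"
            )
        idx = (dup[["key", "gene", "chrom", "pos"]]
               .drop_duplicates("key")
               .sort_values(["gene", "chrom", "pos"])["key"].tolist())
        detected_pairs = set(zip(dup["key"], dup["sample_id"]))
    else:
        idx, detected_pairs = [], set()

    cols = plasma_ids + tissue_ids
    mat = pd.DataFrame(NOT_DETECTED, index=idx, columns=cols)
    for key, sid in detected_pairs:
        if sid in mat.columns:
            mat.loc[key, sid] = DETECTED
    # absences in low-abundance samples are uninformative; tissue samples
    # without a tumor-content estimate stay assessable
    for sid in cols:
        if sid not in fracs:
            continue
        frac = fracs[sid]
        if pd.isna(frac) or frac < detect_floor:
            col = mat[sid]
            mat.loc[col == NOT_DETECTED, sid] = NOT_ASSESSABLE
    # samples that were never assessable at all
    if "ctdna_status" in srows.columns:
        for _, s in srows.iterrows():
            if s["ctdna_status"] == "not_assessable":
                mat[s["sample_id"]] = NOT_ASSESSABLE
    return PresenceMatrix(patient_id=patient_id, matrix=mat,
                          plasma_samples=plasma_ids, tissue_samples=tissue_ids,
                          sample_fracs=fracs, detect_floor=detect_floor)


def eligible_for_comparison(pm: PresenceMatrix, min_frac: float = 0.02) -> bool:
    """True iff at least one plasma sample has a ctDNA fraction strictly
    above ``min_frac``; low-abundance patients would only produce
    pseudo-discrepancies."""
    fracs = [pm.sample_fracs.get(s) for s in pm.plasma_samples]
    fracs = [f for f in fracs if f is not None and pd.notna(f)]
    return bool(fracs) and max(fracs) > min_frac


def find_discrepancies(pm: PresenceMatrix) -> list[tuple[str, str]]:
    """Variants private to one compartment, after abundance suppression.

    A variant is ``plasma_only`` when detected in at least one plasma
    sample, absent from every assessable tissue sample, and at least one
    tissue sample was assessable for it (symmetrically for
    ``tissue_only``).  Requires an eligible matrix.
    """
    if not eligible_for_comparison(pm, pm.detect_floor):
        raise DomainError(
            f"patient {pm.patient_id} has no plasma sample above the "
            f"{pm.detect_floor:.0%} eligibility floor"
        )
    out = []
    m = pm.matrix
    for key in m.index:
        plasma = m.loc[key, pm.plasma_samples] if pm.plasma_samples else pd.Series(dtype=object)
        tissue = m.loc[key, pm.tissue_samples] if pm.tissue_samples else pd.Series(dtype=object)
        p_det = (plasma == DETECTED).any()
        t_det = (tissue == DETECTED).any()
        p_assessable = (plasma != NOT_ASSESSABLE).any()
        t_assessable = (tissue != NOT_ASSESSABLE).any()
        if p_det and not t_det and t_assessable:
            out.append((key, "plasma_only"))
        elif t_det and not p_det and p_assessable:
            out.append((key, "tissue_only"))
    return out


def temporal_heterogeneity(pm: PresenceMatrix) -> int | None:
    """Count plasma-to-plasma disparities across timepoints.

    A variant contributes when it is detected at one plasma timepoint and
    confidently absent (assessable yet not detected) at another.  ``None``
    when fewer than two plasma samples exist.
    """
    if len(pm.plasma_samples) < 2:
        return None
    count = 0
    m = pm.matrix[pm.plasma_samples]
    for key in m.index:
        row = m.loc[key]
        if (row == DETECTED).any() and (row == NOT_DETECTED).any():
            count += 1
    return count


def annotate_actionability(variants: pd.DataFrame) -> pd.DataFrame:
    """Static lookup of targeted agents approved in other solid tumors.

    KRAS matches only on the G12C protein change (requires an optional
    ``protein_change`` column); BRCA1/2 and PIK3CA match on the gene.
    """
    rows = []
    seen = set()
    for _, v in variants.iterrows():
        for gene, change, agent in ACTIONABILITY:
            if v["gene"] != gene:
                continue
            if change is not None:
                if str(v.get("protein_change", "")) != change:
                    continue
            key = (v["patient_id"], variant_key(v), agent)
            if key in seen:
                continue
            seen.add(key)
            rows.append([v["patient_id"], v["gene"], variant_key(v), agent])
    return pd.DataFrame(rows, columns=["patient_id", "gene", "variant", "agent"])
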