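"""Tumor-fraction and absolute-burden estimation from plasma variant calls.

The tumor-derived fraction of cell-free DNA (the ctDNA fraction) is anchored
on the maximum non-amplified variant allele frequency (MAF) observed in a
plasma sample.  For a clonal variant sitting on a locus with ``CN`` total
allele copies of which ``M`` are mutated, a mixture of tumor DNA (fraction
``f``) and diploid non-tumor DNA yields an allele frequency of

    VAF = M * f / (CN * f + 2 * (1 - f))

Inverting this forward model at the anchor locus gives the copy-number
corrected tumor fraction

    ctDNA_frac = 2 / (M / MAF - CN + 2)

When no allelic-composition call covers the anchor locus (typically because
the tumor fraction is too low for copy-number analysis), a disomic
background with one mutated allele (CN = 2, M = 1) is assumed, which reduces
the estimate to 2 * MAF.

Absolute circulating tumor burden is expressed as mutated genome
equivalents (mGE) per ml plasma, taking 6 pg of DNA per diploid genome:

    mGE/ml = ctDNA_frac * cfDNA_conc[ng/ml] * 1000 / 6
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import DomainError

logger = logging.getLogger(__name__)

#: picograms of DNA in one diploid human genome
PG_PER_DIPLOID_GENOME = 6.0

#: default total-copy threshold above which a locus is treated as amplified
#: when the upstream copy-number caller did not set an explicit flag
DEFAULT_AMPLIFIED_CN = 5


def _check_cn_m(cn: float, m: float) -> None:
    if cn < 1 or m < 1 or m > cn:
        raise DomainError(f"invalid allelic composition CN={cn}, M={m}; need 1 <= M <= CN")


def expected_vaf(frac: float, cn: int = 2, m: int = 1) -> float:
    """Allele frequency of a clonal variant at tumor fraction ``frac``.

    Forward model: VAF = M*f / (CN*f + 2*(1-f)).  Monotone increasing in
    ``frac``; equals 0 at frac=0 and M/CN at frac=1.
    """
    _check_cn_m(cn, m)
    if not 0.0 <= frac <= 1.0:
        raise DomainError(f"tumor fraction must lie in [0, 1], got {frac}")
    denom = cn * frac + 2.0 * (1.0 - frac)
    return m * frac / denom


def msf_forward(vaf: float, cn: int, m: int, frac: float) -> float:
    """Mutated sample fraction implied by a VAF at a known tumor fraction.

    MSF = VAF * (CN*frac + 2*(1-frac)) / M.  For a clonal mutation
    (MSF == frac) this is the inverse companion of :func:`ctdna_fraction`
    and serves as its roundtrip oracle.
    """
    if m == 0:
        raise DomainError("M = 0: a variant needs at least one mutated allele")
    _check_cn_m(cn, m)
    return vaf * (cn * frac + 2.0 * (1.0 - frac)) / m


def ctdna_fraction(maf: float, cn: int = 2, m: int = 1, *, clamp: bool = True,
                   locus: str | None = None) -> float:
    """Copy-number corrected ctDNA fraction from the anchor MAF.

    Parameters
    ----------
    maf
        Maximum non-amplified variant allele frequency, a fraction in (0, 1].
    cn, m
        Total and mutated allele copies at the anchor locus.  Callers with
        no copy-number information pass the disomic default (2, 1).
    clamp
        Clamp results above 1 (sampling noise pushing the VAF past the
        theoretical pure-tumor maximum) down to 1.0, with a warning.
    """
    _check_cn_m(cn, m)
    if not 0.0 < maf <= 1.0:
        raise DomainError(f"MAF must lie in (0, 1], got {maf}")
    denom = m / maf - cn + 2.0
    if denom <= 0:
        where = f" at locus {locus}" if locus else ""
        raise DomainError(
            f"MAF {maf} is inconsistent with allelic composition CN={cn}, M={m}{where}"
        )
    frac = 2.0 / denom
    if frac > 1.0:
        if not clamp:
            return frac
        logger.warning(
            "ctDNA fraction %.4f exceeds 1 (MAF=%.4f, CN=%d, M=%d)%s; clamped to 1.0",
            frac, maf, cn, m, f" at locus {locus}" if locus else "",
        )
        frac = 1.0
    return frac


def mge_per_ml(frac: float, cfdna_conc: float) -> float:
    """Mutated genome equivalents per ml plasma.

    ``frac * cfdna_conc * 1000 / 6`` with the concentration in ng/ml; the
    constant 6 pg is the mass of one diploid genome, so 1 ng of pure tumor
    DNA corresponds to ~166.7 genome copies.
    """
    if not 0.0 <= frac <= 1.0:
        raise DomainError(f"tumor fraction must lie in [0, 1], got {frac}")
    if cfdna_conc < 0:
        raise DomainError(f"cfDNA concentration must be non-negative, got {cfdna_conc}")
    return frac * cfdna_conc * 1000.0 / PG_PER_DIPLOID_GENOME


@dataclass
class MafSelection:
    """The anchor variant chosen for tumor-fraction estimation."""

    maf: float
    chrom: Optional[str]
    pos: Optional[int]
    cn: int
    m: int
    amplified: bool
    disomic_fallback: bool

    @property
    def empty(self) -> bool:
        return self.chrom is None


_NO_MAF = MafSelection(0.0, None, None, 2, 1, False, False)


def _attach_copy_states(variants: pd.DataFrame, copy_states: Optional[pd.DataFrame],
                        amplified_cn_threshold: int) -> pd.DataFrame:
    v = variants.copy()
    keys = ["chrom", "pos"]
    if copy_states is not None and len(copy_states):
        cs = copy_states
        if "patient_id" in cs.columns and "patient_id" in v.columns:
            keys = ["patient_id", "chrom", "pos"]
        cs = cs.drop_duplicates(subset=keys)
        v = v.merge(cs[keys + ["cn", "m", "amplified"]], on=keys, how="left",
                    suffixes=("", "_cs"))
    else:
        v["cn"] = np.nan
        v["m"] = np.nan
        v["amplified"] = np.nan
    v["disomic_fallback"] = v["cn"].isna()
    v.loc[v["disomic_fallback"], "cn"] = 2
    v.loc[v["disomic_fallback"], "m"] = 1
    v["cn"] = v["cn"].astype(int)
    v["m"] = v["m"].astype(int)
    v["amplified"] = (
        v["amplified"].astype("boolean").fillna(False).astype(bool)
        | (v["cn"] >= amplified_cn_threshold)
    )
    return v


def select_maf(variants: pd.DataFrame, copy_states: Optional[pd.DataFrame] = None,
               amplified_cn_threshold: int = DEFAULT_AMPLIFIED_CN) -> MafSelection:
    """Pick the maximum non-amplified VAF and its allelic composition.

    Amplified loci are excluded from the anchor because amplification
    inflates the VAF beyond what the mixture model assumes.  If *every*
    candidate locus is amplified, the maximum VAF among the lowest-CN loci
    is used instead of declaring the sample not assessable (a warning is
    logged).  An empty input yields a zero MAF: the sample is ctDNA
    negative.
    """
    if variants is None or len(variants) == 0:
        return _NO_MAF
    v = _attach_copy_states(variants, copy_states, amplified_cn_threshold)
    v = v.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    pool = v[~v["amplified"]]
    if len(pool) == 0:
        min_cn = v["cn"].min()
        pool = v[v["cn"] == min_cn]
        logger.warning(
            "all %d candidate loci amplified; anchoring MAF on lowest-CN locus (CN=%d)",
            len(v), int(min_cn),
        )
    row = pool.loc[pool["vaf"].idxmax()]
    return MafSelection(
        maf=float(row["vaf"]),
        chrom=str(row["chrom"]),
        pos=int(row["pos"]),
        cn=int(row["cn"]),
        m=int(row["m"]),
        amplified=bool(row["amplified"]),
        disomic_fallback=bool(row["disomic_fallback"]),
    )


def quantify_samples(samples: pd.DataFrame, variants: pd.DataFrame,
                     copy_states: Optional[pd.DataFrame] = None,
                     amplified_cn_threshold: int = DEFAULT_AMPLIFIED_CN) -> pd.DataFrame:
    """Fill ctDNA status, fraction and mGE/ml for every plasma sample.

    ``variants`` must already have passed the plasma inclusion filter; a
    sample is ctDNA positive iff at least one of its variants survived.
    Samples flagged not assessable keep a ``not_assessable`` status with
    missing quantities.  Negative samples are quantified as exactly zero so
    that trajectories carry them at the floor rather than as gaps.
    """
    out = samples.copy()
    for col, default in [("ctdna_status", "negative"), ("maf", 0.0),
                         ("ctdna_frac", 0.0), ("mge_per_ml", 0.0),
                         ("disomic_fallback", False)]:
        out[col] = default
    assessable = out["assessable"].astype(bool) if "assessable" in out.columns \
        else pd.Series(True, index=out.index)
    by_sample = dict(tuple(variants.groupby("sample_id"))) if len(variants) else {}
    for idx, row in out.iterrows():
        if not assessable.loc[idx]:
            out.loc[idx, "ctdna_status"] = "not_assessable"
            out.loc[idx, ["maf", "ctdna_frac", "mge_per_ml"]] = np.nan
            continue
        sv = by_sample.get(row["sample_id"])
        if sv is None or len(sv) == 0:
            continue  # stays negative with zero burden
        sel = select_maf(sv, copy_states, amplified_cn_threshold)
        try:
            frac = ctdna_fraction(sel.maf, sel.cn, sel.m,
                                  locus=f"{sel.chrom}:{sel.pos}")
        except DomainError as err:
            raise DomainError(f"sample {row['sample_id']}: {err}") from err
        out.loc[idx, "ctdna_status"] = "positive"
        out.loc[idx, "maf"] = sel.maf
        out.loc[idx, "ctdna_frac"] = frac
        out.loc[idx, "mge_per_ml"] = mge_per_ml(frac, float(row["cfdna_conc"]))
        out.loc[idx, "disomic_fallback"] = sel.disomic_fallback
    return out
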