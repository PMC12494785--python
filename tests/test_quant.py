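"""Tumor-fraction algebra, MAF selection and per-sample quantification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ctdna_burden import (ctdna_fraction, expected_vaf, mge_per_ml, msf_forward,
                          select_maf, quantify_samples)
from ctdna_burden.exceptions import DomainError


@pytest.mark.parametrize("maf,cn,m,expected", [
    (0.25, 2, 1, 0.5),          # disomic het: 2/(4-2+2)
    (0.4, 1, 1, 2 / 3.5),       # LOH, mutant allele retained
    (0.5, 2, 1, 1.0),           # pure tumor het
    (1e-9, 2, 1, pytest.approx(2e-9, rel=1e-6)),  # vanishing MAF -> vanishing fraction
])
def test_ctdna_fraction_values(maf, cn, m, expected):
    assert ctdna_fraction(maf, cn, m) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("vaf,cn,m,frac,expected", [
    (0.25, 2, 1, 0.5, 0.5),
    (0.5, 2, 1, 1.0, 1.0),
    (0.0, 3, 2, 0.7, 0.0),
])
def test_msf_forward_values(vaf, cn, m, frac, expected):
    assert msf_forward(vaf, cn, m, frac) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("frac,cn,m,expected", [
    (0.0, 2, 1, 0.0),
    (1.0, 2, 1, 0.5),
    (0.5, 2, 1, 0.25),
])
def test_expected_vaf_values(frac, cn, m, expected):
    assert expected_vaf(frac, cn, m) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("frac,conc,expected", [
    (0.0, 50.0, 0.0),
    (0.06, 35.0, 350.0),
    (1.0, 6.0, 1000.0),
])
def test_mge_per_ml_values(frac, conc, expected):
    assert mge_per_ml(frac, conc) == pytest.approx(expected, abs=1e-12)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(frac=st.floats(1e-6, 1.0), cn=st.integers(1, 6), data=st.data())
def test_roundtrip_fraction_vaf(frac, cn, data):
    """Inverting the forward VAF model recovers the tumor fraction exactly."""
    m = data.draw(st.integers(1, cn))
    vaf = expected_vaf(frac, cn, m)
    assert ctdna_fraction(vaf, cn, m) == pytest.approx(frac, abs=1e-12)
    # the forward MSF map is the same identity seen from the other side
    assert msf_forward(vaf, cn, m, frac) == pytest.approx(frac, abs=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(vaf=st.floats(1e-6, 0.5))
def test_disomic_special_case(vaf):
    assert ctdna_fraction(vaf, 2, 1) == pytest.approx(2 * vaf, abs=1e-12)


def test_monotone_in_maf():
    mafs = np.linspace(0.01, 0.45, 40)
    fr = [ctdna_fraction(v, 3, 2) for v in mafs]
    assert np.all(np.diff(fr) > 0)


def test_mge_homogeneity():
    for f in (0.1, 0.37, 0.9):
        assert mge_per_ml(f, 42.0) == pytest.approx(f * mge_per_ml(1.0, 42.0))


def test_correction_only_matters_off_disomy():
    vaf = 0.12
    assert ctdna_fraction(vaf, 2, 1) == pytest.approx(2 * vaf)
    for cn, m in [(1, 1), (3, 1), (3, 2), (4, 2)]:
        assert ctdna_fraction(vaf, cn, m) != pytest.approx(2 * vaf)


@pytest.mark.parametrize("call,err", [
    (lambda: ctdna_fraction(0.0, 2, 1), DomainError),
    (lambda: ctdna_fraction(0.9, 4, 1), DomainError),   # denominator <= 0
    (lambda: expected_vaf(0.5, 2, 3), DomainError),     # m > cn
    (lambda: expected_vaf(0.5, 0, 0), DomainError),
    (lambda: msf_forward(0.2, 2, 0, 0.5), DomainError),
    (lambda: mge_per_ml(-0.1, 10), DomainError),
    (lambda: mge_per_ml(0.1, -10), DomainError),
])
def test_domain_errors(call, err):
    with pytest.raises(err):
        call()


def test_clamp_above_pure_tumor(caplog):
    # VAF above the theoretical maximum for (2,1) -> fraction clamps to 1
    with caplog.at_level("WARNING"):
        assert ctdna_fraction(0.6, 2, 1) == 1.0
    assert ctdna_fraction(0.6, 2, 1, clamp=False) > 1.0


def _vrow(sample, chrom, pos, vaf):
    return {"patient_id": "P1", "sample_id": sample, "chrom": chrom, "pos": pos,
            "ref": "A", "alt": "T", "gene": "G", "vaf": vaf}


class TestSelectMaf:
    def test_singleton(self):
        v = pd.DataFrame([_vrow("s", "1", 100, 0.10)])
        sel = select_maf(v)
        assert sel.maf == 0.10 and sel.disomic_fallback

    def test_amplified_excluded(self):
        v = pd.DataFrame([_vrow("s", "1", 100, 0.30), _vrow("s", "2", 200, 0.20)])
        cs = pd.DataFrame([
            {"patient_id": "P1", "chrom": "1", "pos": 100, "cn": 8, "m": 6, "amplified": True},
            {"patient_id": "P1", "chrom": "2", "pos": 200, "cn": 2, "m": 1, "amplified": False},
        ])
        sel = select_maf(v, cs)
        assert sel.maf == 0.20 and sel.chrom == "2"

    def test_cn_threshold_counts_as_amplified(self):
        v = pd.DataFrame([_vrow("s", "1", 100, 0.30), _vrow("s", "2", 200, 0.20)])
        cs = pd.DataFrame([
            {"patient_id": "P1", "chrom": "1", "pos": 100, "cn": 5, "m": 3, "amplified": False},
            {"patient_id": "P1", "chrom": "2", "pos": 200, "cn": 2, "m": 1, "amplified": False},
        ])
        assert select_maf(v, cs).maf == 0.20

    def test_all_amplified_falls_back_to_lowest_cn(self, caplog):
        v = pd.DataFrame([_vrow("s", "1", 100, 0.30), _vrow("s", "2", 200, 0.40)])
        cs = pd.DataFrame([
            {"patient_id": "P1", "chrom": "1", "pos": 100, "cn": 6, "m": 4, "amplified": True},
            {"patient_id": "P1", "chrom": "2", "pos": 200, "cn": 8, "m": 5, "amplified": True},
        ])
        with caplog.at_level("WARNING"):
            sel = select_maf(v, cs)
        assert sel.chrom == "1" and sel.maf == 0.30

    def test_empty_is_negative(self):
        sel = select_maf(pd.DataFrame(columns=["chrom", "pos", "vaf"]))
        assert sel.maf == 0.0 and sel.empty


class TestQuantifySamples:
    def _samples(self):
        return pd.DataFrame([
            {"patient_id": "P1", "sample_id": "S1", "timepoint": "BL",
             "days_from_baseline": 0, "cfdna_conc": 20.0, "assessable": True},
            {"patient_id": "P1", "sample_id": "S2", "timepoint": "1M",
             "days_from_baseline": 28, "cfdna_conc": 12.0, "assessable": True},
            {"patient_id": "P1", "sample_id": "S3", "timepoint": "3M",
             "days_from_baseline": 84, "cfdna_conc": 30.0, "assessable": False},
        ])

    def test_negative_and_fallback_and_not_assessable(self):
        variants = pd.DataFrame([_vrow("S2", "1", 100, 0.25)])
        q = quantify_samples(self._samples(), variants)
        s1 = q[q.sample_id == "S1"].iloc[0]
        assert s1.ctdna_status == "negative" and s1.mge_per_ml == 0.0
        s2 = q[q.sample_id == "S2"].iloc[0]
        assert s2.ctdna_status == "positive"
        assert s2.ctdna_frac == pytest.approx(0.5)      # disomic fallback doubles the VAF
        assert s2.mge_per_ml == pytest.approx(1000.0)   # 0.5 * 12 * 1000 / 6
        assert bool(s2.disomic_fallback)
        s3 = q[q.sample_id == "S3"].iloc[0]
        assert s3.ctdna_status == "not_assessable" and np.isnan(s3.mge_per_ml)

    def test_copy_state_correction_applied(self):
        variants = pd.DataFrame([_vrow("S1", "1", 100, 0.4)])
        cs = pd.DataFrame([{"patient_id": "P1", "chrom": "1", "pos": 100,
                            "cn": 1, "m": 1, "amplified": False}])
        q = quantify_samples(self._samples(), variants, cs)
        s1 = q[q.sample_id == "S1"].iloc[0]
        assert s1.ctdna_frac == pytest.approx(2 / 3.5)
        assert not bool(s1.disomic_fallback)
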