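"""Clone-fraction quantification: MSF/MCF equations, purity, clonality calls."""

import math

import numpy as np
import pytest

from clonespread import (SegmentCall, estimate_tcf, mcf_normalize,
                         msf_from_log2r, msf_from_mbaf, quantify_sample)
from clonespread.errors import (DegenerateCompositionError,
                                InsufficientAnchorsError, InvalidInputError,
                                QualityWarning)
from clonespread.segments import SamplePurity


@pytest.mark.parametrize("log2r, np_, nt, expected", [
    (math.log2(1.5), 2, 3, 1.0),  # fully clonal one-copy gain on diploid background
    (0.0, 2, 3, 0.0),  # no intensity shift, no altered cells
    (math.log2(1.2), 2, 3, 0.4),  # 40% at 3 copies: mean CN 2.4
    (math.log2(0.5), 2, 1, 1.0),  # clonal one-copy loss
])
def test_msf_from_log2r_known_mixtures(log2r, np_, nt, expected):
    assert msf_from_log2r(log2r, np_, nt) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("mbaf, n_a, n_b, expected", [
    (1.0, 0, 2, 1.0),  # pure copy-neutral LOH
    (0.5, 0, 2, 0.0),  # balanced alleles
    (0.75, 0, 2, 0.5),  # half the cells are (B,B)
])
def test_msf_from_mbaf_known_mixtures(mbaf, n_a, n_b, expected):
    assert msf_from_mbaf(mbaf, n_a, n_b) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("msf", np.linspace(0, 1, 11))
@pytest.mark.parametrize("np_", [2, 4])
@pytest.mark.parametrize("nt", [0, 1, 3, 4, 5, 6, 7, 8])
def test_log2r_roundtrip(msf, np_, nt):
    """Forward mixture log2R inverts back to the simulated MSF."""
    if nt == np_:
        return
    mean_cn = np_ + msf * (nt - np_)
    if mean_cn <= 0:
        return
    log2r = math.log2(mean_cn / np_)
    assert msf_from_log2r(log2r, np_, nt) == pytest.approx(msf, abs=1e-9)


@pytest.mark.parametrize("msf", np.linspace(0, 1, 11))
@pytest.mark.parametrize("n_a, n_b", [(0, 2), (1, 3)])
def test_mbaf_roundtrip(msf, n_a, n_b):
    """Copy-neutral forward mixture mBAF inverts back to the simulated MSF."""
    np_ = n_a + n_b
    mbaf = (np_ / 2.0 + msf * (n_b - np_ / 2.0)) / np_
    assert msf_from_mbaf(mbaf, n_a, n_b) == pytest.approx(msf, abs=1e-9)


def test_copy_neutral_input_rejected_by_log2r_path():
    with pytest.raises(InvalidInputError):
        msf_from_log2r(0.1, 2, 2)


def test_degenerate_composition_rejected():
    # altered state (1,3) on a diploid background: the denominator vanishes at mBAF = 1
    with pytest.raises(DegenerateCompositionError):
        msf_from_mbaf(1.0, 1, 3, np_=2)


def test_quality_warning_outside_plausible_range():
    with pytest.warns(QualityWarning):
        assert msf_from_log2r(math.log2(1.6), 2, 3) == 1.0
    with pytest.warns(QualityWarning):
        assert msf_from_log2r(-0.2, 2, 3) == 0.0


class TestPurity:
    def test_equal_anchors(self):
        p = estimate_tcf([0.8, 0.8])
        assert (p.tcf, p.sd_msf) == (0.8, 0.0)
        assert (p.clonal_low, p.clonal_high) == (1.0, 1.0)

    def test_two_anchor_interval(self):
        p = estimate_tcf([0.75, 0.85])
        assert p.tcf == pytest.approx(0.8)
        assert p.sd_msf == pytest.approx(0.070710678, abs=1e-6)
        assert p.clonal_low == pytest.approx(0.823223, abs=1e-4)
        assert p.clonal_high == pytest.approx(1.176776, abs=1e-4)

    def test_single_anchor(self):
        p = estimate_tcf([0.6])
        assert (p.tcf, p.sd_msf, p.clonal_low, p.clonal_high) == (0.6, 0.0, 1.0, 1.0)

    def test_no_anchors(self):
        with pytest.raises(InsufficientAnchorsError):
            estimate_tcf([])


class TestMcfNormalize:
    def test_inside_interval_is_clonal(self):
        purity = estimate_tcf([0.75, 0.8, 0.85])
        assert mcf_normalize(0.72, purity) == (1.0, True)

    def test_subclonal_ratio(self):
        purity = SamplePurity("s", 0.8, 0.0, 1.0, 1.0, 1)
        assert mcf_normalize(0.4, purity) == (0.5, False)

    def test_exact_one_is_clonal(self):
        purity = SamplePurity("s", 0.8, 0.0, 1.0, 1.0, 1)
        assert mcf_normalize(0.8, purity) == (1.0, True)

    def test_monotone_and_capped(self):
        purity = estimate_tcf([0.7, 0.8])
        vals = [mcf_normalize(m, purity)[0] for m in np.linspace(0, 1, 21)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert max(vals) <= 1.0

    def test_zero_sd_clonal_iff_ratio_one(self):
        purity = SamplePurity("s", 0.5, 0.0, 1.0, 1.0, 1)
        assert mcf_normalize(0.5, purity)[1] is True
        assert mcf_normalize(0.49, purity)[1] is False


def _seg(sample, log2r=None, mbaf=None, kind="gain", start=1_000_000):
    nt, na, nb = {"gain": (3, 1, 2), "loss": (1, 0, 1), "cnni": (2, 0, 2)}[kind]
    return SegmentCall("P1", sample, "chr1", start, start + 40_000, kind,
                       n_alleles_total=nt, n_a=na, n_b=nb,
                       log2r=log2r, mbaf=mbaf, marker_count=40)


class TestQuantifySample:
    def test_mixed_gain_and_cnni_anchors(self):
        segs = [
            _seg("s1", log2r=math.log2((2 + 0.8) / 2)),  # gain, MSF 0.8
            _seg("s1", mbaf=0.9, kind="cnni", start=2_000_000),  # cnni, MSF 0.8
        ]
        out, purity = quantify_sample(segs)
        assert purity.tcf == pytest.approx(0.8, abs=1e-9)
        assert all(s.is_clonal for s in out)

    def test_subclonal_third_segment(self):
        segs = [
            _seg("s1", log2r=math.log2((2 + 0.8) / 2), start=1_000_000),
            _seg("s1", log2r=math.log2((2 + 0.8) / 2), start=2_000_000),
            _seg("s1", log2r=math.log2((2 + 0.32) / 2), start=3_000_000),
        ]
        out, purity = quantify_sample(segs)
        assert purity.tcf == pytest.approx(0.8, abs=1e-9)
        assert out[2].mcf == pytest.approx(0.4, abs=1e-9)
        assert out[2].is_clonal is False

    def test_tcf_override(self):
        segs = [_seg("s1", log2r=math.log2((2 + 0.4) / 2))]
        out, purity = quantify_sample(segs, tcf_override=0.8)
        assert purity.tcf == 0.8
        assert out[0].mcf == pytest.approx(0.5, abs=1e-9)

    def test_mixed_samples_rejected(self):
        segs = [_seg("s1", log2r=0.3), _seg("s2", log2r=0.3)]
        with pytest.raises(InvalidInputError):
            quantify_sample(segs)


def test_cna_size_and_marker_filters():
    small = SegmentCall("P1", "s1", "chr1", 100, 10_099, "gain",
                        n_alleles_total=3, log2r=0.3, marker_count=40)
    sparse = SegmentCall("P1", "s1", "chr1", 100, 100_099, "gain",
                         n_alleles_total=3, log2r=0.3, marker_count=10)
    ok = SegmentCall("P1", "s1", "chr1", 100, 100_099, "gain",
                     n_alleles_total=3, log2r=0.3, marker_count=40)
    assert not small.passes_cna_filters()
    assert not sparse.passes_cna_filters()
    assert ok.passes_cna_filters()
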