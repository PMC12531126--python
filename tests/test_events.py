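"""Event merging and subclonal deconvolution."""

import pytest

from clonespread import (SegmentCall, analyze_patient, deconvolve_patient,
                         deconvolve_sample, merge_events,
                         reconcile_across_samples)
from clonespread.errors import AmbiguityError, InvalidInputError
from clonespread.events import EventRecord, EventTable


def _seg(sample, chrom, start, end, kind, mcf, patient="P1", clonal=None):
    nt = {"gain": 3, "loss": 1, "cnni": 2, "snv": None}[kind]
    na, nb = {"gain": (1, 2), "loss": (0, 1), "cnni": (0, 2), "snv": (None, None)}[kind]
    return SegmentCall(patient, sample, chrom, start, end, kind,
                       n_alleles_total=nt, n_a=na, n_b=nb, mcf=mcf,
                       is_clonal=clonal if clonal is not None else mcf >= 1.0,
                       marker_count=40)


class TestMergeEvents:
    def test_identical_footprints_merge(self):
        segs = [_seg("s1", "chr17", 30_000_000, 80_000_000, "gain", 0.8),
                _seg("s2", "chr17", 30_000_000, 80_000_000, "gain", 0.5)]
        table = merge_events(segs)
        assert len(table.events) == 1
        assert table.events[0].mcf == {"s1": 0.8, "s2": 0.5}

    def test_high_reciprocal_overlap_merges(self):
        segs = [_seg("s1", "chr1", 1_000_000, 2_000_000, "gain", 0.8),
                _seg("s2", "chr1", 1_050_000, 2_050_000, "gain", 0.5)]
        assert len(merge_events(segs).events) == 1

    def test_low_overlap_stays_separate(self):
        segs = [_seg("s1", "chr1", 1_000_000, 2_000_000, "gain", 0.8),
                _seg("s2", "chr1", 1_800_000, 2_800_000, "gain", 0.5)]
        assert len(merge_events(segs).events) == 2

    def test_kind_mismatch_stays_separate(self):
        segs = [_seg("s1", "chr1", 1_000_000, 2_000_000, "gain", 0.8),
                _seg("s2", "chr1", 1_000_000, 2_000_000, "loss", 0.5)]
        assert len(merge_events(segs).events) == 2

    def test_conflicting_mcfs_in_one_sample_rejected(self):
        segs = [_seg("s1", "chr1", 1_000_000, 2_000_000, "gain", 0.8),
                _seg("s1", "chr1", 1_000_000, 2_000_000, "gain", 0.3)]
        with pytest.raises(AmbiguityError):
            merge_events(segs)

    def test_mixed_patients_rejected(self):
        segs = [_seg("s1", "chr1", 1_000_000, 2_000_000, "gain", 0.8),
                _seg("s2", "chr1", 1_000_000, 2_000_000, "gain", 0.5, patient="P2")]
        with pytest.raises(InvalidInputError):
            merge_events(segs)


def _table(sample_mcfs, clonal=()):
    """EventTable from {event_id: {sample: mcf}}."""
    samples = sorted({s for m in sample_mcfs.values() for s in m})
    events = []
    for eid, m in sample_mcfs.items():
        ev = EventRecord(eid, "gain", "chr1", 1, 2, mcf=dict(m),
                         clonal={s: eid in clonal for s in m},
                         present={s: v > 0 for s, v in m.items()})
        events.append(ev)
    return EventTable("P1", events, samples)


class TestDeconvolveSample:
    def test_clonal_parent_with_nested_subclone(self):
        table = _table({"A": {"s1": 1.0}, "B": {"s1": 0.4}}, clonal=("A",))
        subs = deconvolve_sample(table, "s1")
        by_events = {tuple(sorted(sc.events)): sc.fractions["s1"] for sc in subs}
        assert by_events == {("A",): pytest.approx(0.6), ("A", "B"): pytest.approx(0.4)}

    def test_pigeonhole_forces_cooccurrence(self):
        table = _table({"B": {"s1": 0.6}, "C": {"s1": 0.6}})
        subs = deconvolve_sample(table, "s1")
        assert len(subs) == 1
        assert subs[0].events == frozenset({"B", "C"})
        assert subs[0].fractions["s1"] == pytest.approx(0.6)

    def test_ambiguous_pair_defaults_to_disjoint_with_flag(self):
        table = _table({"B": {"s1": 0.3}, "C": {"s1": 0.3}})
        subs = deconvolve_sample(table, "s1")
        assert sorted(sorted(sc.events) for sc in subs) == [["B"], ["C"]]
        assert any(sc.ambiguous for sc in subs)


class TestReconcileAcrossSamples:
    def test_cross_sample_nesting_imposed(self):
        """Nesting visible in one sample resolves the ambiguity in another."""
        t1 = _table({"B": {"s1": 0.3}, "C": {"s1": 0.3}})
        t2 = _table({"B": {"s2": 1.0}, "C": {"s2": 0.2}}, clonal=("B",))
        frags = {"s1": deconvolve_sample(t1, "s1"), "s2": deconvolve_sample(t2, "s2")}
        subs, matrix = reconcile_across_samples(frags, patient_id="P1")
        sets = sorted(sorted(sc.events) for sc in subs)
        assert ["B", "C"] in sets  # C nested inside B patient-wide
        nested = next(sc for sc in subs if sc.events == frozenset({"B", "C"}))
        assert nested.fractions["s1"] == pytest.approx(0.3, abs=0.05)

    def test_identical_event_sets_unify(self):
        frags = {}
        for s in ("s1", "s2", "s3"):
            t = _table({"A": {s: 1.0}, "B": {s: 0.5}}, clonal=("A",))
            frags[s] = deconvolve_sample(t, s)
        subs, matrix = reconcile_across_samples(frags)
        assert matrix.matrix.shape == (2, 2)


class TestDeconvolvePatient:
    def test_two_sample_stem_and_branch(self):
        table = _table({"A": {"s1": 1.0, "s2": 1.0}, "X": {"s2": 0.6}}, clonal=("A",))
        subs, matrix = deconvolve_patient(table)
        assert sorted(sorted(sc.events) for sc in subs) == [["A"], ["A", "X"]]

    def test_empty_table_rejected(self):
        with pytest.raises(InvalidInputError):
            deconvolve_patient(EventTable("P1", [], []))

    def test_deterministic_output(self, clean_cohort, clean_pipeline_config):
        p = clean_cohort.patients[0]
        runs = []
        for _ in range(2):
            res = analyze_patient(p.patient_id, p.segments, p.variants,
                                  clean_cohort.bed, p.metadata, clean_pipeline_config)
            runs.append((res.matrix.matrix.to_csv(), res.matrix.fractions.to_csv()))
        assert runs[0] == runs[1]


class TestNoiseFreeRecovery:
    def test_exact_event_sets_and_conservation(self, clean_cohort, clean_pipeline_config):
        for p in clean_cohort.patients:
            res = analyze_patient(p.patient_id, p.segments, p.variants,
                                  clean_cohort.bed, p.metadata, clean_pipeline_config)
            assert res.error is None
            alias = p.truth.event_aliases
            truth_sets = sorted(sorted(alias[e] for e in ev)
                                for ev in p.truth.clone_events.values())
            got_sets = sorted(sorted(sc.events) for sc in res.subclones)
            assert got_sets == truth_sets
            # conservation: summed fractions of carriers reproduce each MCF
            for ev in res.event_table.events:
                for s in res.event_table.samples:
                    if not ev.present.get(s):
                        continue
                    total = sum(sc.fractions.get(s, 0.0) for sc in res.subclones
                                if ev.event_id in sc.events)
                    assert total == pytest.approx(ev.mcf[s], abs=1e-6)

    def test_fraction_sums_bounded(self, clean_cohort, clean_pipeline_config):
        for p in clean_cohort.patients:
            res = analyze_patient(p.patient_id, p.segments, p.variants,
                                  clean_cohort.bed, p.metadata, clean_pipeline_config)
            sums = res.matrix.fractions.sum(axis=0)
            assert (sums <= 1.0 + 0.1 + 1e-9).all()
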