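"""Normalization, SNV hard filter, long-indel chain and overlap counting."""

import numpy as np
import pytest

from wgs_bakeoff.filters import (callset_overlap, check_ledger, indel_length,
                                 long_indel_filter, normalize_callset,
                                 normalize_variant, snv_hard_filter,
                                 split_multiallelic)
from wgs_bakeoff.masks import GenomeMask
from wgs_bakeoff.variants import CallSet, VariantKey, VariantRecord


REF = {"chr1": "GGGCCAAAAAATTTTGACGTACGTACGTAGCTAGCTAGGG"}
#                0123456789...    (A run at 5..11, 0-based)


def _rec(pos, ref, alts, qual=100.0, gts=None, gq=None, dp=None, sp=None,
         filt="PASS"):
    n = len(gts) if gts else 1
    return VariantRecord("chr1", pos, ref, tuple(alts), qual=qual, filter=filt,
                         genotypes=gts or [(0, 1)],
                         gq=gq or [60] * n, dp=dp or [30] * n,
                         sp=sp or [2] * n)


class TestNormalization:
    def test_snv_identity(self):
        out, dropped = normalize_variant(_rec(4, "C", ["T"]), REF)
        assert not dropped
        rec = out[0]
        assert (rec.pos, rec.ref, rec.alts) == (4, "C", ("T",))

    def test_deletion_left_aligned_in_homopolymer(self):
        # delete one A placed at the right end of the A run: A6..A11 (1-based)
        out, _ = normalize_variant(_rec(10, "AA", ["A"]), REF)
        rec = out[0]
        # leftmost equivalent representation anchors just before the run
        assert (rec.pos, rec.ref, rec.alts) == (5, "CA", ("C",))

    def test_normalization_idempotent_exhaustive_shifts(self):
        # every placement of a 1-bp deletion inside the run is equivalent
        keys = set()
        for pos in range(6, 11):
            out, _ = normalize_variant(_rec(pos, "AA", ["A"]), REF)
            keys.add(out[0].key())
            again, _ = normalize_variant(out[0], REF)
            assert again[0].key() == out[0].key()
        assert len(keys) == 1

    def test_insertion_left_aligned(self):
        out, _ = normalize_variant(_rec(11, "A", ["AA"]), REF)
        rec = out[0]
        assert (rec.pos, rec.ref, rec.alts) == (5, "C", ("CA",))

    def test_multiallelic_split_reindexes_genotypes(self):
        rec = _rec(4, "C", ["T", "G"], gts=[(1, 2)])
        parts = split_multiallelic(rec)
        assert [p.alts for p in parts] == [("T",), ("G",)]
        assert [p.genotypes[0] for p in parts] == [(0, 1), (0, 1)]

    def test_reference_mismatch_dropped(self):
        out, dropped = normalize_variant(_rec(4, "T", ["A"]), REF)
        assert out == [] and len(dropped) == 1

    def test_unknown_sequence_rejected(self):
        with pytest.raises(KeyError):
            normalize_variant(
                VariantRecord("chrX", 1, "A", ("C",), genotypes=[(0, 1)]), REF)

    def test_callset_normalization_idempotent_on_random_indels(self):
        rng = np.random.default_rng(17)
        seq = "".join(rng.choice(list("ACGT"), 500))
        seq = seq[:100] + "T" * 8 + seq[108:]
        ref = {"chr1": seq}
        cs = CallSet(["s"])
        for _ in range(50):
            pos = int(rng.integers(1, 480))
            ln = int(rng.integers(1, 6))
            refa = seq[pos - 1: pos - 1 + ln + 1]
            if rng.random() < 0.5:
                rec = _rec(pos, refa, [refa[0]])        # deletion
            else:
                ins = "".join(rng.choice(list("ACGT"), ln))
                rec = _rec(pos, refa[0], [refa[0] + ins])  # insertion
            cs.add(rec)
        once, _ = normalize_callset(cs, ref)
        twice, _ = normalize_callset(once, ref)
        assert [r.key() for r in once.records] == \
               [r.key() for r in twice.records]


class TestSnvHardFilter:
    def _cs(self, records):
        return CallSet(["s"], records)

    @pytest.mark.parametrize("qual,kept", [(40.0, 0), (40.5, 1), (41.0, 1)])
    def test_qual_strictly_greater(self, qual, kept):
        out, ledger = snv_hard_filter(self._cs([_rec(4, "C", ["T"],
                                                     qual=qual)]))
        assert len(out) == kept

    def test_all_pass_example(self):
        rec = _rec(4, "C", ["T"], qual=41, gq=[21], dp=[11], sp=[19])
        out, _ = snv_hard_filter(self._cs([rec]))
        assert len(out) == 1

    @pytest.mark.parametrize("field,value", [("gq", 20), ("dp", 10),
                                             ("sp", 20)])
    def test_format_boundaries_strict(self, field, value):
        kwargs = {field: [value]}
        out, _ = snv_hard_filter(self._cs([_rec(4, "C", ["T"], **kwargs)]))
        assert len(out) == 0

    def test_missing_format_fails_criterion(self):
        rec = _rec(4, "C", ["T"], gq=[None])
        out, ledger = snv_hard_filter(self._cs([rec]))
        assert len(out) == 0
        assert next(e for e in ledger if e.step == "gq").n_out == 0

    def test_any_mode_relaxes(self):
        rec = _rec(4, "C", ["T"], gts=[(0, 1), (0, 1)], gq=[10, 50],
                   dp=[30, 30], sp=[2, 2])
        cs = CallSet(["a", "b"], [rec])
        strict, _ = snv_hard_filter(cs, mode="all")
        loose, _ = snv_hard_filter(cs, mode="any")
        assert len(strict) == 0 and len(loose) == 1

    def test_repeat_mask_removal_and_ledger(self):
        mask = GenomeMask({"chr1": [(0, 10)]}, label="repeat")
        recs = [_rec(p, REF["chr1"][p - 1], ["T" if REF["chr1"][p - 1] != "T"
                                             else "G"])
                for p in (2, 5, 20, 25)]
        out, ledger = snv_hard_filter(self._cs(recs), repeat_mask=mask)
        check_ledger(ledger)
        masked_step = next(e for e in ledger if e.step == "repeat_mask")
        assert masked_step.n_in - masked_step.n_out == 2
        assert all(r.pos > 10 for r in out.records)

    def test_planted_mask_count(self, callset_sim):
        truth = callset_sim.truth
        snvs = CallSet(truth.samples, [r for r in truth.records if r.is_snv])
        inside = [r for r in snvs.records[:10]]
        mask = GenomeMask({"chr1": [(r.pos - 1, r.pos) for r in inside]},
                          label="repeat")
        out_nomask, _ = snv_hard_filter(snvs)
        out, ledger = snv_hard_filter(snvs, repeat_mask=mask)
        surviving_inside = sum(1 for r in out_nomask.records if r in inside)
        assert len(out_nomask) - len(out) == surviving_inside


class TestLongIndelFilter:
    def _indel(self, pos, diff, qual=50.0, gq=30, filt="PASS"):
        ins = "C" * diff
        return _rec(pos, "A", ["A" + ins], qual=qual, gq=[gq], filt=filt)

    @pytest.mark.parametrize("diff,kept", [(19, 0), (20, 1), (100, 1),
                                           (101, 0)])
    def test_length_boundaries_inclusive(self, diff, kept):
        cs = CallSet(["s"], [self._indel(4, diff)])
        out, ledger = long_indel_filter(cs)
        assert len(out) == kept
        check_ledger(ledger)

    def test_non_pass_removed_first(self):
        cs = CallSet(["s"], [self._indel(4, 30, filt="q20")])
        out, ledger = long_indel_filter(cs)
        assert len(out) == 0 and ledger[0].n_out == 0

    @pytest.mark.parametrize("qual,gq,kept", [(40.0, 30, 0), (50.0, 20, 0),
                                              (50.0, 21, 1)])
    def test_quality_boundaries(self, qual, gq, kept):
        cs = CallSet(["s"], [self._indel(4, 30, qual=qual, gq=gq)])
        out, _ = long_indel_filter(cs)
        assert len(out) == kept

    def test_mask_overlap_excluded(self):
        mask = GenomeMask({"chr1": [(0, 10)]}, label="merged")
        cs = CallSet(["s"], [self._indel(4, 30), self._indel(20, 30)])
        out, ledger = long_indel_filter(cs, mask=mask)
        assert [r.pos for r in out.records] == [20]
        assert ledger[-1].step == "masks"

    def test_ledger_conservation(self, callset_sim):
        out, ledger = long_indel_filter(callset_sim.truth)
        check_ledger(ledger)
        assert ledger[0].n_in == len(callset_sim.truth)
        assert ledger[-1].n_out == len(out)

    def test_indel_length_is_absolute_difference(self):
        assert indel_length(_rec(1, "A", ["A" + "C" * 25])) == 25
        assert indel_length(_rec(1, "A" + "C" * 25, ["A"])) == 25


class TestOverlap:
    def _key(self, pos):
        return VariantKey("chr1", pos, "A", "C")

    def test_identical_sets_all_center(self):
        keys = {self._key(i) for i in range(5)}
        regions, pct = callset_overlap({"a": keys, "b": set(keys),
                                        "c": set(keys)})
        assert regions == {frozenset("abc"): 5}
        assert pct["a"]["shared_all"] == 100.0

    def test_disjoint_sets_unique_only(self):
        regions, pct = callset_overlap({
            "a": {self._key(1)}, "b": {self._key(2)}, "c": {self._key(3)}})
        assert regions == {frozenset("a"): 1, frozenset("b"): 1,
                           frozenset("c"): 1}
        assert pct["a"]["unique"] == 100.0

    def test_enumerated_example(self):
        k = self._key
        regions, _ = callset_overlap({"A": {k(1), k(2), k(3)},
                                      "B": {k(2), k(3), k(4)},
                                      "C": {k(3)}})
        assert regions[frozenset("ABC")] == 1
        assert regions[frozenset("AB")] == 1
        assert regions[frozenset("A")] == 1
        assert regions[frozenset("B")] == 1

    def test_counts_sum_to_union(self):
        k = self._key
        sets = {"a": {k(i) for i in range(6)},
                "b": {k(i) for i in range(3, 9)},
                "c": {k(i) for i in range(5, 7)}}
        regions, _ = callset_overlap(sets)
        assert sum(regions.values()) == len(set().union(*sets.values()))

    def test_single_set_rejected(self):
        with pytest.raises(ValueError):
            callset_overlap({"a": {self._key(1)}})
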