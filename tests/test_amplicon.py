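"""Read handling, alignment, pileups, and the deletion-template screen."""

import numpy as np
import pytest

import plasmut as pm
from plasmut.amplicon import (
    DELETION_INTERVALS,
    IndexedRead,
    align_read,
    align_sample_reads,
    build_pileup,
    deletion_fraction,
    demultiplex,
    filter_short,
    match_deletion_templates,
    substitution_rate,
    substitution_types,
)
from plasmut.error_model import SubstitutionType


def _read(bases, read_id="r0"):
    return IndexedRead(read_id=read_id, bases=bases)


class TestReferences:
    def test_windows_cover_169_positions_507_types(self, references):
        n_pos = sum(len(r.window_positions) for r in references.values())
        assert n_pos == 169
        n_types = sum(len(substitution_types(r)) for r in references.values())
        assert n_types == 507

    def test_printed_deletion_intervals_shipped(self):
        cdna = [iv for _, iv, _ in DELETION_INTERVALS]
        assert cdna == [
            (2233, 2247), (2235, 2246), (2235, 2249), (2236, 2250),
            (2236, 2256), (2238, 2252), (2239, 2247), (2239, 2256),
        ]
        genomic = [g for _, _, g in DELETION_INTERVALS]
        assert genomic[0] == (55242463, 55242477)
        assert genomic[-1] == (55242469, 55242486)

    def test_template_sequences_drop_the_interval(self, references):
        ref = references["exon19"]
        for tpl in pm.deletion_templates(ref):
            assert len(tpl.sequence) == len(ref.sequence) - tpl.deletion_length

    def test_coordinate_maps_strictly_monotone(self, references):
        for ref in references.values():
            genomic = [ref.genomic_of(p) for p in ref.window_positions]
            assert all(a < b for a, b in zip(genomic, genomic[1:]))


class TestDemultiplex:
    def test_exact_prefix_assignment_and_stripping(self):
        table = {"ACGTA": "s1", "TTTTT": "s2"}
        reads = [_read("ACGTA" + "G" * 80, "a"), _read("NNNNN" + "G" * 80, "b")]
        by_sample, discarded = demultiplex(reads, table)
        assert [r.read_id for r in by_sample["s1"]] == ["a"]
        assert by_sample["s1"][0].bases == "G" * 80
        assert by_sample["s1"][0].index == "ACGTA"
        assert by_sample["s2"] == []
        assert discarded == 1

    def test_empty_input(self):
        by_sample, discarded = demultiplex([], {"ACGTA": "s1"})
        assert by_sample == {"s1": []} and discarded == 0

    def test_conservation_and_order_independence(self, rng):
        table = {"AAAAA": "s1", "CCCCC": "s2"}
        reads = [
            _read(rng.choice(["AAAAA", "CCCCC", "GGGGG"]) + "T" * 70, f"r{i}")
            for i in range(60)
        ]
        fwd, d1 = demultiplex(reads, table)
        rev, d2 = demultiplex(reads[::-1], table)
        assert d1 == d2
        assert sum(map(len, fwd.values())) + d1 == len(reads)
        for s in table.values():
            assert sorted(r.read_id for r in fwd[s]) == sorted(r.read_id for r in rev[s])

    def test_bad_index_length_rejected(self):
        with pytest.raises(ValueError):
            demultiplex([], {"ACGT": "s1"})


class TestLengthFilter:
    def test_boundary_at_70(self):
        reads = [_read("A" * n, f"r{n}") for n in (69, 70, 150)]
        kept = filter_short(reads)
        assert [len(r) for r in kept] == [70, 150]

    def test_identity_and_empty(self):
        long_reads = [_read("A" * 90)]
        assert filter_short(long_reads) == long_reads
        assert filter_short([_read("A" * 10)]) == []


class TestAlignment:
    def test_exact_substring_aligns_without_gaps(self, references):
        ref = references["exon21"]
        aln = align_read(_read(ref.sequence[5:90]), ref)
        assert aln is not None
        assert aln.operations == (("M", 85),)
        assert aln.ref_start == 5
        assert aln.score == 85

    def test_deletion_template_read_vs_intact_reference(self, references):
        """A read generated from a deletion template aligns to the intact
        exon 19 with a single deletion gap of the template's length."""
        ref = references["exon19"]
        for tpl in pm.deletion_templates(ref)[:3]:
            aln = align_read(_read(tpl.sequence), ref)
            dels = [n for op, n in aln.operations if op == "D"]
            assert dels == [tpl.deletion_length]

    def test_random_read_unaligned(self, references, rng):
        bases = "".join(rng.choice(list("ACGT"), 70))
        # shuffled sequence shares no layout with the reference
        assert align_read(_read(bases), references["exon19"], try_reverse=False) is None

    def test_reverse_complement_detected_and_flagged(self, references):
        from plasmut.amplicon import reverse_complement

        ref = references["exon20"]
        with pytest.warns(UserWarning, match="reverse"):
            aln = align_read(_read(reverse_complement(ref.sequence)), ref)
        assert aln is not None and aln.reverse


class TestPileup:
    def test_perfect_reads_give_uniform_depth(self, references):
        ref = references["exon21"]
        alns = [align_read(_read(ref.sequence, f"r{i}"), ref) for i in range(100)]
        pile = build_pileup(alns, ref)
        assert (pile.depth == 100).all()
        for pos in list(ref.window_positions)[:10]:
            assert pile.count_at(pos, ref.base_at(pos)) == 100

    def test_single_substitution_counted(self, references):
        ref = references["exon21"]
        pos = 2573
        j = ref.index_of(pos)
        mutant = ref.sequence[:j] + "G" + ref.sequence[j + 1:]
        alns = [align_read(_read(ref.sequence, f"r{i}"), ref) for i in range(99)]
        alns.append(align_read(_read(mutant, "mut"), ref))
        pile = build_pileup(alns, ref)
        assert pile.count_at(pos, "T") == 99
        assert pile.count_at(pos, "G") == 1
        st = SubstitutionType("exon21", pos, "T", "G")
        assert substitution_rate(pile, st) == pytest.approx(0.01)

    def test_n_bases_excluded_from_depth(self, references):
        ref = references["exon21"]
        pos = 2573
        j = ref.index_of(pos)
        with_n = ref.sequence[:j] + "N" + ref.sequence[j + 1:]
        pile = build_pileup([align_read(_read(with_n), ref)], ref)
        assert pile.depth_at(pos) == 0

    def test_indel_pool_conserves_events(self, references):
        ref = references["exon19"]
        tpl = pm.deletion_templates(ref)[2]
        alns = [align_read(_read(tpl.sequence, f"d{i}"), ref) for i in range(5)]
        pile = build_pileup(alns, ref)
        lo, hi = tpl.cdna_interval
        for pos in range(lo, hi + 1):
            assert pile.indel(pos) == pile.deletions[pile._idx(pos)] + pile.insertions[pile._idx(pos)]
            assert pile.indel(pos) == 5

    def test_zero_depth_rate_undefined(self, references):
        ref = references["exon21"]
        pile = build_pileup([], ref)
        with pytest.raises(ZeroDivisionError):
            substitution_rate(pile, SubstitutionType("exon21", 2573, "T", "G"))


class TestDeletionScreen:
    def test_planted_template_recovered(self, references, rng):
        """Reads simulated from one template at ~1% are assigned back to it."""
        ref = references["exon19"]
        templates = pm.deletion_templates(ref)
        target = next(t for t in templates if t.template_id == "del_2235_2249")
        n, frac = 3000, 0.01
        n_mut = rng.binomial(n, frac)
        reads = [_read(target.sequence, f"m{i}") for i in range(n_mut)]
        reads += [_read(ref.sequence, f"w{i}") for i in range(n - n_mut)]
        counts, intact, chosen = match_deletion_templates(reads, ref, templates)
        assert chosen == "del_2235_2249"
        assert counts[chosen] == n_mut
        assert intact == n - n_mut
        assert deletion_fraction(counts, n) == pytest.approx(frac, abs=3 * np.sqrt(frac * (1 - frac) / n))

    def test_no_deletion_reads_no_call(self, references):
        ref = references["exon19"]
        reads = [_read(ref.sequence, f"w{i}") for i in range(50)]
        counts, intact, chosen = match_deletion_templates(reads, ref, pm.deletion_templates(ref))
        assert chosen is None and sum(counts.values()) == 0 and intact == 50

    def test_unlisted_deletion_assigned_to_best_listed_template(self, references):
        """A deletion absent from the template list still lands on a
        deletion template rather than the intact reference."""
        ref = references["exon19"]
        i, j = ref.index_of(2236), ref.index_of(2251)  # 16-bp deletion, not listed
        novel = ref.sequence[:i] + ref.sequence[j + 1:]
        counts, intact, chosen = match_deletion_templates(
            [_read(novel)], ref, pm.deletion_templates(ref)
        )
        assert sum(counts.values()) == 1
        assert chosen is not None

    def test_indel_read_errors_do_not_reach_the_threshold(self, references, rng):
        """Short random indel errors at realistic rates never win the
        template match, so normal samples show no deletion signal."""
        from plasmut.simulate import _mutate_read

        ref = references["exon19"]
        templates = pm.deletion_templates(ref)
        n = 1500
        reads = [
            _read(_mutate_read(ref.sequence, rng, sub_rate=1e-3, indel_rate=2e-3), f"w{i}")
            for i in range(n)
        ]
        counts, intact, chosen = match_deletion_templates(reads, ref, templates)
        # threshold is 7 per 100,000 reads; even one misassigned read here
        # (67 per 100k) would break the screen's specificity
        assert max(counts.values()) == 0

    def test_fraction_numerator_conventions(self):
        counts = {"a": 500, "b": 100}
        assert deletion_fraction(counts, 100_000) == pytest.approx(0.005)
        assert deletion_fraction(counts, 100_000, numerator="sum") == pytest.approx(0.006)
        assert deletion_fraction({}, 100_000) == 0.0
        with pytest.raises(ZeroDivisionError):
            deletion_fraction(counts, 0)


class TestSamplePath:
    def test_round_trip_recovers_planted_counts(self):
        """Error-free simulated reads pass through demultiplex, alignment and
        pileup with the planted mutant count recovered exactly."""
        reads, manifest = pm.simulate_reads(
            600, fraction=0.05, mutation="L858R",
            per_base_substitution_rate=0.0, seed=9,
        )
        by_sample, discarded = demultiplex(reads, {"ACGTA": "s1"})
        assert discarded == 0
        kept = filter_short(by_sample["s1"])
        pileups, template_counts, exon19_total = align_sample_reads(kept)
        st = pm.TARGET_SUBSTITUTIONS["L858R"]
        pile = pileups["exon21"]
        assert pile.count_at(st.position, st.alt_base) == manifest["planted_mutant_reads"]
        assert sum(template_counts.values()) == 0
        assert exon19_total == manifest["reads_per_amplicon"]["exon19"]
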