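"""UMI family grouping and consensus: hand oracles, brute-force equivalence,
and the two error tiers (suppression of late errors, penetrance of early)."""

from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from umicall.consensus import (ConsensusRead, UmiFamily, build_all_consensus,
                               build_consensus, consensus_pileup,
                               group_families)
from umicall.reads import TaggedRead, process_fastq
from umicall.simulate import SimulationParams, simulate_sample


def _tag(umi, insert, assay="a1", rid=None):
    return TaggedRead(rid or f"{umi}-{id(insert)}", assay, umi, insert, 0)


class TestGroupFamilies:
    def test_exact_grouping_by_hand(self):
        tagged = ([_tag("AAA", "ACGT", rid=f"x{i}") for i in range(3)]
                  + [_tag("AAT", "ACGT", rid=f"y{i}") for i in range(2)]
                  + [_tag("GGG", "ACGT", rid="z0")])
        fams = group_families(tagged, "exact")
        assert sorted((f.umi, f.size) for f in fams) == [
            ("AAA", 3), ("AAT", 2), ("GGG", 1)]

    def test_hamming1_merges_into_larger(self):
        tagged = ([_tag("AAA", "ACGT", rid=f"x{i}") for i in range(3)]
                  + [_tag("AAT", "ACGT", rid=f"y{i}") for i in range(2)]
                  + [_tag("GGG", "ACGT", rid="z0")])
        fams = group_families(tagged, "hamming1")
        assert sorted((f.umi, f.size) for f in fams) == [("AAA", 5), ("GGG", 1)]

    def test_empty_input(self):
        assert group_families([], "exact") == []

    def test_conservation(self, nb_panel, fastq_writer):
        reads, _ = simulate_sample(
            nb_panel, SimulationParams(molecules_per_assay=40, seed=2))
        tagged, _ = process_fastq(fastq_writer(reads), nb_panel)
        for mode in ("exact", "hamming1"):
            fams = group_families(tagged, mode)
            assert sum(f.size for f in fams) == len(tagged)

    def test_families_are_per_assay(self, nb_panel, fastq_writer):
        reads, _ = simulate_sample(
            nb_panel, SimulationParams(molecules_per_assay=30, seed=6))
        tagged, _ = process_fastq(fastq_writer(reads), nb_panel)
        for mode in ("exact", "hamming1"):
            fams = group_families(tagged, mode)
            keys = [(f.assay_id, f.umi) for f in fams]
            assert len(keys) == len(set(keys))
            assert {f.assay_id for f in fams} <= {
                a.assay_id for a in nb_panel.assays}


class TestBuildConsensus:
    def test_identical_triplet(self):
        fam = UmiFamily("a1", "AAA", ["ACGTACGT"] * 3)
        cons = build_consensus(fam)
        assert cons.sequence == "ACGTACGT"
        assert "N" not in cons.sequence

    def test_family_of_two_rejected(self):
        fam = UmiFamily("a1", "AAA", ["ACGT", "ACGT"])
        assert build_consensus(fam, min_family_size=3) is None

    def test_single_discordant_read_outvoted(self):
        fam = UmiFamily("a1", "AAA", ["ACGT", "ACGT", "ACGT", "AGGT"])
        cons = build_consensus(fam)
        assert cons.sequence == "ACGT"  # 3/4 = 0.75 >= 0.6

    def test_smallest_family_with_one_discordant_resolves(self):
        # 2/3 ~ 0.67 >= 0.6: the paper-minimal family still yields a call
        fam = UmiFamily("a1", "AAA", ["ACGT", "ACGT", "AGGT"])
        assert build_consensus(fam).sequence == "ACGT"

    def test_below_threshold_gives_n(self):
        # 1/2 at a position covered by only 2 of 3 (tie) -> N
        fam = UmiFamily("a1", "AAA", ["AC", "AG", "A"])
        cons = build_consensus(fam, min_family_size=3, target_length=2)
        assert cons.sequence == "AN"

    def test_exactly_at_threshold_called(self):
        # 3/5 = 0.6 == threshold -> called
        fam = UmiFamily("a1", "AAA", ["A", "A", "A", "C", "C"])
        assert build_consensus(fam, target_length=1).sequence == "A"

    def test_uncovered_tail_is_n(self):
        fam = UmiFamily("a1", "AAA", ["AC", "AC", "AC"])
        cons = build_consensus(fam, target_length=4)
        assert cons.sequence == "ACNN"

    def test_empty_family_is_error(self):
        with pytest.raises(ValueError):
            build_consensus(UmiFamily("a1", "AAA", []))

    def test_consensus_count_vs_family_count(self, nb_panel, fastq_writer):
        reads, _ = simulate_sample(
            nb_panel, SimulationParams(molecules_per_assay=60, seed=14))
        tagged, _ = process_fastq(fastq_writer(reads), nb_panel)
        fams = group_families(tagged)
        cons, n_small = build_all_consensus(fams)
        assert len(cons) + n_small == len(fams)
        assert len(cons) <= len(fams)


def brute_force_consensus(members, target_length, threshold=0.6):
    """Independent per-position tally (kept deliberately different from the
    implementation: builds explicit per-position lists)."""
    out = []
    for pos in range(target_length):
        column = [m[pos] for m in members if pos < len(m) and m[pos] != "N"]
        if not column:
            out.append("N")
            continue
        tally = Counter(column)
        best = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(best) > 1 and best[0][1] == best[1][1]:
            out.append("N")
        elif best[0][1] / len(column) >= threshold:
            out.append(best[0][0])
        else:
            out.append("N")
    return "".join(out)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.lists(
    st.lists(st.text(alphabet="ACGT", min_size=4, max_size=4),
             min_size=1, max_size=6),
    min_size=1, max_size=5))
def test_consensus_matches_brute_force(families):
    """Exhaustive small-instance equivalence with an independent tally."""
    for i, members in enumerate(families):
        fam = UmiFamily("a1", f"UMI{i}", members)
        cons = build_consensus(fam, min_family_size=1, target_length=4)
        assert cons.sequence == brute_force_consensus(members, 4)


class TestPileup:
    def _assay(self, nb_panel):
        return nb_panel.assays[0]

    def test_identical_reads(self, nb_panel):
        a = self._assay(nb_panel)
        cons = [ConsensusRead(a.assay_id, f"u{i}", 3, a.reference_insert)
                for i in range(10)]
        pile = consensus_pileup(cons, a)
        for i in range(a.target_length):
            counts = pile[a.target_start + i]
            assert counts[a.reference_insert[i]] == 10
            assert sum(counts.values()) == 10

    def test_n_reduces_depth(self, nb_panel):
        a = self._assay(nb_panel)
        seq_n = "N" + a.reference_insert[1:]
        cons = [ConsensusRead(a.assay_id, f"u{i}", 3, a.reference_insert)
                for i in range(9)] + [ConsensusRead(a.assay_id, "u9", 3, seq_n)]
        pile = consensus_pileup(cons, a)
        assert sum(pile[a.target_start].values()) == 9
        assert sum(pile[a.target_start + 1].values()) == 10

    def test_mixed_assays_rejected(self, nb_panel):
        a = nb_panel.assays[0]
        other = ConsensusRead(nb_panel.assays[1].assay_id, "u", 3, "ACGT")
        with pytest.raises(ValueError, match="pileup"):
            consensus_pileup([other], a)

    def test_pileup_matches_recount(self, nb_panel):
        import random
        rng = random.Random(0)
        a = self._assay(nb_panel)
        cons = []
        for i in range(20):
            seq = "".join(rng.choice("ACGTN") for _ in range(a.target_length))
            cons.append(ConsensusRead(a.assay_id, f"u{i}", 3, seq))
        pile = consensus_pileup(cons, a)
        for i in range(a.target_length):
            for base in "ACGT":
                manual = sum(1 for c in cons if c.sequence[i] == base)
                assert pile[a.target_start + i][base] == manual


class TestErrorTiers:
    def test_late_errors_suppressed_100x(self, hras_panel, fastq_writer):
        """Raw non-reference rate ~ p; a consensus error needs a >=60%
        same-base majority of wrong reads, whose leading term for the minimal
        family (2 of 3 same substitution) is 9*(p/3)^2 ~ 1e-6 at p=1e-3 —
        three orders below raw, so a 100x floor is conservative."""
        reads, _ = simulate_sample(
            hras_panel,
            SimulationParams(molecules_per_assay=2500,
                             late_error_rate=1e-3, seed=17))
        tagged, _ = process_fastq(fastq_writer(reads), hras_panel)
        assay = hras_panel.assays[0]
        ref = assay.reference_insert

        raw_bases = raw_nonref = 0
        for t in tagged:
            for i, b in enumerate(t.insert):
                raw_bases += 1
                raw_nonref += b != ref[i]
        raw_rate = raw_nonref / raw_bases

        fams = group_families(tagged)
        cons, _ = build_all_consensus(
            fams, target_length_by_assay={assay.assay_id: assay.target_length})
        assert len([c for c in cons if c.family_size >= 3]) >= 2000
        cons_bases = cons_nonref = 0
        for c in cons:
            for i, b in enumerate(c.sequence):
                if b in "ACGT":
                    cons_bases += 1
                    cons_nonref += b != ref[i]
        cons_rate = cons_nonref / cons_bases
        assert raw_rate > 0
        assert cons_rate <= raw_rate / 100

    def test_early_errors_penetrate_consensus(self, hras_panel, fastq_writer):
        """First-copy errors reach every read of the family, so consensus
        carries them at the molecule-level rate: UMI correction cannot
        remove them."""
        eps = 0.01
        reads, manifest = simulate_sample(
            hras_panel,
            SimulationParams(molecules_per_assay=2000,
                             early_error_rate=eps, seed=19))
        tagged, _ = process_fastq(fastq_writer(reads), hras_panel)
        assay = hras_panel.assays[0]
        fams = group_families(tagged)
        cons, _ = build_all_consensus(
            fams, target_length_by_assay={assay.assay_id: assay.target_length})
        ref = assay.reference_insert
        nonref = sum(b != ref[i]
                     for c in cons for i, b in enumerate(c.sequence)
                     if b in "ACGT")
        bases = sum(b in "ACGT" for c in cons for b in c.sequence)
        rate = nonref / bases
        sd = (eps * (1 - eps) / bases) ** 0.5
        assert abs(rate - eps) < 5 * sd
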