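import random

import pandas as pd
import pytest

from iresmpra.readproc import (
    AMBIGUOUS,
    UNASSIGNED,
    ProcessedRead,
    assign_to_construct,
    count_unique_umis,
    extract_umi_and_stagger,
    hamming,
    iterate_fastq_pairs,
    merge_pairs,
    precollapse_duplicates,
    process_pairs,
    split_cap_classes,
)
from iresmpra.reference import ConstructLibrary, ConstructRecord, revcomp
from iresmpra.simulate import ReadArchitecture

ARCH = ReadArchitecture()


def _rand_seq(n, seed=0):
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestMergePairs:
    def test_exact_overlap_arithmetic(self):
        r1 = _rand_seq(150, 1)
        r2 = revcomp(r1[75:])  # overlap 75, 0 mismatches
        merged = merge_pairs(r1, r2)
        assert merged == r1
        assert len(merged) == len(r1) + len(r2) - 75

    def test_extension_beyond_r1(self):
        amplicon = _rand_seq(200, 2)
        r1, r2 = amplicon[:150], revcomp(amplicon[50:])
        assert merge_pairs(r1, r2) == amplicon

    def test_no_overlap_returns_none(self):
        r1 = "A" * 40 + _rand_seq(20, 3)
        r2 = "C" * 60
        assert merge_pairs(r1, r2, min_overlap=10) is None

    def test_mismatch_rate_threshold(self):
        # best (and only real) overlap is 20 nt; inject mismatches around the
        # floor(rate x overlap) budget, verified by hand against the enumerated
        # best overlap
        core = _rand_seq(20, 4)
        r1 = _rand_seq(60, 5) + core
        tail = core + _rand_seq(60, 6)
        two_off = list(tail)
        two_off[3] = {"A": "C", "C": "A", "G": "T", "T": "G"}[two_off[3]]
        two_off[8] = {"A": "C", "C": "A", "G": "T", "T": "G"}[two_off[8]]
        r2_ok = revcomp("".join(two_off))  # 2 mismatches / 20 = 0.10 <= 0.1
        assert merge_pairs(r1, r2_ok, min_overlap=15, max_mismatch_rate=0.1) is not None
        three_off = list("".join(two_off))
        three_off[13] = {"A": "C", "C": "A", "G": "T", "T": "G"}[three_off[13]]
        r2_bad = revcomp("".join(three_off))  # 3/20 just above threshold
        assert merge_pairs(r1, r2_bad, min_overlap=15, max_mismatch_rate=0.1) is None

    def test_consensus_resolves_toward_r1(self):
        amplicon = _rand_seq(120, 7)
        r1 = amplicon[:80]
        mism = list(amplicon)
        mism[60] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mism[60]]
        r2 = revcomp("".join(mism)[40:])
        merged = merge_pairs(r1, r2)
        assert merged[:80] == r1  # disagreement at 60 resolved to r1's base
        assert merged[80:] == amplicon[80:]


class TestSplitCapClasses:
    def _merged(self, cls, utr):
        return ARCH.cap_adapter(cls) + utr + ARCH.common_adapter + "NN"

    def test_gcap_adapter_exact(self):
        utr = _rand_seq(60, 8)
        cls, insert, partial = split_cap_classes(self._merged("g_cap", utr), ARCH, "single")
        assert (cls, insert, partial) == ("g_cap", utr, False)

    def test_acap_adapter_exact(self):
        utr = _rand_seq(60, 9)
        assert split_cap_classes(self._merged("a_cap", utr), ARCH, "single")[0] == "a_cap"

    def test_neither_adapter_unassigned(self):
        read = _rand_seq(40, 10) + ARCH.common_adapter
        assert split_cap_classes(read, ARCH, "single")[0] == "unassigned"

    def test_both_adapters_unassigned(self):
        read = ARCH.acap_adapter + ARCH.gcap_adapter + "ACGT" + ARCH.common_adapter
        assert split_cap_classes(read, ARCH, "single")[0] == "unassigned"

    def test_missing_common_adapter_unassigned(self):
        read = ARCH.gcap_adapter + _rand_seq(60, 11)
        assert split_cap_classes(read, ARCH, "single")[0] == "unassigned"

    def test_mismatch_budget_single_vs_paired(self):
        # one substitution in the cap adapter: rejected in single mode (-e 0),
        # accepted in paired mode (floor(0.07 x 17) = 1)
        utr = _rand_seq(60, 12)
        bad_adapter = "A" + ARCH.gcap_adapter[1:]  # T->A at position 0
        merged = bad_adapter + utr + ARCH.common_adapter
        assert split_cap_classes(merged, ARCH, "single")[0] == "unassigned"
        m1t = ARCH.pair_5p_anchor + revcomp(utr)
        m2t = bad_adapter + utr + ARCH.common_adapter
        cls, insert, partial = split_cap_classes((m1t, m2t), ARCH, "paired")
        assert cls == "g_cap" and insert == utr and partial is False

    def test_paired_partial_insert(self):
        utr = _rand_seq(200, 13)
        m1t = ARCH.pair_5p_anchor + revcomp(utr)[:100]
        m2t = ARCH.acap_adapter + utr[:120]  # common adapter out of reach
        cls, insert, partial = split_cap_classes((m1t, m2t), ARCH, "paired")
        assert cls == "a_cap" and partial is True and insert == utr[:120]

    def test_paired_requires_mate1_anchor(self):
        utr = _rand_seq(60, 14)
        m2t = ARCH.gcap_adapter + utr + ARCH.common_adapter
        assert split_cap_classes(("GGGG" + _rand_seq(40, 15), m2t), ARCH, "paired")[0] == "unassigned"


class TestExtractUmiStagger:
    def _mate1(self, stagger):
        return "N" * stagger + ARCH.pair_5p_anchor + _rand_seq(80, 16)

    def _mate2(self, umi):
        return umi + ARCH.umi_anchor + _rand_seq(80, 17)

    @pytest.mark.parametrize("stagger", [0, 3, 6])
    def test_stagger_prefix_count(self, stagger):
        umi, st, _ = extract_umi_and_stagger(self._mate1(stagger), self._mate2("ACGTACGTA"))
        assert st == stagger

    @pytest.mark.parametrize("umi", ["ACGTACGTA", "ACGTACGTAC", "ACGTACGTACG"])
    def test_umi_lengths_disambiguated_by_anchor(self, umi):
        got, st, (m1t, m2t) = extract_umi_and_stagger(self._mate1(2), self._mate2(umi))
        assert got == umi
        assert not m2t.startswith(ARCH.umi_anchor)

    def test_missing_anchor_excludes_read(self):
        r2 = _rand_seq(100, 18)
        umi, st, (m1t, m2t) = extract_umi_and_stagger(self._mate1(1), r2)
        assert umi is None
        assert m2t == r2  # untrimmed


class TestPrecollapse:
    def _read(self, insert, umi, st):
        return ProcessedRead("r", insert, "a_cap", umi, st, True)

    def test_stagger_variants_survive_stage_one(self):
        reads = [self._read("AAAA", "CCCCCCCCC", s) for s in (2, 2, 5, 5)]
        assert len(precollapse_duplicates(reads)) == 2

    def test_unique_reads_identity(self):
        reads = [self._read(f"AAA{i}".replace("0", "A"), "C" * 9, 1) for i in range(1, 4)]
        assert precollapse_duplicates(reads) == reads

    def test_empty_input(self):
        assert precollapse_duplicates([]) == []

    def test_cap_classes_never_collapse_together(self):
        # adapters are trimmed from the insert, so an a_cap and a g_cap
        # molecule of one construct can collide on (insert, umi, stagger);
        # they are distinct molecules and must both survive
        a = ProcessedRead("r1", "AAAA", "a_cap", "C" * 9, 2, True)
        g = ProcessedRead("r2", "AAAA", "g_cap", "C" * 9, 2, True)
        assert len(precollapse_duplicates([a, g])) == 2


class TestAssignment:
    @pytest.fixture(scope="class")
    @staticmethod
    def lib():
        rng = random.Random(99)
        recs = [
            ConstructRecord(f"c{i}", "".join(rng.choice("ACGT") for _ in range(80)))
            for i in range(30)
        ]
        return ConstructLibrary(recs)

    def test_exact_match(self, lib):
        for rec in lib:
            assert assign_to_construct(rec.utr_sequence, lib) == rec.construct_id

    def test_tie_between_siblings_is_ambiguous(self):
        # two scanning-mutant siblings each 1 mismatch from the query
        base = _rand_seq(80, 20)
        v1 = "A" + base[1:] if base[0] != "A" else "C" + base[1:]
        v2 = base[:-1] + ("A" if base[-1] != "A" else "C")
        lib = ConstructLibrary([ConstructRecord("s1", v1), ConstructRecord("s2", v2)])
        assert assign_to_construct(base, lib, max_mismatches=2) == AMBIGUOUS

    def test_no_hit_within_budget_unassigned(self, lib):
        foreign = _rand_seq(80, 21)
        assert assign_to_construct(foreign, lib, max_mismatches=2) == UNASSIGNED

    def test_mutated_inserts_against_bruteforce_oracle(self, lib):
        rng = random.Random(7)
        seqs = {r.construct_id: r.utr_sequence for r in lib}
        for _ in range(50):
            cid = rng.choice(list(seqs))
            s = list(seqs[cid])
            for p in rng.sample(range(len(s)), 2):
                s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
            query = "".join(s)
            dists = {c: hamming(query, seq) for c, seq in seqs.items()}
            best = min(dists.values())
            winners = [c for c, d in dists.items() if d == best]
            expected = (
                UNASSIGNED if best > 2 else (winners[0] if len(winners) == 1 else AMBIGUOUS)
            )
            assert assign_to_construct(query, lib, max_mismatches=2) == expected

    def test_partial_prefix_assignment(self, lib):
        rec = lib.constructs[0]
        prefix = rec.utr_sequence[:50]
        assert assign_to_construct(prefix, lib, cap_class="a_cap", partial=True) == rec.construct_id


class TestCountUniqueUmis:
    def test_set_cardinality(self):
        triples = [("X", "a_cap", "AAAAAAAAA"), ("X", "a_cap", "AAAAAAAAA"), ("X", "a_cap", "CCCCCCCCC")]
        df = count_unique_umis(triples, "s")
        assert df.loc[0, "count"] == 2

    def test_same_umi_on_two_constructs_counts_for_each(self):
        triples = [("X", "a_cap", "AAAAAAAAA"), ("Y", "a_cap", "AAAAAAAAA")]
        df = count_unique_umis(triples, "s").set_index("construct_id")["count"]
        assert df["X"] == 1 and df["Y"] == 1

    def test_matches_bruteforce_triple_tally(self):
        rng = random.Random(3)
        triples = [
            (f"c{rng.randrange(5)}", rng.choice(["a_cap", "g_cap"]), _rand_seq(9, rng.randrange(10**6)))
            for _ in range(2000)
        ]
        df = count_unique_umis(triples, "s")
        brute = {}
        for t in set(triples):
            brute[(t[0], t[1])] = brute.get((t[0], t[1]), 0) + 1
        got = {(r.construct_id, r.cap_class): r.count for r in df.itertuples()}
        assert got == brute


class TestProcessPairs:
    def test_class_totals_partition_input(self, toy_processed):
        for sid in ("in1", "ip1"):
            rep = toy_processed[sid]["result"].report
            assert rep["a_cap"] + rep["g_cap"] + rep["unassigned"] == rep["total"]
            assert rep["merged"] + rep["unmerged"] + rep["umi_or_stagger_missing"] == rep["total"]

    def test_error_free_channel_recovers_sidecar_exactly(self, toy_processed):
        for sid in ("in1", "ip1"):
            res = toy_processed[sid]["result"]
            assert res.report["unassigned"] == 0
            assert res.report["ambiguous"] == 0
            for rid, cid, cls, umi, mol in toy_processed[sid]["sidecar"]:
                assert res.assignments[rid] == (cls, cid)

    def test_counts_equal_bruteforce_sidecar_tally(self, toy_processed):
        for sid in ("in1", "ip1"):
            res = toy_processed[sid]["result"]
            brute = {}
            for rid, cid, cls, umi, mol in toy_processed[sid]["sidecar"]:
                brute.setdefault((cid, cls), set()).add(umi)
            expected = {k: len(v) for k, v in brute.items()}
            got = {(r.construct_id, r.cap_class): r.count for r in res.counts.itertuples()}
            assert got == expected

    def test_invariant_to_read_order_and_duplication(self, toy_library, toy_processed):
        reads = toy_processed["in1"]["reads"][:3000]
        base = process_pairs(iter(reads), toy_library, "s").counts
        shuffled = list(reads)
        random.Random(1).shuffle(shuffled)
        assert process_pairs(iter(shuffled), toy_library, "s").counts.equals(base)
        doubled = reads + [(rid + "dup", a, b) for rid, a, b in reads]
        assert process_pairs(iter(doubled), toy_library, "s").counts.equals(base)


class TestFastqPairIteration:
    def _write(self, path, records):
        path.write_text("".join(f"@{r}\n{s}\n+\n{'I' * len(s)}\n" for r, s in records))

    def test_pairs_yielded_with_shared_stem(self, tmp_path):
        self._write(tmp_path / "r1.fastq", [("a/1", "ACGT"), ("b/1", "GGGG")])
        self._write(tmp_path / "r2.fastq", [("a/2", "TTTT"), ("b/2", "CCCC")])
        out = list(iterate_fastq_pairs(tmp_path / "r1.fastq", tmp_path / "r2.fastq"))
        assert out == [("a", "ACGT", "TTTT"), ("b", "GGGG", "CCCC")]

    def test_mate_id_mismatch_is_error(self, tmp_path):
        self._write(tmp_path / "r1.fastq", [("a/1", "ACGT")])
        self._write(tmp_path / "r2.fastq", [("z/2", "TTTT")])
        with pytest.raises(ValueError, match="mismatch"):
            list(iterate_fastq_pairs(tmp_path / "r1.fastq", tmp_path / "r2.fastq"))
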