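"""Tag/error k-mer selection filters and database round trips."""

import numpy as np
import pytest

from tagdepth.kmer_core import KmerCode, encode_canonical, min_strand_distance
from tagdepth.list_builder import (
    DatabaseFormatError,
    KmerDatabase,
    TagKmer,
    build_database,
    build_genome_index,
    filter_hamming_isolated,
    filter_spacing,
    generate_error_kmers,
    read_database,
    select_unique_universal,
    write_database,
)
from tagdepth.simulator import Repeat, generate_genome

from _oracles import (
    brute_force_tags,
    canonical,
    genome_kmer_counts,
    min_strand_hamming,
    revcomp,
    scan_windows,
)
from conftest import random_seq


class TestGenomeIndex:
    def test_hand_enumerated_counts(self):
        ix = build_genome_index(("r", "ACGTACGT"), 5)
        # windows: ACGTA CGTAC GTACG TACGT; canonical by hand
        expected = {}
        for w in ["ACGTA", "CGTAC", "GTACG", "TACGT"]:
            expected[canonical(w)] = expected.get(canonical(w), 0) + 1
        got = {c.decode(): n for c, n in ix.as_dict().items()}
        assert got == expected
        assert ix.total_windows == 4

    def test_total_windows_fixed_seed(self, rng):
        seq = random_seq(rng, 1000)
        ix = build_genome_index(("r", seq), 25)
        assert ix.total_windows == 976

    def test_counts_equal_naive_oracle(self, rng):
        records = [("a", random_seq(rng, 600, p_n=0.02)), ("b", random_seq(rng, 400))]
        ix = build_genome_index(records, 9)
        oracle = genome_kmer_counts(records, 9)
        got = {c.decode(): n for c, n in ix.as_dict().items()}
        assert got == oracle
        assert ix.total_windows == sum(oracle.values())

    def test_empty_input_rejected(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        with pytest.raises(DatabaseFormatError):
            build_genome_index(p, 25)

    def test_fasta_roundtrip_gzip(self, rng, tmp_path):
        from tagdepth.simulator import write_fasta

        records = [("chr1", random_seq(rng, 500)), ("chr2", random_seq(rng, 300))]
        path = tmp_path / "g.fa.gz"
        write_fasta(records, path)
        ix = build_genome_index(path, 11)
        ix2 = build_genome_index(records, 11)
        assert np.array_equal(ix.codes, ix2.codes)
        assert np.array_equal(ix.counts, ix2.counts)
        assert ix.record_lengths == {"chr1": 500, "chr2": 300}


class TestSelectUniqueUniversal:
    def test_duplicated_segment_excluded(self, rng):
        seq = random_seq(rng, 1000)
        dup = seq[:400] + seq[100:200] + seq[400:]  # exact 100 bp duplication
        ix = build_genome_index(("r", dup), 15)
        cand = select_unique_universal(ix, [])
        counts = genome_kmer_counts([("r", dup)], 15)
        inside = {canonical(dup[i : i + 15]) for i in range(100, 200 - 14)}
        got = {c.decode() for c, _, _ in cand.to_tuples()}
        assert not (got & inside)
        assert got == {w for w, n in counts.items() if n == 1}

    def test_no_others_keeps_all_count1(self, rng):
        seq = random_seq(rng, 500)
        ix = build_genome_index(("r", seq), 13)
        cand = select_unique_universal(ix, [])
        oracle = {w for w, n in genome_kmer_counts([("r", seq)], 13).items() if n == 1}
        assert {c.decode() for c, _, _ in cand.to_tuples()} == oracle

    def test_set_algebra_oracle_with_second_assembly(self, rng):
        primary = random_seq(rng, 5000)
        other = primary[:2500] + random_seq(rng, 2500)  # shares half
        ixp = build_genome_index(("p", primary), 15)
        ixo = build_genome_index(("o", other), 15)
        cand = select_unique_universal(ixp, [ixo])
        cp = genome_kmer_counts([("p", primary)], 15)
        co = genome_kmer_counts([("o", other)], 15)
        oracle = {w for w, n in cp.items() if n == 1 and co.get(w) == 1}
        assert {c.decode() for c, _, _ in cand.to_tuples()} == oracle

    def test_locus_is_the_unique_occurrence(self, rng):
        seq = random_seq(rng, 400)
        ix = build_genome_index(("r", seq), 11)
        cand = select_unique_universal(ix, [])
        for code, rec, pos in cand.to_tuples():
            assert rec == "r"
            assert canonical(seq[pos : pos + 11]) == code.decode()

    def test_k_mismatch_rejected(self, rng):
        a = build_genome_index(("r", random_seq(rng, 200)), 11)
        b = build_genome_index(("r", random_seq(rng, 200)), 13)
        with pytest.raises(ValueError):
            select_unique_universal(a, [b])


class TestHammingIsolation:
    def _survivor_oracle(self, records, k):
        counts = genome_kmer_counts(records, k)
        unique = {w for w, n in counts.items() if n == 1}
        out = set()
        for w in unique:
            if all(min_strand_hamming(w, v) > 1 for v in counts if v != w):
                out.add(w)
        return out

    def test_one_mismatch_copy_removes_overlapping_candidates(self, rng):
        k = 15
        # segment S plus a copy of S with one substituted base
        g = generate_genome(
            1200, np.random.default_rng(5), repeat_spec=[Repeat(100, 400, 700, mismatches=1)]
        )
        ix = build_genome_index(g, k)
        cand = select_unique_universal(ix, [])
        surv = filter_hamming_isolated(cand, ix)
        got = {c.decode() for c, _, _ in surv.to_tuples()}
        assert got == self._survivor_oracle([g], k)
        assert len(surv) < len(cand)  # windows near the substitution got removed

    def test_identity_on_isolated_genome(self, rng):
        k = 15
        seq = random_seq(rng, 800)
        records = [("r", seq)]
        ix = build_genome_index(records, k)
        cand = select_unique_universal(ix, [])
        # verified isolated by brute force
        assert self._survivor_oracle(records, k) == {
            c.decode() for c, _, _ in cand.to_tuples()
        }
        surv = filter_hamming_isolated(cand, ix)
        assert len(surv) == len(cand)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_all_pairs_oracle(self, seed):
        k = 11
        g = generate_genome(
            2000, np.random.default_rng(seed),
            repeat_spec=[Repeat(50, 250, 500, mismatches=1), Repeat(900, 1000, 1500)],
        )
        ix = build_genome_index(g, k)
        surv = filter_hamming_isolated(select_unique_universal(ix, []), ix)
        assert {c.decode() for c, _, _ in surv.to_tuples()} == self._survivor_oracle([g], k)


class TestSpacing:
    def _mk_candidates(self, rng, n, k=25):
        from tagdepth.list_builder import CandidateSet

        seqs = {random_seq(rng, k) for _ in range(3 * n)}
        codes = sorted(encode_canonical(s).word for s in seqs)[:n]
        return codes

    def test_every_window_occupied_gives_every_third(self, rng):
        seq = random_seq(rng, 1000)
        ix = build_genome_index(("r", seq), 5)  # k=5: candidates everywhere
        cand = select_unique_universal(ix, [])
        tags = filter_spacing(cand)
        wins = {t.position // 100 for t in tags}
        # eligible windows 0,3,6,9 (those that still have unique 5-mers)
        assert wins <= {0, 3, 6, 9}

    def test_arithmetic_with_dense_synthetic_candidates(self):
        from tagdepth.list_builder import CandidateSet

        # one candidate at every position of a 1000 bp record
        n = 976
        cand = CandidateSet(
            k=25,
            codes=np.arange(n, dtype=np.uint64),
            record_ids=np.zeros(n, np.int32),
            positions=np.arange(n, dtype=np.int64),
            record_names=["r"],
        )
        tags = filter_spacing(cand)
        assert [(t.record, t.position) for t in tags] == [
            ("r", 0), ("r", 300), ("r", 600), ("r", 900),
        ]

    def test_empty_eligible_window_contributes_nothing(self):
        from tagdepth.list_builder import CandidateSet

        # candidates only in windows 1 and 3: window 1 ineligible, window 3 kept
        cand = CandidateSet(
            k=25,
            codes=np.array([5, 9], np.uint64),
            record_ids=np.zeros(2, np.int32),
            positions=np.array([150, 330], np.int64),
            record_names=["r"],
        )
        tags = filter_spacing(cand)
        assert [(t.position) for t in tags] == [330]

    @pytest.mark.parametrize("seed", range(5))
    def test_spacing_at_least_200_within_record(self, seed):
        from tagdepth.list_builder import CandidateSet

        rng = np.random.default_rng(seed)
        n = 500
        positions = np.sort(rng.choice(5000, size=n, replace=False)).astype(np.int64)
        cand = CandidateSet(
            k=25,
            codes=rng.permutation(np.arange(10 * n))[:n].astype(np.uint64),
            record_ids=rng.integers(0, 2, n).astype(np.int32),
            positions=positions,
            record_names=["a", "b"],
        )
        tags = filter_spacing(cand)
        by_rec: dict[str, list[int]] = {}
        for t in tags:
            by_rec.setdefault(t.record, []).append(t.position)
        for poss in by_rec.values():
            assert all(b - a >= 200 for a, b in zip(poss, poss[1:]))


class TestErrorKmers:
    @pytest.fixture
    def toy(self):
        g = generate_genome(4000, np.random.default_rng(9), name="g")
        ix = build_genome_index(g, 15)
        cand = filter_hamming_isolated(select_unique_universal(ix, []), ix)
        tags = filter_spacing(cand)
        return g, ix, tags

    def test_invariants_by_brute_force(self, toy):
        g, ix, tags = toy
        errors = generate_error_kmers(tags, ix, rng_seed=3)
        counts = genome_kmer_counts([g], 15)
        tag_words = {t.code.word for t in tags}
        seen = set()
        for e in errors:
            assert min_strand_distance(e.code, e.parent.code) == 1
            assert e.code.decode() not in counts  # absent from the genome
            assert e.code.word not in tag_words
            assert e.code.word not in seen
            seen.add(e.code.word)
            # no genomic k-mer other than the parent within distance 1
            for v in counts:
                if v == e.parent.code.decode():
                    continue
                assert min_strand_hamming(e.code.decode(), v) > 1
            # recorded mismatch reproduces the code from the parent
            p = e.parent.code.decode()
            mutated = p[: e.mm_position] + e.mm_base + p[e.mm_position + 1 :]
            assert canonical(mutated) == e.code.decode()

    def test_determinism_and_seed_sensitivity(self, toy):
        g, ix, tags = toy
        a = generate_error_kmers(tags, ix, rng_seed=3)
        b = generate_error_kmers(tags, ix, rng_seed=3)
        c = generate_error_kmers(tags, ix, rng_seed=4)
        assert a == b
        assert [(e.mm_position, e.mm_base) for e in a] != [
            (e.mm_position, e.mm_base) for e in c
        ]

    def test_near_full_acceptance_on_random_genome(self):
        g = generate_genome(20000, np.random.default_rng(17), name="g")
        ix = build_genome_index(g, 25)
        tags = filter_spacing(filter_hamming_isolated(select_unique_universal(ix, []), ix))
        errors = generate_error_kmers(tags, ix, n_variants=4, rng_seed=1)
        assert len(errors) == 4 * len(tags)  # collisions vanishingly rare at k=25


class TestDatabaseIO:
    def test_roundtrip(self, tmp_path):
        g = generate_genome(3000, np.random.default_rng(2), name="g")
        db = build_database([g], k=15, seed=8)
        path = tmp_path / "db.tsv"
        write_database(db, path)
        back = read_database(path)
        assert back.k == db.k
        assert back.tags == db.tags
        assert back.errors == db.errors
        assert back.provenance == db.provenance

    def test_duplicate_tag_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "#tagdepth-db v1\n#k=5\n"
            "ACGTA\ttag\tr\t0\t0\t.\t.\t.\n"
            "ACGTA\ttag\tr\t300\t0\t.\t.\t.\n"
        )
        with pytest.raises(DatabaseFormatError, match="duplicate"):
            read_database(path)

    def test_hand_written_file(self, tmp_path):
        path = tmp_path / "tiny.tsv"
        path.write_text(
            "#tagdepth-db v1\n"
            "#k=5\n"
            '#provenance={"note": "hand-written"}\n'
            "AACGA\ttag\tchr1\t120\t0\t.\t.\t.\n"
            "AACTA\terr\tchr1\t120\t0\tAACGA\t3\tT\n"
            "AACCA\terr\tchr1\t120\t0\tAACGA\t3\tC\n"
        )
        db = read_database(path)
        assert db.k == 5
        assert len(db.tags) == 1 and len(db.errors) == 2
        assert db.tags[0] == TagKmer(encode_canonical("AACGA"), "chr1", 120)
        assert {e.code.decode() for e in db.errors} == {
            canonical("AACTA"), canonical("AACCA")
        }
        assert all(e.parent is db.tags[0] for e in db.errors)
        assert db.provenance == {"note": "hand-written"}

    def test_bad_magic_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("#something-else\n")
        with pytest.raises(DatabaseFormatError, match="magic"):
            read_database(path)

    def test_orphan_error_parent_rejected(self, tmp_path):
        path = tmp_path / "orphan.tsv"
        path.write_text(
            "#tagdepth-db v1\n#k=5\nAACTA\terr\tchr1\t0\t0\tAACGA\t3\tT\n"
        )
        with pytest.raises(DatabaseFormatError, match="parent"):
            read_database(path)


class TestEndToEnd:
    @pytest.mark.parametrize("seed", [4, 5])
    def test_pipeline_equals_brute_force(self, seed):
        k = 13
        g = generate_genome(
            2500, np.random.default_rng(seed),
            repeat_spec=[Repeat(0, 150, 1200), Repeat(300, 450, 2000, mismatches=1)],
        )
        db = build_database([g], k=k, seed=0)
        oracle = brute_force_tags([g], k)
        got = [(t.code.decode(), t.record, t.position) for t in db.tags]
        assert got == oracle

    def test_multi_assembly_uniqueness(self, rng):
        k = 13
        primary = ("p", random_seq(rng, 3000))
        other = ("o", primary[1][:1500] + random_seq(rng, 1500))
        db = build_database([primary, other], k=k, seed=0)
        oracle = brute_force_tags([primary], k, others=[[other]])
        assert [(t.code.decode(), t.record, t.position) for t in db.tags] == oracle

    def test_database_invariants(self):
        g = generate_genome(5000, np.random.default_rng(33), name="g")
        db = build_database([g], k=15, seed=2)
        tag_words = {t.code.word for t in db.tags}
        err_words = {e.code.word for e in db.errors}
        assert len(tag_words) == len(db.tags)
        assert not (tag_words & err_words)
        assert len(db.errors) <= 4 * len(db.tags)

    def test_full_determinism(self):
        g = generate_genome(3000, np.random.default_rng(6), name="g")
        a = build_database([g], k=15, seed=5)
        b = build_database([g], k=15, seed=5)
        assert a.tags == b.tags and a.errors == b.errors and a.provenance == b.provenance
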