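"""Mining contracts: sampling, clustering vs a brute-force k-mer
oracle, tandem period detection, consensus recovery and the iterative
round loop."""

from itertools import combinations

import numpy as np
import pytest

from satellitome._seq import Read, canonical_rotation, revcomp
from satellitome.classification import ConsensusRecord, pairwise_identity
from satellitome.mining import (
    EmptyLibraryError,
    build_consensus,
    cluster_reads,
    detect_tandem_period,
    filter_matched_reads,
    greedy_assemble,
    match_known_library,
    run_mining_rounds,
    sample_reads,
)
from satellitome.synthetic_data import (
    FamilySpec,
    LibrarySpec,
    make_consensus,
    mutate_copy,
    plant_genome,
    simulate_library,
)


def _canonical_kmers(seq: str, k: int) -> set:
    out = set()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        out.add(min(w, revcomp(w)))
    return out


def _brute_force_components(reads, k, min_shared):
    """Independent oracle: pairwise canonical k-mer sharing, then
    connected components of size >= 2."""
    kmers = [_canonical_kmers(r.sequence, k) for r in reads]
    adj = {i: set() for i in range(len(reads))}
    n_edges = 0
    for i, j in combinations(range(len(reads)), 2):
        if len(kmers[i] & kmers[j]) >= min_shared:
            adj[i].add(j)
            adj[j].add(i)
            n_edges += 1
    seen, comps = set(), []
    for s in range(len(reads)):
        if s in seen or not adj[s]:
            continue
        stack, comp = [s], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    edge_count = {
        c: sum(1 for i, j in combinations(sorted(c), 2) if j in adj[i]) for c in comps
    }
    return {c: edge_count[c] for c in comps}


class TestSampleReads:
    def test_clamps_to_library_size(self):
        lib = [Read(f"r{i}", "ACGT" * 10) for i in range(10)]
        assert len(sample_reads(lib, 20, 1)) == 10

    def test_deterministic_and_distinct(self):
        lib = [Read(f"r{i}", "ACGT" * 10) for i in range(10_000)]
        a = sample_reads(lib, 2_000, 5)
        b = sample_reads(lib, 2_000, 5)
        assert a == b
        assert len({r.id for r in a}) == 2_000

    def test_empty_library_rejected(self):
        with pytest.raises(EmptyLibraryError):
            sample_reads([], 5, 0)


class TestClusterReads:
    def test_matches_brute_force_oracle(self, two_family_reads):
        reads = [r for r in two_family_reads["reads"][:3000]][:120]
        got = cluster_reads(reads, k=13, min_shared_kmers=3, min_kmer_count=2)
        want = _brute_force_components(reads, 13, 3)
        got_sets = {frozenset(c.member_indices): c for c in got}
        assert set(got_sets) == set(want)
        for comp, cl in got_sets.items():
            n = len(comp)
            assert cl.graph_density == pytest.approx(want[comp] / (n * (n - 1) / 2))

    def test_one_tandem_array_clusters_fully(self):
        cons = make_consensus(36, 0.6, 21)
        array = cons * 60
        rng = np.random.default_rng(0)
        reads = [
            Read(f"t{i}", array[p : p + 100])
            for i, p in enumerate(rng.integers(0, len(array) - 100, 50))
        ]
        clusters = cluster_reads(reads, k=13, min_shared_kmers=3)
        assert len(clusters) == 1
        assert clusters[0].size == 50
        assert clusters[0].graph_density == 1.0

    def test_two_families_stay_disjoint(self, two_family_reads):
        cons = two_family_reads["consensuses"]
        ra = [Read(f"a{i}", (cons["famA"] * 5)[i : i + 100]) for i in range(0, 60, 4)]
        rb = [Read(f"b{i}", (cons["famB"] * 5)[i : i + 100]) for i in range(0, 30, 2)]
        clusters = cluster_reads(ra + rb, k=13, min_shared_kmers=3)
        assert len(clusters) == 2
        members = [set(c.member_read_ids) for c in clusters]
        assert {m for ms in members for m in ms} == {r.id for r in ra + rb}
        assert all(
            ids <= {r.id for r in ra} or ids <= {r.id for r in rb} for ids in members
        )

    def test_unique_background_forms_no_cluster(self):
        cons = make_consensus(36, 0.6, 22)
        array = cons * 60
        rng = np.random.default_rng(1)
        tandem = [
            Read(f"t{i}", array[p : p + 100])
            for i, p in enumerate(rng.integers(0, len(array) - 100, 50))
        ]
        bg = make_consensus(20_000, 0.6, 23)
        # non-overlapping background reads: no shared k-mers
        unique = [Read(f"u{i}", bg[i * 150 : i * 150 + 100]) for i in range(50)]
        clusters = cluster_reads(tandem + unique, k=13, min_shared_kmers=3)
        clustered = {m for c in clusters for m in c.member_read_ids}
        assert clustered == {r.id for r in tandem}

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            cluster_reads([Read("r", "ACGT" * 10)], k=8)


class TestDetectTandemPeriod:
    def test_perfect_tandem(self):
        assert detect_tandem_period("ACGTG" * 10) == 5

    def test_random_sequence_has_no_period(self):
        seq = make_consensus(200, 0.5, 31)
        assert detect_tandem_period(seq) is None
        # agree with an exhaustive shift-identity scan in plain python
        for p in range(5, 101):
            overlap = [a == b for a, b in zip(seq, seq[p:])]
            assert sum(overlap) / len(overlap) < 0.8

    def test_mutated_tandem_recovers_monomer_length(self):
        cons = make_consensus(36, 0.6, 32)
        seq = "".join(mutate_copy(cons, 0.05, 2.0, 100 + i) for i in range(6))
        assert detect_tandem_period(seq) == 36

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            detect_tandem_period("ACGTACG")


class TestBuildConsensus:
    def _reads_from_array(self, array, n, seed, rl=100):
        rng = np.random.default_rng(seed)
        return [
            Read(f"r{i}", array[p : p + rl])
            for i, p in enumerate(rng.integers(0, len(array) - rl, n))
        ]

    def test_error_free_recovery(self):
        cons = make_consensus(36, 0.6, 41)
        reads = self._reads_from_array(cons * 60, 40, 2)
        rec = build_consensus(reads, record_id="c")
        assert rec is not None
        assert rec.sequence == canonical_rotation(cons)

    def test_divergent_copies_recovered_above_95pct(self):
        cons = make_consensus(36, 0.6, 42)
        array = "".join(mutate_copy(cons, 0.05, 2.0, 200 + i) for i in range(60))
        reads = self._reads_from_array(array, 60, 3)
        rec = build_consensus(reads, record_id="c")
        assert rec is not None
        assert pairwise_identity(rec.sequence, cons) >= 0.95

    def test_long_monomer_via_assembly(self):
        cons = make_consensus(177, 0.55, 43)
        array = "".join(mutate_copy(cons, 0.03, 2.0, 300 + i) for i in range(40))
        reads = self._reads_from_array(array, 300, 4)
        rec = build_consensus(reads, record_id="c")
        assert rec is not None
        assert rec.rul == 177
        assert pairwise_identity(rec.sequence, cons) >= 0.95

    def test_canonical_rotation_normalization(self):
        rec = ConsensusRecord.from_sequence("x", "GTAC")
        assert rec.sequence == canonical_rotation("GTAC")
        assert rec.sequence == min(
            min("GTAC"[i:] + "GTAC"[:i] for i in range(4)),
            min(revcomp("GTAC")[i:] + revcomp("GTAC")[:i] for i in range(4)),
        )

    def test_greedy_assembly_reconstructs_tandem(self):
        cons = make_consensus(150, 0.6, 44)
        array = cons * 20
        reads = self._reads_from_array(array, 200, 5)
        contig = greedy_assemble(reads)
        assert len(contig) >= 350
        assert detect_tandem_period(contig) == 150


class TestFilterMatchedReads:
    def test_family_library_reduced_to_noise(self, one_family):
        rec = ConsensusRecord.from_sequence("famA", one_family["consensus"])
        remaining = filter_matched_reads(one_family["reads"], [rec])
        # all reads drawn fully from the planted arrays must be gone
        survivors = {r.id for r in remaining}
        truth = one_family["truth"].loci
        spans = list(zip(truth["start"], truth["end"]))
        genome = one_family["genome"]
        inside = []
        for r in one_family["reads"]:
            seq = r.sequence
            pos = genome.find(seq)
            if pos < 0:
                pos = genome.find(revcomp(seq))
            if any(s <= pos and pos + len(seq) <= e for s, e in spans):
                inside.append(r.id)
        assert len(set(inside) & survivors) / max(1, len(inside)) <= 0.01

    def test_unrelated_consensus_changes_nothing(self, one_family):
        other = ConsensusRecord.from_sequence("x", make_consensus(36, 0.6, 55))
        remaining = filter_matched_reads(one_family["reads"], [other])
        assert remaining == list(one_family["reads"])

    def test_idempotent(self, one_family):
        rec = ConsensusRecord.from_sequence("famA", one_family["consensus"])
        once = filter_matched_reads(one_family["reads"], [rec])
        twice = filter_matched_reads(once, [rec])
        assert twice == once


class TestMatchKnownLibrary:
    def test_rotation_invariance(self):
        c = make_consensus(40, 0.6, 61)
        rot = c[7:] + c[:7]
        hit = match_known_library(rot, [c], 0.8)
        assert hit is not None and hit[1] == pytest.approx(1.0)

    def test_strand_invariance(self):
        c = make_consensus(40, 0.6, 62)
        hit = match_known_library(revcomp(c), [c], 0.8)
        assert hit is not None and hit[1] == pytest.approx(1.0)

    def test_unrelated_below_threshold(self):
        a = make_consensus(60, 0.5, 63)
        b = make_consensus(60, 0.5, 64)
        assert match_known_library(a, [b], 0.8) is None


class TestRunMiningRounds:
    def test_no_satellites_one_round(self):
        genome = make_consensus(200_000, 0.6, 71)
        reads = simulate_library(
            genome, LibrarySpec("bg", n_reads=5_000, seed=1, error_rate=0.0)
        )
        found, rounds = run_mining_rounds(reads, base_sample=2_000, seed=2)
        assert found == []
        assert len(rounds) == 1

    def test_sample_doubling_schedule(self):
        spec = FamilySpec("f", rul=30, divergence_target=0.02, copies_female=300, n_loci_female=2)
        genome, _ = plant_genome([spec], 400_000, "female", 72)
        reads = simulate_library(
            genome, LibrarySpec("sch", n_reads=20_000, seed=3, error_rate=0.0)
        )
        _, rounds = run_mining_rounds(reads, base_sample=1_000, max_rounds=4, seed=4)
        for r in rounds:
            assert r.sample_size == min(1_000 * 2 ** (r.round_index - 1), 20_000)

    def test_library_shrinks_monotonically(self, two_family_reads):
        reads = two_family_reads["reads"]
        _, rounds = run_mining_rounds(reads, base_sample=4_000, max_rounds=4, seed=5)
        sizes = [len(reads)] + [r.remaining_library_size for r in rounds]
        assert all(b <= a for a, b in zip(sizes, sizes[1:]))

    def test_emitted_consensuses_are_tandem_and_canonical(self, two_family_reads):
        found, _ = run_mining_rounds(
            two_family_reads["reads"], base_sample=4_000, max_rounds=4, seed=6
        )
        assert found
        for rec in found:
            assert rec.sequence == canonical_rotation(rec.sequence)
            assert detect_tandem_period(rec.sequence * 4) == rec.rul

    def test_recovers_both_planted_families(self, two_family_reads):
        found, _ = run_mining_rounds(
            two_family_reads["reads"], base_sample=4_000, max_rounds=4, seed=7
        )
        for fid, cons in two_family_reads["consensuses"].items():
            best = max(pairwise_identity(cons, f.sequence) for f in found)
            assert best >= 0.95, fid

    def test_determinism(self, two_family_reads):
        a, _ = run_mining_rounds(two_family_reads["reads"], base_sample=4_000, seed=8)
        b, _ = run_mining_rounds(two_family_reads["reads"], base_sample=4_000, seed=8)
        assert [r.sequence for r in a] == [r.sequence for r in b]
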