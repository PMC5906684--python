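"""Knuckle scanning, chelation calls, exact identity alignment and clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from znrfold.io import SequenceRecord
from znrfold.knuckles import (
    ClusterParams, KnuckleHit, classify_chelation, cluster_by_identity,
    find_knuckles, global_align_identity,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_hits(residues):
    """Independent exhaustive window enumeration with the published scoring."""
    hits = []
    for i in range(len(residues) - 4):
        w = residues[i:i + 5]
        n_cys = (w[0] == "C") + (w[3] == "C")
        score = {0: 0, 1: 1, 2: 2}[n_cys] + (w[1] == "P") + (w[4] == "G")
        if score >= 1:
            hits.append((i + 1, score))
    return hits


class TestFindKnuckles:
    def test_canonical_motif(self):
        hits = find_knuckles(SequenceRecord(id="a", residues="CPKCG"))
        assert len(hits) == 1
        h = hits[0]
        assert h.pattern_score == 4 and h.cys_present == {"C1", "C2"} and h.start == 1

    def test_no_motif(self):
        assert find_knuckles(SequenceRecord(id="a", residues="AAAAA")) == []

    def test_single_cysteine_scores_one(self):
        hits = find_knuckles(SequenceRecord(id="a", residues="CAKAA"))
        assert hits[0].pattern_score == 1 and hits[0].cys_present == {"C1"}

    @given(st.text(alphabet=AA, min_size=5, max_size=60))
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_enumeration(self, residues):
        hits = find_knuckles(SequenceRecord(id="p", residues=residues))
        assert [(h.start, h.pattern_score) for h in hits] == brute_force_hits(residues)


class TestClassifyChelation:
    def test_two_intact_knuckles(self):
        call = classify_chelation(
            SequenceRecord(id="a", residues="MAACPKCGAAAAAAAAAAAACPHCGAA"))
        assert call.state == "intact" and call.n_cys == 4
        assert call.spacing == 17

    def test_all_alanine_is_lost(self):
        call = classify_chelation(SequenceRecord(id="a", residues="A" * 40))
        assert call.state == "lost" and call.n_cys == 0
        assert call.knuckles == (None, None)

    def test_short_sequence_is_lost_not_error(self):
        call = classify_chelation(SequenceRecord(id="a", residues="CPK"))
        assert call.state == "lost"

    def test_partial_when_one_cysteine_mutated(self):
        call = classify_chelation(
            SequenceRecord(id="a", residues="MAASPKCGAAAAAAAAAAAACPHCGAA"))
        assert call.state == "partial" and call.n_cys == 3

    def test_spacing_bounds_respected(self):
        # knuckles only 6 apart: no valid pair, best single knuckle used
        call = classify_chelation(
            SequenceRecord(id="a", residues="CPKCGACPHCGA"), min_spacing=10)
        assert call.knuckles[1] is None and call.n_cys == 2
        assert call.state == "partial"

    def test_flank_invariance(self):
        core = "CPKCG" + "A" * 20 + "CPHCG"
        near = classify_chelation(SequenceRecord(id="a", residues=core))
        far = classify_chelation(SequenceRecord(id="b", residues="M" * 30 + core + "W" * 30))
        assert (near.state, near.n_cys) == (far.state, far.n_cys)

    def test_generator_truth_recovered_exactly(self):
        from znrfold.simulate import KnuckleSimSpec, simulate_knuckle_sequences

        pairs = simulate_knuckle_sequences(KnuckleSimSpec(n_sequences=120, seed=9))
        assert all(classify_chelation(rec).state == state for rec, state in pairs)


def oracle_identity(a, b):
    """Independent memoized-recursion NW oracle (match +1 / mismatch 0 / gap -1)
    with the same traceback preference (diagonal, then up, then left)."""
    import functools

    @functools.lru_cache(maxsize=None)
    def score(i, j):
        if i == 0 and j == 0:
            return 0.0
        best = -1e18
        if i > 0 and j > 0:
            best = max(best, score(i - 1, j - 1) + (1.0 if a[i - 1] == b[j - 1] else 0.0))
        if i > 0:
            best = max(best, score(i - 1, j) - 1.0)
        if j > 0:
            best = max(best, score(i, j - 1) - 1.0)
        return best

    i, j = len(a), len(b)
    matches = columns = both = 0
    while i > 0 or j > 0:
        s = score(i, j)
        if i > 0 and j > 0 and s == score(i - 1, j - 1) + (1.0 if a[i - 1] == b[j - 1] else 0.0):
            matches += a[i - 1] == b[j - 1]
            both += 1
            i, j = i - 1, j - 1
        elif i > 0 and s == score(i - 1, j) - 1.0:
            i -= 1
        else:
            j -= 1
        columns += 1
    return 100.0 * matches / columns, both / max(len(a), len(b))


class TestGlobalAlignIdentity:
    def test_identical(self):
        r = SequenceRecord(id="a", residues="MKVLW")
        assert global_align_identity(r, r) == (100.0, 1.0)

    def test_fully_different(self):
        identity, _ = global_align_identity(SequenceRecord(id="a", residues="AAAA"),
                                            SequenceRecord(id="b", residues="TTTT"))
        assert identity == 0.0

    def test_coverage_uses_longer_length(self):
        identity, coverage = global_align_identity(
            SequenceRecord(id="a", residues="MKVL"),
            SequenceRecord(id="b", residues="MKVLWXYH"))
        assert coverage == pytest.approx(4 / 8)
        assert identity == pytest.approx(100 * 4 / 8)

    @given(st.text(alphabet=AA, min_size=1, max_size=30),
           st.text(alphabet=AA, min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_identity_matches_independent_dp_oracle(self, sa, sb):
        got = global_align_identity(SequenceRecord(id="a", residues=sa),
                                    SequenceRecord(id="b", residues=sb))
        expected = oracle_identity(sa, sb)
        assert got[0] == pytest.approx(expected[0])
        assert got[1] == pytest.approx(expected[1])


class TestClusterByIdentity:
    def test_identical_set_single_cluster(self):
        seqs = [SequenceRecord(id=f"s{i}", residues="MKVLWAAGE") for i in range(4)]
        clusters = cluster_by_identity(seqs, ClusterParams(50.0, 0.9))
        assert len(clusters) == 1 and len(clusters[0].members) == 4

    def test_distinct_sequences_singletons_at_full_identity(self):
        seqs = [SequenceRecord(id="a", residues="MKVLWAAGE"),
                SequenceRecord(id="b", residues="PQRSTNYHE"),
                SequenceRecord(id="c", residues="GGGGIIIII")]
        clusters = cluster_by_identity(seqs, ClusterParams(100.0, 0.9))
        assert len(clusters) == 3
        assert all(len(c.members) == 1 for c in clusters)

    def test_planted_two_families(self, rng):
        base1 = "MKVLIAGTEWSDKLAAGELPKMQR"
        base2 = "PQRSTNYHEDFWCPILKMGGHHEE"

        def mutate(base, k):
            s = list(base)
            for pos in rng.choice(len(s), size=k, replace=False):
                s[pos] = AA[(AA.index(s[pos]) + 1) % 20]
            return "".join(s)

        seqs = ([SequenceRecord(id=f"f1_{i}", residues=mutate(base1, 3)) for i in range(5)]
                + [SequenceRecord(id=f"f2_{i}", residues=mutate(base2, 3)) for i in range(5)])
        clusters = cluster_by_identity(seqs, ClusterParams(50.0, 0.9))
        assert len(clusters) == 2
        families = {frozenset(c.members) for c in clusters}
        assert families == {frozenset(f"f1_{i}" for i in range(5)),
                            frozenset(f"f2_{i}" for i in range(5))}

    def test_output_partitions_input(self, rng):
        seqs = [SequenceRecord(id=f"s{i}",
                               residues="".join(AA[j] for j in rng.integers(20, size=20)))
                for i in range(12)]
        clusters = cluster_by_identity(seqs, ClusterParams(40.0, 0.5))
        all_members = [m for c in clusters for m in c.members]
        assert sorted(all_members) == sorted(s.id for s in seqs)

    def test_raising_threshold_never_merges(self, rng):
        seqs = [SequenceRecord(id=f"s{i}",
                               residues="".join(AA[j] for j in rng.integers(20, size=25)))
                for i in range(8)]
        loose = cluster_by_identity(seqs, ClusterParams(30.0, 0.5))
        strict = cluster_by_identity(seqs, ClusterParams(60.0, 0.5))
        # every strict cluster is inside one loose cluster
        loose_of = {m: frozenset(c.members) for c in loose for m in c.members}
        for c in strict:
            assert len({loose_of[m] for m in c.members}) == 1
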