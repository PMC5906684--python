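"""Zinc-knuckle motif scanning, chelation-state calls and identity clustering.

The zinc ribbon (ZnR) fold chelates a single Zn ion through two cysteine pairs,
one pair per beta-hairpin turn ("knuckle"), with the consensus motif CPxCG —
cysteines at motif positions 1 and 4. Cren7-like archaeal chromatin proteins
retain zero to four of these cysteines; scanning for degraded knuckles and
counting the surviving ligands is how a sequence is called intact / partial /
lost. A small BLASTCLUST-style single-linkage identity clustering supports
redundancy reduction of sequence sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .io import AMINO_ACIDS, SequenceRecord

__all__ = [
    "KnuckleHit",
    "ChelationCall",
    "ClusterParams",
    "SequenceCluster",
    "find_knuckles",
    "classify_chelation",
    "global_align_identity",
    "cluster_by_identity",
]

MOTIF_LENGTH = 5  # C P x C G
AROMATIC = frozenset("YWFH")


@dataclass(frozen=True)
class KnuckleHit:
    """A scored CPxCG-like window.

    ``start`` is the 1-based residue index of the window; ``cys_present``
    records which of the knuckle's two cysteines (C1 = motif position 1,
    C2 = motif position 4) are present.
    """

    start: int
    pattern_score: int
    cys_present: frozenset
    matched_text: str

    def __post_init__(self) -> None:
        assert self.start >= 1 and self.pattern_score >= 0
        assert len(self.matched_text) == MOTIF_LENGTH

    @property
    def n_cys(self) -> int:
        return len(self.cys_present)


@dataclass(frozen=True)
class ChelationCall:
    """Intact/partial/lost call over the best pair of knuckles.

    intact <=> 4 motif cysteines; partial <=> 2-3; lost <=> 0-1.
    """

    state: str
    n_cys: int
    knuckles: tuple[Optional[KnuckleHit], Optional[KnuckleHit]]
    spacing: Optional[int]

    def __post_init__(self) -> None:
        expected = _state_for(self.n_cys)
        assert self.state == expected, f"state {self.state} inconsistent with n_cys {self.n_cys}"


def _state_for(n_cys: int) -> str:
    if n_cys == 4:
        return "intact"
    if n_cys in (2, 3):
        return "partial"
    return "lost"


def find_knuckles(seq: SequenceRecord) -> list[KnuckleHit]:
    """Score every 5-residue window against the CPxCG knuckle consensus.

    Scoring: +2 if Cys at window positions 1 and 4, +1 if exactly one of them
    is Cys; +1 each for Pro at position 2 and Gly at position 5. Windows with
    score >= 1 are reported in position order; overlapping windows are all
    kept — pair selection happens in :func:`classify_chelation`.
    """
    s = seq.residues
    hits: list[KnuckleHit] = []
    for i in range(len(s) - MOTIF_LENGTH + 1):
        window = s[i:i + MOTIF_LENGTH]
        cys = frozenset(
            tag for tag, pos in (("C1", 0), ("C2", 3)) if window[pos] == "C"
        )
        score = {0: 0, 1: 1, 2: 2}[len(cys)]
        if window[1] == "P":
            score += 1
        if window[4] == "G":
            score += 1
        if score >= 1:
            hits.append(KnuckleHit(start=i + 1, pattern_score=score,
                                   cys_present=cys, matched_text=window))
    return hits


def classify_chelation(seq: SequenceRecord, min_spacing: int = 10,
                       max_spacing: int = 60) -> ChelationCall:
    """Call the chelation state from the best-scoring knuckle pair.

    Among all pairs of hits whose start positions are ``min_spacing`` to
    ``max_spacing`` residues apart, the pair maximising the summed pattern
    score wins (ties broken by the smaller first start, then second start).
    If no valid pair exists the single best hit is used; no hits at all gives
    a lost call with zero cysteines. Sequences shorter than the motif are
    treated the same way rather than raising.
    """
    if len(seq.residues) < MOTIF_LENGTH:
        return ChelationCall(state="lost", n_cys=0, knuckles=(None, None), spacing=None)
    hits = find_knuckles(seq)
    if not hits:
        return ChelationCall(state="lost", n_cys=0, knuckles=(None, None), spacing=None)

    best_pair: Optional[tuple[KnuckleHit, KnuckleHit]] = None
    best_key: Optional[tuple] = None
    for i, h1 in enumerate(hits):
        for h2 in hits[i + 1:]:
            gap = h2.start - h1.start
            if gap < max(min_spacing, MOTIF_LENGTH) or gap > max_spacing:
                continue
            key = (-(h1.pattern_score + h2.pattern_score), h1.start, h2.start)
            if best_key is None or key < best_key:
                best_key = key
                best_pair = (h1, h2)

    if best_pair is not None:
        h1, h2 = best_pair
        n_cys = h1.n_cys + h2.n_cys
        return ChelationCall(state=_state_for(n_cys), n_cys=n_cys,
                             knuckles=(h1, h2), spacing=h2.start - h1.start)

    solo = min(hits, key=lambda h: (-h.pattern_score, h.start))
    return ChelationCall(state=_state_for(solo.n_cys), n_cys=solo.n_cys,
                         knuckles=(solo, None), spacing=None)


# ---------------------------------------------------------------------------
# global alignment + identity clustering


def global_align_identity(a: SequenceRecord, b: SequenceRecord) -> tuple[float, float]:
    """Percent identity and coverage from an exact global alignment.

    Needleman–Wunsch with match +1, mismatch 0, linear gap −1, traceback
    preferring diagonal, then up (gap in ``b``), then left. Identity is
    matches over aligned column pairs (double-gap columns cannot occur in a
    pairwise global alignment) as a percentage; coverage is the number of
    columns aligning residue to residue, over the length of the longer input.
    """
    sa, sb = a.residues, b.residues
    n, m = len(sa), len(sb)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        H[i][0] = -float(i)
    for j in range(1, m + 1):
        H[0][j] = -float(j)
    for i in range(1, n + 1):
        row, prev = H[i], H[i - 1]
        ai = sa[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (1.0 if ai == sb[j - 1] else 0.0)
            up = prev[j] - 1.0
            left = row[j - 1] - 1.0
            row[j] = diag if diag >= up and diag >= left else (up if up >= left else left)

    # traceback, diagonal > up > left on ties
    i, j = n, m
    matches = 0
    aligned_cols = 0
    residue_cols = 0
    while i > 0 or j > 0:
        cur = H[i][j]
        if i > 0 and j > 0 and cur == H[i - 1][j - 1] + (1.0 if sa[i - 1] == sb[j - 1] else 0.0):
            matches += 1 if sa[i - 1] == sb[j - 1] else 0
            residue_cols += 1
            i, j = i - 1, j - 1
        elif i > 0 and cur == H[i - 1][j] - 1.0:
            i -= 1
        else:
            j -= 1
        aligned_cols += 1

    identity = 100.0 * matches / aligned_cols if aligned_cols else 0.0
    coverage = residue_cols / max(n, m)
    return identity, coverage


@dataclass(frozen=True)
class ClusterParams:
    """BLASTCLUST-style thresholds: S = percent identity, L = coverage fraction."""

    identity_threshold: float = 50.0
    coverage_threshold: float = 0.9

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold <= 100:
            raise ValueError("identity_threshold must be in (0, 100]")
        if not 0 < self.coverage_threshold <= 1:
            raise ValueError("coverage_threshold must be in (0, 1]")


@dataclass(frozen=True)
class SequenceCluster:
    representative: str
    members: tuple[str, ...]


def cluster_by_identity(seqs: list[SequenceRecord],
                        params: ClusterParams = ClusterParams()) -> list[SequenceCluster]:
    """Single-linkage clustering on the identity/coverage graph.

    Two sequences are linked iff identity >= S and coverage >= L; clusters are
    the connected components. The representative is the longest member
    (ties: lexicographically smallest id); clusters are sorted by decreasing
    size, then representative id.
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")

    parent = list(range(len(seqs)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if find(i) == find(j):
                continue
            identity, coverage = global_align_identity(seqs[i], seqs[j])
            if identity >= params.identity_threshold and coverage >= params.coverage_threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(len(seqs)):
        groups.setdefault(find(i), []).append(i)

    clusters = []
    for members in groups.values():
        rep = min(members, key=lambda k: (-len(seqs[k].residues), seqs[k].id))
        clusters.append(SequenceCluster(
            representative=seqs[rep].id,
            members=tuple(sorted(seqs[k].id for k in members)),
        ))
    clusters.sort(key=lambda c: (-len(c.members), c.representative))
    return clusters
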