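"""Cα-level strand topology and zinc-ribbon (ZnR) type classification.

The ZnR fold comes in two major flavours distinguished purely by strand
topology: type-1 ribbons keep their N- and C-terminal β-hairpins in separate
sheets (type-1A: nothing else; type-1B: an extra C-terminal strand joins the
N-terminal hairpin's sheet), while in type-2 ribbons the N-terminal hairpin
extends into a third strand that completes a three-stranded meander with the
C-terminal hairpin. This module operationalises that typology as a decision
table over a strand-pairing graph computed from Cα coordinates alone.

Secondary structure is assigned from Cα(i)–Cα(i+2) and Cα(i)–Cα(i+3)
distance windows (P-SEA style) rather than hydrogen bonds: the criteria are
topological, many small deposited domains lack complete backbones, and the
distance windows need nothing beyond the Cα trace. A residue whose window
distances fall in the strand range witnesses extended geometry for itself and
the two residues after it, so detected segments are extended two residues
past the last labelled position; single-residue holes in a run are filled
and isolated labels dropped before segments are formed (the usual smoothing
steps of Cα-based assigners).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import StructureModel
from .knuckles import ChelationCall

__all__ = [
    "StrandSegment",
    "StrandPairing",
    "StrandTopology",
    "ZnRTypeCall",
    "ZnSiteCall",
    "assign_strands",
    "pair_strands",
    "classify_znr_type",
    "detect_zn_site",
    "type_structure",
]

# distance windows (Å) for strand-like residues, P-SEA style
D13_RANGE = (6.1, 7.4)
D14_RANGE = (9.0, 11.1)
MIN_RUN = 3
END_EXTENSION = 2         # residues of witnessed extended geometry past a run
PAIR_CUTOFF = 5.6         # Å, inter-strand Cα–Cα contact
MIN_CONTACT_PAIRS = 2
MAX_TURN = 6              # residues between hairpin strands
ZN_DISTANCE = 8.0         # Å, max pairwise ligand-atom distance in a Zn site
ZN_CA_EXTRA = 1.5         # relaxation when falling back to Cα as ligand atom


@dataclass(frozen=True)
class StrandSegment:
    """A β-strand as a residue index range [start_index, end_index] (0-based into the model)."""

    label: str
    start_index: int
    end_index: int
    direction: np.ndarray  # unit vector start->end

    @property
    def indices(self) -> range:
        return range(self.start_index, self.end_index + 1)

    def __len__(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass(frozen=True)
class StrandPairing:
    first: str
    second: str
    orientation: str        # "parallel" or "antiparallel"
    n_contact_pairs: int


@dataclass
class StrandTopology:
    strands: list[StrandSegment]
    pairings: list[StrandPairing]
    hairpins: list[tuple[str, str, int]]  # (beta_i, beta_i+1, turn length)

    def paired(self, x: str, y: str) -> Optional[StrandPairing]:
        for p in self.pairings:
            if {p.first, p.second} == {x, y}:
                return p
        return None

    def sheet_components(self) -> list[frozenset]:
        """Connected components of the strand-pairing graph, as label sets."""
        labels = [s.label for s in self.strands]
        parent = {l: l for l in labels}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for p in self.pairings:
            parent[find(p.first)] = find(p.second)
        comps: dict[str, set] = {}
        for l in labels:
            comps.setdefault(find(l), set()).add(l)
        return sorted((frozenset(c) for c in comps.values()), key=lambda c: sorted(c))


@dataclass(frozen=True)
class ZnRTypeCall:
    znr_type: str           # type1A | type1B | type2 | unclassified
    evidence: str
    topology: StrandTopology


@dataclass(frozen=True)
class ZnSiteCall:
    competent: bool
    cys_residues: tuple[int, ...]
    max_pairwise: Optional[float]


def assign_strands(model: StructureModel) -> list[StrandSegment]:
    """Label strand-like residues from Cα distance windows and form segments.

    Residue i is strand-like if d(Cα_i, Cα_{i+2}) ∈ [6.1, 7.4] Å and
    d(Cα_i, Cα_{i+3}) ∈ [9.0, 11.1] Å. After single-hole filling and removal
    of isolated labels, maximal runs of >= 3 become strands (extended 2
    residues at the C-terminal end, clipped at the next run), labelled β1, β2,
    ... in sequence order.
    """
    n = len(model)
    if n < 6:
        return []
    ca = model.ca_coords
    strandlike = np.zeros(n, dtype=bool)
    for i in range(n - 3):
        d13 = np.linalg.norm(ca[i] - ca[i + 2])
        d14 = np.linalg.norm(ca[i] - ca[i + 3])
        strandlike[i] = (D13_RANGE[0] <= d13 <= D13_RANGE[1]
                         and D14_RANGE[0] <= d14 <= D14_RANGE[1])
    # fill single holes, then drop isolated singletons
    for i in range(1, n - 1):
        if not strandlike[i] and strandlike[i - 1] and strandlike[i + 1]:
            strandlike[i] = True
    for i in range(n):
        left = strandlike[i - 1] if i > 0 else False
        right = strandlike[i + 1] if i < n - 1 else False
        if strandlike[i] and not left and not right:
            strandlike[i] = False

    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if strandlike[i]:
            j = i
            while j + 1 < n and strandlike[j + 1]:
                j += 1
            if j - i + 1 >= MIN_RUN:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1

    segments: list[StrandSegment] = []
    for k, (start, end) in enumerate(runs):
        limit = runs[k + 1][0] - 1 if k + 1 < len(runs) else n - 1
        end = min(end + END_EXTENSION, limit)
        direction = ca[end] - ca[start]
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 0 else direction
        segments.append(StrandSegment(label=f"b{k + 1}", start_index=start,
                                      end_index=end, direction=direction))
    return segments


def pair_strands(model: StructureModel, strands: list[StrandSegment]) -> StrandTopology:
    """Build the strand-pairing graph from inter-strand Cα contacts.

    Strands pair iff at least 2 residue pairs are within 5.6 Å and at least
    one such set of pairs is sequence-consecutive on both strands (k, k+1 on
    one; l, l±1 on the other). Orientation comes from the sign of the
    direction-vector dot product. Hairpins are sequence-adjacent antiparallel
    pairs separated by a turn of at most 6 residues.
    """
    ca = model.ca_coords
    pairings: list[StrandPairing] = []
    for s1, s2 in itertools.combinations(strands, 2):
        i_idx = np.array(list(s1.indices))
        j_idx = np.array(list(s2.indices))
        dist = np.linalg.norm(ca[i_idx][:, None, :] - ca[j_idx][None, :, :], axis=2)
        contacts = dist <= PAIR_CUTOFF
        n_contacts = int(contacts.sum())
        if n_contacts < MIN_CONTACT_PAIRS:
            continue
        consecutive = any(
            contacts[k, l] and k + 1 < contacts.shape[0]
            and 0 <= l + dl < contacts.shape[1] and contacts[k + 1, l + dl]
            for k in range(contacts.shape[0])
            for l in range(contacts.shape[1])
            for dl in (-1, 1)
        )
        if not consecutive:
            continue
        orientation = "parallel" if float(s1.direction @ s2.direction) >= 0 else "antiparallel"
        pairings.append(StrandPairing(first=s1.label, second=s2.label,
                                      orientation=orientation, n_contact_pairs=n_contacts))

    hairpins: list[tuple[str, str, int]] = []
    topo = StrandTopology(strands=strands, pairings=pairings, hairpins=[])
    for s1, s2 in zip(strands, strands[1:]):
        p = topo.paired(s1.label, s2.label)
        turn = s2.start_index - s1.end_index - 1
        if p is not None and p.orientation == "antiparallel" and 0 <= turn <= MAX_TURN:
            hairpins.append((s1.label, s2.label, turn))
    topo.hairpins = hairpins
    return topo


def classify_znr_type(topology: StrandTopology) -> ZnRTypeCall:
    """Decision table over the sheet-component structure of the pairing graph.

    type1A: exactly 4 strands in two disjoint hairpin components {β1,β2} and
    {β3,β4}. type1B: 5 strands with the C-terminal strand joining the
    N-terminal hairpin's sheet ({β1,β2,β5} + {β3,β4}). type2: 5 strands with
    the middle strand joining the C-terminal hairpin's sheet ({β1,β2} +
    {β3,β4,β5}). Anything else is unclassified, with the failed row recorded.
    """
    n = len(topology.strands)
    comps = set(topology.sheet_components())
    hairpin_pairs = {frozenset((a, b)) for a, b, _ in topology.hairpins}

    if n == 4:
        want = {frozenset({"b1", "b2"}), frozenset({"b3", "b4"})}
        if comps == want and frozenset({"b1", "b2"}) in hairpin_pairs \
                and frozenset({"b3", "b4"}) in hairpin_pairs:
            return ZnRTypeCall("type1A", "4 strands; two disjoint hairpins {b1,b2} and {b3,b4}",
                               topology)
        return ZnRTypeCall("unclassified",
                           f"4 strands but components {sorted(map(sorted, comps))} "
                           "are not two disjoint hairpins", topology)
    if n == 5:
        if comps == {frozenset({"b1", "b2", "b5"}), frozenset({"b3", "b4"})} \
                and frozenset({"b1", "b2"}) in hairpin_pairs:
            return ZnRTypeCall("type1B",
                               "5 strands; C-terminal strand b5 joins the N-terminal "
                               "hairpin sheet {b1,b2,b5}; {b3,b4} separate", topology)
        if comps == {frozenset({"b1", "b2"}), frozenset({"b3", "b4", "b5"})} \
                and frozenset({"b4", "b5"}) in hairpin_pairs:
            return ZnRTypeCall("type2",
                               "5 strands; middle strand b3 joins the C-terminal "
                               "hairpin sheet {b3,b4,b5}; {b1,b2} separate", topology)
        return ZnRTypeCall("unclassified",
                           f"5 strands but components {sorted(map(sorted, comps))} match "
                           "neither the type1B nor the type2 row", topology)
    return ZnRTypeCall("unclassified", f"{n} strands; decision table covers 4 or 5", topology)


def detect_zn_site(model: StructureModel,
                   call: Optional[ChelationCall] = None) -> ZnSiteCall:
    """Search for a chelation-competent 4-cysteine cluster.

    Ligand atom per cysteine: Sγ if present, else Cβ, else Cα (the distance
    threshold is relaxed by 1.5 Å for any pair involving a Cα fallback).
    Competent iff some 4-cysteine subset keeps all pairwise ligand distances
    within threshold; the subset minimising the largest pairwise distance is
    reported. An optional sequence-level chelation call can restrict the
    search to the motif cysteines it identified.
    """
    keep: Optional[set[int]] = None
    if call is not None and call.knuckles[0] is not None:
        keep = set()
        for hit in call.knuckles:
            if hit is None:
                continue
            for tag, offset in (("C1", 0), ("C2", 3)):
                if tag in hit.cys_present:
                    keep.add(hit.start + offset)  # 1-based sequence position

    cys = []
    for seq_pos, res in enumerate(model.residues, start=1):
        if res.amino_acid != "C":
            continue
        if keep is not None and seq_pos not in keep:
            continue
        if res.sg is not None:
            cys.append((res.number, res.sg, False))
        elif res.cb is not None:
            cys.append((res.number, res.cb, False))
        else:
            cys.append((res.number, res.ca, True))

    if len(cys) < 4:
        return ZnSiteCall(competent=False, cys_residues=tuple(c[0] for c in cys),
                          max_pairwise=None)

    best: Optional[tuple[bool, float, tuple[int, ...]]] = None
    for subset in itertools.combinations(cys, 4):
        max_d = 0.0
        ok = True
        for (n1, p1, fb1), (n2, p2, fb2) in itertools.combinations(subset, 2):
            d = float(np.linalg.norm(p1 - p2))
            limit = ZN_DISTANCE + (ZN_CA_EXTRA if (fb1 or fb2) else 0.0)
            max_d = max(max_d, d)
            if d > limit:
                ok = False
        key = (not ok, max_d, tuple(c[0] for c in subset))  # competent subsets first
        if best is None or key < best:
            best = key
    not_ok, max_d, numbers = best
    return ZnSiteCall(competent=not not_ok, cys_residues=numbers, max_pairwise=max_d)


def type_structure(model: StructureModel) -> ZnRTypeCall:
    """Convenience: assign strands, pair them and classify in one call."""
    return classify_znr_type(pair_strands(model, assign_strands(model)))
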