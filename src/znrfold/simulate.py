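"""Synthetic inputs with the statistical and geometric structure each
analysis stage assumes, so the whole pipeline is testable without downloads.

Four generators are provided: family alignments with controlled aromatic
composition at five cage columns; Cren7-like sequences carrying 0-4 knuckle
cysteines in two CPxCG-templated turns; idealized Cα traces for the three
zinc-ribbon types built from textbook β-sheet geometry (3.8 Å consecutive
Cα-Cα, 4.8 Å inter-strand spacing); and paired E-value/Z-score matrices with
planted clade structure. All generators are bit-reproducible under a fixed
seed. Jitter parameters are the standard deviation of the 3-D displacement
magnitude (per-axis σ = sd/√3), so a jitter of x Å perturbs each atom by
x Å RMS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .io import AMINO_ACIDS, Alignment, Residue, SequenceRecord, SimilarityTable, StructureModel
from .knuckles import AROMATIC

__all__ = [
    "CageSimSpec",
    "KnuckleSimSpec",
    "ZnRSimSpec",
    "CladeSimSpec",
    "simulate_cage_msa",
    "simulate_knuckle_sequences",
    "simulate_znr_structure",
    "simulate_similarity_pair",
    "perturb_rigid",
]

CA_CA = 3.8          # Å, consecutive Cα spacing
RISE = 3.35          # Å, strand axis step per residue
PLEAT = float(np.sqrt(CA_CA ** 2 - RISE ** 2) / 2)  # ±0.897 Å zig-zag
SHEET_SPACING = 4.8  # Å, between paired strands
RAIL_OFFSET = 7.0    # Å, between the two sheet groups (no pairing across)
TURN_RESIDUES = 3
CA_SG = 2.8          # Å, pseudo-Sγ offset from Cα toward the Zn centre

_AROMATIC = sorted(AROMATIC)
_NON_AROMATIC = sorted(set(AMINO_ACIDS) - AROMATIC)
_NO_CYS = sorted(set(AMINO_ACIDS) - {"C"})


# ---------------------------------------------------------------------------
# cage alignments


@dataclass(frozen=True)
class CageSimSpec:
    """Family-MSA generator settings; cage columns are 1-based."""

    n_sequences: int = 200
    n_columns: int = 60
    cage_columns: tuple[int, int, int, int, int] = (10, 20, 30, 40, 50)
    aromatic_prob: float = 0.8
    gap_prob: float = 0.05
    seed: int = 0
    family_label: str = "sim_family"

    def __post_init__(self) -> None:
        if not (0 <= self.aromatic_prob <= 1 and 0 <= self.gap_prob <= 1):
            raise ValueError("probabilities must be in [0, 1]")
        if len(set(self.cage_columns)) != 5:
            raise ValueError("cage_columns must be 5 distinct columns")
        if any(not 1 <= c <= self.n_columns for c in self.cage_columns):
            raise ValueError("cage_columns out of range")
        if self.n_sequences < 2:
            raise ValueError("need at least 2 sequences")


def simulate_cage_msa(spec: CageSimSpec) -> Alignment:
    """Alignment whose cage columns are aromatic with the requested probability.

    Non-gap cells in a cage column draw uniformly from {Y,W,F,H} with
    probability ``aromatic_prob`` and uniformly from the other 16 letters
    otherwise; all other columns draw uniformly from the 20 letters.
    """
    rng = np.random.default_rng(spec.seed)
    cage = set(spec.cage_columns)
    records = []
    for i in range(spec.n_sequences):
        row = []
        for col in range(1, spec.n_columns + 1):
            if rng.random() < spec.gap_prob:
                row.append("-")
            elif col in cage:
                if rng.random() < spec.aromatic_prob:
                    row.append(_AROMATIC[rng.integers(len(_AROMATIC))])
                else:
                    row.append(_NON_AROMATIC[rng.integers(len(_NON_AROMATIC))])
            else:
                row.append(AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))])
        records.append(SequenceRecord(id=f"seq{i + 1:04d}", residues="".join(row)))
    return Alignment(records=records, family_label=spec.family_label)


# ---------------------------------------------------------------------------
# knuckle sequences


@dataclass(frozen=True)
class KnuckleSimSpec:
    """Cren7-like sequence generator: two CPxCG knuckles with controlled decay."""

    n_sequences: int = 300
    chelation_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # intact, partial, lost
    spacer_range: tuple[int, int] = (10, 35)   # residues between the knuckles
    mutation_rate: float = 0.0
    flank_range: tuple[int, int] = (8, 15)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.chelation_mix) - 1.0) > 1e-9 or any(p < 0 for p in self.chelation_mix):
            raise ValueError("chelation_mix must be nonnegative proportions summing to 1")
        lo, hi = self.spacer_range
        # knuckle starts are spacer + 5 apart; keep inside the scanner's window
        if not 5 <= lo <= hi <= 55:
            raise ValueError("spacer_range must lie within [5, 55]")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")


def _quota_counts(n: int, proportions: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment so small sets match proportions exactly."""
    raw = [n * p for p in proportions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda k: (-(raw[k] - counts[k]), k))
    for k in order[:remainder]:
        counts[k] += 1
    return counts


def simulate_knuckle_sequences(spec: KnuckleSimSpec) -> list[tuple[SequenceRecord, str]]:
    """Sequences built as flank + knuckle + spacer + knuckle + flank, with truth.

    States are assigned by quota (not multinomially) so realized counts match
    the requested proportions exactly. "partial" replaces 1-2 of the four
    motif cysteines by serine, "lost" 3-4. Flanks and spacers avoid cysteine
    so the planted motif cysteines are the only ones; mutations (applied
    everywhere except the motif cysteine positions) may introduce new ones.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _quota_counts(spec.n_sequences, spec.chelation_mix)
    states = ["intact"] * counts[0] + ["partial"] * counts[1] + ["lost"] * counts[2]
    rng.shuffle(states)

    out: list[tuple[SequenceRecord, str]] = []
    for i, state in enumerate(states):
        def draw(alphabet: list[str], k: int) -> str:
            return "".join(alphabet[j] for j in rng.integers(len(alphabet), size=k))

        flank1 = draw(_NO_CYS, int(rng.integers(spec.flank_range[0], spec.flank_range[1] + 1)))
        flank2 = draw(_NO_CYS, int(rng.integers(spec.flank_range[0], spec.flank_range[1] + 1)))
        spacer = draw(_NO_CYS, int(rng.integers(spec.spacer_range[0], spec.spacer_range[1] + 1)))
        knuckles = [list("CP" + draw(_NO_CYS, 1) + "CG") for _ in range(2)]

        n_delete = {"intact": 0, "partial": int(rng.integers(1, 3)),
                    "lost": int(rng.integers(3, 5))}[state]
        cys_slots = [(0, 0), (0, 3), (1, 0), (1, 3)]
        doomed = rng.choice(4, size=n_delete, replace=False)
        for d in doomed:
            k, pos = cys_slots[int(d)]
            knuckles[k][pos] = "S"

        residues = list(flank1 + "".join(knuckles[0]) + spacer + "".join(knuckles[1]) + flank2)
        k1_start = len(flank1)
        k2_start = len(flank1) + 5 + len(spacer)
        protected = {k1_start, k1_start + 3, k2_start, k2_start + 3}
        if spec.mutation_rate > 0:
            for pos in range(len(residues)):
                if pos in protected:
                    continue
                if rng.random() < spec.mutation_rate:
                    residues[pos] = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
        out.append((SequenceRecord(id=f"knk{i + 1:04d}", residues="".join(residues)), state))
    return out


# ---------------------------------------------------------------------------
# idealized ZnR structures


@dataclass(frozen=True)
class ZnRSimSpec:
    znr_type: str = "type2"              # type1A | type1B | type2
    noise_sd: float = 0.0                # Å RMS displacement per atom
    strand_length: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.znr_type not in ("type1A", "type1B", "type2"):
            raise ValueError("znr_type must be type1A, type1B or type2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.strand_length < 3:
            raise ValueError("strand_length must be >= 3")


def _turn_arc(p: np.ndarray, q: np.ndarray, n_points: int, bulge: np.ndarray) -> np.ndarray:
    """``n_points`` interior points on a circular arc from p to q, every
    consecutive chord (including p->first and last->q) exactly CA_CA long.

    The arc lies in the plane spanned by q-p and ``bulge`` and bows toward
    ``bulge``; it wraps past a semicircle when the endpoints are closer than
    the chain length requires, which is exactly what a β-turn does.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    chord = float(np.linalg.norm(q - p))
    n_chords = n_points + 1
    if not 0 < chord < n_chords * CA_CA:
        raise ValueError(f"gap {chord:.2f} Å not bridgeable with {n_points} turn residues")
    ratio = chord / CA_CA

    def f(phi: float) -> float:
        return np.sin(n_chords * phi / 2) / np.sin(phi / 2) - ratio

    phi = brentq(f, 1e-9, 2 * np.pi / n_chords - 1e-9, xtol=1e-13)
    theta = n_chords * phi
    radius = CA_CA / (2 * np.sin(phi / 2))

    x_hat = (q - p) / chord
    u = np.asarray(bulge, float)
    u = u - (u @ x_hat) * x_hat
    un = np.linalg.norm(u)
    if un < 1e-9:
        raise ValueError("bulge direction is parallel to the endpoint axis")
    y_hat = u / un

    half = chord / 2
    h = float(np.sqrt(max(radius ** 2 - half ** 2, 0.0)))
    centre2d = np.array([half, -h if theta <= np.pi else h])
    ang_p = np.arctan2(0.0 - centre2d[1], 0.0 - centre2d[0])
    ang_q = np.arctan2(0.0 - centre2d[1], chord - centre2d[0])
    ccw = (ang_q - ang_p) % (2 * np.pi)
    sweep = ccw if abs(ccw - theta) < abs((ccw - 2 * np.pi) - (-theta)) else ccw - 2 * np.pi
    pts = []
    for k in range(1, n_points + 1):
        ang = ang_p + sweep * k / n_chords
        pt2d = centre2d + radius * np.array([np.cos(ang), np.sin(ang)])
        pts.append(p + pt2d[0] * x_hat + pt2d[1] * y_hat)
    return np.array(pts)


def _strand_points(x_start: float, direction: int, y: float, z: float,
                   n: int, phase: int = 0) -> np.ndarray:
    """Pleated strand along ±x: axis step RISE, ±PLEAT zig-zag along y."""
    pts = np.zeros((n, 3))
    for k in range(n):
        pts[k] = (x_start + direction * RISE * k,
                  y + PLEAT * (-1) ** (k + phase),
                  z)
    return pts


def _linker_points(p: np.ndarray, q: np.ndarray, bulge: np.ndarray) -> np.ndarray:
    """A helical coil connector with every consecutive chord exactly CA_CA.

    A smooth circular arc between distant strand ends is nearly straight and
    its Cα(i)-Cα(i+2/3) distances fall dangerously close to the strand
    windows; a coil with a compact per-residue rise (~2.2 Å) keeps the
    connector unambiguously non-strand-like. The winding count is chosen so
    both endpoints lie exactly on the helix axis.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    gap = float(np.linalg.norm(q - p))
    n_seg = max(4, int(round(gap / 2.2)))
    rise = gap / n_seg
    m_turns = max(1, int(round(1.35 * n_seg / (2 * np.pi))))
    omega = 2 * np.pi * m_turns / n_seg
    r_sq = CA_CA ** 2 - rise ** 2
    if r_sq <= 0:
        raise ValueError(f"gap {gap:.2f} Å too wide for a {n_seg}-segment coil")
    radius = np.sqrt(r_sq) / (2 * np.sin(omega / 2))
    w = (q - p) / gap
    e1 = np.asarray(bulge, float)
    e1 = e1 - (e1 @ w) * w
    if np.linalg.norm(e1) < 1e-9:
        e1 = np.array([0.0, 0.0, 1.0]) - w[2] * w
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(w, e1)
    pts = []
    for k in range(1, n_seg):
        pts.append(p + radius * ((np.cos(k * omega) - 1) * e1 + np.sin(k * omega) * e2)
                   + k * rise * w)
    return np.array(pts)


def simulate_znr_structure(spec: ZnRSimSpec) -> StructureModel:
    """Idealized Cα trace for one ZnR type, knuckle cysteines at the turn apices.

    Strands run along x on two rails (y = 0 and y = 7 Å) at z-levels 4.8 Å
    apart; the two Zn-knuckle turns sit at the x ≈ 0 end of the domain so
    their cysteines cluster around a common Zn position, where pseudo-Sγ
    atoms are placed 2.8 Å from each Cα toward the site centre.
    """
    L = spec.strand_length
    x_hi = RISE * (L - 1)
    minus_x = np.array([-1.0, 0.0, 0.0])
    plus_x = np.array([1.0, 0.0, 0.0])
    plus_z = np.array([0.0, 0.0, 1.0])

    # each element: ("strand"|"turn"|"knuckle", points)
    pieces: list[tuple[str, np.ndarray]] = []

    def add_strand(x_start, direction, y, z):
        pieces.append(("strand", _strand_points(x_start, direction, y, z, L)))

    def add_turn(kind, next_start, bulge):
        prev_end = pieces[-1][1][-1]
        pieces.append((kind, _turn_arc(prev_end, next_start, TURN_RESIDUES, bulge)))

    def add_linker(next_start, bulge):
        prev_end = pieces[-1][1][-1]
        pieces.append(("turn", _linker_points(prev_end, next_start, bulge)))

    def strand_start(direction, y, z):
        x0 = x_hi if direction < 0 else 0.0
        return np.array([x0, y + PLEAT, z])

    if spec.znr_type == "type1A":
        add_strand(x_hi, -1, 0.0, 0.0)                       # b1
        add_turn("knuckle", strand_start(+1, 0.0, SHEET_SPACING), minus_x)
        add_strand(0.0, +1, 0.0, SHEET_SPACING)              # b2
        add_linker(strand_start(-1, RAIL_OFFSET, 0.0), plus_x)
        add_strand(x_hi, -1, RAIL_OFFSET, 0.0)               # b3
        add_turn("knuckle", strand_start(+1, RAIL_OFFSET, SHEET_SPACING), minus_x)
        add_strand(0.0, +1, RAIL_OFFSET, SHEET_SPACING)      # b4
    elif spec.znr_type == "type1B":
        add_strand(x_hi, -1, 0.0, 0.0)                       # b1
        add_turn("knuckle", strand_start(+1, 0.0, SHEET_SPACING), minus_x)
        add_strand(0.0, +1, 0.0, SHEET_SPACING)              # b2
        add_linker(strand_start(-1, RAIL_OFFSET, 0.0), plus_x)
        add_strand(x_hi, -1, RAIL_OFFSET, 0.0)               # b3
        add_turn("knuckle", strand_start(+1, RAIL_OFFSET, SHEET_SPACING), minus_x)
        add_strand(0.0, +1, RAIL_OFFSET, SHEET_SPACING)      # b4
        add_linker(strand_start(-1, 0.0, 2 * SHEET_SPACING), plus_x)
        add_strand(x_hi, -1, 0.0, 2 * SHEET_SPACING)         # b5 joins the b1/b2 sheet
    else:  # type2
        add_strand(x_hi, -1, 0.0, 0.0)                       # b1
        add_turn("knuckle", strand_start(+1, 0.0, SHEET_SPACING), minus_x)
        add_strand(0.0, +1, 0.0, SHEET_SPACING)              # b2
        add_linker(strand_start(+1, RAIL_OFFSET, 2 * SHEET_SPACING), plus_z)
        add_strand(0.0, +1, RAIL_OFFSET, 2 * SHEET_SPACING)  # b3 (meander top)
        add_turn("turn", strand_start(-1, RAIL_OFFSET, SHEET_SPACING), plus_x)
        add_strand(x_hi, -1, RAIL_OFFSET, SHEET_SPACING)     # b4
        add_turn("knuckle", strand_start(+1, RAIL_OFFSET, 0.0), minus_x)
        add_strand(0.0, +1, RAIL_OFFSET, 0.0)                # b5

    coords: list[np.ndarray] = []
    kinds: list[str] = []
    for kind, pts in pieces:
        for pt in pts:
            coords.append(pt)
            kinds.append(kind)
    ca = np.array(coords)

    # sequence: strands alternate V/T, plain turns G/S, knuckles C-G-C
    amino: list[str] = []
    knuckle_cys: list[int] = []
    turn_counter = 0
    i = 0
    while i < len(kinds):
        kind = kinds[i]
        j = i
        while j + 1 < len(kinds) and kinds[j + 1] == kind:
            j += 1
        length = j - i + 1
        if kind == "strand":
            amino.extend("VT"[(k % 2)] for k in range(length))
        elif kind == "knuckle":
            assert length == TURN_RESIDUES
            amino.extend(["C", "G", "C"])
            knuckle_cys.extend([i, i + 2])
        else:
            amino.extend("GS"[(k % 2)] for k in range(length))
        i = j + 1

    # pseudo-Sγ toward the shared Zn site
    zn_centre = ca[knuckle_cys].mean(axis=0)
    sg: dict[int, np.ndarray] = {}
    for idx in knuckle_cys:
        direction = zn_centre - ca[idx]
        norm = np.linalg.norm(direction)
        sg[idx] = ca[idx] + CA_SG * (direction / norm if norm > 1e-9 else plus_z)

    rng = np.random.default_rng(spec.seed)
    sigma = spec.noise_sd / np.sqrt(3.0)
    residues = []
    for idx in range(len(ca)):
        pos = ca[idx] + (rng.normal(0.0, sigma, 3) if sigma > 0 else 0.0)
        sg_pos = None
        if idx in sg:
            sg_pos = sg[idx] + (rng.normal(0.0, sigma, 3) if sigma > 0 else 0.0)
        residues.append(Residue(number=idx + 1, amino_acid=amino[idx], ca=pos, sg=sg_pos))
    return StructureModel(chain_id="A", residues=residues)


def perturb_rigid(model: StructureModel, rotation_seed: int,
                  translation: np.ndarray = (0.0, 0.0, 0.0),
                  jitter_sd: float = 0.0) -> StructureModel:
    """Apply a seeded uniform random rotation, a translation, then isotropic
    jitter (per-atom RMS displacement = jitter_sd); identities unchanged."""
    rng = np.random.default_rng(rotation_seed)
    R = Rotation.random(rng=rng).as_matrix()
    t = np.asarray(translation, float)
    sigma = jitter_sd / np.sqrt(3.0)

    def move(v: Optional[np.ndarray]) -> Optional[np.ndarray]:
        if v is None:
            return None
        out = R @ v + t
        if sigma > 0:
            out = out + rng.normal(0.0, sigma, 3)
        return out

    residues = [
        Residue(number=r.number, amino_acid=r.amino_acid, ca=move(r.ca),
                cb=move(r.cb), sg=move(r.sg), insertion_code=r.insertion_code)
        for r in model.residues
    ]
    return StructureModel(chain_id=model.chain_id, residues=residues)


# ---------------------------------------------------------------------------
# planted clade similarity matrices


@dataclass(frozen=True)
class CladeSimSpec:
    planted_partition: tuple[tuple[str, ...], ...] = (
        ("A1", "A2", "A3"), ("B1", "B2", "B3"), ("C1", "C2", "C3"))
    within_z: float = 8.0
    between_z: float = 2.0
    within_loge: float = 10.0     # mean -log10(E) inside groups
    between_loge: float = 2.0
    noise_sd: float = 1.0
    missing_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        leaves = [l for g in self.planted_partition for l in g]
        if len(set(leaves)) != len(leaves):
            raise ValueError("planted groups must be disjoint")
        if len(leaves) < 2:
            raise ValueError("need at least 2 leaves")
        if self.within_z <= self.between_z or self.within_loge <= self.between_loge:
            raise ValueError("within-group means must exceed between-group means")
        if not 0 <= self.missing_frac <= 1:
            raise ValueError("missing_frac must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def labels(self) -> list[str]:
        return [l for g in self.planted_partition for l in g]


def simulate_similarity_pair(spec: CladeSimSpec) -> tuple[SimilarityTable, SimilarityTable]:
    """Paired (E-value, Z-score) tables with planted groups and missing cells.

    Z entries draw Normal(within or between mean, noise_sd) truncated at 0;
    E entries are 10**(-Normal(...)) truncated to (0, 10]. Off-diagonal cells
    are blanked independently (including each direction of a symmetric pair)
    with probability ``missing_frac``; diagonals are left missing (ignored).
    """
    rng = np.random.default_rng(spec.seed)
    labels = spec.labels
    n = len(labels)
    group_of = {l: gi for gi, g in enumerate(spec.planted_partition) for l in g}

    z = np.full((n, n), np.nan)
    e = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            same = group_of[labels[i]] == group_of[labels[j]]
            mu_z = spec.within_z if same else spec.between_z
            mu_e = spec.within_loge if same else spec.between_loge
            z[i, j] = max(0.0, rng.normal(mu_z, spec.noise_sd))
            e[i, j] = min(10.0, 10.0 ** (-rng.normal(mu_e, spec.noise_sd)))
            if rng.random() < spec.missing_frac:
                z[i, j] = np.nan
            if rng.random() < spec.missing_frac:
                e[i, j] = np.nan
    return (SimilarityTable(labels=labels, values=e, measure="evalue"),
            SimilarityTable(labels=labels, values=z, measure="zscore"))
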