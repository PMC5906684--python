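# Methods

This note documents the models, parameters and numerical choices behind
`znrfold`, what the synthetic-data generators do and do not emulate, and the
known limitations.

## Knuckle scanning and chelation calls

Zinc ribbons chelate one Zn²⁺ through four cysteines, two per β-hairpin turn
("knuckle"), consensus `CPxCG` with the cysteines at motif positions 1 and 4.
The scanner scores every 5-residue window: +2 for both cysteines, +1 for
exactly one, and +1 each for the proline at position 2 and the glycine at
position 5. Proline and glycine are a bonus rather than a requirement because
degraded knuckles — the object of the partial/lost analysis — frequently keep
the small residues while losing a ligand, or vice versa. Windows scoring ≥ 1
are all reported; pair selection happens at classification time.

The chelation call picks the pair of windows, 10–60 residues apart by default
(configurable; ZnRs are small domains, so the spacing constraint stands in
for the structural requirement that both knuckles be hairpin turns), that
maximises the summed score, breaking ties toward the N-terminus so calls are
deterministic. The state is a pure function of the motif-cysteine count of
the chosen pair: 4 → intact, 2–3 → partial, ≤ 1 → lost. If no valid pair
exists the best single window is used; sequences shorter than the motif are
called lost rather than raising.

## Identity clustering

Redundancy reduction uses exact global alignment (Needleman–Wunsch, match +1,
mismatch 0, linear gap −1, traceback preferring diagonal, then the gap in the
second sequence) instead of BLAST heuristics: inputs at this scale are small
enough that exactness costs nothing and buys reproducibility. Identity is
matches over alignment columns; coverage is residue-to-residue columns over
the longer sequence's length. Two sequences are linked when identity ≥ S and
coverage ≥ L (defaults S = 50 %, L = 0.9); clusters are connected components
(single linkage), represented by their longest member (ties: smallest id).
Raising S can only refine the partition, which the tests assert.

## Aromatic-cage profiles

Chromo-like domains read methylated lysines/arginines through a cage of ~5
aromatic side chains; the family-level statistic is the fraction of Y/W/F/H
at each of the five cage columns of the family alignment. Cage columns are
user input, mapped from ungapped residue positions of an annotated reference
row — locating cages structurally is out of scope. The denominator excludes
gapped rows by default (conservation among residues actually present); the
non-gap coverage is always reported alongside so the choice is auditable, and
a flag switches to the gap-including denominator. An all-gap column yields
fraction 0 with coverage 0.

## Cα-level strand topology and ZnR typing

Strand assignment uses P-SEA-style Cα distance windows — residue *i* is
strand-like when d(Cαᵢ, Cαᵢ₊₂) ∈ [6.1, 7.4] Å and d(Cαᵢ, Cαᵢ₊₃) ∈
[9.0, 11.1] Å — rather than hydrogen-bond criteria: the typology is
topological, many small deposited domains lack complete backbones, and the
Cα trace is all the pipeline requires. Because the windows look forward,
a strand's last residues cannot witness themselves; a strand-like label at
*i* witnesses extended geometry through *i*+3, so maximal runs (≥ 3 after
single-hole filling and removal of isolated labels — the usual smoothing of
Cα-based assigners) are extended two residues at the C-terminal end, clipped
at the next run. Strands pair when ≥ 2 Cα pairs are within 5.6 Å (standard
inter-strand spacing 4.5–5.2 Å plus tolerance) with at least one
sequence-consecutive pair on both strands; hairpins are sequence-adjacent
antiparallel pairs with a turn of ≤ 6 residues.

Typing is a pure decision table over the connected components of the
pairing graph: two disjoint hairpins {β1,β2} + {β3,β4} → type-1A; five
strands with β5 joining the N-terminal hairpin's sheet → type-1B; five
strands with β3 joining the C-terminal hairpin's sheet (three-stranded
meander) → type-2; everything else, including the five-stranded Cren7/SH3
barrel, is reported as unclassified with the failed row in the evidence
string. The barrel deliberately gets no class of its own — the analyses here
need only the ribbon typology — and the circular-permutation relation between
type-1B and type-2 is a fact about the classes, not something detected per
structure. Real borderline structures may legitimately disagree with
expert labels; all thresholds are module constants exposed for adjustment.

Zn-site detection checks whether some 4-cysteine subset keeps all pairwise
ligand-atom distances ≤ 8.0 Å (Sγ preferred, then Cβ, then Cα with the
threshold relaxed by 1.5 Å for pairs using a Cα fallback), reporting the
subset with the smallest maximum distance.

## Superposition and the TM-score search

Kabsch fitting is the standard SVD solution with the reflection excluded;
fewer than three points or near-collinear sets raise a degeneracy error
(tolerance 1e-8 on the relative second singular value). The TM-score is

    TM = (1/L_norm) Σᵢ 1 / (1 + (dᵢ/d₀)²),  d₀ = max(0.5, 1.24·(L_norm−15)^⅓ − 1.8)

evaluated at the superposition maximising the sum for the given alignment,
found by iteratively refitting on pairs closer than 2·d₀ (at least the three
closest). The d₀ floor of 0.5 Å keeps the score defined for the ~50-residue
domains this package targets. Normalisation is by the first structure's
length by default (the convention when quoting similarity to a reference),
with "second" and "shorter" available.

The alignment search is deterministic: seeds are gapless threadings of
fragments of A over B (lengths: the full shorter length, half of it, and 20;
starts on a half-fragment grid) plus one secondary-structure seed pairing
sequence-matched strand segments. Each seed is refined by iterating
{superpose → score matrix sᵢⱼ = 1/(1+(dᵢⱼ/d₀)²) → global affine-gap DP
(open −0.6, extend 0, gap states non-chaining, ties preferring match, then
the gap consuming A) → refit on pairs with d < 2·d₀} until the alignment
repeats, at most 30 rounds. The best result wins by TM, then by aligned-pair
count, then by earlier seed — bit-reproducible, no stochastic restarts.
Because the seeding threads A over B, "shorter" normalisation runs both
directions and keeps the better result, making the score symmetric under
input swap. DALI Z-scores and HHpred E-values are never computed here; they
are inputs recorded from external programs.

## Evidence channels and the consensus tree

These domains diverge too fast for conventional phylogenetics, so clade
relationships are summarised from two independent channels recorded
clade-against-clade. E-values become similarities via −log₁₀ clipped to
[0, 300] (the cap absorbs E = 0 underflow; some monotone map is required and
−log₁₀ is the field's convention); Z-scores are used as-is, clipped at 0.
Each matrix is symmetrised by the pairwise mean, with a one-sidedly missing
entry contributing just the present value; a pair missing in both directions
gets similarity 0 — no reported hit is treated as maximal dissimilarity,
since both source programs only report hits they find. Distance is the
matrix maximum minus the symmetrised similarity (an order-reversing shift;
single linkage depends only on ranks, so the shift is harmless and the tests
assert rank invariance).

Single linkage is implemented directly so tie-breaking is deterministic:
among equal-distance merges, the pair whose lexicographically smallest member
label is smallest wins. The two dendrograms are combined by strict consensus
— the clades formed at any merge of both — which for exactly two inputs
coincides with majority rule; clustering per channel and then taking the
consensus is the reading most consistent with rendering a single "consensus
clustering" from two evidence sources. Kept internal nodes carry support 2.
The intersection of two laminar clade families is laminar, so assembly into
a rooted tree always succeeds; output is Newick with support counts as
internal labels and no branch lengths.

## Synthetic data: what it emulates and what it does not

All generators are bit-reproducible under a fixed seed, and their defaults
are the conditions the analyses assume.

**Cage alignments** draw each cage-column cell aromatic with probability
`aromatic_prob` (default 0.8, uniform within {Y,W,F,H} — the four letters are
one class for this statistic, so their relative frequencies are not
modelled), other columns uniform over the 20 letters, gaps i.i.d. at 0.05.
Real family alignments have phylogenetic correlation between rows and
position-specific gap structure; passing tests show the estimator is correct,
not that any family's cage is conserved.

**Knuckle sequences** are flank + knuckle + spacer + knuckle + flank with the
knuckles templated on CPxCG; "partial" replaces 1–2 of the four cysteines by
serine, "lost" 3–4. States are assigned by largest-remainder quota rather
than multinomially so small test sets match the requested mix exactly.
Flanks and spacers avoid cysteine, so the planted ligands are unambiguous;
point mutations (default rate 0) may introduce new cysteines anywhere except
the four motif positions. Spacers default to 10–35 residues so knuckle
starts fall inside the scanner's default spacing window.

**ZnR structures** are idealized Cα traces built from textbook β-geometry:
3.8 Å consecutive Cα-Cα, strands as pleated zig-zags (3.35 Å axial rise,
±0.90 Å pleat), antiparallel partners at 4.8 Å, 3-residue turns placed on
circular arcs with exact 3.8 Å chords, and the two sheet groups on rails
7 Å apart (close enough to be one domain, far enough never to pair). Both
knuckle turns sit at the same end of the domain, as in real ribbons, with
C-G-C turns and pseudo-Sγ atoms 2.8 Å from each Cα toward the common site
centre. Longer inter-sheet connectors are helical coils (~2.2 Å rise per
residue, integer winding so both ends sit on the axis) rather than smooth
arcs: a near-straight arc's Cα(i, i+2/3) distances fall inside the strand
windows under noise and created phantom strands. Coordinate noise adds an
isotropic Gaussian per atom whose 3-D displacement magnitude has RMS equal
to `noise_sd` (per-axis σ = sd/√3) — the same convention as
`perturb_rigid`'s `jitter_sd`, so a 0.5 Å jitter produces ≈ 0.5 Å RMSD
against the original after refitting. These models have no side chains, no
barrel closure and no real packing; they exercise the topology criteria,
not force-field realism.

**Similarity pairs** plant a partition (default three groups of three) with
within/between mean Z of 8/2 and mean −log₁₀E of 10/2, Gaussian noise
(σ = 1), Z truncated at 0, E truncated to (0, 10], and 10 % of directional
cells blanked independently. The planted separation is strong — the point is
end-to-end recovery of the machinery, not a power analysis.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` regenerate all inputs at run time:
300 knuckle sequences per condition, 100 structures per ZnR type at 0.3 Å
noise, 1000 random alignments for the cage-counting oracle, 200 planted
similarity pairs for consensus recovery, and staged random-rotation sampling
(hundreds of thousands of rotations, progressively narrowed) as the
independent check on Kabsch optimality — sizes chosen so the whole pipeline
re-runs from scratch in seconds while keeping binomial error well inside the
asserted margins. Every stochastic step takes an explicit seed; the
acceptance script derives all sub-seeds from its single `--seed`.

## Known limitations

- The published Cren7-vs-ZnR TM-score benchmark needs the two public PDB
  entries on disk (see README); they are not redistributed with the package.
- The typing decision table covers the ribbon typology only; segment-swapped
  variants and the SH3 barrel itself are reported as unclassified.
- mmCIF, multi-model NMR ensembles (beyond model 1) and full PDB header
  parsing are unsupported; '.' gaps are normalised to '-'.
- The DP alignment search is a faithful heuristic of the TM-align family,
  not a reimplementation of any specific released binary; scores on real
  pairs agree at fold level, not to the last digit.
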