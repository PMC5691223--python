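# Methods notes

This note records the models, parameter choices and numerical
conventions behind each module, the design decisions that were
genuinely open, and what the synthetic-data validation does and does
not demonstrate about real sequences.

## Domain detection

**Cysteine-framework scanner.** A canonical-inhibitor domain is called
when an ordered run of framework cysteines (Kazal/Kunitz/Pacifastin 6,
WAP 8, TIL 10) has every successive spacing inside a family window.
The default windows, written PROSITE-style with `x(min,max)` counting
residues strictly between cysteines:

| family | pattern |
|---|---|
| Kazal | C-x(1,12)-C-x(4,12)-C-x(1,14)-C-x(4,16)-C-x(6,30)-C |
| Kunitz/BPTI | C-x(6,10)-C-x(12,18)-C-x(5,9)-C-x(10,16)-C-x(2,6)-C |
| Pacifastin | C-x(7,12)-C-x(4,8)-C-x(2,6)-C-x(6,10)-C-x(3,7)-C |
| WAP | C-x(4,10)-C-x(4,8)-C-x(4,8)-C-x(4,10)-C-x(4,8)-C-x(2,6)-C-x(2,6)-C |
| TIL | C-x(4,10)-C-x(4,10)-C-x(3,8)-C-x(3,10)-C-x(4,12)-C-x(3,8)-C-x(3,10)-C-x(2,8)-C-x(3,10)-C |

These envelopes are this package's own generous defaults (the families'
literature gives no single canonical spacing); they are configurable,
and calibrating them against a real proteome is explicitly a user
task. Matching is greedy left-to-right and non-overlapping within a
family; when windows admit several cysteine choices the leftmost,
most-compact chain wins (depth-first search trying smaller gaps
first). Hit spans add 3 flanking residues, clipped to the sequence.
The hit score is the mean centrality of the observed gaps inside their
windows (1 = all gaps dead-center).

**Cross-family overlap resolution.** The envelopes genuinely nest: a
correct 10-cysteine TIL framework usually contains 6-cysteine
sub-chains that satisfy the Kazal envelope. `detect_all` therefore
resolves overlapping canonical hits of different families by keeping
the larger framework (more cysteines), then the higher score. Nested
sub-framework calls are artifacts of envelope overlap, not evidence of
a second domain. Same-size ambiguity (Kazal vs Kunitz vs Pacifastin)
is rare under the default windows and is reported as whichever family
scores higher.

**Serpin detection** uses the P17–P9 hinge consensus as a regular
expression, `[ED].{0,2}G[TS][EKRQ][AG][AGS][AGST][AGSTV]`, and
requires ≥ 200 residues N-terminal of the motif (a typical mature
serpin is 300–400 residues with the hinge in the C-terminal third).
Tandem twin-domain serpins yield one hit per motif at ≥ 250 residues
separation. The 9-position consensus classes used for scoring are
ED / EDGST / G / TS / EKRQ / AG / AGS / AGST / AGSTV; a serpin is
flagged inhibitory when its mapped hinge matches ≥ 6/9 (threshold
0.667) — degenerate hinges mark likely non-inhibitory serpins.

**A2M gate:** whole-protein hit when length ≥ 1000 residues (configurable)
and a thioester motif is present.

## Serpin RCL annotation

The hinge start and P1 column of an annotated reference serpin are
mapped onto the query through a deterministic global pairwise
alignment (BLOSUM62, gap open 10 / extend 1, Biopython
`PairwiseAligner`). P-numbering: hinge = P17–P9, P1 = last RCL
residue before the scissile bond, P1′ immediately after, so
P1 = hinge start + 16. A reference column aligned to a query gap
reports that field "unresolved". The query must support the reference
RCL: at least 50% of the reference RCL columns (P17–P1′) have to align
to positively scoring query residues, otherwise the RCL is declared
unmappable — the profile of serpins missing the definitive hinge
residues. This mapping is homology-based by construction; it is
meaningful for sequences sharing the serpin fold, not for arbitrary
proteins.

The packaged reference (`spiscan/data/synthetic_serpin_reference.*`)
is a **synthetic** 387-residue serpin generated deterministically by
`synthetic_data.build_reference_serpin`; its fixture annotations
(hinge 280–288, P1 296) define truth for the tests. Users with a
structurally characterized serpin (e.g. alpha-1 antitrypsin) can
substitute their own reference plus sidecar annotations.

## Canonical annotation

Disulfide maps are fixed constants per family (see README table).
P1 calls use a fixed offset from an anchor framework cysteine:
Kazal Cys2+2, Kunitz Cys1+2, Pacifastin Cys4+1, TIL Cys5+2, WAP
Cys2+2. In the original survey P1 was read off multiple alignments;
fixed offsets make the pipeline deterministic and testable, and the
synthetic generator plants P1 at the same offsets. Calibrating
offsets on real alignments is a user task. Genes whose domains yield
no assignable P1 keep an empty specificity set (absence of evidence)
rather than being labelled non-inhibitors.

## Pacifastin processing

Cleavage sites are the dibasic pairs RR, RK and KK (KR deliberately
excluded), reported with overlaps. Splitting cleaves **C-terminal of
the pair, removing no residues**, so product lengths always sum to the
precursor length — the prediction concerns sites, not processing
chemistry, and whether the enzyme cuts N- or C-terminal of the pair is
unknown; the choice is stated here and in the output header. A site
within one residue of a domain span is suppressed (domains are never
bisected); overlapping usable sites resolve greedily leftmost.

## TEP classification

Features: thioester `[GD]CGEQ` (leftmost canonical GCGEQ preferred),
catalytic His searched in a ±20 window around +100 residues downstream
of the motif start (the conserved spacing is only "approximately 100"),
ties to the position nearest +100 then smaller; bait region = first
exact FPETW; C-terminal cysteine enrichment = Cys fraction of the last
150 residues, flagged at ≥ 0.06. Rule cascade: no thioester →
`not_tep`; GCGEQ + His + bait → `A2M`; GCGEQ + His, no bait → `iTEP`;
variant motif or missing His → `atypical`. These motif-level rules are
a surrogate for clade placement; with user-supplied reference TEPs the
phylogenetics module can refine the call, and a divergent member
(DCGEQ, His substituted) classified `atypical` here may still fall
inside the iTEP clade on a tree.

## Phylogenetics

Distances are uncorrected p-distances on pre-aligned protein blocks
(pairwise gap deletion by default; complete deletion available) — the
simplest closed-form protein distance, chosen for testability;
multiple alignment itself is out of scope (input is pre-aligned).
Neighbor joining is the standard Saitou–Nei agglomeration with the
Q-criterion; ties break to the lowest index pair, and negative
branch-length estimates are clamped to zero with the clamped deficit
recorded on the tree (`nj_clamped_deficit`). Bootstrap supports are
integer percentages of column-resampled replicates containing each
internal bipartition of the full-data tree; replicates in which some
pair has no comparable columns are discarded and counted. Everything
is seeded and deterministic. On additive matrices NJ provably recovers
the generating topology; the tests verify this on random trees with
n ≤ 8 and branch lengths in [0.1, 1].

## Expression analysis

The venom-specificity threshold (BH-adjusted p < 0.001, log₂ ratio
> 1, FPKM_VG > 10) is applied exactly. The per-gene p-value engine is
a declared stand-in: an exact one-sided binomial test on FPKM-scaled
pseudo-counts (k = round(FPKM_VG·10) of n = round((FPKM_VG +
FPKM_carcass)·10) trials, null 0.5). It is deterministic, swappable
via the `library_scale` parameter, and deliberately simple; it is not
DEGSeq, so on real data the filter preserves the thresholds but not
necessarily the published gene membership. log₂ ratios use a
pseudocount of 1 in numerator and denominator to handle zero FPKM.
One consequence worth knowing: under this stand-in at scale 10, any
gene passing both the abundance and the enrichment gates is
automatically significant, so a gene can fail the p-gate only by
sitting at (or below) the enrichment boundary as well — the
generator's "p-gate near-miss" genes therefore fail p and ratio
together, and their truth table says so.

Pseudogene flag: max FPKM over all samples ≤ 1 (profiling elsewhere
includes genes with FPKM > 1).

qPCR: replicate Ct values are averaged per (gene, sample) before
ΔCt = Ct_target − Ct_reference; ΔΔCt subtracts the calibrator sample's
ΔCt; fold = 2^−ΔΔCt, so the calibrator fold is 1 by construction.
Shifting every Ct by a constant leaves folds unchanged.

## Physicochemical properties

Molecular weight sums average-isotopic residue masses plus one water
(18.015 Da); X uses the mean residue mass. Isoelectric point bisects
the Henderson–Hasselbalch net charge over pH 0–14 with the
Bjellqvist/Expasy-style pKa set (N-term 7.5, C-term 3.55, K 10.0,
R 12.0, H 5.98, D 4.05, E 4.45, C 9.0, Y 10.0) to 1e-6 pH; agreement
with any particular web tool to the last digit is not claimed. The
signal-peptide check is a labelled heuristic (≥ 8-residue stretch with
mean Kyte–Doolittle hydropathy > 1.6 within the first 30 residues,
preceded by K/R or starting by position 6), not a trained predictor.

## Synthetic data: what it emulates, and what it does not

The generators mirror the survey's input structure: canonical
architectures from single domains to 11-copy tandem repeats plus a
mixed Kunitz/WAP mosaic (60 canonical domains over 5 families by
default), 6 serpin genes including one twin-domain gene, one TEP per
feature class, 200 decoys, Pacifastin precursors with one dibasic
site per linker, a 100-gene FPKM matrix with 8 venom-specific genes,
per-gate near-misses and 5 pseudogenes, and Ct tables with three
replicates. All generators are byte-deterministic given the seed.

Deliberate simplifications, and hence the limits of what passing
tests show:

- Planted domains sample **inside** the detection windows and are
  rejection-sampled against same-size rival family envelopes; decoys
  are i.i.d. residues (Cys frequency ≤ 0.02) rejection-sampled to
  contain no detectable signal. Recovery ≥ 0.95 therefore measures
  scanner correctness, not the windows' fit to real proteomes.
- Synthetic serpins are substitution-only divergences (rate 0.3) of
  the reference template with the hinge held fixed; real serpins have
  indels, so exact P1 recovery holds only for the indel-free case.
- Inter-domain linkers exceed every spacing-window maximum, which
  real multi-domain proteins do not guarantee.
- Expression backgrounds are constructed to fail the enrichment gate;
  the filter's false-positive behavior on realistic null expression
  is not measured.
- Phylogenetic test data are additive matrices and two-cluster
  alignments, not evolved sequences.

Problem sizes in the default test-suite runs (200 decoys, 200
bootstrap-free additive matrices with n ≤ 8, 100 bootstrap replicates,
100-gene expression matrices, 200-gene qPCR Monte Carlo) were chosen
as the smallest scales at which the checked properties are
non-trivial; all are configurable upward.

## Known limitations

- The spacing windows, P1 anchor offsets, serpin length bounds, His
  window and cysteine-richness threshold are package defaults, not
  field constants; real-data use requires calibration.
- Accessory (non-inhibitor) domains of mixed-type genes are accepted
  as external annotations, never detected.
- The inventory table records the survey's printed per-row domain
  counts verbatim; the TIL rows print a shared count of 5 whose
  reading (per gene vs per range) the source leaves ambiguous, and the
  count-summary operations use gene counts, which are unambiguous.
- No multiple sequence alignment, HMM detection, or ML/Bayesian
  phylogenetics; genome coordinates (gene clustering on scaffolds) are
  out of scope.
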