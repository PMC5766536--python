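# Methods

`ecrtmine` re-implements, as a tested library, a mining pipeline for
endogenous caulimovirid reverse-transcriptase loci (ECRTs) in plant
genome assemblies: translated homology search, two-pass classification
against a labelled RT library, greedy identity clustering with a
similarity-network OTU definition, maximum-likelihood phylogenetic
placement on a fixed reference tree, and per-genome summary statistics.
Because the original study conditions (72 Viridiplantae assemblies)
cannot be reproduced at desk scale, a first-class synthetic-data module
generates benchmark genomes with planted, mutationally decayed viral
insertions and ground truth, and every stage is validated against that
truth or an independent brute-force oracle.

## Translated search

The first pass emulates a tBLASTn-style search of protein RT queries
against genome nucleotides:

- All six reading frames are translated (stops `*`, N-containing codons
  `X`); each frame is indexed by exact amino-acid k-mers (default k = 4;
  no BLAST neighbourhood words — decay benchmarks showed exact 4-mers
  give adequate sensitivity, and the seed length is configurable).
- Seeds are grouped by diagonal (band 16) and extended ungapped under an
  X-drop rule (drop 20). Groups whose ungapped score reaches the gapped
  trigger (default 40 raw, the conventional BLAST-style two-stage
  threshold; on decayed-copy benchmarks true hits score ≥ ~240 while
  random seed groups stay ≤ ~50) receive a gapped Smith–Waterman
  extension over the subject window the group spans; overlapping windows
  are collapsed first.
- Scoring is BLOSUM62 with affine gaps (open 11, extend 1). E-values use
  the Karlin–Altschul form `E = K·m·n·exp(−λS)` with the published
  gapped BLOSUM62/11,1 constants λ = 0.267, K = 0.041 (configurable);
  `n` is the genome length minus assembly gaps (N-runs). Retained HSPs
  need E ≤ 1e−5.
- HSP footprints are merged into loci whenever they overlap, regardless
  of strand or frame (half-open intervals that merely touch are not
  merged; strand is recovered later from the best translation), then
  extended 120 bp on each side, clamped, and re-merged. Coordinates are
  0-based, half-open, forward strand throughout (BED convention).

The acceptance suite checks that, on 20 kb genomes, every frame whose
full per-frame Smith–Waterman score is significant (and which shares a
seed with the query) is recovered with the same score within 1 unit;
the full-DP oracle is an independent numba implementation in the test
suite.

## Two-pass classification

Pass 1 (protein level): each extended locus is translated in six
frames; maximal stop-free segments of ≥ 200 aa are kept, and the
longest is aligned locally against every record of the combined
two-family library (caulimovirid targets + Ty3/Gypsy outgroup). The
locus is `accepted` iff its best-scoring subject is caulimovirid and
the alignment covers ≥ 170 residues; otherwise `rejected_family` or
`rejected_length`. Ties are broken by higher identity, then
lexicographic subject id. The "reciprocal" check is operationalized as
best-score family assignment against the combined library — the
outgroup records make the comparison two-sided without a second search
direction.

Pass 2 (nucleotide level): the locus sequence itself is aligned, frame
by frame, against the library; internal stops are crossed at matrix
cost (`*` columns score −4), which is what makes this pass sensitive to
pseudogenized copies that pass 1 cannot see. The locus is eligible for
placement iff the best subject is caulimovirid and the nucleotide
footprint of the alignment (3 bp per alignment column) reaches 80% of
the subject length — 576 bp for the generic 240-aa RT domain (computed
with exact rational arithmetic; naive floating arithmetic yields 577).
Frameshifted copies whose best single-frame span falls below the cutoff
are not recovered; no frameshift-aware alignment is attempted.

## Clustering and OTUs

Pairwise identity is defined (the upstream tools leave it unstated) as
identical columns over alignment columns, under a BLOSUM62 global
alignment with free terminal gaps and with terminal-gap columns
excluded from the denominator; a `shorter`-sequence denominator is
available behind a flag. Greedy centroid clustering processes sequences
longest-first; each joins the first centroid at or above the threshold
(0.80 within a species, 0.55 globally) and the longest member
represents each cluster.

Aligned sets are cleaned with a three-round filter: drop sequences
whose well-supported residues (columns non-gap in ≥ 75% of the other
rows) cover < 50% of the alignment width; drop columns < 50% non-gap;
repeat the sequence round. The multiple alignment behind this step is
produced by mafft (single-threaded).

OTUs are connected components of the similarity graph over cluster
representatives (edge iff identity ≥ threshold). This replaces a
NeighborNet reconstruction with manual curation: components are a
deterministic, reproducible surrogate, with the threshold exposed as
configuration. The default network threshold is 0.45, midway between
the toy reference's cross-clade (~0.35) and within-clade (~0.7)
identities; the criterion-level separation checks use the 0.55
clustering threshold itself. The cluster→network loop iterates until
the component partition is stable (in practice one round).

## Phylogenetic placement

The reference package (Newick tree with branch lengths, ungapped
nucleotide reference alignment, GTR+Γ model, leaf→OTU map) is an input;
no tree inference is performed. Queries are projected into reference
columns by semi-global alignment to their best-matching row (chosen by
shared 8-mers, both orientations tried since mined loci carry no
strand), with keep-length semantics: query insertions relative to the
reference are dropped, so the output row has exactly the reference
length. Queries with no shared 8-mer are reported as unalignable
rejects.

The likelihood engine is Felsenstein pruning under GTR with discrete-
Gamma rate heterogeneity (4 equal-probability categories with
mean-of-bin rates, shape 1.0 by default, `ncat=1` to disable), gaps and
Ns as missing data, per-node rescaling against underflow. The rate
matrix is scaled to one expected substitution per site per unit branch
length and exponentiated through the symmetrized eigendecomposition.
The engine is checked against the two-leaf Jukes–Cantor closed form and
an exhaustive ancestral-state enumeration (≤ 8 leaves × 100 sites,
tolerance 1e−6 in log space).

Placement attaches the query to the midpoint of every edge by a pendant
branch optimized by bounded golden-section search (bounds 1e−8 to 5
substitutions/site, tolerance 1e−4); the highest-likelihood edge wins
and exactly one placement is kept. Full attachment-position
optimization is deliberately omitted — the midpoint surrogate is
cheaper and a brute-force per-edge scan (10 pendant lengths) bounds the
error in tests; `attach_position` is carried in the result for future
refinement. The like-weight ratio is the softmax weight of the winning
edge over all edges. A placement's OTU is the label shared by every
leaf on the leafward side of its edge, else `inner`.

## Summaries

Per-genome ECRT counts are post-pass-2 locus counts (the placement-
eligible set). Density is count per megabase of ungapped assembly
(N-runs excluded; minimum run length configurable, default 1), computed
with exact rational arithmetic before the final float. The trendline is
an ordinary least squares fit of count on log10(ungapped Mb) — matching
the "logarithmic trendline" convention — with R² = 1 − SSres/SStot and
R² defined as 0 for a constant response; a log-log variant sits behind
a flag. The distribution matrix counts placed loci per species × OTU
(plus `inner`), with per-OTU totals and species-presence counts.

## Synthetic benchmarks

The generator emulates what matters to this pipeline and nothing more:

- Backgrounds are i.i.d. nucleotides at a configurable GC fraction
  (default 0.40, typical of plant genomes), optionally interrupted by
  N-runs emulating assembly gaps (default two 1-kb runs per genome).
  No repeats, isochores or gene structure are modelled, so passing
  benchmarks say nothing about specificity against real retroelement
  landscapes beyond the explicit Ty3/Gypsy decoys.
- The toy reference is a fixed 8-leaf, 2-clade tree; leaf proteins
  descend from one random 240-aa ancestor (240 aa = the average RT
  domain size behind the generic pass-2 cutoff) with per-branch
  substitution probabilities chosen to give ~0.85–0.9 identity within
  cherries, ~0.7 within clades and ~0.3–0.35 across clades — the
  gradient the 0.55/0.45 thresholds are meant to resolve. Conserved
  residues keep their ancestral codon, so the leaf coding sequences
  double as the ungapped reference nucleotide alignment. Four unrelated
  ~240-aa proteins (pairwise ~0.1 identity to the targets) form the
  gypsy decoy family.
- Decay applies, in order: per-site substitutions (always to a
  different base), forced in-frame stop codons (expected `stop_rate`
  per 100 codons of the donor's original frame, emulating
  pseudogenization), and per-site indels with geometric lengths
  (single-parameter, heavy-tailed enough to create frameshifts). Every
  edit is logged and the log replays exactly to the decayed sequence.
- Insertions are planted between background bases at uniform positions
  (optional minimum spacing keeps flanked loci separable), on a random
  strand, never overlapping or nested — planted loci are treated as
  independent, as the mined loci are downstream.
- The default pipeline demonstration uses 3 genomes × 100 kb, 8 target
  + 4 decoy insertions each, sub_rate 0.05, indel_rate 0.001, stop_rate
  1.0/100 codons; the recovery benchmark uses 5 genomes × 1 Mb with 20
  + 10 insertions at sub_rate 0.10. No decay parameters are claimed
  realistic for ancient EVEs — substitution rates are benchmark knobs
  meant to be swept.

## Numerical and degenerate-input choices

- All randomness flows through `numpy` Generators seeded from a single
  integer; repeated runs are byte-identical, and output tables are
  written sorted.
- Alignment ties take the first optimal alignment of the underlying
  aligner; subject ties in classification resolve by identity then id.
- Empty genomes, empty donor lists, zero-length backgrounds, emptied
  alignments and unalignable queries return empty/flagged results;
  invalid rates, non-rectangular alignments and unmapped loci raise.
- The test suite's problem sizes (20 genomes × 20 kb for oracle
  equivalence, 5 × 1 Mb for recovery, 50 queries for placement) were
  chosen to exercise each guarantee at meaningful scale while keeping
  the whole suite to a few minutes on one CPU.

## Known limitations

- No low-complexity masking, composition-based statistics or two-hit
  triggering; E-values are calibrated by the published constants, not
  re-fit.
- Locus merging is strandless; if the original procedure merged
  strand-aware, counts could differ on genomes with overlapping
  opposite-strand elements.
- Pass 2 is not frameshift-aware; heavily indel-decayed copies are
  missed once no single frame spans the cutoff.
- The placement surrogate optimizes only the pendant branch at the edge
  midpoint, and the reference tree/model are trusted inputs.
- OTU delineation by threshold components is a deterministic surrogate
  for curated network analysis; near-threshold identities can merge or
  split groups under small parameter changes.
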