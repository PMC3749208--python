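# Methods

This note records the models, conventions and numerical choices behind
`omzplume`, and what the synthetic-data generators do and do not emulate.

## Synthetic data

**Reference taxonomy and sequences.** A ranked tree is grown level by level
(`children_per_rank` children per node). The root sequence is i.i.d.
uniform over ACGT; every child mutates its parent's sequence independently,
substituting each base with the per-rank probability (always to a different
base). Sequence identity therefore decays with taxonomic distance in a
controllable way — the property the annotation tests rely on. Insertions,
deletions, chimeras, GC bias and pyrosequencing homopolymer errors are *not*
modelled; conclusions about indel-rich real data need external validation.

**Community reads.** DNA reads are drawn from whole reference sequences
with probability proportional to taxon abundance; RNA reads only from
annotated gene intervals with probability proportional to
abundance × per-gene transcription multiplier. Read lengths are normal,
truncated to [50 bp, source length]; start positions are uniform; per-base
substitution errors are applied at `error_rate` (capped at 0.2). Every read
carries a provenance row (true taxon, gene, coordinates), which is what
makes ground-truth recovery tests possible without an aligner in the loop.

**Profiles and incubations.** Depth profiles are piecewise-linear between
breakpoints plus additive Gaussian noise, clipped at zero because
concentrations are non-negative; with zero noise the output is exactly
piecewise-linear, so finite-difference gradients inside one segment equal
the segment slope. Incubations follow
`c(t) = intercept + slope·t/24 + noise` with timepoints in hours (default
0, 6, 12, 24, 48 h, the standard Exetainer sampling design) and at least
three timepoints, since a slope t-test needs a residual degree of freedom.
The zero-clip biases fitted slopes when the true curve hugs zero; bias
checks therefore use a positive intercept.

All generators are driven by `numpy.random.default_rng(seed)` and are
byte-reproducible for identical spec + seed.

## Annotation

**Toy search.** The built-in aligner is a k-mer-seeded (word length 11),
*ungapped* local search: each (subject, diagonal) pair reached by a shared
word is extended once to its best-scoring segment via a max-subarray over
the +2/−3 match/mismatch scores; bit scores use the classic ungapped
nucleotide parameters λ = 0.625, K = 0.41. It exists so the pipeline is
self-contained on synthetic (substitution-only) data; gapped or
heuristic-rich search is out of scope, and external BLAST outfmt-6 tables
are accepted as an equal input through `omzplume.io.read_blast6`.

**Clustering identity.** Greedy incremental clustering, longest sequence
first, with an 8-mer prefilter. Identity is matching columns divided by
the length of the shorter sequence (the CD-HIT convention); matching
columns are computed as shorter-length minus the semi-global (infix) edit
distance from `edlib`. The representative is the founding — hence longest —
member.

**rRNA partition and LCA.** The reference-database bit-score cutoff (86)
is inclusive at the boundary. LCA assignment keeps hits within 10% of the
best bit score, places the query at the lowest common ancestor of their
taxa, and applies the minimum-support rule (5) on *cumulative* support:
queries on under-supported taxa are promoted to the nearest ancestor whose
subtree holds enough queries ("promote"); a "discard" mode drops them to
UNASSIGNED instead. Ties everywhere break by (score desc, subject id asc).

**Calibration sweep.** Database fragments are re-searched against the
unfragmented database; a best hit is correct if it is the source sequence
or differs from the true lineage at ≤ 2 root-aligned rank positions.
Confusion counts are evaluated at every distinct best-hit score, and the
selected threshold is the smallest one reaching the specificity criterion
(default 0.99). Sensitivity is non-increasing and specificity
non-decreasing by construction; the function asserts this on every run.
Fragments with no hits have no score to threshold and are excluded, keeping
TP+FP+TN+FN constant across rows. The published exercise ran on a
477,749-sequence rRNA database; the packaged simulation runs at 200
reference leaves and 2,000 fragments, which preserves every structural
property of the sweep while fitting a desktop run.

## Recruitment

Coordinates are 0-based half-open throughout (GFF3-style 1-based inputs
must be converted at the boundary). The ambiguity filter discards reads
whose best and second-best genome bit scores differ by less than 5%
*relative to the best score* (the denominator is a convention choice).
Window coverage is mean per-base depth over non-overlapping 300-bp windows,
the trailing window keeping its true width, so `Σ depth·width` equals the
total recruited bases exactly. The expression-ratio divides library-size-
normalized RNA by library-size-normalized DNA coverage; windows with zero
DNA coverage are flagged undefined by default (a declared pseudocount is
the alternative), and an optional extra scalar (`size_correction`) is
provided for workflows that applied a separate metatranscriptome/
metagenome size correction on top of the per-library normalization — here
that correction is interpreted as the normalization itself, so the scalar
defaults to 1. Library totals are the protein-coding hit counts; using
all-sequence totals is a caller choice, since both appear in practice.
Strand is ignored (unstranded pyrosequencing-style reads). Gene-level
ratios average defined windows weighted by overlap length.

## Community statistics

Equalization subsamples every sample without replacement to the smallest
sample total (multivariate hypergeometric, seeded). Diversity follows
`D = Σ Pᵢ²`, `1/D`, `E = (1/D)/S`. Bray-Curtis is `Σ|x−y| / Σ(x+y)`;
a distance between two all-zero samples is undefined and raises.
Hierarchical clustering uses group-average (UPGMA) linkage via scipy —
the default of the PRIMER package this style of analysis is usually run
in — and exports an ultrametric newick. ANOSIM is implemented in-package:
rank-transformed distances (mean ranks on ties),
`R = (r̄_B − r̄_W)/(n(n−1)/4)`, add-one permutation estimator
`p = (1 + #{R* ≥ R})/(1 + n_permutations)`, with an exact mode that
enumerates all distinct label arrangements for small designs. scikit-bio's
ANOSIM serves as an independent cross-check in the tests, never as the
implementation.

## Geochemistry

Depth is positive downward, so stable stratification (density increasing
with depth) gives `N² = (g/ρ̄)·∂ρ/∂z > 0`; this matches the physical sign
of the usual z-up formula `N² = −(g/ρ)·∂ρ/∂z`. Density and concentration
gradients are least-squares slopes over 4-m bins (robust to uneven
sampling). Bins with `N² ≤ 10⁻⁹ s⁻²` are flagged neutral/unstable and get
no diffusivity — the floor prevents unbounded `Ez = γε/N²`. Fluxes use
µmol l⁻¹ ≡ mmol m⁻³ so `J = Ez·∂C/∂z·86400` lands in mmol m⁻² d⁻¹; a layer
rate is flux divided by layer thickness, reported in nmol l⁻¹ d⁻¹. Plume
budgets are pure unit-consistent arithmetic (volume = area × thickness;
inventory = volume × concentration; mass via molar mass). Seawater density
is accepted as an input column; computing it from T/S via an equation of
state is out of scope.

## Rates

Production rates are OLS slopes of product concentration versus time in
days. Acceptance requires the slope t-test `p < 0.05`, `R² > 0.8`, and a
no-lag check: refitting without the first timepoint must not raise the
slope by more than 50% (the criterion in the field is stated only
qualitatively, so the check is flag-controlled and deliberately
conservative — with five timepoints, dropping one point rarely shifts a
genuinely linear slope by half). Mole-fraction correction follows standard
isotope-pairing usage: single-labelled products (²⁹N₂ from anammox, ¹⁵NO₂⁻,
¹⁵NH₄⁺) divide by F, double-labelled ³⁰N₂ from denitrification by F²;
F is amendment/(amendment + ambient) when the ambient pool is supplied.
Rates are net production; isotope dilution and the full ²⁹/³⁰N₂ pairing
decomposition into co-occurring anammox and denitrification are not
modelled. ¹³C fixation evaluates the atom-percent enrichment formula
exactly, clipping (and flagging) samples below background. Zone integration
multiplies the zone-mean volumetric rate by the zone thickness; regional
budgets convert through 12.011 g mol⁻¹ C and report fractions of reference
production unclamped.

## Problem sizes and tolerances

The packaged simulations run at sizes chosen to exercise every code path
while remaining desktop-scale: 200-leaf reference database with 2,000
fragments for calibration, 50-read clustering oracles, 6-sample exhaustive
ANOSIM enumeration (20 arrangements), 30,000 + 30,000 reads for
expression-ratio recovery, and 1,000 Monte-Carlo replicates for the rate
filter's type-I error and slope bias. Numerical comparisons in the tests
use exact equality where arithmetic is exact (window coverage conservation,
unit round trips) and sampling-theory tolerances (binomial/multinomial
standard errors, 2 SE bias bounds) where results are stochastic.

## Known limitations

* The toy search is ungapped; imported alignments are required for
  indel-rich data.
* The generator's error model is substitution-only, so clustering and
  calibration results on real pyrosequencing data (homopolymer indels)
  will be somewhat worse than the synthetic tests suggest.
* Protein-level (BLASTx-style) assignment is consumed as tabular input
  only; no toy protein search is provided.
* NMDS ordination, SIMPER/PERMANOVA, KEGG pathway mapping and profile-HMM
  scanning are out of scope.
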