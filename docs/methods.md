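# Methods

This note documents the models, numerical choices and limitations behind
`revecol`, module by module.

## Proteome composition traits

**Sanitization.** All composition statistics run over the 20 canonical
residues only.  Ambiguity codes (B, J, O, U, X, Z) and stop characters are
stripped before counting, from numerator and denominator alike, so
frequencies always sum to 1 over counted residues; the number of dropped
characters is reported as a warning.

**IVYWREL → OGT.** The summed frequency *F* of Ile, Val, Tyr, Trp, Arg,
Glu and Leu correlates linearly with prokaryotic optimal growth
temperature.  We expose the map `OGT = slope·F + intercept` with defaults
slope = 937.0 °C and intercept = −335.0 °C, the published fit for this
proxy; both are plain parameters, because regression constants of this
kind drift between training corpora.  The map is affine by construction
(tested), and inputs outside [0, 1] are rejected.  R+E and proline
fractions are computed from the same frequency vector.

**Net charge and pI.** A protein's charge at pH *x* is modelled per
ionizable group:

    Q(x) = Σ_basic  n_g / (1 + 10^(x − pKa_g))
         − Σ_acidic n_g / (1 + 10^(pKa_g − x))

counting one N-terminus and one C-terminus per chain plus side chains of
D, E, C, Y (acidic) and H, K, R (basic).  Q is strictly decreasing in pH,
so pI (the root of Q) is unique and bisection on [0, 14] converges
unconditionally; we iterate to an interval below 1e−12 pH units (well
inside the 1e−4 charge tolerance) with a hard cap of 100 iterations.  The
whole proteome is solved in one vectorised pass over a protein × group
count matrix.  Two named pKa tables ship: an IPC-protein-style set
(default: N-term 9.094, C-term 2.869, C 7.555, D 3.872, E 4.412, H 5.637,
K 9.052, R 11.84, Y 10.85) and an EMBOSS-style set (N-term 8.6, C-term
3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1).  The choice
shifts individual pIs by ~0.2–0.5 pH units, which is why it is explicit
rather than buried.  Proteins with no ionizable groups (possible only
when termini are disabled) have undefined pI and are excluded and counted.

**Trough detection.** The acidic/basic breakpoint is the minimum of a
Gaussian kernel density (Silverman bandwidth) evaluated on a 0.01-pH grid
over [0, 14], taken between the two highest density peaks and clipped to
a configurable search window (default [4, 10]).  Peaks are screened with
a prominence threshold of 5% of the maximum density; plain
local-maximum detection flags KDE ripples on finite samples as modes,
which the prominence filter suppresses.  Unimodal densities, samples
smaller than 10, and windows that collapse to nothing fall back to a
fixed breakpoint of 7.0 with an explicit `unimodal` flag.

**pI bias.** `bias = (n_basic − n_acidic)/(n_basic + n_acidic)`, where
acidic means pI ≤ breakpoint (ties count acidic, a deterministic
convention) — a signed proportion difference in [−1, 1], positive when
basic proteins predominate.  It is antisymmetric under reflection of the
pI values about the breakpoint (tested as a property).

## Genome features

Coordinates are 1-based inclusive everywhere.  Coding density merges both
strands before taking the interval union (coverage is a per-base
property), and is invariant to splitting a gene into abutting pieces.
The overlapping-gene ratio is the fraction of genes sharing ≥1 bp with
another gene on the same contig, strand-agnostic — the simplest
deterministic reading of "ratio of overlapping genes".  The CDS~size
relationship is ordinary least squares of CDS count on genome size
(statsmodels), reporting slope, intercept, adjusted R² and the F-test
p-value.

## Marker QC

Completeness is the percentage of expected markers present at least once;
contamination is the percentage of excess copies, `100·Σ max(c−1, 0)/|set|`.
This is deliberately the simple per-marker formula, not the
collocated-marker-set machinery of the full CheckM models: the
methodological point here is the *lineage adjustment*, not the scoring.
Deep-branching lineages genuinely lack some "universal" markers, so
`derive_exclusion` computes, per genus, the markers absent from every
member genome, and `adjusted_set` removes them from the expected set
before scoring.  Excluding markers that are absent can only raise
completeness (tested as a monotonicity property), and a genome whose only
gaps are genus-universal absences scores 100% on its adjusted set.

Curated absence lists for Jingweiarchaeum (9), Haiyanarchaeum (21),
Rehaiarchaeum (29), Acidifodinimicrobium (24) and Parvarchaeum (17)
against the 149-marker archaeal set ship as versioned data, together with
the 9 markers absent across all five genera.  Only the accessions named
in those lists are known individually; the remainder of the 149-marker
set is padded with editable placeholders, which users scoring real HMM
output should replace with their own accession list (all set arithmetic
is exact regardless of naming).  Marker hits are consumed as a TSV; this
package does not run HMM searches.  Quality tiers follow MIMAG-style
thresholds: high = completeness ≥90%, contamination <5%, both rRNAs and
>18 tRNAs (rRNA/tRNA flags are inputs); medium = completeness >50% and
contamination <5%.

## AAI

Alignment is Smith–Waterman under BLOSUM62 with affine gaps (open −11,
extend −1) via Biopython's `PairwiseAligner`.  Identity is matching
columns over *all* alignment columns (gap columns included in the
denominator), matching common identity-over-alignment-length usage.
Candidate hits are filtered by raw score (default ≥50) and coverage of
the shorter sequence (default ≥0.5); this replaces an E-value threshold —
full Karlin–Altschul statistics are out of scope — and the defaults are
declared substitutes, exposed as parameters.  Best hits break score ties
to the lexicographically smallest subject id, making reciprocal-best-hit
sets deterministic and independent of record order.  AAI = 100 × mean
identity over RBH pairs; pairs with no RBH yield NaN with a warning
rather than a fabricated number.  Scores are computed without traceback
(the expensive all-vs-all pass); tracebacks run only for best-hit
candidates and final ortholog pairs.

## Ancestral reconstruction

Traits evolve by Brownian motion: child = parent + N(0, σ²·branch).
For fixed tips the joint likelihood over internal states is Gaussian, and
the ML state at a node is the inverse-path-length weighted combination of
the "messages" from each adjacent subtree — equivalently, the root
estimate of the tree re-rooted at that node, the scheme the classic
`fastAnc` estimator implements.  We compute it by message-passing pruning
on the unrooted graph (O(n) per node, O(n²) per tree, ample for
desk-scale trees) and verified it three ways: against brute-force
numerical maximization of the joint likelihood on random small trees
(≤1e−6), against the two-tip closed form
`(x₁/v₁ + x₂/v₂)/(1/v₁ + 1/v₂)`, and against R phytools `fastAnc`
(states and variances to 1e−6).

The rate is estimated from independent contrasts,
`σ̂² = Σ cᵢ²/vᵢ /(n−1)`; per-node variances are the pruning variances
scaled by σ̂², and 95% CIs use the normal quantile.  On 500 simulated
64-tip datasets the root CI covers the truth ~95% of the time and
standardized contrasts have unit variance — the calibration the
acceptance script re-measures.  Only BM is implemented (no trend or OU
models, no discrete traits); trees are consumed, never inferred.

Polytomies are resolved to binary with zero-length branches, and any
zero or missing length is then replaced by 1e−8 × tree height so that
contrasts are always defined.  Internal nodes without labels get stable
preorder ids `n0, n1, …` (`n0` = root).  Annotated output writes the ML
state (2 decimals) as the internal node label plus a full node TSV
(state, variance, CI); the label replaces the node id in the Newick
because id=value compounds are not parseable as unquoted Newick labels.

## Synthetic data

Every generator is a pure function of its arguments including the seed
(one `numpy` PCG64 generator per call; no global state) and returns the
latent truth it embeds.  Residues are drawn i.i.d. from normalized
weights — no codon structure, no length/composition coupling, no
homology between unrelated proteins.  Bimodal proteomes enrich D/E
(acidic class) or K/R (basic class) 8-fold over a flat background, which
places the pI modes near 4 and 10 as in real archaeal proteomes; real
proteomes have broader, overlapping modes, so trough detection on real
data is harder than on these fixtures.  Diverged pairs apply independent
point substitutions to a uniformly random different residue and report
the exact realized identity — no indels, so AAI calibration tests
alignment identity, not gap handling.  Marker tables hit their
completeness/contamination targets exactly up to rounding (duplicated
markers get copy number 2).  Trees are built by recursive splitting
(balanced or uniform random splits) with uniform branch lengths in
[0.1, 1.0] by default; BM simulation uses exact Gaussian increments, not
Euler steps.  Gene tables chain the requested number of overlapping genes
with small (≥1 bp) overlaps and separate the rest by ≥1 bp gaps;
requesting exactly one overlapping gene is rejected (an overlap needs a
partner), and infeasible packings raise.

What passing tests show, therefore, is that the estimators recover known
truth under their own model assumptions at realistic sizes; they do not
show robustness to real-data violations (annotation errors, compositional
heterogeneity within proteomes, indels, non-BM trait evolution).

## Pipeline and statistics

`run_all` executes traits → AAI → QC → ancestral → group statistics from
a YAML config, logging the package version and a SHA-256 config hash;
reruns are byte-identical.  Group differences use the unpaired two-sample
Wilcoxon rank-sum (Mann–Whitney U) test per genus pair: genera are
independent groups of unequal size, for which the paired signed-rank
variant is undefined.  P-values are Benjamini–Hochberg adjusted across
pairs (adjustment is switchable), with letter groupings at a configurable
alpha (default 0.005).  Singleton groups are dropped with a warning.

## Problem sizes

Defaults used by the test suite and acceptance script: 1000 random
proteins for the pI oracle comparison; 100 random trees of ≤6 tips for
the brute-force cross-check; 500 replicates on a 64-tip tree for CI
calibration; 100 × 100-residue proteins (10 kaa) per AAI calibration
point; 600-protein bimodal proteomes for trough/bias behaviour.  These
sizes give Monte-Carlo noise comfortably below the asserted tolerances
while keeping a full run in tens of seconds on one CPU.
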