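# Methods

This note documents the models and procedures implemented in `genebirth`,
the defaults and why they were chosen, the numerical details, and what the
synthetic benchmarks do and do not demonstrate.

## Coordinates and formats

All internal coordinates are 1-based inclusive (the GFF3 convention); BED
input is converted at the boundary and exon/repeat arithmetic is performed
on merged, disjoint interval sets, so overlap fractions are invariant to how
a repeat annotation splits its intervals. Strand is carried but ignored by
all positional filters. The representative transcript of a gene is the one
with the longest total CDS; ties break to the lexicographically smallest
transcript id (the tie rule is arbitrary but fixed, for determinism).

## Gene-age dating

The species tree must be ultrametric with branch lengths in MY and a
designated reference leaf. The splits on the root-to-reference path, ordered
by decreasing age, define "species groups": group *i* holds the leaves whose
lineage diverges at split *i*. A gene's branch is the index of the deepest
group containing a species with a syntenic ortholocus; a gene absent
everywhere is reference-specific (maximum branch).

**Patchy rule.** A presence pattern is patchy when some group *more recent*
than the deepest present group is entirely absent: such a pattern needs
either multiple origins or multiple independent losses and is excluded
rather than dated. This is the minimal rule consistent with excluding
distant-presence/intermediate-absence patterns; on a ladder tree it means
exactly the monotone ("suffix") patterns are datable, which is what the
exhaustive-enumeration test asserts.

**Filters and precedence.** Repeat overlap (fraction of exonic bases covered
by repeats strictly above 0.70) is checked first, then patchiness, then —
for candidate new genes only — homology validation: a protein hit with
identity strictly above 20% and E-value strictly below 1e-5 in a species
older than the assigned branch disqualifies the gene. Precedence affects
only the reported reason, never membership. Homology conflicts drop the
new-gene flag; no reassignment to an older branch is attempted, since a
cross-species protein hit localises the homolog's species but not a
syntenic branch.

The new-gene branch threshold defaults to 4 (in the seven-species wasp
ladder, the split separating the reference clade from its closest dated
outgroups at ~8 MY) and is configurable so the pipeline generalises.

## Origin classification

Parent search is restricted to dated genes on branches 0–3 (old paralogs);
the best within-genome hit wins by lowest E-value, then highest bitscore,
then smallest id. "Intronless" means exactly one exon. A single-exon child
of a ≥2-exon parent is a retrocopy; any other parented child is a DNA
duplication — including single-exon children of single-exon parents, where
retroposition is undetectable from exon structure. Orphans must pass two
sequential de novo criteria: (1) no protein homolog in the designated
outgroup species and at most one per other species; (2) at most one
homologous DNA locus per species with at least one ortholog covering
strictly more than 20% of the ORF.

Enabling-mutation reconstruction globally aligns the ORF to the outgroup
non-coding ortholog (match +1, mismatch −1, gap open −2, gap extend −0.5;
all configurable — no published scoring applies to this step). Indels whose
length is not a multiple of 3 are frameshift events; the aligned outgroup
bases are then read in the ORF's frame, and any in-frame stop codon before
the ORF's last codon is a premature stop. Substitutions are reported without
directional polarity (which state is ancestral is not decidable from a
pairwise comparison).

## Selection tests

Codon alignments are built PAL2NAL-style: proteins are aligned (BLOSUM62,
gap open −10, extend −0.5) and each residue column is replaced by its source
codon, so gaps are always 3-nt blocks on codon boundaries and internal stops
are rejected.

**ML estimator.** The pairwise likelihood uses a 61-state reversible codon
model: off-diagonal rate π_target for single-nucleotide changes, × κ for
transitions, × ω for nonsynonymous changes, zero for multi-nucleotide
changes; the matrix is scaled to one expected substitution per codon so *t*
is divergence in substitutions/codon. Codon frequencies are F1x4 estimated
from the pair (with one pseudocount per nucleotide; a uniform option
exists). The likelihood is maximised by multi-start L-BFGS-B in log
parameter space, t ∈ (1e-6, 50), ω ∈ (1e-6, 10), κ ∈ (0.1, 50), function
tolerance 1e-10; κ is profiled jointly with t by default and fixable by
config (simulation studies fix it at its true value for speed). Ka and Ks
are decomposed from (t̂, ω̂, κ̂) with model-based site counts (synonymous
substitution-flow fraction evaluated at ω = 1), so ω̂ = Ka/Ks exactly.

**LRT.** The null fixes ω = 0.5; the statistic 2(lnL_free − lnL_null) is
referred to χ²(1). Because the free fit is seeded from multiple starts and
clamped to be at least the null, nesting holds numerically. The
negative-selection *call* additionally requires ω̂ < 0.5, so a significant
ω̂ > 0.5 is never reported as constraint; calibration of the test itself is
therefore measured as the rejection rate p < 0.05 (≈5% at the null), while
the directional call rejects at ≈2.5% there by construction.

**Counting oracle.** NG86 pathway counting (equal-weight minimal pathways,
stop-passing paths excluded unless all paths hit stops) with Jukes–Cantor
correction is implemented independently and agrees to machine precision
with the reference implementation in Biopython on simulated pairs; it
cross-checks the ML estimator (factor-2 agreement at Ks < 0.3) but is never
the primary estimator. Saturation (p ≥ 3/4) is flagged, not raised.

**Exclusion filters.** Ka > 0.5, then Ks > 5, then Ks above the upper Tukey
fence Q3 + 1.5·IQR computed on the survivors of the first two rules
(quartiles by linear interpolation). The fence is the standard reading of a
"1.5 × IQR" outlier rule; a literal `Ks > 1.5·IQR` cutoff would not be
scale-consistent. Excluded pairs lose any negative-selection call. Summary
proportions use half-up rounding at 2 decimals.

## Tissue specificity

Replicate samples of one tissue are collapsed by the median TPM before
anything else; τ, expressed calls, breadth and maxima are all computed on
the collapsed per-tissue vector, so pipeline order cannot change a result.
τ is computed on raw TPM, as the index's definition implies (a
log-transform option exists). Expressed means TPM strictly above 1 in at
least one tissue; τ > 0.85 (strict) assigns the tissue of the maximum, ties
to the first tissue in the configured order. The default tissue list has
N = 7 (testis, ovary, venom gland, salivary gland at 3.5 d and 5.5 d, gut
at 3.5 d and 5.5 d), configurable.

Age groups are branch 0–1, 2–3 and 4–6. Comparisons use a one-sided
unpaired Wilcoxon rank-sum test (older greater) on log2(max TPM + 1) and on
breadth. The normal approximation uses the tie-corrected variance and a
continuity correction applied toward the null, so two identical samples
give exactly p = 0.5; this convention is why the statistic is computed
in-package rather than through a library wrapper whose boundary behaviour
differs.

## Co-expression network

The gene universe is genes with TPM > 1 in at least one sample and nonzero
variance; analysis runs on log2(TPM + 1) by default (standard practice for
correlation networks on TPM; configurable). Adjacency is |Pearson r|^β with
β = 9 (unsigned); an optional scale-free-fit chooser exists in spirit via
the configurable β but the default is fixed for determinism. TOM follows
the usual form TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij).

**Module detection** clusters 1 − TOM by average linkage and applies a
simplified dynamic tree cut in two stages: (1) static stage — maximal
subtrees fully merged below 0.99 × the maximum merge height become cluster
roots (noise genes, whose dissimilarities concentrate near the tree top,
never form such subtrees of meaningful size); (2) dynamic stage — a branch
splits recursively when the merge-height gap to its children exceeds 5% of
its own height and both children hold ≥ min module size (30) leaves.
Clusters below the minimum size are unassigned (label 0), labels are
renumbered by decreasing size. A plain static-height cut is available as a
fallback. This reimplements the *behaviour* (planted-partition recovery;
no modules from pure noise), not the reference algorithm's many heuristics;
label-for-label parity with any particular package is not a goal.

Module eigengenes are PC1 of the z-scored module block, unit variance,
sign-oriented toward the module's mean profile. Merging repeatedly joins
the closest eigengene pair while 1 − cor < 0.5, recomputing eigengenes each
step; the module count strictly decreases so it terminates, and it is
idempotent at the fixed point. Traits are one-hot tissue indicators per
sample (the two salivary-gland and gut time points are distinct traits);
module–trait p-values come from the Student-t transform with n − 2 df. kME
is the gene–eigengene correlation; each module's hub is its highest-kME
member (ties to the smallest id), optionally restricted to a candidate set
such as the new genes.

## Synthetic data

The generator is the package's study system, not a tuning knob. Defaults:
the seven-species ladder with splits at 89.83, 75, 40, 8, 4 and 1.49 MY
(the root, reference-clade and youngest splits follow the wasp system; the
three undated intermediate splits are plausible interpolations and affect
only per-branch birth-rate denominators); 300 background genes on branches
0–3; 30 planted births (10 per branch 4/5/6) cycling through DNA
duplication, retroposition and de novo; 5 repeat decoys (80% exonic
overlap), 5 patchy decoys, 3 homology-conflict decoys; 40 venom genes drawn
from the background (disjoint from new genes). Duplicate children evolve
from their parent CDS under the same codon model the estimator uses
(ω = 0.2, t = 0.3, κ = 2). De novo outgroup orthologs are built by applying
the inverse enabling events to the ORF (insert a premature stop, delete one
base), guaranteeing a recoverable signal.

Presence-flip noise is a per-gene probability (default 0, benchmarks use
5%) that one randomly chosen species flag flips. A per-cell flip rate would
conflate noise with the patchy filter (a single flip usually breaks the
monotone pattern entirely), so the per-gene formulation is what the ≥90%
recovery benchmark refers to.

Expression: 7 tissues × 2 replicates. log2 TPM = age-dependent baseline
(5.0 / 3.5 / 1.5 for old / middle / new genes, ±0.8 between genes) +
2.0 × module latent factor + N(0, 1) noise, exponentiated; loading 2 with
unit noise gives within-module gene–gene correlation ≈ 0.8. Tissue-linked
module factors are 1.5 × indicator + N(0, 0.3). Designated tissue-biased
new genes instead get a modest peak (baseline + 1) in their tissue and
bias-suppressed (−6 log2) expression elsewhere — a plain additive boost
would make new genes the most highly expressed group and invert the planted
age trend. TPM columns are *not* renormalised to sum to 1e6; every
downstream analysis uses thresholds, ratios and correlations only.

All randomness flows from one integer seed through a single RNG stream, and
writers use fixed float formats, so regeneration is byte-identical.

**What passing the synthetic benchmarks shows — and what it does not.** The
benchmarks demonstrate correctness of the logic (branch arithmetic, filter
semantics, estimator calibration, module recovery under a known factor
model) at the generator's noise levels. Real data differ in ways the
generator does not emulate: synteny calls from whole-genome alignment carry
correlated, assembly-quality-dependent errors rather than independent
flips; real paralogs diverge under heterogeneous rates and gene conversion;
expression covariance is not a clean low-rank factor structure; and TPM
matrices carry batch and library-composition effects. Recovery rates on
real genomes will be lower and should be validated against orthogonal
evidence (as the homology-validation and structural filters begin to do).

## Numerical conventions

Half-up rounding for every printed rate and percentage (banker's rounding
deliberately avoided, matching how fixed-precision figures are normally
quoted). Strict inequalities throughout (TPM > 1, τ > 0.85, overlap > 0.70,
identity > 20%, coverage > 0.20). Degenerate inputs fail loudly and early:
all-zero expression vectors, zero-variance genes in the network, empty
alignments and non-positive intervals raise validation errors naming the
offender; saturation in NG86 flags rather than raises because it is a data
property, not a usage error.

## Problem sizes

The shipped benchmarks use 330–350 genes, 14 samples, 20 parent–child pairs
and 500/200 LRT replicates of 500-codon pairs — sizes chosen so the entire
suite replays in a few minutes on one CPU while keeping every statistical
check adequately powered (the type-I band is ±2 binomial s.e. at 500
replicates). All sizes scale up through `SimulationConfig`.

## Known limitations

- Synteny presence is an input; the pipeline does not compute whole-genome
  alignments or call orthologs from sequence.
- Retrocopies of ancestrally intronless parents are systematically labelled
  DNA duplications (undetectable from exon structure).
- The codon model has no among-site rate variation and no branch/site
  heterogeneity; it is a pairwise estimator only.
- The dynamic tree cut is a simplified reimplementation; module boundaries
  on marginal data will differ from other implementations.
- GO enrichment, read mapping/TPM quantification, structural validation of
  annotations and wet-lab validation are out of scope.
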