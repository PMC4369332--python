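# Methods

## Demultiplexing model

Reads are assigned to (sample, PCR replicate) bins by exact string
matching: one orientation of the read must begin with the forward MID
plus forward primer and end with the reverse complement of the reverse
MID plus reverse primer. Degenerate IUPAC codes in primers match their
nucleotide sets; MIDs must be unambiguous. A per-tag mismatch allowance
exists but defaults to 0, since the genotyping protocol this package
models binned only perfect-tag reads. Reads are handled 5′→3′ on the
forward strand after orientation resolution; all coordinates are
1-based with closed intervals. Indel-bearing reads are *not* detected
at this stage — they are removed downstream by the genotyping module's
target-length gate, mirroring the removal of indel-containing
sequences before variant validation.

## Variant validation

Candidates are exact-identity read groups within one individual's bin.
Validation has two steps with fixed order:

1. **Dual-replicate depth**: keep candidates with ≥ `r_min` (default 3)
   reads in each of the two independent PCRs. "Net reads" — the depth
   denominator for the genotyping threshold — is the summed count of
   these survivors, i.e. computed *after* the replicate filter and
   *before* the distinctness rule.
2. **Distinctness**: walk survivors in descending total count (ties
   broken lexicographically — the ordering is otherwise undefined and a
   deterministic rule is required for reproducibility) and drop any
   candidate within Hamming distance < `min_nt_diff` (default 2) of an
   already-accepted variant. Distances are gap-free Hamming because the
   length gate runs first. The rule is applied within one individual's
   amplicon only.

A sample is genotyped when net reads ≥ 275 (default), the depth at
which a 3-copy variant still represents a 1.1% frequency — the margin
chosen to absorb roughly one order of magnitude of amplification bias.

### Minimum-depth calculator

For *m* equiprobable variants, required copies *r* and confidence *c*,
the smallest *n* with P(every variant drawn ≥ r times in n multinomial
draws) ≥ c is found by bisection on the exact probability

P(all ≥ r) = Σ_{j=0..m} (−1)^j C(m,j) A_j,

where A_j, the probability that a fixed set of j categories are all
below r, is a finite sum over their total count with composition
weights read off the coefficients of (Σ_{k<r} x^k/k!)^j; terms are
evaluated in log space and summed with `math.fsum`. A seeded
Monte-Carlo estimator of the same probability serves as a cross-check,
and an `extrapolate_linear` mode reproduces the historical practice of
fitting n against m ≤ 8 and extrapolating (clearly labelled an
approximation; for m = 20, r = 3, c = 0.999 the exact answer is 289
while the linear extrapolation gives 274). The exact path falls back to
Monte Carlo with a warning when m·r is large enough to make the
alternating sum untrustworthy.

## Selection tests

**Wu–Kabat variability** of a residue column is V = k / f_max (k
distinct residues; f_max the modal residue's frequency); V = 1 iff the
column is invariant. Sites with V ≥ 2× the profile mean are flagged,
per species, and the reported polymorphic-site set is the intersection
across species (sites hypervariable in every species).

**Nei–Gojobori counting.** Potential synonymous sites per codon follow
the 1/3-fraction rule (synonymous fraction of the three possible
changes per position; mutations to stops are never synonymous), so
S + N = 3 per codon. Observed differences between codons are averaged
with equal weight over all orderings of the differing positions;
pathways through stop codons are excluded, and if every pathway is
blocked the unrestricted average is used with stop steps counted as
nonsynonymous. Proportions use potentials averaged over the two
sequences, and rates are Jukes–Cantor corrected,
d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 yields a flagged missing value
(saturation), never an exception. All 61×61 codon-pair counts are
precomputed into dense tables so pairwise distances and bootstrap
resampling reduce to integer-indexed array sums.

**Z test.** Mean dN and dS over all sequence pairs restricted to a
codon partition; the standard error of (mean dN − mean dS) comes from a
seeded codon-site bootstrap (default 1000 replicates) rather than the
analytic variance, and the p-value is the one-tailed normal upper tail
(a test of positive selection). Alignments with zero bootstrap variance
(e.g. identical sequences) report p = 1. Masks below 3 codons are
rejected as variance-unstable. Under neutral simulation the empirical
size at α = 0.05 is ≈ 5%.

**Ancestral reconstruction** is per-nucleotide-site marginal maximum
likelihood under JC69 with a uniform prior, computed by the standard
two-pass (postorder partials, preorder outside messages) with per-site
rescaling; multifurcations and zero-length branches are accepted.
Near-ties (relative 1e−9) are broken toward the parent's state, then
alphabetically — both choices minimise implied changes within the tied
set. Fitch parsimony is available behind a flag.

**Per-codon counting (SLAC-style).** For every branch, codon changes
are resolved into synonymous/nonsynonymous counts by the same pathway
averaging; per codon, the observed (Sd, Nd) is tested against the
neutral expectation p_N = N/(N+S) (potential sites averaged over all
node states at that codon) with a one-tailed binomial test extended to
fractional counts through the regularised incomplete beta function.
Codons are flagged positively selected at α = 0.05 when dN − dS > 0.
The test is conservative at desk-scale alignment sizes (measured
type-I rate ~0% at 12 sequences); it reaches significance only with
the large change counts that hundreds of sequences provide, which is
why the command-line pipeline falls back to the Wu–Kabat partition for
supertyping when no codon is significant.

**Diversity.** π is the mean pairwise per-site p-distance; πS and πN
are mean pairwise NG86 proportions over a codon mask. Standard errors
come from a seeded site (codon) bootstrap. The ratio reported as
dN/dS is the ratio of the two means (not the mean of per-pair ratios).

## Phylogenetics

Distance matrices: JC69 on nucleotide p-distances, or pairwise NG86 dN
/ dS. Neighbor joining is the Saitou–Nei agglomeration with
deterministic tie-breaking (lexicographically smallest index pair among
Q-minima); negative branch lengths are clamped to zero with the deficit
moved to the sibling branch. On additive matrices the implementation is
exact (topology and branch lengths to 1e−9; verified on 100 random
trees of up to 12 taxa).

Bootstrap support resamples columns with replacement — nucleotide sites
for the JC metric, whole codons for dN/dS — rebuilds the NJ tree, and
reports for each internal edge of the *original* tree the percentage of
replicates containing the same bipartition (support annotates a
reference topology, not a consensus). Saturated (missing) distances are
imputed per matrix by the matrix maximum with a logged warning —
saturation is information about a large distance, and NJ needs complete
input; replicates whose matrices are entirely undefined are dropped and
supports renormalised.

The interspecific-clade statistic enumerates internal edges with
support at or above a threshold (reported at both 50 and 70), takes the
smaller bipartition side as the supported clade, and counts clades
whose species set covers all required species. Nested qualifying clades
collapse to maximal ones for the clade count; the variant fraction
counts each leaf once regardless of how many qualifying clades contain
it (both "maximal-only" and "any-clade" counts are retained).

## Supertyping

Alleles are reduced to their residues at selected sites, collapsed to
unique amino-acid strings, and encoded by concatenating five
physicochemical descriptors per residue (z1 hydrophobicity, z2 steric
bulk, z3 polarity, z4/z5 electronic terms; the packaged table is the
published five-z scale and is user-replaceable). Columns are
standardised to unit variance by default. K-means runs on the full PCA
transform for K = 1..k_max (default 20, 10 seeded restarts) and K is
chosen by the BIC of a hard-assignment spherical Gaussian mixture —
including the mixing-proportion term, without which the criterion
oversplits — with ties within 2 BIC units resolved to the smallest K.
DAPC retains 10 principal components and up to 3 discriminant functions
(capped at K−1 and the matrix rank) via linear discriminant analysis on
the retained PCs. The sharing summary reports the species set
possessing each supertype and flags supertypes confined to a proper
subset of the species.

## Synthetic data

The generator produces the study conditions end to end: 3 species × 18
individuals, 82 codons with an 11-codon selected-site partition, 7–20
variants per individual, and raw double-tagged reads.

**Allele histories** use a class-structured forward model rather than a
coalescent with balancing selection — the pipeline's discriminating
signal depends only on whether allelic classes predate the species
splits, and the forward model keeps runs at desk scale.

- *TSP*: 6 ancestral allelic classes arise before the splits; each
  carries a diagnostic amino-acid motif at the selected codons
  (realised once, so selected sites carry synonymous signal too) and
  Poisson neutral-site divergence at rate 0.12/site on the class
  branch. Every species inherits every class; species branches add
  0.012/site and each allele drifts another 0.005/site, all at neutral
  sites.
- *Convergence*: species backbones diverge at 0.012/site after the
  splits; each allele then receives a motif from the *shared* motif set
  (assigned round-robin, since balancing selection maintains the whole
  repertoire in each species), realised with per-allele random
  synonymous codon choices so codon usage is species-independent only
  at the amino-acid level.
- *Null*: species-level divergence at every site, no shared structure.

Motifs are drawn from a per-site alphabet of 4 residues; in-frame stops
are never emitted (blocked draws resample). Gene conversion copies a
geometric tract (mean 100 nt) between random same-species alleles at
0.3 events per allele — per event an order of magnitude more
nucleotides than a point mutation, the regime reported for avian MHC.
After conversion, within-species pools are nudged to pairwise distance
≥ 2 nt (identical alleles are kept): the observable variant universe
under the ≥2-nt distinctness rule contains no 1-nt neighbours, and
without this constraint recovery statistics would penalise the
validation rule for removing alleles it is designed to remove.

**Genotypes** draw L ∈ {6..10} loci per individual; each haplotype is
an L-subset of the species pool sampled without replacement, yielding
7–20 distinct variants.

**Reads**: per replicate, variant weights are copy number × an
independently redrawn log-normal bias factor with σ = ln(10)/3.29, so
the 5th–95th percentile weight ratio is ≈ 10 (one order of magnitude of
amplification bias). Default 600 reads per replicate (~1200 per
individual, matching the per-amplicon read counts of the modelled
instrument runs). Each read is a chimera with probability 0.06 (second
parent and uniform breakpoint recorded), loses one base through the
indel channel with probability 0.02 (a stand-in for homopolymer errors,
whose reads were discarded by length downstream), and has each base
substituted independently at 0.11/171 ≈ 6.4×10⁻⁴ (the per-read error
rate reported for a 171 bp fragment converted to a per-base rate;
substitutions only, uniform over the three alternatives). Reads are
wrapped in the replicate's MID/primer pair (degenerate positions
concretised per read) and emitted on a random strand with full
provenance.

**What passing tests do and do not show.** The generator reproduces the
artifact *rates* and the allele-history *topologies*, not 454 flowgram
physics, real primer-template mismatch behaviour, locus-specific
amplification chemistry, or population-genetic drift within species.
Pipeline-level results (validation error rates, scenario
discrimination) therefore demonstrate correctness of the method under
the stated model, not field performance on any particular instrument.

## Problem sizes and numerical choices

Simulation-backed checks run at sizes chosen to keep the full suite in
a few minutes on one CPU: scenario discrimination uses 2 alleles per
class (36-leaf trees), 100 bootstrap replicates and 20 simulation
replicates per scenario; validation error rates use 102 individuals at
600 reads × 2 replicates; type-I error uses 200 neutral replicates of
12 sequences with 200-replicate bootstraps. Margins at these sizes are
wide (e.g. the TSP dN/dS clade-fraction gap is ≈ 0.02 against a 0.15
bound, the convergence gap ≈ 0.73 against a 0.25 bound). Larger sizes
change runtimes, not conclusions.

Known limitations: marginal (not joint) ML ancestral states; JC69 only
(no gamma rate variation in reconstruction; a gamma-corrected JC
distance is available through the ``gamma_alpha`` option of the
distance matrix); the binomial SLAC test is
underpowered below ~100 sequences; K-means/BIC supertype counts are
sensitive to descriptor standardisation (on by default, flaggable); and
the depth calculator assumes equiprobable variants — the 275-read
threshold exists precisely because real amplicons are not equiprobable.
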