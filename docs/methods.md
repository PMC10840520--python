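# Methods

## Scope and model of the data

`barcodediv` analyses a *panel*: an aligned set of DNA barcode sequences
(equal length L, IUPAC characters, gaps and `N` allowed) joined to
per-sample metadata. The intended marker is the 658-bp 5' region of
mitochondrial *cox1*, but nothing depends on that beyond the default
alignment length of the simulator. Alignment itself is out of scope:
inputs are assumed pre-aligned, and sequences of unequal length are
rejected rather than padded, because silent padding shifts homology.
Partial sequences (e.g. undetermined 3' ends) are expected to arrive
padded with `N` in the input alignment.

## p-distance

The uncorrected p-distance between two aligned sequences is the proportion
of differing sites among *jointly determinate* sites, i.e. positions where
both sequences carry one of A/C/G/T. Everything else — gap, `N`, and all
IUPAC ambiguity codes — is treated as indeterminate. Ambiguity codes get
no partial-match credit: a chromatogram `R` carries no more usable
information for a mismatch proportion than an `N`, and a partial-scoring
rule would complicate the estimator without changing any downstream
conclusion at barcode-level divergences.

Two deletion modes are provided. **Pairwise deletion** (default) excludes
indeterminate sites per sequence pair; it is the conventional default of
distance software, and the right choice when some sequences are truncated:
complete deletion would discard those columns for every pair. **Complete
deletion** removes any column containing an indeterminate character in any
sequence before computing all distances.

A pair with zero jointly determinate sites has an *undefined* distance,
stored as NaN and flagged: NJ, the species summaries and the paired design
all refuse matrices containing undefined entries rather than imputing a
zero (a silent zero would fabricate similarity).

Distances are stored as proportions throughout; percent formatting happens
only in reports.

## Species summaries and the 2% flag

Per species: minimum/maximum/mean intraspecific distance over all
within-species pairs (undefined for singletons), and the nearest-neighbour
species, defined as the other species minimising the arithmetic mean of
all between-species pairwise distances, with lexicographic tie-breaking
for determinism. `threshold_flags` reports, for every species with ≥ 2
samples, whether its maximum intraspecific distance exceeds a cutoff
(default 0.02, the conventional heuristic for insect barcode species
boundaries — a screening device, not a delimitation method).

## Neighbour joining

Classical Saitou–Nei: with r active nodes, join the pair minimising
Q(i,j) = (r−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k); branch lengths from the
two-point formulas l_i = d(i,j)/2 + (Σ_k d(i,k) − Σ_k d(j,k))/(2(r−2));
reduction by d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2; three-point closure at the
end. The output is an unrooted tree represented with a trifurcating root.

Determinism: ties in Q are broken by the smallest (i,j) position pair in
the current node order, so identical inputs give byte-identical Newick.

Negative branch lengths (possible on non-additive inputs) are clamped to
zero by default with the deficit transferred to the sibling branch of the
same join, preserving the joined pair's path length — the standard remedy
for display and for downstream consumers expecting nonnegative lengths. A
flag keeps the raw values. In the final three-point closure negative
lengths are simply clamped (there is no unique sibling to absorb the
deficit among three branches).

On additive matrices the algorithm recovers the generating tree exactly
(topology and lengths); the test suite verifies this against randomly
generated 5–8-leaf trees and checks the 4-taxon choice against an
ordinary-least-squares fit of all three unrooted quartet topologies, plus
a topology cross-check against scikit-bio's independent implementation.

Clade support is computed by **site bootstrap**: resample L columns with
replacement, recompute the matrix and the NJ tree, and report for each
internal edge of the point-estimate tree the proportion of retained
replicates containing the same bipartition. Replicates producing an
undefined distance are dropped; losing more than half of them is an error.

## The locality-paired design

Comparing raw intraspecific diversity between species is confounded by
sampling range, so the comparison is restricted to k species all collected
at the same m locality groups (group numbers are supplied in the metadata;
geographic clustering of nearby sites is a curation step, not computed
here). One sample is kept per (species, group): if several candidates have
identical sequences the lowest seq_id is taken (deterministic, and the
distances are unaffected); if they differ, a seeded random draw decides
and a warning is emitted. Each unordered group pair (stratum) then
contributes one p-distance per species — a k × C(m,2) table. With m = 14,
that is 91 strata. The *mean within-species p-distance* is the row mean.

## Permutation test

Null hypothesis: within each stratum the k species' distances are
exchangeable. Each replicate applies, independently in every stratum, a
uniformly random permutation of the species labels to that stratum's k
values — shuffling *within* strata preserves the between-locality
structure of the data while breaking the species assignment. The statistic
for a species pair is the difference of their mean distances; the reported
p-value is

    p = (1 + #{shuffled |Δ| ≥ observed |Δ|}) / (n_shuffles + 1),

two-sided by default (the absolute difference; a one-sided option exists),
with the observed arrangement counted in both numerator and denominator so
p ≥ 1/(n_shuffles+1) and a test at level α is exact. Ties count as ≥.
Default n_shuffles = 9,999 (10,000 total replicates). An exhaustive mode
enumerates all (k!)^S assignments when that count is below a configurable
cap, giving the exact permutation p-value; Monte-Carlo p-values converge
to it (verified in tests within binomial error).

An alternative shuffling unit — permuting species labels once per
*locality* rather than per locality pair, which induces correlated cells —
is a defensible design but is not implemented as the default because the
per-stratum shuffle matches the declared exchangeability null directly.

Caveat: the C(m,2) cells of one species share the m chosen samples, so
they are not independent observations. The permutation scheme is valid
under the stated null (it permutes entire cells within strata), but the
effective information content is closer to m than to C(m,2); p-values
should be read alongside the bootstrap SEs, not as a substitute for them.
No multiple-testing correction is applied across the k(k−1)/2 pairs; with
k = 3 the three comparisons are reported raw and flagged as such here.

## Bootstrap standard errors

The SE of each species' mean distance is estimated by resampling alignment
*columns* with replacement — one column draw shared by all sequences per
replicate — recomputing every design cell and the species means, and
taking the standard deviation (denominator n−1) of the replicate means
over the default 1,000 replicates. Column resampling is the natural
bootstrap for distance statistics (the sampling unit is the site) and is
applied jointly to the whole design, preserving between-species
correlation induced by shared columns. For a single pair of sequences
differing at a fraction p of L sites the closed form is √(p(1−p)/L),
which the implementation matches within Monte-Carlo error (tested at 15%
relative tolerance). Replicates in which any pair loses all valid sites
are dropped with a warning.

Implementation note: each replicate's mismatch/valid counts are obtained
as a matrix product of precomputed per-pair site indicators with the
column-multiplicity matrix, so 1,000 replicates of a 3 × 91 design cost a
single BLAS call.

## Synthetic panels

`simulate_panel` draws a uniform random root sequence, derives each
species ancestor by substituting each site with probability D (uniform
choice among the three alternative bases, so repeated events can revert),
and draws each (species, group) sample from its ancestor with per-site
probability q_s — a star phylogeny within species. Trailing
`missing_fraction`·L sites can be masked `N` to mimic 3'-truncated reads.

Exact expectations used as test oracles: two lineages independently
diverged from a common ancestor at rate q differ per site with probability
2q(1−q) + (2/3)q², i.e. 2q(1−2q/3) (exactly one substitution always
differs; two independent substitutions differ 2/3 of the time). The same
form in D governs ancestor–ancestor divergence.

`make_three_species_fixture` is the desk-scale study panel: 3 species ×
14 groups × 658 sites, q = (0.007, 0.001, 0.0025), D = 0.10. These rates
put the realized mean within-species p-distances near 1.3%, 0.2% and 0.5%
— one clearly diverse species, one nearly invariant, one intermediate —
and ancestors ~17% apart, within the range typical of congeneric insect
barcodes.

What the simulator does *not* emulate: coalescent genealogy within species
(real samples share history, inflating distance variance), geographic
structure (isolation by distance, distinct clades), rate heterogeneity
across sites, and introgression. Passing tests on synthetic panels
therefore demonstrate correctness of the estimators and calibration of the
test under exchangeability — not robustness to phylogeographic structure,
which no permutation of a confounded design could rescue anyway.

## Numerical and design choices

- Tie comparisons in permutation counting use a 1e-12 absolute guard so
  exact ties (common with discrete distances) count as ≥ despite float
  arithmetic.
- All random processes take a seed and use one `numpy` Generator stream
  per call; identical seeds give bit-identical results.
- Newick serialization quotes labels containing whitespace or structural
  characters and formats lengths with `%.10g`.
- Problem sizes in the test suite (e.g. 500 exchangeability simulations at
  399 shuffles, 100 seeds for the power check at 999 shuffles) were chosen
  to give stable pass/fail margins at the package's default effect sizes
  while keeping the default suite fast.

## Known limitations

- p-distances only; no model-corrected distances (JC69, K2P), no
  codon-aware handling, no saturation analysis.
- NJ only; no maximum-likelihood or Bayesian tree inference, no outgroup
  rooting.
- The permutation test compares means; it is not a test of equality of
  full distance distributions.
- Checklist coverage accounting treats "barcoded" as a supplied boolean;
  it does not query sequence databases.
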