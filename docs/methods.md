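# Methods

This note documents the models, estimators and numerical choices behind
`sagisou`, and what the synthetic-data generators do and do not emulate.

## Lip morphometrics

**Contract.** Measurement starts from vector data: a closed whole-lip
contour, a closed left-wing sub-contour, and landmark points (body base and
tip, a body-width segment, wing base and tip, and a half-open vertex range
marking the serrated distal margin of the left wing).  Image segmentation
is deliberately out of scope — the quantities of interest are purely
geometric, and outlines digitised with any tool can be supplied as CSV.
Contours are stored 0-based and counter-clockwise with an implicit closing
edge; orientation is normalised on load.

**Measurements.** Area is the shoelace formula; perimeter the Euclidean
edge sum including the closing edge.  The dissection index DI =
perimeter/√area is computed on the left-wing sub-polygon, while whole-lip
area and perimeter are reported separately, so both conventions are
available.  DI is scale-free and bounded below by 2√π (isoperimetric
inequality); the test suite enforces DI ≥ 2√π − 10⁻³ on every generated
contour, with the 10⁻³ slack covering vertex discretisation.  Body length,
body width, wing length and the body–wing angle come straight from the
landmarks; the angle is unsigned in the open interval (0°, 180°), and
parallel/anti-parallel axes are rejected as degenerate rather than clamped.

**Serration counting.**  Teeth are high-frequency modulation riding the
low-frequency sweep of the wing margin.  A raw chord-clearance profile is
unsuitable on its own: a perfectly smooth circular arc bulges above its
chord in one dome whose topographic prominence far exceeds any reasonable
tooth threshold, which would count a toothless margin as one tooth.  The
margin is therefore detrended by a least-squares circular baseline (Kåsa
fit); teeth are local maxima of the residual clearance with topographic
prominence ≥ the threshold (default 0.2 mm, one tunable parameter),
plateaus counting once, via `scipy.signal.find_peaks`.  A near-straight
margin falls back to perpendicular chord clearance.  This detector returns
0 on smooth arcs, is robust to vertex density, and recovers the generating
tooth count exactly for k up to 50 when the tooth amplitude is at least
twice the threshold.

**Radar normalisation.** Six traits are divided by fixed maxima — DI 40,
body length 30 mm, body width 10 mm, wing length 40 mm, angle 90°,
serration number 50 — the scaling used to draw comparable radar charts.
Note that a *normalised* DI of 0.04–0.8 corresponds to a raw DI of 1.6–32;
both raw and normalised values are reported.  Population summaries give
per-trait mean and sample SD (n−1 denominator, SD = 0 reported at n = 1).

## Synthetic lips

The generator builds an egret-shaped outline from interpretable parameters:
a round-tipped body lobe (length × width), two circular wing fans of radius
R spanning a given angular extent, wing axes at ±(body–wing angle) from the
body axis, attached 15% down the body.  Serration is a sinusoidal radial
modulation r(t) = R + a·sin(2πkt) along the left wing's distal arc, giving
exactly k teeth of prominence a; the wing tip lies at the modulation node,
so the true wing length is R regardless of serration.  The whole-lip
contour is the exterior of the shapely union of the three lobes; parameter
combinations producing self-intersections or holes raise an error rather
than being repaired.  Vertex density defaults to 10 vertices/mm (perimeter
discretisation error < 0.1%), with at least 8 vertices per tooth.

Optional Gaussian vertex jitter (`jitter_sd`, default 0) emulates
digitisation noise.  Two practical consequences: (i) jitter occasionally
crosses adjacent dense edges, so the generator validates the noise-free
shape once and then redraws the jitter (deterministically, up to 20 times)
until the noisy outline is simple; (ii) jitter adds roughness and therefore
*biases the measured perimeter upward* — landmark- and count-based traits
remain unbiased under noise, but DI means sit a few tenths of a percent
above the noiseless value, which is why DI recovery is checked as a
relative-bias bound rather than against its (much smaller) standard error.

## SSR genotype simulation

Per population and locus, allele frequencies are drawn from a symmetric
Dirichlet with concentration θ (default 1; θ ≈ 0.2 yields the skewed,
divergent spectra used for "well-separated populations", with pairwise Nei
D typically > 0.5 at 20 loci).  Defaults mirror the eight-habitat survey
regime: 8 populations with sample sizes (9, 9, 9, 7, 10, 9, 5, 18), 21
loci, alleles coded as dinucleotide-like fragment sizes 100, 102, 104, …

Three mutually exclusive regimes:

* **Inbreeding** — genotypes drawn with P(ii) = p_i² + F·p_i(1−p_i),
  P(ij) = 2p_i p_j(1−F).  Combinations where F < 0 would drive a
  homozygote probability negative are rejected outright (silently clamping
  would change the regime being simulated).
* **Admixture** — individual proportions q ~ Dirichlet(α, …, α) over K =
  n_populations ancestral clusters; every allele copy picks a source
  cluster from q, then an allele from that cluster's spectrum.  Combining
  admixture with nonzero F_IS is rejected; the joint regime is never
  needed.
* **Clonal propagation** — per population, a configurable number of
  distinct founder genotypes drawn at Hardy–Weinberg proportions, the
  sample filled by uniform copying (every founder represented at least
  once).  Heterozygous founders produce Ho > He and hence negative F, the
  signature of vegetative (bulb) propagation after a bottleneck.

Missing data is inserted per call (both allele copies together) at a
configurable rate.  One root seed drives deterministically spawned child
streams for frequencies, genotypes and missingness, so every simulation is
bitwise reproducible.  The generators do *not* model mutation, coalescent
history, linkage, genotyping error, or spatial structure — parameter
recovery on these simulations validates the estimators under their own
assumptions, not the field realism of those assumptions.

## Diversity statistics

* *He* per locus is Nei's unbiased gene diversity (2n/(2n−1))(1 − Σp̂²),
  with n the typed individuals at that locus; the correction makes the
  estimator exactly unbiased for 1 − Σp² under random sampling of copies.
* *Ho* is the fraction of typed individuals with two distinct alleles.
* Population means are unweighted across loci with ≥ 2 typed individuals.
* **F = 1 − H̄o/H̄e** is computed from the locus-averaged heterozygosities
  rather than averaging per-locus F, which is unstable when individual
  loci are near-monomorphic.  F is undefined (NaN) when H̄e = 0.
* **HWE exact test** — conditional on allele counts, a genotype table with
  h heterozygotes has null probability N!/(Πn_ij!) · 2^h · (Πn_a!)/(2N)!.
  The p-value sums the probabilities of all tables no more probable than
  the observed one, by full recursive enumeration up to 10⁶ tables and
  otherwise by a seeded Monte-Carlo permutation of the flattened allele
  vector (re-pairing consecutive copies).  Enumeration probabilities must
  sum to 1 within 10⁻⁶ or the test aborts.  Note the test is
  *conservative*: at N = 20 with two equifrequent alleles its true size at
  α = 0.05 is 0.024 (computed by exact enumeration over the allele-count
  distribution), a property of all discrete exact tests, not an
  implementation artefact.
* **F significance** — a within-population permutation test: allele copies
  are shuffled among typed individuals independently per locus.  He
  depends only on allele counts and is permutation-invariant, so only Ho
  varies; the two-sided p-value uses the add-one correction
  (b+1)/(reps+1).  Significance is flagged at α = 0.05 with no
  multiple-testing correction by default (a Bonferroni-style correction
  can be applied downstream; none is applied here).
* **Null alleles** — Chakraborty's r = (He − Ho)/(He + Ho), reported
  as-is; negative values indicate heterozygote excess.

## Distances and trees

Nei's standard distance uses across-locus means of Σx², Σy² and Σxy
restricted, per pair, to loci typed in both units.  The default unit is the
individual plant (frequency vectors 0/0.5/1), matching trees that place
individuals at the leaves; population mode pools allele counts.  By
Cauchy–Schwarz D ≥ 0, with D = 0 iff the profiles coincide; D is not a
metric and no triangle property is assumed.  Unit pairs sharing no alleles
have infinite D and are rejected unless the caller supplies a finite cap
(the pipeline defaults to cap = 10, far beyond any within-species value).

Neighbor joining is the Saitou–Nei agglomeration with the standard Q
criterion and two-point branch-length formulas; ties in Q break to the
lexicographically smallest index pair, and negative branch-length estimates
are clamped to zero.  On additive matrices the recovery is exact (verified
to 10⁻⁹ against generated trees and an exhaustive minimum-evolution search
over all 15 five-leaf topologies).

Bootstrap supports resample loci with replacement (the multilocus
convention), rebuild the tree per replicate, and report for each internal
edge of the full-data tree the percentage of replicates containing the same
bipartition; replicates with undefined distances are redrawn, aborting
after 10× the replicate count.  Supports below a display threshold
(default 50%) are suppressed only at rendering; the data model keeps all
values.  Newick output carries 6-decimal branch lengths and integer
supports as internal node labels, quoting labels that contain spaces, and
round-trips through the reader.

## Admixture model

The sampler implements the basic admixture model with *independent* allele
frequencies: p_kl ~ Dirichlet(λ, …, λ) per cluster and locus (λ = 1),
q_i ~ Dirichlet(α, …, α), each allele copy drawn by cluster-then-allele.
One Gibbs sweep samples every copy's latent origin Z ∝ q_ik·p_k(allele),
then P and Q from their Dirichlet full conditionals (via gamma draws), and
updates α by a Gaussian Metropolis step (sd 0.05) under a Uniform(0, 10)
prior.  Missing copies are skipped in counts and likelihood.  The data
log-likelihood Σ ln Σ_k q_ik p_k(a) is recorded every retained sweep; α is
thinned.  Whether the original field analysis used the correlated-frequency
prior is unknowable from the published record; the independent-frequency
variant is implemented and this is a documented divergence risk for any
comparison against that software's output.

ln P(D) per run is the usual harmonic-style approximation mean(lnL) −
var(lnL)/2 with sample variance.  Evanno's ΔK = |L″(K)|/sd(K), with sd
over runs, is defined only at interior K with sd > 0; the optimal K is the
argmax, ties toward smaller K, and a flat profile (all ΔK = 0) is reported
as inconclusive rather than forcing a winner.

Default chain settings are desk-scale — burn-in 5,000 and 20,000 sweeps —
while the field-standard protocol (burn-in 50,000, 10⁶ sweeps, 10 runs per
K) remains available through `MCMCConfig`.  The verification suite runs
K = 1…4 with 4 runs each at burn-in 2,000/10,000 sweeps on two divergent
simulated populations of 20 plants × 20 loci, which selects K = 2 with
every individual's dominant q > 0.95.

Label switching across replicate runs is resolved by exhaustively
permuting columns (k ≤ 8 ⇒ ≤ 40,320 permutations) to minimise the L1
difference from the first run — the first run, being seeded, makes the
alignment deterministic; a greedy matcher is provided and agrees with the
exhaustive search on planted-permutation instances.  Membership tables
order individuals by population, then dominant-cluster fraction, then
identifier, so the ordering is invariant to input row order.

## File formats

Genepop: 3-digit alleles on write (SSR fragment sizes exceed two digits),
2- or 3-digit auto-detected on read, "000" missing, `Pop` separators.  The
format carries no population names, so the reader infers them from each
block's last individual label with trailing digits and separators stripped
— the only place population identity is inferred rather than explicit.
STRUCTURE: tab-separated with a locus header, one- or two-row layouts,
−9 missing; the population column holds the population label (integer
labels are what the upstream program itself expects; keeping the label
preserves round-trip identity).  All readers reject malformed input with
the offending line number; nothing is silently repaired.

## Problem sizes

The shipped verification suite and `scripts/acceptance.py` use synthetic
problem sizes chosen to exercise every code path while completing in
minutes on one CPU: 500 contours for the isoperimetric sweep, 120
lip generations for serration recovery, 2,000 replicates for exact-test
calibration, 200 seeds for the clonal regime, 1,000 bootstrap replicates
on 50 individuals, and the K = 1…4 × 4-run admixture scan above.  These
are the package's own reference conditions; larger runs are a matter of
configuration, not code.
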