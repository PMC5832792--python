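# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `hchc-clonality`. The package decides whether the two
histological components of a combined hepatocellular-cholangiocarcinoma
(H-ChC) — an HCC component and an iCCA component microdissected from one
tumor — descend from a single transformed clone, and quantifies the
intratumor heterogeneity between them, starting from per-sample somatic
variant calls, CNV segments, tumor purities and HBV integration sites.

## Sharing analysis

A mutation's identity is its sample-independent key `(chrom, pos, ref, alt)`
(chromosome names normalized by stripping any `chr` prefix; mitochondrial
records dropped; indels compared by their left-aligned representation as
given — inputs are assumed to come from one caller per study, so no
re-normalization is attempted; a position-window alternative would be needed
when mixing callers). A key is *present* in a component when it was called
there with at least `min_alt` supporting reads (default 3, guarding against
FFPE/sequencing-noise false sharing; an optional `min_vaf` floor is exposed
because published analyses rarely state whether caller presence alone
sufficed). Keys present in both components are *ubiquitous*, all others
*private*; the private fraction uses union semantics — each ubiquitous key
counts once in the denominator, matching a Venn-diagram reading. The
per-sample-averaging alternative (each component's private share averaged)
is deliberately not the default.

The effect filter defaults to the nonsynonymous SNV classes
{missense, nonsense, splice}; when an input table lacks an effect column,
all SNVs default to `missense` with a warning (functional annotation is out
of scope).

**CNV sharing.** A segment pair is *common* when chromosomes match, copy
number moves in the same direction (gain with gain, loss with loss), and
reciprocal overlap reaches 1.0 — identical intervals, attainable in
practice because window-based callers quantize breakpoints. A relaxed
reciprocal-overlap parameter is exposed for segmentations with jitter.
Matching is greedy 1-to-1 in coordinate order, each segment used at most
once.

**Integration sharing.** Sites match when on the same chromosome within
`tolerance_bp` (default 500 bp, reflecting breakpoint-assembly jitter; no
published tolerance exists for this comparison), greedy nearest-first.

## Independent-origin test

Under the null hypothesis that the two components are unrelated tumors,
their somatic point mutations are placed independently and uniformly over
an exome of L callable positions (default L = 3×10⁷ bp). The number of
shared keys is then hypergeometric and, for n ≪ L, Poisson with rate

    lambda = n_a · n_b / L .

The reported p-value is the upper tail P(X ≥ observed). With p below 10⁻⁶
the data support a monoclonal origin; an observed count at or below lambda
supports independence; anything else is inconclusive. For realistic counts
(tens of shared nonsynonymous mutations against lambda ~ 10⁻³) the p-value
is astronomically small, which formalizes the argument that unrelated
tumors essentially never share tens of identical point mutations. The test
is calibrated against a direct collision simulation (fixing one component's
positions, drawing the other's uniformly without replacement and counting
collisions; the per-draw count is sampled from its exact hypergeometric
law, which is the same simulation vectorized).

## Cancer cell fractions and joint clustering

The VAF of a mutation carried by a fraction φ of tumor cells at
multiplicity m, local tumor copy number c_t, in a sample of purity ρ is

    VAF = φ·ρ·m / (ρ·c_t + (1−ρ)·2) .

Multiplicity is estimated per observation as
`clamp(round(VAF·(ρ·c_t + (1−ρ)·2)/ρ), 1, c_t)`; point CCFs invert the
formula and are clipped to [0, 1.5] with values above 1 flagged rather than
truncated — they usually indicate a miscalled multiplicity or copy number
and are worth seeing.

Mutations are clustered jointly across the two components with a finite
binomial mixture: cluster k has CCF parameters (φ_a, φ_b), and the alt
count of mutation i in sample s is Binomial(depth_is, ξ_is(φ_ks)) with ξ
the forward VAF transform. Fitting is EM; the M-step maximizes each
cluster/component CCF on [0,1] by staged vectorized grid refinement with a
final parabolic step (the weighted log-likelihood is concave in φ, so the
bracketed optimum is global; in-loop updates use a coarse two-stage grid,
and converged CCFs are re-polished at ~10⁻⁸ precision). K is selected from
1..k_max (default 8) by BIC with 3K−1 free parameters; initialization is a
seeded k-means++-style draw on the 2D CCF points, making the whole fit
deterministic given its seed. This is a desk-scale, deterministic stand-in
for Dirichlet-process samplers (PyClone): BIC pruning of K plays the role
of the DP's complexity control, and the binomial emission matches what the
synthetic generator produces, making parameter recovery a clean test.
Overdispersed (beta-binomial) emissions are a documented extension, not
implemented.

Mutations observed in only one component are force-included in the other
with alt = 0 at that component's median depth (multiplicity 1). Without
this, clusters on a component's axis — the signature of private clonal
mutations in 2D CCF plots — would be unobservable, because absence is
itself the informative observation. Indels are excluded from clustering;
their read support is not comparable under the binomial read model.

With fewer than 5 usable mutations the clustering refuses to run and
advises pooled analysis.

**Cluster geometry and verdict.** A cluster is *off-axis* when both CCFs
exceed τ (default 0.1), on an axis when exactly one does, and at the origin
otherwise (strict inequality at the boundary). The patient verdict is

* **monoclonal** — an off-axis cluster with ≥ `min_cluster` members
  (default 10) *and* origin-test p < 10⁻⁶;
* **independent** — the origin test supports independence *and* no
  off-axis cluster reaches `min_cluster` members (a smaller off-axis
  cluster is treated as noise; requiring literally zero off-axis clusters
  would let a single stray mutation veto the verdict);
* **ambiguous** otherwise.

All three thresholds are configuration, echoed into every report; no
numeric decision rule exists in the literature for this combination of
evidence, so the defaults are explicit package choices.

## Mutation spectra and signatures

Spectra use the standard pyrimidine-normalized channels: 6 substitution
classes or 96 = 6 × 16 trinucleotide contexts, ordered substitution class
first (C>A, C>G, C>T, T>A, T>C, T>G), then 5' base, then 3' base, each in
A,C,G,T order, labelled `A[C>A]A`-style. Purine-reference SNVs are
reverse-complemented (ref, alt and context) before binning. Channel order
in catalog files is validated by label, never assumed from position. SNVs
lacking a context, or flagged as mismatching the reference FASTA during
annotation, are excluded from spectra with a logged count.

De-novo extraction is non-negative matrix factorization with Frobenius
loss and multiplicative updates: best of `n_restarts` (default 50) seeded
random initializations, up to 2,000 iterations, relative-improvement
tolerance 10⁻⁸; a debug mode asserts the objective is non-increasing every
iteration. Signature columns are normalized to sum 1 with the scale
absorbed into the exposures. The default rank is k = 3 with an optional
scan over k ∈ [2,5] reporting reconstruction error. Extracted signatures
are matched to a reference catalog by cosine similarity with the
conventional 0.9 threshold: above it, same process; below it, a candidate
novel signature. KL-divergence NMF was evaluated as an alternative loss
and recovered planted signatures no better, so the simpler Frobenius
choice stands.

Components of one patient are kept as separate samples in the spectrum
matrix (not pooled): per-component signature exposures are themselves
evidence of shared ancestry.

The bundled catalog generator (`synthetic_signature_catalog`) is a
synthetic stand-in, not a published reference: three shaped processes
(CpG-focused C>T dominating the default mixture — giving simulated cohorts
the C:G>T:A-predominant spectrum typical of liver cancer — plus C>A-heavy
and T>C-heavy processes) and sparse Dirichlet draws for the remainder.
User-supplied catalogs in the documented CSV format are read and validated.

## Phylogenies

Each patient yields a two-leaf tree: trunk length = ubiquitous
nonsynonymous count, branch lengths = private counts, 1 mutation = 1 unit;
Newick output `((HCC:La,iCCA:Lb)MRCA:Lt)NORMAL;`. Driver genes from any
supplied catalog are annotated on the edge carrying their mutation,
deduplicated per edge, case-insensitively. A CCF-gated variant (a mutation
contributes to an edge only where its CCF exceeds 0.05) stands in for
copy-number-aware trees, for which no published algorithm is specified.
General n-region parsimony trees are a non-goal: the study design has
exactly two components per patient.

## Significantly mutated genes

The background mutation rate is total somatic SNVs / (callable_bp ×
n_samples), with the callable size defaulting to a 50 Mb whole-exome
capture. Gene g with coding length L_g is tested against
X ~ Binomial(L_g × n_samples, μ) by its upper tail, with
Benjamini–Hochberg correction across tested genes. This single-rate test
deliberately simplifies convolution-based SMG tests (no per-category rates
for transitions/transversions/CpG, no covariates); the simplification is
calibration-tested under the null (the flagged fraction at FDR 0.1 stays
within Monte-Carlo error of the nominal level) and its tail probabilities
are verified against an exact rational-arithmetic oracle. Consequences:
cohort-scale SMG counts from real studies are not comparable quantities
and are treated as documentation, not targets. Coding lengths come from a
two-column input table; no annotation database is bundled.

Driver and predisposition screens are case-insensitive symbol
intersections of mutated (respectively germline-mutated) gene lists with
user-supplied catalogs.

## The synthetic tumor-pair generator

The generator produces patient pairs with known truth under two origin
modes. Monoclonal: a trunk of mutations at CCF (1,1), private clonal
branches at CCF 1 on one axis, and optional subclones at CCF ~ U(0.2,
0.6). Independent: no trunk; each component accumulates its own mutations,
and any shared key is a positional coincidence (expected count
n_a·n_b/L). Positions are drawn uniformly without replacement from an
exome coordinate space (default 3×10⁷ bp over 22 equal pseudo-chromosomes);
channel identities are drawn from a signature mixture and reverse-mapped to
(ref, alt, context) directly in pyrimidine-normalized space (a tiny random
FASTA writer exists solely for I/O tests, so no genome ships with the
package). Read counts follow depth ~ Poisson(mean_depth), alt ~
Binomial(depth, VAF) with VAF from the CCF transform above using the local
simulated copy-number state — the same likelihood the clustering stage
inverts, by design, so parameter recovery is a clean test of the inference
rather than of model mismatch. No overdispersion, sequencing error, FFPE
artifacts or segmentation noise are simulated; passing recovery tests
therefore demonstrates correctness of the inference machinery under its
own model, not robustness to real-data artifacts.

A variant row is emitted for a sample only when the sampled alt count is
at least 1 — a caller reports nothing without supporting reads — and
downstream absence-modelling (forced alt = 0 observations) handles the
partner component, mirroring how real paired calls behave.

Default architecture (one simulated patient): trunk 70, branches 45/45
(union 160 nonsynonymous+silent mutations, private fraction 0.56), purity
0.7 per component, mean depth 150×, silent fraction 0.3, 5 shared +30
private CNV segments per component (shared segments breakpoint-identical
by construction, so the strict overlap rule recovers them exactly),
integration sites shared with probability 0.15 plus one private site per
component. These sit in the middle of the ranges reported for real
two-component liver-tumor exomes (per-patient private fractions ~33–86%,
ubiquitous counts 29–108, depth ~93–216×, CNV sharing a small minority,
HBV integration shared in a minority of patients). CNV-prone regions and
shared germline background are not modelled; the independence argument
rests on somatic point-mutation coincidence.

`simulate_cohort` derives per-patient seeds deterministically from one
master seed; identical configs and seeds give byte-identical outputs.

**Benchmark exposure design.** For signature-recovery benchmarks,
per-patient exposures over the three generating signatures are sparse
Dirichlet(0.5) draws, redrawn until every signature is dominant (≥ 0.8) in
at least one patient. NMF is only identifiable up to a cone rotation:
with no near-pure sample, even the noise-free mixture matrix cannot be
recovered at cosine ≈ 1, and a signature drawing near-zero exposure in
every patient is unrecoverable by any method. The constraint encodes the
premise — standard in signature benchmarking — that every reported process
is clearly active somewhere in the cohort.

## Benchmarks and problem sizes

The `benchmarks` module (also driven by `scripts/acceptance.py`) measures,
at these sizes: sharing exactness on 5 noise-free patients (depth 10⁴,
purity 1); origin-test calibration against 10⁵ collision draws at
λ ∈ {0.1, 1, 5}; verdict accuracy on 100 mixed-origin patients (50
monoclonal with trunks drawn from 29–108, 50 independent); signature
recovery over 20 cohort seeds (7 patients, 14 samples, ≥300 SNVs each);
CCF recovery over 50 seeds of planted (1,1)/(1,0)/(0,1) clusters with 30
mutations each at depth 100; the K=1 analytic limit on 50 mutations; SMG
null calibration over 200 genes × 50 seeds; and write/read round-trips.
These sizes keep a full run in the minutes range on one core while leaving
the Monte-Carlo error well below each decision margin.

## Numerical notes and degenerate inputs

* EM tolerance 10⁻⁸ (relative log-likelihood change), ≤200 iterations;
  binomial success probabilities clipped to [10⁻⁹, 1−10⁻⁹].
* Clusters that lose essentially all responsibility mass are left in
  place; BIC prefers the smaller K on refit, and empty clusters are
  dropped from the output.
* A component with zero usable SNVs yields a missing (not erroneous)
  spectrum cosine; an all-zero sharing partition yields a degenerate star
  tree with a warning; an empty variant table is an empty collection, not
  an error.
* Ties in greedy integration matching resolve by distance then input
  order; CNV matching scans coordinate order.
* VCF records lacking FORMAT/AD (or INFO/AD) raise — depths are never
  silently zero-filled. Multi-allelic records split into one variant per
  alt allele.

## Known limitations

* Two components per patient, by design; no multi-region (>2) clustering
  or tree search.
* Binomial (not beta-binomial) read model; no overdispersion.
* Single-rate SMG background; cohort-scale SMG counts are not comparable
  with convolution-based tests.
* Indels: exact-key matching only; excluded from spectra and CCF
  clustering.
* Purity is an input contract (upstream estimates); it is not estimated
  here, and defaults in simulations are package choices, not literature
  assertions.
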