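# Methods

This note documents the models, algorithms and numerical choices behind
`mycometer`, what the synthetic-data generators do and do not emulate, and
the known limitations.

## 1. Why copy number matters

The fungal rDNA locus is a tandem array: LSU rRNA gene / ITS spacer / SSU
rRNA gene, repeated tens to hundreds of times per genome with an intergenic
spacer between repeats. Amplicon sequencing of the ITS therefore yields
read counts proportional to *abundance × copy number*; because copy number
varies widely between (and within) species, amplicon profiles are
systematically distorted at species level. Single-copy marker genes give
exactly one locus per genome-equivalent, so shotgun reads scored against
them estimate abundance directly. The package provides two independent
copy-number estimators and a benchmark that quantifies the distortion.

## 2. CN-HMM: copy number from assemblies

**Profile HMMs.** Each ITS flank (588 bp on the LSU side, 142 bp on the SSU
side) is modelled by a Plan7-style profile built from a multiple alignment:
match columns are alignment columns with < 50% gaps; match emissions are
Laplace-smoothed base counts, (count + 1)/(total + 4); transitions among
match/insert/delete get the same +1 pseudocount over their outgoing
options; the background is uniform. Local alignment uses free entry into
any match state (uniform begin, log₂(1/M)) and free exit from any match
state — chosen over glocal alignment because flanks are frequently
truncated at contig ends in collapsed assemblies. Scores are log₂-odds
against the background, so insert states (background emissions) score 0 and
unaligned sequence needs no explicit state. The Viterbi recursion is exact
and is verified in the tests against exhaustive enumeration of all
alignments on short sequences.

**Acceleration.** A full dynamic program over megabase assemblies is
wasteful; as in production profile-search tools, a seeding stage restricts
it: exact 16-mers of the profile consensus anchor candidate alignment
starts, and the DP runs only inside windows of the profile length (±30 bp
indel slack) around the anchors. At the divergences rDNA flanks show (a few
percent), a true flank contains hundreds of exact consensus words, while a
random 16-mer hit occurs a handful of times per 100 kb; the prefilter
therefore loses essentially no recall and can only reduce false positives.
`scan_sequence(..., prefilter=False)` forces the full DP.

**E-values.** Hit significance follows the Gumbel law E(S) = K·L·2^(−S)
with the decay rate fixed at λ = ln 2 (the asymptotic value for log₂-odds
scores). K is fitted once per profile by scanning a decoy sequence
resampled from a first-order Markov chain of the input (preserving expected
dinucleotide composition) and anchoring the tail at the 20th-best
non-overlapping decoy score. Only the ≤ 0.001 filter semantics are
contractual; bit-exact agreement with any external search tool is a
non-goal. On random 100 kb sequences the filter admits ~e_max false hits
per scan, which the tests check.

**Pairing.** Hits are paired greedily in reading order along each strand:
an LSU hit takes the nearest downstream same-strand SSU hit whose
inner-edge gap — the ITS length — lies in [400, 800] bp (fungal ITS
lengths average ~550 bp); equidistant ties go to the higher bit score, and
each hit is used once. The gap is measured between the inner edges of the
two flank hits because that gap *is* the ITS, consistent with the 400–800
acceptance band and the 550 bp average. An unpaired hit still counts as
one copy iff the window where its partner would sit extends past the
contig boundary (within `end_window` = 800 bp of the appropriate end) —
assemblies often break inside the array, and dropping those copies would
bias counts low. LSU/SSU hits whose intervals overlap are discarded
pairwise with a warning. At zero flank divergence recovered hit intervals
equal the planted intervals exactly; at a few percent divergence the free
local exit shaves terminal mismatches off a flank, shifting the inner edge
by a base or two — far inside the 400 bp of slack in the pairing window.

## 3. CN-MD: copy number from reads

Reads are mapped to the ITS sequence and the single-copy marker genes
jointly; records with MAPQ < 30 are excluded; per-base depth is summed over
aligned reference spans. Per-gene depth is the mean over positions
[50, L−50) — the first and last 50 bp are trimmed because fewer reads fit
near gene ends. "Normalized by gene length" is interpreted as exactly this
per-base mean (total covered bases / usable length): dividing the mean by
the length a second time would leave the ITS/marker ratio with units of
1/length and break the copy-number interpretation. The estimator is
CN-MD = ITS depth / **median** marker depth; the median protects against
individual markers with outlying coverage (repeats, contamination), which
the tests exercise directly.

**Internal aligner.** Exact-seed (first 20 bp) lookup against the forward
strand of the references, queried with the read and its reverse complement,
followed by full-length ungapped comparison; fewest mismatches wins, a
unique best location gets MAPQ 42, ties MAPQ 0, and reads overhanging a
reference end are unmapped (CIGAR is restricted to a full-length match; SAM
from external mappers is ingested with soft clips honoured as reference
span). Because overhanging reads are lost, coverage ramps down over the
last ~read-length bases of each gene; the 50 bp end trim removes most of
that, and the default read length of 100 bp keeps the residual depletion
nearly identical between the 550 bp ITS and ~1 kb markers, so the ratio
stays within a few percent of truth. With 150 bp reads the ramp extends
past the trim and CN-MD biases several percent low — hence 100 bp as the
default simulated read length.

## 4. Mock-community benchmark

`mockbench` builds communities of 10–14 small synthetic genomes (9.6 kb,
four 800 bp markers, one physical ITS locus) with Dirichlet(1.5) abundances
and nominal ITS copy numbers drawn uniformly from 11–137 (the range the two
estimators target). Shotgun mode simulates reads from whole genomes and
profiles them against the marker genes; amplicon mode draws reads from the
ITS sequences with sampling weight abundance × CN — the amplification bias
itself. Both profiles pass the same pipeline: per-gene trimmed-mean depth,
the depth ≥ 15 filter (hits below it are likely off-target), per-hit
abundance = depth / Σ depths, aggregation at the requested rank, and
pooling of unexpected taxa into an off-target mass. Accuracy is the
weighted UniFrac distance to the known composition over a rank-lineage
tree (root → kingdom → genus → species, unit branch lengths; the pooled
off-target mass hangs as an extra leaf under the root so normalization is
preserved without inventing a lineage). The tree choice is shared between
the two methods, so the ITS-vs-shotgun contrast is insensitive to it. At
species level the amplicon profile tracks abundance × CN and lands far from
the truth; at genus level copy numbers partially average out within genera
and the gap shrinks — the benchmark asserts exactly this ordering.

## 5. Ecology statistics

**Weighted UniFrac** is computed as Σ_b l_b |A_b − B_b| over branches
(A_b, B_b = abundance fractions descending branch b), divided by
Σ_b l_b (A_b + B_b) in the normalized (default, [0, 1]-bounded) form; the
implementation is cross-checked against scikit-bio and against the L1/2
closed form on star trees.

**TMM** follows the canonical trimmed-mean-of-M-values recipe: reference
sample = the one whose upper quartile of counts/library-size is closest to
the mean upper quartile; per sample, log₂ ratios against the reference over
doubly positive genes are trimmed 30% on M and 5% on A and averaged with
inverse asymptotic-variance weights; factors are rescaled to geometric mean
1. The implementation reproduces edgeR's `calcNormFactors` to 7 digits on
random matrices (frozen as a test oracle).

**SparCC.** Fractions are the pseudocount point estimate (deterministic;
Dirichlet resampling behind a seed is optional), the variation matrix is
T_ij = var(log x_i/x_j), basis variances solve the sparsity-assumption
linear system, and up to 10 exclusion rounds remove the strongest remaining
pair above |ρ| = 0.1 and re-solve. Correlations are clipped to [−1, 1].
Calibration on independent log-normal bases (50 taxa × 200 samples) leaves
< 5% of pairs beyond |ρ| = 0.3; a planted basis correlation of 0.8 has its
sign recovered essentially always. Permutation p-values shuffle each taxon
independently and use the add-one estimator, so the attainable minimum is
1/(n_perm + 1) — with the default FDR cutoff of 0.001 this means edge-level
significance needs n_perm ≥ a few thousand, or the permutation count
chosen to match the intended FDR floor.

**Network deconvolution** scales the observed matrix so its largest
absolute eigenvalue is β = 0.99, maps every eigenvalue λ → λ/(1 + λ)
(inverting the geometric series that accumulates indirect paths), and
reassembles; the transform is exactly invertible (λ → λ/(1 − λ)), which the
tests verify to 1e−8. Note the map bounds direct eigenvalues below
β/(1+β) ≈ 0.5, so magnitude thresholds appropriate for raw correlations
(e.g. 0.78) are conservative on a deconvolved matrix; the RMT threshold can
be derived from the deconvolved matrix itself to stay on one scale.

**RMT threshold.** For each candidate cutoff on the 0.30–0.95 grid the
matrix is hard-thresholded, taxa left without any connection are dropped,
eigenvalues are unfolded with a degree-5 polynomial fit of the empirical
spectral CDF, and the nearest-neighbour spacings are tested against the
Poisson (exponential) form with a 20-bin chi-square at p > 0.05. The
returned threshold is the smallest that passes and keeps passing to the end
of the grid. When fewer than 25 eigenvalues (or 20 spacings) remain there
is no random-matrix bulk left to test and the candidate counts as passing;
pure-noise matrices therefore threshold at the low end of the grid, and
planted block structure pushes the threshold strictly above the noise
level without reaching the block correlation.

**Graph metrics.** Edges require |ρ| ≥ 0.78 *and* BH-FDR ≤ 0.001, with the
BH adjustment computed jointly over all unique pairs; both cutoffs are
boundary-tested bit-exactly (0.77 drops, 0.78 keeps; FDR 0.01 drops).
Betweenness is raw (unnormalized) shortest-path counting and closeness is
(n − 1)/Σ distances within the component — both match exhaustive
enumeration on 100 random ≤ 8-node graphs. Keystones are the intersection
of the top-20 lists by degree and by betweenness, ties at rank 20
included, deterministic ordering by (betweenness, degree, label). Degree
distributions are fitted by the discrete zeta-likelihood MLE at fixed
xmin with a KS goodness-of-fit statistic; a constant degree sequence is
flagged degenerate.

## 6. Diet statistics

Nutrients are energy-adjusted by the residual method: OLS of nutrient on
total energy, adjusted value = residual + grand mean, which removes the
caloric confound and is invariant to shifting energy by a constant;
constant energy degrades gracefully to the identity with a warning.
Reproducibility of repeated questionnaires uses ICC(2,1) — two-way random
effects, absolute agreement, single measure, from the standard
mean-squares decomposition (a consistency ICC(3,1) switch exists; values
match pingouin to machine precision) — and the paired Wilcoxon signed-rank
test, computed exactly (dynamic programming over the 2ⁿ sign assignments,
midranks for ties, doubled ranks to stay integer) for n ≤ 25 and by the
tie-corrected normal approximation with continuity correction above.
Associations between diet variables and microbiome features are Spearman
correlations with midrank ties, BH-adjusted over the whole screen,
significant at FDR < 0.05; constant columns are excluded with a warning,
and a partial-correlation mode (OLS residualization on user-supplied
covariates before ranking) is available but off by default because the
covariate set is study-specific. Longitudinal dynamics label all pairwise
Bray–Curtis dissimilarities intra- or inter-individual, compare them by
rank-sum, track per-subject trajectories against the first timepoint as
baseline, and compare two communities' dynamics by paired Wilcoxon on
matched (subject, timepoint) trajectories.

## 7. Synthetic data: what it does and does not emulate

The generators are deterministic per seed and byte-stable. Genomes plant
tandem arrays (LSU/ITS/SSU repeated, 2 kb spacers) with per-copy flank
substitutions at a controlled divergence and an identical ITS across copies
(it is one locus repeated); coordinates are 0-based half-open everywhere,
and truth (loci, flags, marker positions) is exact as long as the default
substitutions-only mutation model is used (an optional indel rate exists
but shifts coordinates). Reads are single-end with uniform starts, uniform
strand, i.i.d. substitutions and constant quality strings: paired ends,
position-dependent error profiles, PCR chimeras and GC bias are
deliberately out of scope, so passing tests demonstrate the estimators'
arithmetic and filtering logic, not robustness to platform-specific
artefacts. Compositional counts are multinomial draws at fixed depth from
log-normal bases with a requested correlation structure — the regime
SparCC assumes; real data add zero inflation and overdispersion beyond
this. Diet tables give each subject a stable baseline with multiplicative
noise and energy coupled to the macronutrients by construction; nutrient
values are plausible magnitudes, not a nutrient database.

Default study-scale conditions: flanks 588/142 bp, ITS 550 bp, spacer
2 kb, copy numbers 1–170, 30× marker coverage (read length 100 bp, 0.5%
substitution error), mock communities of 10–14 species × 50k reads per
mode, compositional matrices of 50 taxa × 200 samples, diet tables of 6
subjects × 2 administrations. These sizes keep the full validation run in
minutes on one CPU while leaving every estimator's operating range
(including the 150–170 copy extreme) covered.

## 8. Known limitations

- CN-HMM counts loci in the *assembly*; on collapsed assemblies this is a
  property of the input, not the algorithm, and no attempt is made to
  detect collapse.
- E-value calibration is empirical per profile; cross-tool bit
  compatibility is out of scope.
- The internal aligner is ungapped and single-end by design; indel-rich
  data need an external mapper (ingested via SAM).
- SparCC exclusion operates pairwise; dense strong correlation structure
  (many correlated cliques) violates the sparsity assumption in ways no
  exclusion schedule fully repairs.
- The RMT spacing test is data-starved below ~40 connected taxa and then
  intentionally permissive.
- Deconvolved correlation magnitudes live on a compressed scale (≈ ≤ 0.5);
  thresholds should be derived on the same scale (see §5).
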