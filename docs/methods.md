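# Methods

This note documents the models, algorithms and design choices behind
`crossqtl`, in the spirit of the methods documentation of packages like
msprime or statsmodels: what is computed, under what assumptions, with
which defaults, and what the synthetic data do and do not establish.

## The cross and its synthetic stand-in

The package targets three-generation F2 intercrosses between two divergent
but outbred founder lines — concretely, the slow-growing Huiyang Beard (HB,
"line B") x fast-growing commercial HQLA ("line A") broiler cross: 4 cocks
and 12 hens per line as F0, reciprocal matings (A x B and B x A), 56
selected F1 parents (8 cocks each mated to 6 hens of the opposite cross
type), ~48 full-sib F2 families, 800 F2 birds hatched in 6 batches, of
which ~500 have phenotype records. `CrossDesign` defaults encode exactly
these counts; studies scale only `n_f2`.

`simulate_cross` tracks real haplotypes through the pedigree. F0 birds are
unrelated within line (the real F0 are sibs; relatedness does not enter
any estimator tested here and independence keeps allele-frequency
estimation clean) with two pure-line haplotypes drawn from per-marker line
allele frequencies. `FounderModel.random` makes a configurable fraction of
markers fully diagnostic (frequency 1 vs 0; default 0.3) and draws the
rest from U(0.55, 1) vs U(0, 0.45) — outbred lines genotyped on a chip are
only partially informative per marker. Meiosis follows the Haldane model:
no interference, so gamete origin along a chromosome is a two-state Markov
chain whose switching probability per interval is the Haldane fraction
r = (1 − e^(−2d))/2 of the cM gap. This choice is forced by coherence: the
downstream line-origin model is first-order Markov, which is exact under
Haldane and approximate under any interference model. True line origins of
every F2 gamete are recorded on the union of marker and grid positions and
carried on the returned object — the ground truth for recovery tests.

`simulate_phenotypes` builds each trait as mean + sex effect + batch
offsets + covariate terms + Σ(a·A* + d·D*) + Σ interaction terms +
N(0, σ) noise, where A*/D* are the indicators implied by the *true*
origin (A* ∈ {1, 0, −1}, D* ∈ {0, 1}). Useful variance identities: under
Mendelian segregation Var(A*) = 1/2 and Var(A*₁A*₂) = 1/4 for unlinked
loci, so an additive QTL explaining share s of phenotypic variance needs
a = sqrt(2s/(1−s))·σ, and an additive-by-additive pair needs
i₁ = sqrt(4s/(1−s))·σ. Missing genotype calls are injected at rate 0.02
by default (to exercise QC); phenotype attrition (the real cross
phenotyped ~493 of 800) is modelled as simple random dropout because the
true attrition mechanism is unrecorded. Feed intake for FCR traits is
generated as gain x (true FCR + noise), since intake recording granularity
for the real birds is unknown.

What the generator does **not** emulate: selection of F1 parents on body
weight, hatch-batch environmental autocorrelation, sex chromosomes,
genotyping error beyond missingness (a per-call error rate is available in
the origin model but defaults to 0), and linkage disequilibrium within
founder lines. Passing recovery tests therefore demonstrates correctness
of the estimators under the stated genetic model, not robustness to every
artefact of real chip data.

## Quality control

Filters and their keep-rules (all strict inequalities): individual call
rate > 0.9; marker call frequency > 0.9; minor allele frequency > 0.05;
inheritance-error rate < 0.05 for both individuals and markers.
Inheritance errors are parent–offspring genotype incompatibilities at a
biallelic locus (trio table when both parents are called, duo rule when
one is); the denominator is the number of non-missing parent–offspring
comparisons, not the marker count. Individuals are filtered before
markers in a single pass each — individual-level failures distort marker
statistics more than the reverse — and marker statistics (call frequency,
MAF, error rate) are recomputed on the retained individuals. MAF is
computed among F2 only by default: the founder lines are divergent by
design, so pooled MAF would mislead. Each exclusion carries one primary
reason (first failing criterion in the documented order) and the report
also counts overlapping failures per criterion, so counts under this
filter order are auditable rather than forced to match any external tally.
QC is idempotent on realistic data; exact idempotence is not a theorem for
threshold filters (a second pass recomputes individual call rates over the
retained markers), which is why the property is tested on simulator output.

## Line-origin probabilities

The multipoint model is the standard line-cross hidden-process model, used
here as a stand-in for the original cross's triM computation (whose
internals are not documented; no claim of bit-equivalence is made). Hidden
state = (maternal gamete origin, paternal gamete origin) ∈ {A, B}²; prior
at each chromosome start is (¼, ¼, ¼, ¼); per-gamete transitions are
independent with Haldane switching fractions; emissions are
P(observed dosage | state) under line allele frequencies, with missing
calls emitting 1. Line frequencies are estimated from the genotyped F0 of
each line with a pseudocount of 0.5 per allele (a marker unscored in a
line falls back to the uninformative 0.5, with a warning). An optional
symmetric per-call miscall rate ε (default 0) can be mixed into the
emissions. Posteriors at grid positions (1 cM for 1D scans, 5 cM for 2D)
come from pseudo-loci with unit emission inserted into a scaled
forward–backward pass, vectorised across individuals; co-located markers
multiply their emissions. The grid is anchored at each group's first
marker and always includes the last marker. Orientation (which gamete is
"first") never affects results because A and D are symmetric in AB/BA;
forward–backward output is checked against exhaustive enumeration over all
gamete-origin configurations to 1e−10 on small chromosomes.

## Phenotype preparation

Outliers follow the boxplot rule: flag values beyond 1.5 IQR from the
quartiles, with quartiles by linear interpolation of order statistics (a
convention choice — Tukey hinges would shift the fences slightly; the
whisker multiple and quartile method are fixed but the multiple is a
parameter). A flag is retained rather than excluded when (a) the same
individual is flagged at ≥2 consecutive ages of a longitudinal family, or
(b) ≥K individuals (default 5) are flagged on the same side at the same
age; these two rules operationalise the qualitative practice of keeping
"clustered" or "consistent" extremes. GR windows are 0–4, 4–8, 8–12 weeks
(weight gain); FCR windows are 6–8, 8–10, 10–12 weeks (intake/gain, set
missing on non-positive gain). Trait correlations are pairwise-complete
Pearson with p-values from the t transform. The non-genetic null model per
trait is selected by backward elimination with partial F-tests at
α = 0.05 over candidate factors {sex, batch, family} and covariates;
aliased terms drop out through the rank check. Family is treated as a
candidate like any other (the real analysis's per-trait choices are not
recoverable).

## Genome scans

All fits are ordinary least squares. The 1D scan is vectorised exactly via
Frisch–Waugh: the base design (null-model columns + any cofactor A/D
pairs) is orthonormalised once by QR and projected out of y, A and D; the
per-position 2x2 normal equations then give a, d, their SEs and
F = ((RSS_red − RSS_full)/2)/(RSS_full/df) in a handful of matrix
products. A reference single-position implementation (`fit_position`,
plain lstsq) exists alongside and the two are cross-checked against an
explicit normal-equations oracle in the tests. Degenerate fits
(RSS_full ≈ 0) are reported as an explicit degenerate flag with infinite
F, never as a spurious finite number; positions where A and D are
numerically collinear fall back to zero explained variance. Ties in the
peak are broken by grid order (first group, then smallest cM). The peak
marker is the map marker nearest the peak in cM.

Forward selection freezes the top significant peak's A/D as cofactors and
rescans until no peak clears the 5% genome-wide threshold; thresholds are
computed once per trait from the first-round permutations and reused
across rounds (recomputing per round is cost-prohibitive and changes
little under the null). Calls are classified 1%-level where exceeded, and
named `<cross tag> <chromosome><letter>` with letters increasing along
the chromosome. Two peaks on one chromosome can be re-tested jointly
(`test_linked_pair`): both A/D pairs in one model, each QTL's partial F
from dropping its own pair, "independent" iff both clear the threshold; a
collinearity guard rejects positions closer than one grid step.

The 2D scan fits models (3)/(4) for every admissible pair (distinct
positions; same-chromosome pairs ≥ 2 grid steps apart — conservative
plumbing, the interesting pairs are inter-chromosomal), with interaction
columns formed as raw indicator products and then projected against the
base design. Significant pairs clear the 2D permutation threshold (maxima
taken over the same 5 cM pair grid as the real scan, matching its
multiplicity); pairs with F > 8 are reported separately as suggestive.
Adjacent significant grid pairs within 20 cM on both axes merge into one
pair region — an epistatic pair is a property of two QTL-peak regions, not
of two single grid points. Per-term t statistics from the full model
identify the dominant interaction component. The two-locus
genotype–phenotype map pools AB/BA (summing before thresholding, matching
D's definition), assigns a discrete genotype only where the pooled
posterior strictly exceeds 0.8, drops birds without confident calls at
both loci, and averages model-(1) residuals per 3x3 cell; a 4x4
orientation-resolved variant is available behind `pooled=False`.

Var% = (MS′_R − MS_F)/MS_R x 100 throughout, with MS′_R from the reduced
model including other QTL as cofactors (model (3) for pairs), MS_F from
the full model, and MS_R from the plain null model. The estimator is
mildly biased upward at these sample sizes; the recovery study bounds the
bias empirically (mean estimate within ~1 point of a 15% truth at
n = 500).

## Permutation machinery

Genome-wide thresholds shuffle the *residuals* of the null model among
individuals while indicators stay fixed — permuting residuals rather than
raw phenotypes preserves the fixed-effect structure under the null. The
threshold is the empirical (1 − α) quantile of the per-permutation maxima;
1000 permutations by default, with 200 used in the calibration study
(adequate for a 5% quantile). Everything is deterministic given the seed.

The region-overlap permutation re-places the observed regions at random:
per replicate, sizes are drawn without replacement from the observed size
vector; each region's chromosome is drawn uniformly with replacement from
the supplied set, re-drawn when the sizes already placed there plus the
new one exceed the chromosome (and also when no non-overlapping start can
be found — feasibility of the start is not implied by the size check);
starts are uniform over valid bases with overlap/boundary rejection. A
region scores when it shares ≥1 base with ≥1 gene (closed 1-based
intervals; genes straddling region edges count). Both the upper-tail
probability P(count ≥ observed) and the exact-count P(count = observed)
are reported, since published summaries are sometimes read off a
histogram and the intended tail can be ambiguous. Converters to and from
0-based half-open BED are provided.

## Problem sizes and numerical choices

Simulation studies run on a 5-chromosome x 100 cM map with markers every
2 cM and n = 500 F2 — sizes chosen so each study finishes in minutes on a
single core while keeping Monte-Carlo error small relative to the
properties checked. Note the real chip is ~25x denser (≈13 markers/cM),
so real-data line-origin posteriors are sharper than the study's; the
epistasis power measured here (~0.7–0.85 for a pure additive-by-additive
pair at a 6% variance share against its genome-wide threshold) is
accordingly a lower bound on the dense-chip setting, and is the main
quantity that fluctuates between cross realizations.

Numerical details: forward–backward is scaled per locus; state quadruples
are renormalised and validated to sum to 1 within 1e−9. The scan's 2x2
solve guards against collinear indicators via a relative determinant
threshold (1e−12). Degenerate fits are flagged at RSS_full ≤ 1e−10 x
RSS_red. Map-summary rates are rounded half-up to one decimal and left
undefined below a 3 Mb physical-size floor (tiny groups give unstable
cM/Mb ratios). Seeds derived from a user seed use `numpy.random.
SeedSequence` spawning, reduced mod 2^31.

## Known limitations

No sex-chromosome handling; no interval estimates of QTL location; no
three-way interactions; regression (Haley–Knott) mapping only, not
maximum-likelihood interval mapping; no genotype phasing or imputation;
no gene-set retrieval (region and gene coordinates are inputs). The
bundled reference tables cover the cross's published linkage-map summary,
trait descriptive statistics, significant epistatic pairs and candidate
genes; the full genotype matrix and the complete 204-gene pathway list
are not redistributed, so enrichment analyses of the real regions use
synthetic stand-in region sets (labelled as such) for demonstration.
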