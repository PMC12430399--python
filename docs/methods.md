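# Methods

This note documents the models, conventions and numerical choices behind
`germid`, in the order the pipeline runs them.

## Synthetic panel generator (`simdata`)

The generator emulates a germplasm collection drawn from a few diverged
source populations plus admixed individuals — the situation of a two-species
tree collection with hybrids.

**Population model.** Each locus has an ancestral allele frequency p drawn
uniformly from `maf_range` (default 0.05–0.5, deliberately straddling the
MAF > 0.05 retention cutoff). Population k's frequency is Balding–Nichols:
Beta(p(1−F)/F, (1−p)(1−F)/F) with drift parameter F = `divergence`
(default 0.1, a typical between-population Fst for diverged conspecific
stands; F = 0 collapses all populations onto p). This is the minimal model
that produces K-group structure recoverable by PCA/clustering.

**Ancestry and genotypes.** Unadmixed samples are one-hot on one population;
a fraction `admixed_fraction` (default 0.3) draws ancestry from a symmetric
Dirichlet(1). Each of a genotype's two alleles picks a population from the
sample's ancestry vector, then Bernoulli(freq); heterozygosity therefore
rises with admixture, the qualitative signature of hybrid accessions.

**Missingness and QC annotations.** Missingness is uniform at
`missing_rate` (default 0.005 — representative of high-coverage resequencing
after genotype calling, and deliberately near the pipeline's 1 %
post-masking cutoff so the filter has work to do; it is not depth-linked).
`simulate_annotations` draws all six caller metrics comfortably inside their
passing regions and pushes exactly `round(fail_fraction × n_loci)` planted
sites past one threshold each; 0.2 % of genotypes get GQ < 30 so the masking
stage is exercised. `simulate_phenotypes` builds the quantitative trait as
Σ effect × dosage over planted causal loci plus Gaussian noise scaled on the
*realised* genetic variance to hit the requested heritability (default 0.3,
a mid-range value for tree growth traits; nothing in the motivating study
pins real effect sizes, so these are stated defaults, not inferences).
Categorical traits are coded 1..k with stated class frequencies.

All randomness flows from one explicit `numpy.random.Generator` seed; a
fixed seed gives bit-identical panels.

**What the generator does not emulate:** linkage (loci are exchangeable given
ancestry, so LD beyond structure-induced correlation is absent),
depth-dependent missingness, genotyping error, and clonal duplicates.
Passing tests therefore demonstrate correctness of the computations under a
clean population-genetic model, not robustness to every artefact of real
resequencing data.

## VCF I/O and substitution spectrum (`variant_io`)

Coordinates are 1-based as in VCF; locus ids are rendered `chrom_pos` with
any `chr` prefix stripped (e.g. `10_31605746`). Phased separators are
accepted and treated as unphased — the pipeline is dosage-only. Multiallelic
records are read and flagged, never split; the biallelic screen removes
them. Missing INFO/FORMAT metrics become NaN ("not evaluable"). Ts/Tv
classifies A↔G and C↔T as transitions; the ratio is undefined (NaN, not an
exception) when no transversions exist. Parsing is delegated to `cyvcf2`;
writing emits minimal VCFv4.2 with GT:GQ:DP and the six filter metrics in
INFO, and round-trips exactly.

## Filter cascade (`snp_filter`)

Five ordered stages (hard filter → marginal screens → GQ masking →
post-masking missingness → depth window). Decisions that were genuinely
open:

- **Boundary semantics** follow the printed inequality symbols strictly:
  QD = 2.0 passes (rule is `< 2.0`), MAF = 0.05 fails (rule is `> 0.05`).
- **Order of the two missingness rules**: the < 20 % screen runs before GQ
  masking, the > 1 % rule after, as two separate stages; the recipe lists
  them separately without fixing an order, and this ordering makes the
  second rule meaningful.
- **"Average depth"** is computed per site across samples (mean of
  non-missing DP), and the 3–100× window is applied as one rule; the
  "< 3× or outside 3–100×" phrasing is redundant.
- A missing caller metric skips its criterion (standard hard-filter
  semantics) rather than failing the site.
- MAF and Hardy–Weinberg use non-missing genotypes only.

**Exact Hardy–Weinberg test.** The conditional exact test: given allele
counts, P(n_het) ∝ n! 2^{n_het} / (n_AA! n_Aa! n_aa!); the two-sided p sums
all heterozygote counts whose conditional probability ≤ the observed one
(with a 1 + 10⁻¹² tolerance against ties lost to rounding). Computed in log
space via `lgamma`, normalised over the parity-consistent support, so it is
exact for any sample size. The test suite checks it against an independent
binomial-coefficient enumeration for every configuration with n ≤ 30.

## Diversity and trait statistics (`diversity`)

Conventions: Ne = 1/Σpᵢ²; Nei's per-locus gene diversity equals He (their
across-locus means coincide too); PIC uses the codominant-marker (Botstein)
formula He − Σᵢ<ⱼ 2pᵢ²pⱼ² — for a biallelic marker its maximum is 0.375 at
p = 0.5. Group reports use each group's own allele frequencies (species- or
cluster-level indices), skipping singleton groups with a warning. Trait SD
is population (divide-by-n) by default, `ddof` configurable; CV = SD/mean ×
100 % with CV ≡ 0 for constant traits and flagged-undefined when mean = 0
with positive SD. Shannon H′ uses natural logs throughout; continuous traits
are binned (equal width, default 10 bins) for H′ only. Trait PCA
standardises columns and drops constant traits with a log entry. Membership
scores rescale each trait to [0,1] (reversed for smaller-better traits) and
average with weights summing to 1.

## Structure, LD and ΔK (`popstruct`)

**PCA.** Missing dosages are mean-imputed per locus; columns are centred but
*not* scaled to unit variance (the conventional genotype-PCA default here;
scaling is a one-line change upstream if wanted). Component signs are fixed
by making each component's largest-magnitude loading positive, so outputs
are reproducible.

**UPGMA.** Implemented directly (O(n³), fine for panels of hundreds) so the
tie-break is explicit: among equal-distance candidate pairs the pair
containing the lowest original sample index merges first. Heights are half
the merge distance, giving an ultrametric Newick tree; the test suite
cross-checks merge heights against `scipy.cluster.hierarchy.linkage`.

**LD.** Composite (Rogers–Huff style) r²: the squared Pearson correlation of
dosage vectors over pairwise-complete samples — no phase needed. The scan
takes the chromosome with the most markers and its first `max_markers`
(default 1000) loci in position order ("top" read as genomic order, since no
other ranking is defined). Monomorphic-in-overlap pairs are skipped and
logged. Decay curves are per-bin means of r² against physical distance.

**Evanno ΔK.** Consumes an external Bayesian-clustering log-likelihood table
(K × replicates; the MCMC itself is out of scope): L′(K) = L(K) − L(K−1),
|L″(K)| = |L(K+1) − 2L(K) + L(K−1)|, ΔK = |L″(K)| / sd(L(K)) on interior K
with positive replicate spread; best K = argmax ΔK, undefined when all
curvature vanishes.

## GLM association scan (`gwas`)

Per SNP, OLS of the trait on intercept + additive dosage over complete cases
(no imputation inside the test); p from t with n − 2 df. No
population-structure covariates by default — the model is the plain
intercept + genotype regression — but a covariate hook exists. Monomorphic
SNPs report NaN p. Hits use raw-p tiers (p < 0.001, p < 0.0001, strict
inequalities); Benjamini–Hochberg q-values are optional output only. The
no-missing path is fully vectorised; both paths are tested against
`statsmodels` OLS and a permutation p-value.

## Core markers and fingerprints (`coreset`, `fingerprint`, `qr`)

A pair of samples is *resolved* by a locus only when both genotypes are
non-missing and differ — a missing call must never be what distinguishes two
accessions. "Most informative" at each greedy step means the largest count
of newly resolved pairs (set-cover gain); ties break by higher PIC, then
genomic position — which also explains why core-marker tables are
conventionally reported with PIC. A final backward pass removes any locus
whose deletion preserves full resolution, so the set is irredundant; greedy
does not guarantee the global minimum, and `brute_force_min_set` (guarded to
≤ 20 candidates, ≤ 12 samples) exists precisely to audit that on small
instances. Byte-identical samples end selection gracefully with an explicit
unresolved-group report.

Fingerprint codes concatenate genotype tokens in (chromosome, position)
order with a `|` separator — an unambiguous grammar chosen over any
punctuation-free rendering, which cannot be parsed back. QR payloads are a
canonical four-line text (version header, `id=`, `fp=`, `traits=` with
percent-escaped reserved characters), lossless and injective over record
content; trait *codes* rather than labels keep payloads within ~1 kB.

The QR codec is self-contained: byte mode, error-correction level M,
versions 1–25, Reed–Solomon over GF(256) (primitive polynomial 0x11D),
standard block interleaving, penalty-scored mask selection, BCH
format/version fields. Encoding is a pure function of the payload, so equal
payloads give pixel-identical images. The decoder targets the clean,
axis-aligned renders the encoder produces (grid resampling from the
finder-pattern run length) and performs full Reed–Solomon error correction
(Berlekamp–Massey/Chien/Forney) — it is a verification decoder, not a
general camera-image reader. Every exported image is decoded back and
byte-compared before the export is reported successful.

## Pipeline defaults and problem sizes

`PipelineConfig` defaults reproduce the documented thresholds verbatim (a
test audits this). The bundled study panel is 197 samples × 4204 loci; the
calibration analyses use 200 × 1000 (GLM null), 500 replicates (null LD),
150 samples × 300 loci (structure recovery) and 200 accessions × 34 traits
(QR integrity) — sizes chosen so each check is statistically meaningful
while the whole suite runs in well under a minute per stage. Structure
recovery is scored on unadmixed samples (admixed individuals sit between
clusters by construction, so "their true group" is only defined for
unadmixed ones); the UPGMA clade check builds the tree over the unadmixed
subset for the same reason.

## Known limitations

- The generator's exchangeable-loci design means LD decay on synthetic
  panels is flat at the null level; the decay machinery is validated on
  constructed block fixtures instead.
- Evanno ΔK requires an external clustering run; the package ships no MCMC.
- The QR decoder does not handle rotation, perspective or print noise.
- Greedy minimality is audited, not proven, beyond the brute-force guard.
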