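# germid

SNP-based evaluation and DNA fingerprinting of germplasm collections.

Living genetic-resource collections (germplasm banks) need two things from a
marker pipeline: an honest picture of the diversity they hold, and a cheap,
unambiguous way to tell accessions apart. `germid` implements both halves as
one tested pipeline over a diploid SNP panel — motivated by tree collections
such as *Liriodendron* (two parental species plus their hybrids), but generic
over any samples × loci dosage matrix:

1. **Quality filtering** — the standard hard-filter cascade on caller
   annotations (fail if QD < 2.0, MQ < 40.0, FS > 60.0, SOR > 3.0,
   MQRankSum < −12.5 or ReadPosRankSum < −8.0), then marginal site screens
   (missing rate < 20 %, MAF > 0.05, exact Hardy–Weinberg p ≥ 10⁻⁴, biallelic
   only), GQ < 30 genotype masking, a post-masking > 1 % missingness drop,
   and a 3–100× mean-depth window.
2. **Diversity indices** — per locus and per group: Na, Ne = 1/Σpᵢ², Ho,
   He = 1 − Σpᵢ², PIC (Botstein), Shannon H′ = −Σpᵢ ln pᵢ, Nei's gene
   diversity; plus trait statistics (CV = SD/mean × 100 %, Shannon H′ over
   trait classes), Pearson correlations, trait PCA and membership-function
   D-values.
3. **Population structure** — genotype PCA (centred dosages, SVD), Euclidean
   UPGMA dendrograms (Newick), composite (Rogers–Huff style) r² LD decay, and
   Evanno ΔK = mean|L″(K)| / sd(L(K)) post-processing of Bayesian-clustering
   log-likelihoods.
4. **Association** — per-SNP GLM, Y = Xβ + ε with X = [1, dosage], two-sided
   t-test p-values, raw-p significance tiers (p < 0.001, p < 0.0001),
   Manhattan/QQ data.
5. **Core markers and fingerprints** — greedy set-cover selection of the
   minimal marker subset whose concatenated genotypes ("0/0", "0/1", "1/1",
   "./.") distinguish every pair of accessions, with an exhaustive oracle for
   auditing minimality; per-accession fingerprint codes and a verified
   one-code-one-image QR export (self-contained QR model-2 codec, byte mode,
   error-correction level M).

A synthetic-panel generator (Balding–Nichols population model, three diverged
source populations plus Dirichlet-admixed individuals, planted QC failures
and causal loci) makes every stage testable end to end without any external
data.

## Worked example

The numbered scripts under `analysis/` run the whole study on the bundled
generator (197 accessions × 4204 loci, seed 1). From the repository root:

```bash
python analysis/01_simulate.py
python analysis/02_filter.py
python analysis/03_diversity.py
python analysis/04_structure_ld.py
python analysis/05_gwas.py
python analysis/06_coreset_fingerprint.py
```

prints, among other things:

```
4204 sites in -> 2233 retained; per stage removed: {'hard_filter': 210,
  'site_screens': 241, 'genotypes_masked_gq': 1611, 'post_mask_missing': 1520,
  'mean_depth': 0}
  group  n_samples    Na    Ne    Ho    He   PIC  H_prime   Nei
   pop1         57 1.985 1.582 0.342 0.339 0.271    0.508 0.339
admixed         59 2.000 1.627 0.361 0.364 0.291    0.542 0.364
genotype PCA: PC1 6.09%, PC2 4.86%
Evanno ΔK selects K = 3
3 hits at p < 1e-3 (1 at p < 1e-4)
top hit: 16_2070980 (p = 3.44e-20)
core set: 7 markers, PIC 0.3724-0.3750; 0 unresolved groups
pairwise resolution rate: 1.0000
QR map: 12 verified images under results/fingerprint/map
```

Reading this: the cascade removed exactly the 210 planted hard-filter
failures plus sites failing the marginal screens; the admixed group shows the
highest diversity on every index (hybrids carry both parental allele pools);
PCA and ΔK recover the three-population structure; the GLM scan pins the one
planted causal locus; and 7 high-PIC markers suffice to give all 197
accessions distinct fingerprint codes, each exported as a QR image that is
decoded back and byte-verified.

The same stages are available as a CLI (`germid simulate|filter|diversity|
structure|ld|gwas|core-select|fingerprint|run-all`) for use on a real VCF.

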