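"""Simulate the synthetic germplasm panel the downstream analyses consume.

Generates a three-population admixed panel (197 accessions, 4204 loci — the
size of the filtered marker set the pipeline is built around), plants
hard-filter failures in the QC annotations and a causal locus behind the
quantitative trait, and writes panel.vcf / meta.csv / traits.csv under
results/panel/.
"""

from pathlib import Path

from germid import simdata
from germid.variant_io import write_vcf

OUT = Path("results/panel")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = simdata.SimConfig(n_samples=197, n_loci=4204, seed=SEED)
    matrix, truth = simdata.simulate_panel(cfg)
    ann, planted = simdata.simulate_annotations(matrix, fail_fraction=0.05,
                                                seed=SEED + 1)
    traits, truth = simdata.simulate_phenotypes(
        matrix, truth, heritability=0.3, n_categorical=3, seed=SEED + 2
    )
    write_vcf(matrix, ann, OUT / "panel.vcf")
    matrix.samples.to_csv(OUT / "meta.csv", index=False)
    traits.to_csv(OUT / "traits.csv")
    print(f"panel: {matrix.n_samples} samples x {matrix.n_loci} loci, "
          f"{len(planted)} planted QC failures, "
          f"causal locus index {truth.causal_loci} -> {OUT}")


if __name__ == "__main__":
    main()
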