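"""Diversity indices per group and phenotypic-trait statistics.

Computes the seven per-locus indices (Na, Ne, Ho, He, PIC, H', Nei) averaged
within each ancestry group of the filtered panel, plus the trait summary
table (max/min/mean/SD/CV%/H'), the Pearson trait-correlation matrix, the
trait PCA and membership-function D-values.
"""

from pathlib import Path

import pandas as pd

from germid import diversity
from germid.variant_io import read_vcf

IN = Path("results/filtered")
TRAITS = Path("results/panel/traits.csv")
OUT = Path("results/diversity")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    meta = pd.read_csv(IN / "meta.csv")
    group_map = dict(zip(meta["accession_id"], meta["group"]))
    matrix, _ = read_vcf(IN / "filtered.vcf", group_map=group_map)

    div = diversity.group_diversity(matrix)
    div.to_csv(OUT / "group_diversity.csv", index=False)
    print("per-group diversity (means across loci):")
    print(div.round(3).to_string(index=False))

    traits = pd.read_csv(TRAITS, index_col=0)
    cont = {c for c in traits.columns if traits[c].dtype.kind == "f"}
    summary = diversity.trait_summary_table(traits, continuous_traits=cont)
    summary.to_csv(OUT / "trait_summary.csv", index=False)
    corr = diversity.trait_correlations(traits)
    corr.to_csv(OUT / "trait_correlations.csv")
    scores, loadings, explained = diversity.pheno_pca(traits)
    print(f"trait PCA: PC1+PC2 explain {explained[:2].sum():.2f}% of variance")
    d = diversity.membership_D(traits[[c for c in traits.columns]].select_dtypes("number"))
    d.to_csv(OUT / "membership_D.csv")
    print(f"membership D-values in [{d.min():.3f}, {d.max():.3f}]; "
          f"top accession: {d.idxmax()}")


if __name__ == "__main__":
    main()
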