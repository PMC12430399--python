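"""Single-marker GLM association scan of the quantitative trait.

Scans the filtered panel against the simulated quantitative trait, reports
hits below p = 1e-3 with their significance tier, and writes Manhattan/QQ
coordinate tables (plus PNG plots) under results/gwas/.
"""

from pathlib import Path

import pandas as pd

from germid import gwas
from germid.variant_io import read_vcf

IN = Path("results/filtered")
TRAITS = Path("results/panel/traits.csv")
OUT = Path("results/gwas")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    matrix, _ = read_vcf(IN / "filtered.vcf")
    traits = pd.read_csv(TRAITS, index_col=0)
    y = traits["quant_trait"].reindex(matrix.samples["accession_id"]).to_numpy()

    res = gwas.glm_scan(matrix, y)
    res.to_csv(OUT / "glm_scan.csv", index=False)
    hits = gwas.significant_hits(res, threshold=1e-3, trait_name="quant_trait")
    hits.to_csv(OUT / "hits.csv", index=False)
    print(f"{len(hits)} hits at p < 1e-3 "
          f"({(hits['tier'] == gwas.TIER_STRONG).sum()} at p < 1e-4)")
    if len(hits):
        top = hits.iloc[0]
        print(f"top hit: {top['snp_id']} (p = {top['p']:.3g})")

    qq = gwas.qq_data(res)
    qq.to_csv(OUT / "qq.csv", index=False)
    man = gwas.manhattan_data(res)
    man.to_csv(OUT / "manhattan.csv", index=False)
    _plot(man, qq)


def _plot(man: pd.DataFrame, qq: pd.DataFrame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 4))
    for parity, sub in man.groupby("parity"):
        ax1.scatter(sub["coord"], sub["neglog10p"], s=6,
                    c="tab:blue" if parity == 0 else "tab:orange")
    ax1.axhline(3.0, ls="--", c="red", lw=0.8)
    ax1.set_xlabel("genome coordinate")
    ax1.set_ylabel(r"$-\log_{10} p$")
    ax1.set_title("Manhattan")
    ax2.plot(qq["expected"], qq["observed"], ".", ms=3)
    lim = max(qq["expected"].max(), qq["observed"].max())
    ax2.plot([0, lim], [0, lim], "r--", lw=0.8)
    ax2.set_xlabel("expected " + r"$-\log_{10} p$")
    ax2.set_ylabel("observed")
    ax2.set_title("QQ")
    fig.tight_layout()
    fig.savefig(OUT / "gwas_plots.png", dpi=120)
    print(f"plots -> {OUT / 'gwas_plots.png'}")


if __name__ == "__main__":
    main()
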