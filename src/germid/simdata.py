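"""Synthetic germplasm panels with known truth.

Generates diploid SNP panels that mimic a tree germplasm collection drawn
from a small number of diverged source populations plus admixed individuals
(two parental species and their hybrids being the motivating case). The
population model is Balding–Nichols-style: each locus has an ancestral allele
frequency p drawn uniformly from ``maf_range``, and population k's frequency
is drawn from Beta(p(1-F)/F, (1-p)(1-F)/F) with drift parameter
F = ``divergence`` (F = 0 means all populations share p exactly).

Each sample carries an ancestry vector over populations; unadmixed samples
are one-hot, admixed samples draw theirs from a symmetric Dirichlet(1). A
genotype at a locus is formed by drawing two alleles, each from a population
chosen by the ancestry vector, so realised heterozygosity grows with
admixture. Missingness is uniform and independent of genotype.

Companion generators plant QC failures in per-site annotations (to exercise
the hard-filter cascade) and build phenotypes: quantitative traits as an
additive genetic value over planted causal loci plus Gaussian noise scaled to
a target heritability, and coded categorical traits with stated class
frequencies.

All randomness flows from one explicit seed through a single
``numpy.random.Generator``; fixed seed implies bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .snp_filter import HARD_FILTER_RULES
from .variant_io import (
    MISSING,
    GenotypeMatrix,
    VariantAnnotations,
    locus_id,
)

_ORDERED_SUBS = [
    (r, a)
    for r in "ACGT"
    for a in "ACGT"
    if r != a
]


@dataclass
class SimConfig:
    """Parameters of a synthetic panel.

    Defaults describe the study conditions the package targets: a
    three-group admixed panel with drift F = 0.1, minor-allele frequencies
    straddling the 0.05 retention cutoff, and light uniform missingness.
    """

    n_samples: int = 197
    n_loci: int = 1000
    n_pops: int = 3
    divergence: float = 0.1
    admixed_fraction: float = 0.3
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.005
    n_chromosomes: int = 19
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence must lie in [0, 1)")
        if not 0.0 <= self.admixed_fraction <= 1.0:
            raise ValueError("admixed_fraction must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")


@dataclass
class TruthRecord:
    """Ground truth behind a simulated panel."""

    ancestry_proportions: np.ndarray  # (n_samples, n_pops), rows sum to 1
    ancestral_freqs: np.ndarray  # (n_loci,)
    pop_freqs: np.ndarray  # (n_pops, n_loci)
    causal_loci: list[int] = field(default_factory=list)
    causal_effects: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        props = np.asarray(self.ancestry_proportions, dtype=float)
        if np.any(props < 0) or not np.allclose(props.sum(axis=1), 1.0):
            raise ValueError("ancestry proportions must be non-negative and sum to 1")
        self.ancestry_proportions = props


def simulate_panel(config: SimConfig) -> tuple[GenotypeMatrix, TruthRecord]:
    """Simulate a diploid dosage panel with population structure.

    Returns the genotype matrix (group labels = modal ancestry, ``admixed``
    for Dirichlet-ancestry samples) and the :class:`TruthRecord`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m, k = config.n_samples, config.n_loci, config.n_pops

    lo, hi = config.maf_range
    p_anc = rng.uniform(lo, hi, size=m)
    f = config.divergence
    if f == 0.0:
        pop_freqs = np.tile(p_anc, (k, 1))
    else:
        shape = (1.0 - f) / f
        pop_freqs = rng.beta(p_anc * shape, (1.0 - p_anc) * shape, size=(k, m))
        pop_freqs = np.clip(pop_freqs, 1e-6, 1 - 1e-6)

    n_adm = int(round(config.admixed_fraction * n))
    admixed = np.zeros(n, dtype=bool)
    admixed[rng.choice(n, size=n_adm, replace=False)] = True
    ancestry = np.zeros((n, k))
    pure_pop = rng.integers(0, k, size=n)
    ancestry[np.arange(n), pure_pop] = 1.0
    if n_adm:
        ancestry[admixed] = rng.dirichlet(np.ones(k), size=n_adm)

    # two allele draws per genotype, each from an ancestry-chosen population
    dosages = np.zeros((n, m), dtype=np.int8)
    for i in range(n):
        if admixed[i]:
            pops = rng.choice(k, size=(2, m), p=ancestry[i])
            freqs = pop_freqs[pops, np.arange(m)]
        else:
            freqs = np.tile(pop_freqs[pure_pop[i]], (2, 1))
        alleles = rng.random((2, m)) < freqs
        dosages[i] = alleles.sum(axis=0)

    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dosages[mask] = MISSING

    loci = _random_loci(rng, m, config.n_chromosomes)
    labels = [
        "admixed" if admixed[i] else f"pop{int(np.argmax(ancestry[i])) + 1}"
        for i in range(n)
    ]
    samples = pd.DataFrame(
        {"accession_id": [f"ACC{i + 1:04d}" for i in range(n)], "group": labels}
    )
    matrix = GenotypeMatrix(dosages, loci, samples)
    truth = TruthRecord(
        ancestry_proportions=ancestry, ancestral_freqs=p_anc, pop_freqs=pop_freqs
    )
    return matrix, truth


def _random_loci(rng: np.random.Generator, m: int, n_chrom: int) -> pd.DataFrame:
    """Locus metadata: positions strictly increasing within each chromosome,
    ref/alt drawn over all 12 ordered substitution types."""
    chrom_of = np.sort(rng.integers(0, n_chrom, size=m))
    rows = []
    pos = 0
    last_chrom = -1
    for j in range(m):
        c = int(chrom_of[j])
        if c != last_chrom:
            pos = 0
            last_chrom = c
        pos += int(rng.integers(1, 50_000))
        ref, alt = _ORDERED_SUBS[int(rng.integers(0, 12))]
        chrom = f"chr{c + 1}"
        rows.append(dict(chrom=chrom, pos=pos, ref=ref, alt=alt,
                         id=locus_id(chrom, pos), multiallelic=False))
    return pd.DataFrame(rows)


def panel_with_spectrum(
    n_transitions: int,
    n_transversions: int,
    n_samples: int = 4,
    seed: int = 0,
) -> GenotypeMatrix:
    """Construct a panel with an exact substitution-class composition.

    Transition sites cycle through the 4 transition classes, transversion
    sites through the 8 transversion classes, so any count partition can be
    realised exactly — used for worked Ts/Tv-ratio examples.
    """
    ts = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]
    tv = [p for p in _ORDERED_SUBS if p not in ts]
    pairs = [ts[i % 4] for i in range(n_transitions)]
    pairs += [tv[i % 8] for i in range(n_transversions)]
    m = len(pairs)
    rng = np.random.default_rng(seed)
    rows = [
        dict(chrom="chr1", pos=j + 1, ref=r, alt=a, id=f"1_{j + 1}", multiallelic=False)
        for j, (r, a) in enumerate(pairs)
    ]
    dosages = rng.integers(0, 3, size=(n_samples, m)).astype(np.int8)
    samples = pd.DataFrame(
        {"accession_id": [f"S{i + 1}" for i in range(n_samples)],
         "group": ["panel"] * n_samples}
    )
    return GenotypeMatrix(dosages, pd.DataFrame(rows), samples)


def simulate_annotations(
    genotypes: GenotypeMatrix,
    fail_fraction: float,
    seed: int,
    low_gq_rate: float = 0.002,
) -> tuple[VariantAnnotations, np.ndarray]:
    """Draw per-site/per-genotype QC metrics with planted hard-filter failures.

    Exactly ``round(fail_fraction * n_loci)`` sites get one metric pushed past
    its threshold; all other sites draw comfortably inside the passing region.
    A ``low_gq_rate`` fraction of genotypes receives GQ below 30 so the
    masking stage has something to do.

    Returns
    -------
    (VariantAnnotations, planted_fail_indices)
    """
    if not 0.0 <= fail_fraction < 1.0:
        raise ValueError("fail_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n, m = genotypes.n_samples, genotypes.n_loci

    site = pd.DataFrame(
        {
            "QD": rng.uniform(15.0, 35.0, m),
            "MQ": rng.uniform(55.0, 60.0, m),
            "FS": rng.uniform(0.0, 10.0, m),
            "SOR": rng.uniform(0.3, 1.5, m),
            "MQRankSum": rng.normal(0.0, 1.0, m),
            "ReadPosRankSum": rng.normal(0.0, 1.0, m),
        }
    )
    n_fail = int(round(fail_fraction * m))
    planted = np.sort(rng.choice(m, size=n_fail, replace=False))
    metric_names = list(HARD_FILTER_RULES)
    for j in planted:
        metric = metric_names[int(rng.integers(0, len(metric_names)))]
        op, thr = HARD_FILTER_RULES[metric]
        delta = rng.uniform(0.5, 5.0)
        site.loc[j, metric] = thr - delta if op == "lt" else thr + delta

    gq = rng.integers(60, 100, size=(n, m)).astype(float)
    if low_gq_rate > 0:
        low = rng.random((n, m)) < low_gq_rate
        gq[low] = rng.integers(5, 30, size=int(low.sum()))
    dp = rng.poisson(30, size=(n, m)).astype(float)
    dp = np.clip(dp, 4, 99)
    return VariantAnnotations(site, gq, dp), planted


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    truth: TruthRecord,
    heritability: float,
    n_categorical: int = 0,
    class_freqs: list[list[float]] | None = None,
    n_causal: int = 1,
    effect_size: float = 1.0,
    seed: int = 0,
    trait_name: str = "quant_trait",
) -> tuple[pd.DataFrame, TruthRecord]:
    """Build a trait table and record the planted causal loci in ``truth``.

    The quantitative trait is ``sum(effect * dosage at causal loci) + noise``
    with noise variance set so the genetic fraction of the realised variance
    equals ``heritability`` (h2 = 0 gives pure noise, h2 = 1 zero noise).
    Categorical traits are coded 1..k with the given class frequencies
    (default: uniform over 3 classes).
    """
    if not 0.0 <= heritability <= 1.0:
        raise ValueError("heritability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n, m = genotypes.n_samples, genotypes.n_loci

    if truth.causal_loci:
        causal = list(truth.causal_loci)
        effects = list(truth.causal_effects)
    else:
        causal = sorted(rng.choice(m, size=n_causal, replace=False).tolist())
        effects = [effect_size] * n_causal
        truth.causal_loci = causal
        truth.causal_effects = effects
    if max(causal) >= m:
        raise ValueError("causal locus index out of range")

    dos = genotypes.dosages_float()[:, causal]
    col_means = np.nanmean(dos, axis=0)
    dos = np.where(np.isnan(dos), col_means, dos)  # impute so g is defined for all
    g = dos @ np.asarray(effects, dtype=float)
    var_g = float(np.var(g))
    if heritability == 0.0:
        y = rng.normal(0.0, 1.0, n)
    elif heritability == 1.0 or var_g == 0.0:
        y = g.copy()
    else:
        var_e = var_g * (1.0 - heritability) / heritability
        y = g + rng.normal(0.0, np.sqrt(var_e), n)

    data = {trait_name: y}
    if class_freqs is None:
        class_freqs = [[1 / 3, 1 / 3, 1 / 3]] * n_categorical
    for t, freqs in enumerate(class_freqs[:n_categorical] if n_categorical else class_freqs):
        freqs = np.asarray(freqs, dtype=float)
        freqs = freqs / freqs.sum()
        codes = rng.choice(np.arange(1, len(freqs) + 1), size=n, p=freqs)
        data[f"cat_trait_{t + 1}"] = codes
    traits = pd.DataFrame(data, index=genotypes.samples["accession_id"].to_numpy())
    traits.index.name = "accession_id"
    return traits, truth
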