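"""Genetic-diversity indices and phenotypic-trait statistics.

Per-locus indices (reported per group as across-locus means):

* Na — number of observed alleles (frequency > 0);
* Ne — effective allele number, 1 / sum(p_i^2);
* Ho — observed heterozygote fraction among non-missing genotypes;
* He — expected heterozygosity, 1 - sum(p_i^2);
* PIC — polymorphic information content (Botstein's codominant-marker
  formula), 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2;
* H' — Shannon index over allele frequencies, -sum(p_i ln p_i), in nats;
* Nei — Nei's gene diversity, which for a single locus equals He.

Trait statistics: max/min/mean, population (divide-by-n) standard deviation,
CV = SD/mean x 100%, and Shannon H' = -sum(P_i ln P_i) over trait-class
relative frequencies (continuous traits are binned for H' only). Membership
scoring rescales each trait to [0, 1] and averages with weights to a D-value
per accession.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .variant_io import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class LocusStats:
    Na: int
    Ne: float
    Ho: float
    He: float
    PIC: float
    H_prime: float
    Nei: float
    p: float  # alt-allele frequency


@dataclass
class TraitSummary:
    maximum: float
    minimum: float
    mean: float
    sd: float
    cv: float  # percent
    H_prime: float  # nats


def allele_freqs(matrix: GenotypeMatrix, locus: int) -> np.ndarray:
    """(ref, alt) allele frequencies at a locus, missing genotypes excluded."""
    col = matrix.dosages[:, locus]
    obs = col[col != MISSING]
    if obs.size == 0:
        raise ValueError(f"locus {locus} has no non-missing genotypes")
    p_alt = float(obs.sum()) / (2.0 * obs.size)
    return np.array([1.0 - p_alt, p_alt])


def _stats_from_freqs(freqs: np.ndarray, ho: float) -> LocusStats:
    present = freqs[freqs > 0]
    na = int(present.size)
    sum_p2 = float(np.sum(freqs**2))
    he = 1.0 - sum_p2
    ne = 1.0 / sum_p2
    hprime = float(-np.sum(present * np.log(present)))
    # Botstein PIC: He minus the double-heterozygote ambiguity term
    cross = 0.0
    for i in range(len(freqs)):
        for j in range(i + 1, len(freqs)):
            cross += 2.0 * freqs[i] ** 2 * freqs[j] ** 2
    pic = he - cross
    return LocusStats(Na=na, Ne=ne, Ho=ho, He=he, PIC=pic, H_prime=hprime,
                      Nei=he, p=float(freqs[-1]))


def locus_stats(matrix: GenotypeMatrix, locus: int) -> LocusStats:
    """The seven diversity indices at one locus."""
    freqs = allele_freqs(matrix, locus)
    col = matrix.dosages[:, locus]
    obs = col[col != MISSING]
    ho = float(np.mean(obs == 1))
    return _stats_from_freqs(freqs, ho)


def locus_stats_table(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus index table over the whole panel (all-missing loci skipped)."""
    rows = []
    for j in range(matrix.n_loci):
        col = matrix.dosages[:, j]
        if np.all(col == MISSING):
            continue
        s = locus_stats(matrix, j)
        rows.append(dict(id=matrix.loci["id"].iloc[j], Na=s.Na, Ne=s.Ne, Ho=s.Ho,
                         He=s.He, PIC=s.PIC, H_prime=s.H_prime, Nei=s.Nei, p=s.p))
    return pd.DataFrame(rows)


def group_diversity(matrix: GenotypeMatrix, groups=None) -> pd.DataFrame:
    """Across-locus mean of each index, per group, on the group's own
    allele frequencies. Singleton groups are skipped with a warning."""
    labels = np.asarray(groups if groups is not None else matrix.samples["group"])
    rows = []
    for g in pd.unique(labels):
        idx = np.flatnonzero(labels == g)
        if idx.size < 2:
            warnings.warn(f"group {g!r} has <2 samples; skipped")
            continue
        sub = matrix.subset_samples(idx)
        table = locus_stats_table(sub)
        if table.empty:
            warnings.warn(f"group {g!r} has no scorable loci; skipped")
            continue
        means = table[["Na", "Ne", "Ho", "He", "PIC", "H_prime", "Nei"]].mean()
        rows.append(dict(group=g, n_samples=int(idx.size), **means.to_dict()))
    return pd.DataFrame(rows)


def shannon_index(values: np.ndarray) -> float:
    """Shannon H' (nats) over the relative frequencies of distinct values."""
    values = np.asarray(values)
    values = values[~pd.isna(values)]
    if values.size == 0:
        return float("nan")
    _, counts = np.unique(values, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def trait_summary(
    traits: pd.DataFrame,
    trait: str,
    continuous: bool = False,
    n_bins: int = 10,
    ddof: int = 0,
) -> TraitSummary:
    """Range, mean, SD, CV% and Shannon H' for one trait column.

    ``continuous=True`` bins the values into ``n_bins`` equal-width classes
    for the H' computation only. Population SD (ddof=0) by default.
    """
    x = traits[trait].dropna().to_numpy(dtype=float)
    if x.size == 0:
        raise ValueError(f"trait {trait!r} has no non-missing values")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=ddof))
    if sd == 0.0:
        cv = 0.0
    elif mean == 0.0:
        log.warning("trait %s: mean 0 with positive SD; CV undefined", trait)
        cv = float("nan")
    else:
        cv = sd / mean * 100.0
    if sd == 0.0:
        h = 0.0
    elif continuous:
        binned = np.digitize(x, np.linspace(x.min(), x.max(), n_bins + 1)[1:-1])
        h = shannon_index(binned)
    else:
        h = shannon_index(x)
    return TraitSummary(maximum=float(np.max(x)), minimum=float(np.min(x)),
                        mean=mean, sd=sd, cv=cv, H_prime=h)


def trait_summary_table(
    traits: pd.DataFrame, continuous_traits: set[str] | None = None
) -> pd.DataFrame:
    """Summary table over all trait columns (one row per trait)."""
    cont = continuous_traits or set()
    rows = []
    for t in traits.columns:
        s = trait_summary(traits, t, continuous=t in cont)
        rows.append(dict(trait=t, maximum=s.maximum, minimum=s.minimum,
                         mean=s.mean, sd=s.sd, cv=s.cv, H_prime=s.H_prime))
    return pd.DataFrame(rows)


def trait_correlations(traits: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix; constant traits give NaN."""
    if len(traits) < 3:
        raise ValueError("need >= 3 samples for correlations")
    return traits.astype(float).corr(method="pearson", min_periods=3)


def pheno_pca(traits: pd.DataFrame, n_components: int | None = None):
    """PCA on standardized trait columns.

    Constant traits are dropped (logged). Returns (scores, loadings,
    explained_pct) with deterministic component signs (largest-magnitude
    loading made positive).
    """
    x = traits.astype(float).to_numpy()
    sd = np.nanstd(x, axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all traits constant; PCA undefined")
    dropped = [c for c, k in zip(traits.columns, keep) if not k]
    if dropped:
        log.info("pheno_pca: dropping constant traits %s", dropped)
    x = x[:, keep]
    mu = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), mu, x)
    z = (x - x.mean(axis=0)) / x.std(axis=0)
    k = min(n_components or z.shape[1], z.shape[1], z.shape[0] - 1)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(z)
    loadings = pca.components_.T  # (traits, components)
    for c in range(loadings.shape[1]):
        piv = np.argmax(np.abs(loadings[:, c]))
        if loadings[piv, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    explained = pca.explained_variance_ratio_ * 100.0
    return scores, loadings, explained


def membership_D(
    traits: pd.DataFrame,
    weights: dict[str, float] | None = None,
    directions: dict[str, str] | None = None,
) -> pd.Series:
    """Membership-function D-value per sample, in [0, 1].

    Each trait is rescaled to u = (x - min)/(max - min), reversed for
    ``smaller-better`` traits, and D is the weighted sum. Weights default to
    equal and must sum to 1.
    """
    cols = list(traits.columns)
    if weights is None:
        weights = {c: 1.0 / len(cols) for c in cols}
    wsum = sum(weights.values())
    if not np.isclose(wsum, 1.0):
        raise ValueError(f"weights must sum to 1 (got {wsum})")
    directions = directions or {}
    d = np.zeros(len(traits))
    for c, w in weights.items():
        if w < 0:
            raise ValueError(f"negative weight for trait {c!r}")
        if w == 0:
            continue
        x = traits[c].to_numpy(dtype=float)
        lo, hi = np.nanmin(x), np.nanmax(x)
        if hi == lo:
            raise ValueError(f"trait {c!r} is constant but has nonzero weight")
        u = (x - lo) / (hi - lo)
        if directions.get(c, "larger-better") == "smaller-better":
            u = 1.0 - u
        d += w * u
    return pd.Series(d, index=traits.index, name="D")
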