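"""Population structure: genotype PCA, UPGMA clustering, LD decay, Evanno ΔK.

Genotype PCA mean-imputes missing dosages per locus, centres columns (no
unit-variance scaling) and takes the SVD; component signs are fixed by making
the largest-magnitude loading positive so results are fully reproducible.

UPGMA operates on pairwise Euclidean distances over mean-imputed dosage rows
and merges with deterministic tie-breaking (among equal-distance candidate
pairs, the pair whose smallest member sample index is lowest merges first).
The dendrogram is ultrametric and serialised as Newick with branch lengths.

LD uses the composite (Rogers–Huff style) estimator: r^2 is the squared
Pearson correlation of the two dosage vectors over pairwise-complete samples,
which needs no haplotype phase. The scan restricts to the chromosome with the
most markers and its first ``max_markers`` loci in position order.

Evanno ΔK post-processes an external Bayesian-clustering log-likelihood table
(K x replicates): ΔK(K) = mean|L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)), defined
on interior K with positive replicate spread; the best K maximises ΔK.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class PCAResult:
    scores: np.ndarray  # samples x components
    explained: np.ndarray  # percent per component
    loadings: np.ndarray  # loci x components


def _imputed_dosages(matrix: GenotypeMatrix) -> np.ndarray:
    x = matrix.dosages_float()
    mu = np.nanmean(x, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)  # all-missing locus -> constant column
    return np.where(np.isnan(x), mu, x)


def geno_pca(matrix: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """PCA of the centred (mean-imputed) dosage matrix."""
    if matrix.n_samples < 2:
        raise ValueError("need >= 2 samples")
    x = _imputed_dosages(matrix)
    x = x - x.mean(axis=0)
    total_var = float(np.sum(x**2))
    if total_var == 0:
        raise ValueError("all loci monomorphic; PCA undefined")
    k = min(n_components, matrix.n_samples - 1, matrix.n_loci)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    loadings = vt.T
    scores = u * s
    for c in range(k):
        piv = np.argmax(np.abs(loadings[:, c]))
        if loadings[piv, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    explained = (s**2) / total_var * 100.0
    return PCAResult(scores=scores, explained=explained, loadings=loadings)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma_linkage(dist: np.ndarray):
    """UPGMA over a condensed-or-square distance matrix.

    Returns (merges, heights): each merge is (cluster_a, cluster_b, height,
    size) in scipy linkage convention (new cluster ids n, n+1, ...). Ties are
    broken by the lowest minimum original sample index, then the second.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim == 1:
        from scipy.spatial.distance import squareform

        d = squareform(d)
    n = d.shape[0]
    active = {i: (1, i, i) for i in range(n)}  # id -> (size, min_idx, id)
    dmat = {}
    for i in range(n):
        for j in range(i + 1, n):
            dmat[(i, j)] = d[i, j]
    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for (i, j), val in dmat.items():
            key = (val, min(active[i][1], active[j][1]), max(active[i][1], active[j][1]))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        h = dmat[(i, j)]
        si, sj = active[i][0], active[j][0]
        merges[step] = (i, j, h, si + sj)
        new_min = min(active[i][1], active[j][1])
        # average-linkage update
        for k in list(active):
            if k in (i, j):
                continue
            dik = dmat.pop((min(i, k), max(i, k)))
            djk = dmat.pop((min(j, k), max(j, k)))
            dmat[(min(next_id, k), max(next_id, k))] = (si * dik + sj * djk) / (si + sj)
        del dmat[(i, j)]
        del active[i], active[j]
        active[next_id] = (si + sj, new_min, next_id)
        next_id += 1
    return merges


def distance_upgma(matrix: GenotypeMatrix) -> str:
    """Euclidean-distance UPGMA dendrogram of the panel, as Newick."""
    ids = list(matrix.samples["accession_id"])
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sample ids")
    if len(ids) < 2:
        raise ValueError("need >= 2 samples")
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(_imputed_dosages(matrix), metric="euclidean"))
    merges = upgma_linkage(d)
    return linkage_to_newick(merges, ids)


def linkage_to_newick(merges: np.ndarray, labels: list[str]) -> str:
    """Serialise a scipy-style linkage matrix to Newick with branch lengths.

    Node heights are half the merge distance (ultrametric convention), so a
    two-leaf tree at distance d has root height d/2.
    """
    n = len(labels)
    height = {i: 0.0 for i in range(n)}
    node = {i: labels[i] for i in range(n)}
    for step, (a, b, dist, _size) in enumerate(merges):
        a, b = int(a), int(b)
        h = dist / 2.0
        left = f"{node[a]}:{h - height[a]:.6g}"
        right = f"{node[b]}:{h - height[b]:.6g}"
        nid = n + step
        node[nid] = f"({left},{right})"
        height[nid] = h
    return node[n + len(merges) - 1] + ";"


def cut_tree_k(merges: np.ndarray, n: int, k: int) -> np.ndarray:
    """Flat cluster labels from a linkage matrix, cutting to k clusters."""
    parent = {}
    for step, (a, b, _h, _s) in enumerate(merges[: n - k]):
        parent[int(a)] = n + step
        parent[int(b)] = n + step
    labels = np.zeros(n, dtype=int)
    roots = {}
    for i in range(n):
        r = i
        while r in parent:
            r = parent[r]
        labels[i] = roots.setdefault(r, len(roots))
    return labels


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def _pairwise_r2(x: np.ndarray) -> np.ndarray:
    """Squared pairwise-complete Pearson correlation of dosage columns.

    ``x`` is samples x loci with NaN for missing. Monomorphic-in-overlap
    pairs yield NaN.
    """
    valid = ~np.isnan(x)
    xz = np.where(valid, x, 0.0)
    v = valid.astype(float)
    n = v.T @ v  # pairwise-complete counts
    sx = xz.T @ v
    sy = v.T @ xz
    sxy = xz.T @ xz
    sxx = (xz**2).T @ v
    syy = v.T @ (xz**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        varx = sxx - sx**2 / n
        vary = syy - sy**2 / n
        r2 = cov**2 / (varx * vary)
    r2[(n < 2)] = np.nan
    return np.clip(r2, 0.0, 1.0)


def ld_scan(matrix: GenotypeMatrix, max_markers: int = 1000) -> pd.DataFrame:
    """Pairwise composite r^2 on the densest chromosome.

    Takes the first ``max_markers`` loci (genomic order) of the chromosome
    with the most markers; returns a table (locus_a, locus_b, distance, r2),
    monomorphic pairs skipped.
    """
    counts = matrix.loci["chrom"].value_counts()
    if counts.empty:
        raise ValueError("no loci")
    chrom = counts.idxmax()
    idx = np.flatnonzero((matrix.loci["chrom"] == chrom).to_numpy())
    idx = idx[np.argsort(matrix.loci["pos"].iloc[idx].to_numpy(), kind="stable")]
    idx = idx[:max_markers]
    if idx.size < 2:
        raise ValueError(f"chromosome {chrom} has <2 markers")
    sub = matrix.subset_loci(idx)
    r2 = _pairwise_r2(sub.dosages_float())
    pos = sub.loci["pos"].to_numpy()
    ids = sub.loci["id"].to_numpy()
    iu, ju = np.triu_indices(idx.size, k=1)
    dist = np.abs(pos[ju] - pos[iu])
    vals = r2[iu, ju]
    ok = ~np.isnan(vals)
    n_skip = int((~ok).sum())
    if n_skip:
        log.info("ld_scan: skipped %d monomorphic/degenerate pairs", n_skip)
    return pd.DataFrame(
        {"locus_a": ids[iu[ok]], "locus_b": ids[ju[ok]],
         "distance": dist[ok], "r2": vals[ok]}
    )


def ld_decay(pairs: pd.DataFrame, bin_width: float) -> pd.DataFrame:
    """Mean r^2 per physical-distance bin (midpoint, mean_r2, n_pairs)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(pairs) == 0:
        raise ValueError("no LD pairs")
    bins = (pairs["distance"] // bin_width).astype(int)
    grouped = pairs.groupby(bins)["r2"]
    out = pd.DataFrame(
        {
            "distance_mid": (grouped.mean().index + 0.5) * bin_width,
            "mean_r2": grouped.mean().to_numpy(),
            "n_pairs": grouped.size().to_numpy(),
        }
    )
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Evanno ΔK
# ---------------------------------------------------------------------------

def evanno_delta_k(logliks: pd.DataFrame) -> pd.DataFrame:
    """Evanno second-difference table from a K x replicate log-likelihoods.

    ``logliks`` is indexed by K (consecutive integers), one column per
    replicate. Returns per-K mean L, sd, L', |L''|, ΔK and a ``best_k``
    attribute (argmax ΔK over defined entries; None if none defined).
    """
    ks = np.asarray(logliks.index, dtype=int)
    if len(ks) < 3:
        raise ValueError("need >= 3 consecutive K values")
    if not np.all(np.diff(ks) == 1):
        raise ValueError("K grid must be consecutive integers")
    if logliks.shape[1] < 2:
        raise ValueError("need >= 2 replicates per K")
    vals = logliks.to_numpy(dtype=float)
    mean_l = vals.mean(axis=1)
    sd_l = vals.std(axis=1, ddof=1)
    lp = np.full(len(ks), np.nan)
    lp[1:] = np.diff(mean_l)
    lpp = np.full(len(ks), np.nan)
    lpp[1:-1] = np.abs(mean_l[2:] - 2 * mean_l[1:-1] + mean_l[:-2])
    with np.errstate(invalid="ignore", divide="ignore"):
        delta_k = lpp / sd_l
    delta_k[sd_l == 0] = np.nan
    table = pd.DataFrame(
        {"K": ks, "mean_L": mean_l, "sd_L": sd_l, "L_prime": lp,
         "L_doubleprime_abs": lpp, "delta_K": delta_k}
    ).set_index("K")
    defined = table["delta_K"].dropna()
    table.attrs["best_k"] = int(defined.idxmax()) if len(defined) and defined.max() > 0 else None
    return table
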