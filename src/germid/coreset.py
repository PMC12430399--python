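"""Minimal core-marker selection and genotype fingerprint codes.

A fingerprint code is the concatenation of a sample's genotype tokens
("0/0", "0/1", "1/1", "./.") at a chosen locus subset, emitted in fixed
genomic order (chromosome, then position) regardless of selection order.

Core selection is a greedy set-cover over sample pairs: starting from the
empty set, each iteration adds the candidate locus that resolves the most
currently-confounded pairs — a pair counts as resolved only when both
genotypes are non-missing and differ at some selected locus (a missing call
must never be what tells two accessions apart). Ties are broken by higher
PIC, then by genomic position. Selection stops when every pair is resolved
or no candidate helps; a final backward pass prunes any locus whose removal
keeps the panel fully resolved, so the reported set is irredundant. Byte-
identical samples are reported as unresolved groups rather than looping.

``brute_force_min_set`` is an exhaustive oracle for small instances, used to
audit greedy minimality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .diversity import locus_stats
from .variant_io import MISSING, GenotypeMatrix

TOKENS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
SEPARATOR = "|"


@dataclass
class CoreMarkerSet:
    """Greedy-selected core loci (in selection order) and their PIC values."""

    locus_ids: list[str]
    pic: list[float]
    unresolved_groups: list[list[str]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.locus_ids)

    def to_frame(self, matrix: GenotypeMatrix) -> pd.DataFrame:
        idx = matrix.locus_index(self.locus_ids)
        return pd.DataFrame(
            {
                "chromosome": matrix.loci["chrom"].iloc[idx].to_numpy(),
                "position": matrix.loci["pos"].iloc[idx].to_numpy(),
                "locus_id": self.locus_ids,
                "PIC": self.pic,
            }
        )


def fingerprint_codes(matrix: GenotypeMatrix, loci: list[str]) -> pd.Series:
    """Per-sample fingerprint code over a locus-id subset.

    Tokens are ordered by (chromosome, position) regardless of the order in
    which ``loci`` is given.
    """
    if not loci:
        raise ValueError("locus subset is empty")
    idx = matrix.locus_index(loci)
    order = np.lexsort(
        (matrix.loci["pos"].iloc[idx].to_numpy(),
         matrix.loci["chrom"].iloc[idx].to_numpy())
    )
    idx = idx[order]
    codes = [
        SEPARATOR.join(TOKENS[int(d)] for d in matrix.dosages[i, idx])
        for i in range(matrix.n_samples)
    ]
    return pd.Series(codes, index=matrix.samples["accession_id"].to_numpy(), name="code")


def _pair_resolution(dosages: np.ndarray, pairs: np.ndarray, locus: int) -> np.ndarray:
    a = dosages[pairs[:, 0], locus]
    b = dosages[pairs[:, 1], locus]
    return (a != b) & (a != MISSING) & (b != MISSING)


def _resolves_all(dosages: np.ndarray, pairs: np.ndarray, loci: list[int]) -> bool:
    if not len(loci):
        return pairs.shape[0] == 0
    sub_a = dosages[pairs[:, 0]][:, loci]
    sub_b = dosages[pairs[:, 1]][:, loci]
    ok = (sub_a != sub_b) & (sub_a != MISSING) & (sub_b != MISSING)
    return bool(ok.any(axis=1).all())


def greedy_core_select(
    matrix: GenotypeMatrix, candidates: list[str] | None = None
) -> CoreMarkerSet:
    """Greedy-plus-pruning core-marker selection over candidate locus ids."""
    if matrix.n_samples < 2:
        raise ValueError("need >= 2 samples")
    if candidates is None:
        candidates = list(matrix.loci["id"])
    if not candidates:
        raise ValueError("empty candidate list")
    cand_idx = matrix.locus_index(candidates)
    dosages = matrix.dosages
    n = matrix.n_samples
    pairs = np.array(list(combinations(range(n), 2)), dtype=int)

    pic = {}
    for ci in cand_idx:
        col = dosages[:, ci]
        if np.all(col == MISSING):
            pic[ci] = -1.0
        else:
            pic[ci] = locus_stats(matrix, int(ci)).PIC
    chrom = matrix.loci["chrom"].to_numpy()
    pos = matrix.loci["pos"].to_numpy()

    selected: list[int] = []
    unresolved = pairs
    remaining = list(cand_idx)
    while unresolved.shape[0] and remaining:
        best = None
        for ci in remaining:
            gain = int(_pair_resolution(dosages, unresolved, ci).sum())
            key = (-gain, -pic[ci], chrom[ci], pos[ci])
            if best is None or key < best[0]:
                best = (key, ci, gain)
        _, ci, gain = best
        if gain == 0:
            break
        selected.append(int(ci))
        remaining.remove(ci)
        unresolved = unresolved[~_pair_resolution(dosages, unresolved, ci)]

    # irredundancy pruning (only meaningful when fully resolved)
    if unresolved.shape[0] == 0 and len(selected) > 1:
        pruned = list(selected)
        for ci in list(selected):
            trial = [c for c in pruned if c != ci]
            if trial and _resolves_all(dosages, pairs, trial):
                pruned = trial
        selected = pruned

    groups = _unresolved_groups(matrix, unresolved)
    return CoreMarkerSet(
        locus_ids=[matrix.loci["id"].iloc[c] for c in selected],
        pic=[pic[c] for c in selected],
        unresolved_groups=groups,
    )


def _unresolved_groups(matrix: GenotypeMatrix, unresolved: np.ndarray) -> list[list[str]]:
    if unresolved.shape[0] == 0:
        return []
    ids = matrix.samples["accession_id"].to_numpy()
    parent = list(range(matrix.n_samples))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in unresolved:
        parent[find(int(i))] = find(int(j))
    groups: dict[int, list[str]] = {}
    members = set(unresolved.ravel().tolist())
    for i in members:
        groups.setdefault(find(int(i)), []).append(ids[int(i)])
    return sorted([sorted(g) for g in groups.values() if len(g) > 1])


def brute_force_min_set(
    matrix: GenotypeMatrix,
    candidates: list[str] | None = None,
    max_size: int | None = None,
) -> list[str] | None:
    """Exhaustive minimum discriminating subset (oracle for small instances).

    Tests subsets in increasing size order and returns the first achieving
    full pairwise resolution, or None if nothing up to ``max_size`` works.
    Guarded to <= 20 candidates and <= 12 samples.
    """
    if candidates is None:
        candidates = list(matrix.loci["id"])
    if len(candidates) > 20 or matrix.n_samples > 12:
        raise ValueError("instance too large for exhaustive search "
                         "(<= 20 candidates, <= 12 samples)")
    cand_idx = list(matrix.locus_index(candidates))
    pairs = np.array(list(combinations(range(matrix.n_samples), 2)), dtype=int)
    limit = max_size or len(cand_idx)
    for size in range(1, limit + 1):
        for subset in combinations(cand_idx, size):
            if _resolves_all(matrix.dosages, pairs, list(subset)):
                return [matrix.loci["id"].iloc[c] for c in subset]
    return None


def discrimination_report(codes: pd.Series) -> dict:
    """Duplicate-code groups and the pairwise resolution rate.

    rate = resolved pairs / total pairs; 1.0 when all codes are distinct
    (a single sample trivially counts as fully resolved).
    """
    if len(codes) == 0:
        raise ValueError("no codes")
    n = len(codes)
    groups = [
        sorted(sub.index.tolist())
        for _, sub in codes.groupby(codes)
        if len(sub) > 1
    ]
    total = n * (n - 1) // 2
    confounded = sum(len(g) * (len(g) - 1) // 2 for g in groups)
    rate = 1.0 if total == 0 else (total - confounded) / total
    return {"duplicate_groups": sorted(groups), "resolution_rate": rate,
            "n_samples": n}
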