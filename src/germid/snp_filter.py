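"""High-quality SNP selection: the hard-filter + site-filter cascade.

The cascade reproduces the conventional short-read hard-filtering recipe for
diploid SNPs, applied in five ordered stages:

1. per-site hard filter on caller annotations — a site fails if any of
   QD < 2.0, MQ < 40.0, FS > 60.0, SOR > 3.0, MQRankSum < -12.5,
   ReadPosRankSum < -8.0 (a missing metric is "not evaluable" and that
   criterion is skipped, matching standard hard-filter semantics);
2. site screens: genotype missing rate < 20%, MAF > 0.05 (strict), exact
   Hardy–Weinberg test p >= 1e-4, biallelic SNVs only;
3. genotype masking: calls with GQ < 30 are set to missing;
4. sites whose post-masking missing rate exceeds 1% are dropped;
5. sites whose mean non-missing depth falls outside [3, 100] are dropped.

Inequalities follow the printed symbols strictly (MAF = 0.05 fails; QD = 2.0
passes). MAF and HWE use non-missing genotypes only.

The Hardy–Weinberg test is the exact conditional test: given the allele
counts, the two-sided p-value sums the probabilities of every heterozygote
count whose conditional probability does not exceed the observed one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from math import lgamma, log, exp

import numpy as np

from .variant_io import MISSING, GenotypeMatrix, VariantAnnotations

#: hard-filter rules: metric -> (direction, threshold); "lt" fails when value < t
HARD_FILTER_RULES = {
    "QD": ("lt", 2.0),
    "MQ": ("lt", 40.0),
    "FS": ("gt", 60.0),
    "SOR": ("gt", 3.0),
    "MQRankSum": ("lt", -12.5),
    "ReadPosRankSum": ("lt", -8.0),
}


@dataclass
class FilterThresholds:
    """Tunable cutoffs of the cascade; defaults are the standard recipe."""

    missing_rate_max: float = 0.20
    maf_min: float = 0.05
    hwe_p_min: float = 1e-4
    gq_min: float = 30.0
    post_mask_missing_max: float = 0.01
    depth_range: tuple[float, float] = (3.0, 100.0)

    def validate(self) -> None:
        if not 0 < self.missing_rate_max <= 1:
            raise ValueError("missing_rate_max must lie in (0, 1]")
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must lie in [0, 0.5)")
        if not 0 < self.hwe_p_min < 1:
            raise ValueError("hwe_p_min must lie in (0, 1)")
        if self.gq_min < 0:
            raise ValueError("gq_min must be non-negative")
        if not 0 <= self.post_mask_missing_max <= 1:
            raise ValueError("post_mask_missing_max must lie in [0, 1]")
        lo, hi = self.depth_range
        if not 0 <= lo <= hi:
            raise ValueError("depth_range must be an ordered non-negative pair")


@dataclass
class FilterReport:
    """Bookkeeping of the cascade: input size, per-stage removals, reasons."""

    n_input: int
    removed_per_stage: dict = field(default_factory=dict)
    fail_reasons: dict = field(default_factory=dict)  # locus id -> [reasons]
    n_output: int = 0

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def hard_filter_site(
    annotations: VariantAnnotations, site: int
) -> tuple[bool, list[str]]:
    """Evaluate the hard filter at one site.

    Returns (passed, violated_criteria); a NaN metric is not evaluable and its
    criterion is skipped.
    """
    row = annotations.site.iloc[site]
    reasons = []
    for metric, (op, thr) in HARD_FILTER_RULES.items():
        v = row[metric]
        if not np.isfinite(v):
            continue
        if (op == "lt" and v < thr) or (op == "gt" and v > thr):
            reasons.append(metric)
    return (len(reasons) == 0), reasons


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy–Weinberg test p-value.

    Conditions on the observed allele counts and sums P(n_het') over all
    heterozygote counts with the right parity whose conditional probability
    is <= that of the observed count. Monomorphic samples return p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_aa + n_Aa  # minor allele count, after swap below
    n_A = 2 * n_AA + n_Aa
    if n_a > n_A:
        n_a, n_A = n_A, n_a
    if n_a == 0:
        return 1.0

    # log P(het = h | allele counts) up to a shared constant:
    #   P(h) propto n! / (nAA! nAa! naa!) * 2^h   with nAa = h
    def logp(h: int) -> float:
        aa = (n_a - h) // 2
        AA = n - h - aa
        return h * log(2.0) - (lgamma(h + 1) + lgamma(aa + 1) + lgamma(AA + 1))

    hs = list(range(n_a % 2, n_a + 1, 2))
    logs = np.array([logp(h) for h in hs])
    logs -= logs.max()
    probs = np.exp(logs)
    probs /= probs.sum()
    obs = n_Aa
    p_obs = probs[hs.index(obs)]
    p = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def minor_allele_frequency(dosages_col: np.ndarray) -> float:
    """MAF from a dosage column, missing entries excluded; NaN if all missing."""
    obs = dosages_col[dosages_col != MISSING]
    if obs.size == 0:
        return float("nan")
    p = obs.sum() / (2.0 * obs.size)
    return float(min(p, 1.0 - p))


def site_filters(
    matrix: GenotypeMatrix,
    annotations: VariantAnnotations | None,
    thresholds: FilterThresholds | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the five-stage cascade; returns the filtered panel and a report.

    ``annotations=None`` skips the hard-filter, GQ-masking and depth stages
    (metrics "not evaluable"), leaving the marginal site screens.
    """
    thr = thresholds or FilterThresholds()
    thr.validate()
    m = matrix.n_loci
    report = FilterReport(n_input=m)
    ids = matrix.loci["id"].to_numpy()
    keep = np.ones(m, dtype=bool)

    def fail(j: int, reason: str) -> None:
        report.fail_reasons.setdefault(ids[j], []).append(reason)

    # stage 1: hard filter on caller annotations
    n_removed = 0
    if annotations is not None:
        for j in range(m):
            ok, reasons = hard_filter_site(annotations, j)
            if not ok:
                keep[j] = False
                n_removed += 1
                for r in reasons:
                    fail(j, f"hard_filter:{r}")
    report.removed_per_stage["hard_filter"] = n_removed

    # stage 2: marginal site screens on survivors
    stage2_removed = 0
    for j in np.flatnonzero(keep):
        col = matrix.dosages[:, j]
        obs = col[col != MISSING]
        bad = False
        if matrix.loci["multiallelic"].iloc[j]:
            fail(j, "not_biallelic")
            bad = True
        miss_rate = 1.0 - obs.size / matrix.n_samples
        if not miss_rate < thr.missing_rate_max:
            fail(j, "missing_rate")
            bad = True
        if obs.size:
            maf = minor_allele_frequency(col)
            if not maf > thr.maf_min:
                fail(j, "maf")
                bad = True
            n_aa = int(np.sum(obs == 2))
            n_Aa = int(np.sum(obs == 1))
            n_AA = int(np.sum(obs == 0))
            if hwe_exact_test(n_AA, n_Aa, n_aa) < thr.hwe_p_min:
                fail(j, "hwe")
                bad = True
        if bad:
            keep[j] = False
            stage2_removed += 1
    report.removed_per_stage["site_screens"] = stage2_removed

    # stage 3: GQ masking (mutates a copy of the dosage matrix)
    dosages = matrix.dosages.copy()
    n_masked = 0
    if annotations is not None:
        mask = np.isfinite(annotations.gq) & (annotations.gq < thr.gq_min)
        mask &= dosages != MISSING
        n_masked = int(mask.sum())
        dosages[mask] = MISSING
    report.removed_per_stage["genotypes_masked_gq"] = n_masked

    # stage 4: post-masking missingness
    stage4_removed = 0
    for j in np.flatnonzero(keep):
        miss = np.mean(dosages[:, j] == MISSING)
        if miss > thr.post_mask_missing_max:
            fail(j, "post_mask_missing")
            keep[j] = False
            stage4_removed += 1
    report.removed_per_stage["post_mask_missing"] = stage4_removed

    # stage 5: mean depth window
    stage5_removed = 0
    if annotations is not None:
        lo, hi = thr.depth_range
        with np.errstate(invalid="ignore"):
            mean_dp = np.nanmean(annotations.dp, axis=0)
        for j in np.flatnonzero(keep):
            if np.isfinite(mean_dp[j]) and not (lo <= mean_dp[j] <= hi):
                fail(j, "mean_depth")
                keep[j] = False
                stage5_removed += 1
    report.removed_per_stage["mean_depth"] = stage5_removed

    kept_idx = np.flatnonzero(keep)
    out = GenotypeMatrix(
        dosages[:, kept_idx],
        matrix.loci.iloc[kept_idx].reset_index(drop=True),
        matrix.samples.copy(),
    )
    report.n_output = len(kept_idx)
    return out, report
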