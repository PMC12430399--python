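"""VCF input/output and the dosage genotype matrix.

The pipeline's backbone container is :class:`GenotypeMatrix`: a samples x loci
table of alternate-allele dosages (0, 1, 2; -1 for a missing call) with locus
metadata (chromosome, 1-based position, ref, alt) and sample metadata
(accession id, group label). Genotype calls "0/0", "0/1" and "1/1" map to
dosages 0, 1 and 2; "./." is missing. Phased separators are accepted and
treated as unphased.

Substitution classification follows the standard transition/transversion
partition of biallelic SNVs: A<->G and C<->T are transitions, the remaining
eight ordered ref->alt pairs are transversions, giving twelve ordered classes
in total.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

MISSING = -1

NUCLEOTIDES = ("A", "C", "G", "T")

#: the 12 ordered ref->alt single-nucleotide substitution classes
SUBSTITUTION_CLASSES = tuple(
    f"{r}>{a}" for r, a in itertools.permutations(NUCLEOTIDES, 2)
)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

#: INFO-field QC metrics consumed by the hard filter
SITE_METRICS = ("QD", "MQ", "FS", "SOR", "MQRankSum", "ReadPosRankSum")


class VcfParseError(ValueError):
    """Malformed VCF content."""


class PloidyError(ValueError):
    """Genotype call is not diploid."""


def locus_id(chrom: str, pos: int) -> str:
    """Render the canonical locus identifier ``chrom_pos``.

    A leading ``chr`` prefix is stripped so ids look like ``10_31605746``.
    """
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return f"{c}_{pos}"


@dataclass
class GenotypeMatrix:
    """Samples x loci alt-allele dosage matrix with metadata.

    Attributes
    ----------
    dosages : int8 array, shape (n_samples, n_loci)
        Values in {0, 1, 2} or :data:`MISSING` (-1).
    loci : DataFrame
        Columns ``chrom, pos, ref, alt, id, multiallelic``; positions strictly
        increasing within a chromosome.
    samples : DataFrame
        Columns ``accession_id, group``.
    """

    dosages: np.ndarray
    loci: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x loci)")
        if self.dosages.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        if "id" not in self.loci.columns:
            self.loci = self.loci.assign(
                id=[locus_id(c, p) for c, p in zip(self.loci["chrom"], self.loci["pos"])]
            )
        if "multiallelic" not in self.loci.columns:
            self.loci = self.loci.assign(multiallelic=False)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def dosages_float(self) -> np.ndarray:
        """Dosages as float with missing entries as NaN."""
        out = self.dosages.astype(float)
        out[self.dosages == MISSING] = np.nan
        return out

    def subset_loci(self, index) -> "GenotypeMatrix":
        """New matrix restricted to loci at positional ``index``."""
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[:, index],
            self.loci.iloc[index].reset_index(drop=True),
            self.samples.copy(),
        )

    def subset_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[index],
            self.loci.copy(),
            self.samples.iloc[index].reset_index(drop=True),
        )

    def locus_index(self, ids) -> np.ndarray:
        """Positional indices for locus ids; raises KeyError on unknown ids."""
        lookup = {lid: i for i, lid in enumerate(self.loci["id"])}
        missing = [lid for lid in ids if lid not in lookup]
        if missing:
            raise KeyError(f"unknown locus id(s): {missing}")
        return np.array([lookup[lid] for lid in ids], dtype=int)


@dataclass
class VariantAnnotations:
    """Per-site and per-genotype QC metrics.

    ``site`` has one row per locus with columns :data:`SITE_METRICS` (NaN where
    the caller did not emit the metric). ``gq`` and ``dp`` are samples x loci
    float arrays (NaN = absent).
    """

    site: pd.DataFrame
    gq: np.ndarray
    dp: np.ndarray

    def __post_init__(self) -> None:
        self.gq = np.asarray(self.gq, dtype=float)
        self.dp = np.asarray(self.dp, dtype=float)
        if self.gq.shape != self.dp.shape:
            raise ValueError("GQ and DP shapes differ")
        if len(self.site) != self.gq.shape[1]:
            raise ValueError("site table length does not match genotype arrays")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dp, initial=0) < 0:
                raise ValueError("DP must be non-negative")

    @property
    def n_loci(self) -> int:
        return len(self.site)

    def subset_loci(self, index) -> "VariantAnnotations":
        index = np.asarray(index)
        return VariantAnnotations(
            self.site.iloc[index].reset_index(drop=True),
            self.gq[:, index],
            self.dp[:, index],
        )


@dataclass
class SubstitutionSpectrum:
    """Counts of the 12 ordered substitution classes and the Ts/Tv ratio."""

    counts: dict = field(default_factory=dict)
    n_transitions: int = 0
    n_transversions: int = 0

    @property
    def tstv(self) -> float:
        """Transition/transversion ratio; NaN when no transversions."""
        if self.n_transversions == 0:
            return float("nan")
        return self.n_transitions / self.n_transversions

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def classify_substitution(ref: str, alt: str) -> str:
    """Classify a biallelic SNV as ``"transition"`` or ``"transversion"``."""
    if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
        raise ValueError(f"ref/alt must be single nucleotides, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt are identical; not a substitution")
    return "transition" if (ref, alt) in _TRANSITIONS else "transversion"


def substitution_spectrum(matrix: GenotypeMatrix) -> SubstitutionSpectrum:
    """Tally ref->alt classes over all loci of a biallelic SNV panel."""
    counts = {c: 0 for c in SUBSTITUTION_CLASSES}
    n_ts = n_tv = 0
    for ref, alt in zip(matrix.loci["ref"], matrix.loci["alt"]):
        key = f"{ref}>{alt}"
        if key not in counts:
            raise ValueError(f"non-SNV substitution {key!r}")
        counts[key] += 1
        if classify_substitution(ref, alt) == "transition":
            n_ts += 1
        else:
            n_tv += 1
    return SubstitutionSpectrum(counts=counts, n_transitions=n_ts, n_transversions=n_tv)


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=germid
##INFO=<ID=QD,Number=1,Type=Float,Description="Variant quality by depth">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias (phred)">
##INFO=<ID=SOR,Number=1,Type=Float,Description="Symmetric odds ratio strand bias">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping-quality rank-sum Z">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read-position rank-sum Z">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, annotations: VariantAnnotations | None, path) -> None:
    """Write the panel as an uncompressed VCFv4.2 file.

    Loci must already be sorted by (chromosome, position); GT:GQ:DP is emitted
    per genotype and the six hard-filter metrics go into INFO when annotations
    are given.
    """
    loci = matrix.loci
    chrom_order: dict[str, int] = {}
    for c in loci["chrom"]:
        chrom_order.setdefault(c, len(chrom_order))
    keys = list(zip((chrom_order[c] for c in loci["chrom"]), loci["pos"]))
    if any(keys[i] >= keys[i + 1] for i in range(len(keys) - 1)):
        raise ValueError("loci must be strictly sorted by (chromosome, position)")
    if annotations is not None and annotations.n_loci != matrix.n_loci:
        raise ValueError("annotation/locus dimension mismatch")

    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        max_pos = loci.groupby("chrom", sort=False)["pos"].max()
        for c in chrom_order:
            fh.write(f"##contig=<ID={c},length={int(max_pos[c]) + 1}>\n")
        ids = "\t".join(matrix.samples["accession_id"])
        fh.write(f"##germid_samples={matrix.n_samples}\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + ids + "\n")
        for j in range(matrix.n_loci):
            row = loci.iloc[j]
            if annotations is None:
                info = "."
            else:
                parts = []
                for m in SITE_METRICS:
                    v = annotations.site.iloc[j][m]
                    if np.isfinite(v):
                        parts.append(f"{m}={v:.4f}")
                info = ";".join(parts) if parts else "."
            fields = [str(row["chrom"]), str(row["pos"]), row["id"], row["ref"],
                      row["alt"], ".", "PASS", info, "GT:GQ:DP"]
            for i in range(matrix.n_samples):
                gt = _GT_STRING[int(matrix.dosages[i, j])]
                if annotations is None:
                    fields.append(gt)
                else:
                    gq, dp = annotations.gq[i, j], annotations.dp[i, j]
                    gq_s = str(int(gq)) if np.isfinite(gq) else "."
                    dp_s = str(int(dp)) if np.isfinite(dp) else "."
                    fields.append(f"{gt}:{gq_s}:{dp_s}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path, group_map: dict[str, str] | None = None):
    """Read a diploid VCF into a :class:`GenotypeMatrix` plus annotations.

    Multiallelic records are retained with ``multiallelic=True`` (downstream
    filtering excludes them); absent INFO/FORMAT metrics become NaN.

    Parameters
    ----------
    group_map
        Optional accession-id -> group-label mapping for the sample table.

    Returns
    -------
    (GenotypeMatrix, VariantAnnotations)
    """
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    dosage_cols, loci_rows, site_rows, gq_cols, dp_cols = [], [], [], [], []
    n = len(sample_ids)
    for rec_no, var in enumerate(vcf, start=1):
        gts = var.genotypes  # [allele0, allele1, phased] per sample
        col = np.empty(n, dtype=np.int8)
        for i, g in enumerate(gts):
            if len(g) != 3:  # cyvcf2 emits [a, phased] for haploid calls
                raise PloidyError(
                    f"non-diploid call for sample {sample_ids[i]} at record {rec_no}"
                )
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                col[i] = MISSING
            else:
                col[i] = (a > 0) + (b > 0)
        dosage_cols.append(col)
        multi = len(var.ALT) > 1
        alt = var.ALT[0] if var.ALT else "."
        loci_rows.append(
            dict(chrom=var.CHROM, pos=var.POS, ref=var.REF, alt=alt,
                 id=locus_id(var.CHROM, var.POS), multiallelic=multi)
        )
        site_rows.append({m: _info_float(var, m) for m in SITE_METRICS})
        gq_cols.append(_format_float(var, "GQ", n))
        dp_cols.append(_format_float(var, "DP", n))
    vcf.close()

    if loci_rows:
        dosages = np.column_stack(dosage_cols)
        gq = np.column_stack(gq_cols)
        dp = np.column_stack(dp_cols)
        loci = pd.DataFrame(loci_rows)
        site = pd.DataFrame(site_rows)
    else:
        dosages = np.zeros((n, 0), dtype=np.int8)
        gq = np.zeros((n, 0))
        dp = np.zeros((n, 0))
        loci = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "id", "multiallelic"])
        site = pd.DataFrame(columns=list(SITE_METRICS))
    groups = [group_map.get(s, "unknown") if group_map else "unknown" for s in sample_ids]
    samples = pd.DataFrame({"accession_id": sample_ids, "group": groups})
    return GenotypeMatrix(dosages, loci, samples), VariantAnnotations(site, gq, dp)


def _info_float(var, key: str) -> float:
    v = var.INFO.get(key)
    return float(v) if v is not None else float("nan")


def _format_float(var, key: str, n: int) -> np.ndarray:
    try:
        arr = var.format(key)
    except KeyError:
        arr = None
    if arr is None:
        return np.full(n, np.nan)
    out = np.asarray(arr, dtype=float).reshape(n, -1)[:, 0]
    out[out < 0] = np.nan  # cyvcf2 encodes missing integers as negative sentinels
    return out
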