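"""Pipeline configuration and the end-to-end run driver.

:class:`PipelineConfig` collects every tunable of the pipeline with defaults
equal to the standard thresholds the stages document (hard-filter cutoffs,
MAF > 0.05, HWE p >= 1e-4, GQ >= 30, post-mask missingness <= 1%, depth
3-100x, GWAS p < 1e-3, LD over the densest chromosome's first 1000 markers).
It round-trips losslessly through a flat ``key = value`` text file.

:func:`run_pipeline` executes simulate-or-ingest -> filter -> diversity ->
structure/LD -> GWAS -> core-selection -> fingerprint export, and writes a
manifest (JSON) recording the config hash, seed and a checksum per output
so identical runs are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import coreset, diversity, fingerprint, gwas, popstruct, simdata, snp_filter
from .variant_io import read_vcf, substitution_spectrum, write_vcf


@dataclass
class PipelineConfig:
    # inputs (empty vcf -> simulate a panel)
    vcf: str = ""
    traits_csv: str = ""
    out_dir: str = "results/pipeline"
    seed: int = 0
    # simulation
    sim_samples: int = 197
    sim_loci: int = 1000
    sim_pops: int = 3
    sim_divergence: float = 0.1
    sim_admixed_fraction: float = 0.3
    sim_missing_rate: float = 0.005
    sim_fail_fraction: float = 0.05
    sim_heritability: float = 0.3
    sim_n_causal: int = 1
    # filter thresholds (defaults = printed recipe)
    qd_min: float = 2.0
    mq_min: float = 40.0
    fs_max: float = 60.0
    sor_max: float = 3.0
    mqranksum_min: float = -12.5
    readposranksum_min: float = -8.0
    missing_rate_max: float = 0.20
    maf_min: float = 0.05
    hwe_p_min: float = 1e-4
    gq_min: float = 30.0
    post_mask_missing_max: float = 0.01
    depth_min: float = 3.0
    depth_max: float = 100.0
    # downstream
    gwas_threshold: float = 1e-3
    ld_max_markers: int = 1000
    ld_bin_width: float = 1000.0
    pca_components: int = 10
    qr_scale: int = 4

    def thresholds(self) -> snp_filter.FilterThresholds:
        return snp_filter.FilterThresholds(
            missing_rate_max=self.missing_rate_max,
            maf_min=self.maf_min,
            hwe_p_min=self.hwe_p_min,
            gq_min=self.gq_min,
            post_mask_missing_max=self.post_mask_missing_max,
            depth_range=(self.depth_min, self.depth_max),
        )

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in types:
                raise KeyError(f"unknown config key {key!r}")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                kwargs[key] = int(val)
            elif isinstance(current, float):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, n_qr: int | None = 12) -> dict:
    """Execute the whole pipeline; returns (and writes) the run manifest.

    ``n_qr`` limits how many accessions get a rendered QR image (None = all);
    the fingerprint codes themselves always cover every sample.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.hash(), "seed": config.seed,
                      "stages": {}, "outputs": {}}

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _checksum(path)}

    # stage 0: ingest or simulate
    if config.vcf:
        if not Path(config.vcf).exists():
            raise FileNotFoundError(f"input VCF not found: {config.vcf}")
        if config.traits_csv and not Path(config.traits_csv).exists():
            raise FileNotFoundError(f"traits file not found: {config.traits_csv}")
        matrix, ann = read_vcf(config.vcf)
        traits = (
            pd.read_csv(config.traits_csv, index_col=0) if config.traits_csv else None
        )
    else:
        sim_cfg = simdata.SimConfig(
            n_samples=config.sim_samples, n_loci=config.sim_loci,
            n_pops=config.sim_pops, divergence=config.sim_divergence,
            admixed_fraction=config.sim_admixed_fraction,
            missing_rate=config.sim_missing_rate, seed=config.seed,
        )
        matrix, truth = simdata.simulate_panel(sim_cfg)
        ann, planted = simdata.simulate_annotations(
            matrix, config.sim_fail_fraction, seed=config.seed + 1
        )
        traits, truth = simdata.simulate_phenotypes(
            matrix, truth, heritability=config.sim_heritability,
            n_categorical=3, n_causal=config.sim_n_causal, seed=config.seed + 2,
        )
        vcf_path = out / "panel.vcf"
        write_vcf(matrix, ann, vcf_path)
        traits.to_csv(out / "traits.csv")
        record("panel_vcf", vcf_path)
        record("traits_csv", out / "traits.csv")
        manifest["stages"]["simulate"] = {
            "n_samples": matrix.n_samples, "n_loci": matrix.n_loci,
            "planted_fail_sites": len(planted),
        }

    # stage 1: filter
    filtered, report = snp_filter.site_filters(matrix, ann, config.thresholds())
    report.to_json(out / "filter_report.json")
    record("filter_report", out / "filter_report.json")
    manifest["stages"]["filter"] = {
        "n_input": report.n_input, "n_output": report.n_output,
    }
    if filtered.n_loci == 0:
        raise RuntimeError("filter stage removed every site; nothing to analyse")

    # stage 2: spectrum + diversity
    spectrum = substitution_spectrum(filtered)
    manifest["stages"]["spectrum"] = {
        "n_transitions": spectrum.n_transitions,
        "n_transversions": spectrum.n_transversions,
        "tstv": None if np.isnan(spectrum.tstv) else round(spectrum.tstv, 4),
    }
    div = diversity.group_diversity(filtered)
    div.to_csv(out / "group_diversity.csv", index=False)
    record("group_diversity", out / "group_diversity.csv")
    if traits is not None:
        tsum = diversity.trait_summary_table(
            traits, continuous_traits={c for c in traits.columns
                                       if traits[c].dtype.kind == "f"}
        )
        tsum.to_csv(out / "trait_summary.csv", index=False)
        record("trait_summary", out / "trait_summary.csv")

    # stage 3: structure + LD
    pca = popstruct.geno_pca(filtered, n_components=config.pca_components)
    pd.DataFrame(
        pca.scores, index=filtered.samples["accession_id"],
        columns=[f"PC{i+1}" for i in range(pca.scores.shape[1])],
    ).to_csv(out / "pca_scores.csv")
    record("pca_scores", out / "pca_scores.csv")
    manifest["stages"]["pca"] = {
        "explained_pct": [round(float(e), 3) for e in pca.explained[:5]]
    }
    newick = popstruct.distance_upgma(filtered)
    (out / "upgma.nwk").write_text(newick + "\n")
    record("upgma_tree", out / "upgma.nwk")
    ld_pairs = popstruct.ld_scan(filtered, max_markers=config.ld_max_markers)
    decay = popstruct.ld_decay(ld_pairs, bin_width=config.ld_bin_width)
    decay.to_csv(out / "ld_decay.csv", index=False)
    record("ld_decay", out / "ld_decay.csv")
    manifest["stages"]["ld"] = {"n_pairs": int(len(ld_pairs))}

    # stage 4: GWAS on quantitative traits
    if traits is not None:
        quant = [c for c in traits.columns if traits[c].dtype.kind == "f"]
        hit_frames = []
        for t in quant:
            res = gwas.glm_scan(filtered, traits[t].reindex(
                filtered.samples["accession_id"]).to_numpy())
            hits = gwas.significant_hits(res, config.gwas_threshold, trait_name=t)
            hit_frames.append(hits)
        if hit_frames:
            all_hits = pd.concat(hit_frames, ignore_index=True)
            all_hits.to_csv(out / "gwas_hits.csv", index=False)
            record("gwas_hits", out / "gwas_hits.csv")
            manifest["stages"]["gwas"] = {
                "traits": quant, "n_hits": int(len(all_hits))
            }

    # stage 5: core-marker selection
    core = coreset.greedy_core_select(filtered)
    core.to_frame(filtered).to_csv(out / "core_markers.csv", index=False)
    record("core_markers", out / "core_markers.csv")
    codes = coreset.fingerprint_codes(filtered, core.locus_ids) if core.size \
        else None
    manifest["stages"]["core_select"] = {
        "n_core_markers": core.size,
        "n_unresolved_groups": len(core.unresolved_groups),
    }

    # stage 6: fingerprints + QR map
    if codes is not None and traits is not None:
        disc = coreset.discrimination_report(codes)
        manifest["stages"]["fingerprint"] = {
            "resolution_rate": disc["resolution_rate"]
        }
        codes.to_frame().to_csv(out / "fingerprint_codes.csv")
        record("fingerprint_codes", out / "fingerprint_codes.csv")
        records = fingerprint.build_records(codes, traits)
        subset = records if n_qr is None else records[:n_qr]
        fingerprint.export_map(subset, out / "fingerprint_map",
                               scale=config.qr_scale)
        record("fingerprint_map", out / "fingerprint_map" / "fingerprint_map.csv")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
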