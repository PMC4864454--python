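"""Stage orchestration: each stage is a pure function of (inputs, config,
seed) that writes TSV/BED/JSON artefacts plus a manifest with parameters,
seeds and input checksums."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import bootstrap as bt
from . import calling, clusters, io, motifs, regions, simulate
from .errors import ConfigError


@dataclass
class RunConfig:
    """Pipeline parameters; defaults follow the published analysis where
    it states them (50 bp chaining, 10 bp complex exclusion, p thresholds
    0.01 / 0.0001, 10 kb local context, 90 kb blocks, 100 randomised
    sets, 10,000 bootstrap replicates)."""

    outdir: str = "a3gscan_out"
    max_spacing: int = 50
    min_spacing_complex: int = 10
    p_threshold: float = 0.01
    p_threshold_strict: float = 0.0001
    motif_panel: list[str] = field(default_factory=lambda: [
        f"{m.pattern}:{m.mutated_index}:{m.label}" for m in motifs.DEFAULT_PANEL])
    background: str = "genomic"
    local_context_window: int = 10_000
    block_size: int = 90_000
    n_random_sets: int = 100
    n_boot: int = 10_000
    seed: int = 0
    confidence_thresholds: list[float] = field(
        default_factory=lambda: [0.05, 0.01, 0.001, 0.0001])
    simulation: dict = field(default_factory=dict)
    lineage: str = "target"

    def validate(self) -> None:
        if not 0 < self.p_threshold <= 1 or not 0 < self.p_threshold_strict <= 1:
            raise ConfigError("p_threshold values must lie in (0, 1]")
        if self.background not in ("genomic", "random_mutations",
                                   "random_clusters", "local_context"):
            raise ConfigError(f"unknown background {self.background!r}")
        for spec in self.motif_panel:
            motifs.parse_motif(spec)  # raises on malformed specs
        simulate.SimulationConfig.from_dict(self.simulation)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def motifs(self) -> list[motifs.Motif]:
        return [motifs.parse_motif(s) for s in self.motif_panel]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: Path, stage: str, params: dict, inputs: Sequence[Path]) -> Path:
    manifest = {
        "stage": stage,
        "parameters": params,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
    }
    path = outdir / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path


def run_simulate(config: RunConfig) -> dict[str, Path]:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg = simulate.SimulationConfig.from_dict(
        {"seed": config.seed, **config.simulation})
    sim = simulate.simulate(sim_cfg)
    paths = io.write_fixture(sim, outdir / "fixture")
    write_manifest(outdir, "simulate", sim_cfg.to_dict(), [])
    return paths


def run_call(config: RunConfig, alignment: Path, masks: Sequence[Path] = ()) -> Path:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln = (io.read_alignment_maf(alignment) if str(alignment).endswith(".maf")
           else io.read_alignment_fasta(alignment))
    mask_frames = [io.read_bed(p) for p in masks]
    muts, callable_length = calling.call_mutations(aln, mask_frames,
                                                   lineage=config.lineage)
    out = outdir / "mutations.tsv"
    io.write_mutations(muts, out)
    write_manifest(outdir, "call",
                   {"callable_length": callable_length, "lineage": config.lineage},
                   [alignment, *masks])
    return out


def _load_call_stage(config: RunConfig) -> tuple[pd.DataFrame, int]:
    outdir = Path(config.outdir)
    mut_path = outdir / "mutations.tsv"
    manifest = outdir / "manifest_call.json"
    if not mut_path.exists() or not manifest.exists():
        raise ConfigError("cluster stage needs the call stage outputs "
                          "(mutations.tsv); run `a3gscan call` first")
    with open(manifest) as fh:
        callable_length = json.load(fh)["parameters"]["callable_length"]
    return io.read_mutations(mut_path), int(callable_length)


def run_cluster(config: RunConfig) -> Path:
    outdir = Path(config.outdir)
    muts, callable_length = _load_call_stage(config)
    cs = clusters.build_cluster_set(
        muts, callable_length, config.max_spacing, config.min_spacing_complex)
    cl_path = outdir / "clusters.tsv"
    cs.clusters.to_csv(cl_path, sep="\t", index=False)
    bed = cs.clusters.assign(
        name=cs.clusters["type"] + ":" + cs.clusters["k"].astype(str),
        score=-np.log10(np.clip(cs.clusters["p_value"], 1e-300, None)).round(3),
        end1=cs.clusters["end"] + 1)
    bed[["chrom", "start", "end1", "name", "score"]].to_csv(
        outdir / "clusters.bed", sep="\t", header=False, index=False)
    # audit trail: excluded complex clusters and mixed-ancestor N clusters
    cs.removed_complex.to_csv(outdir / "clusters_excluded_complex.tsv",
                              sep="\t", index=False)
    cs.removed_n.to_csv(outdir / "clusters_n_type.tsv", sep="\t", index=False)
    cs.mutations.to_csv(outdir / "mutations_clustered.tsv", sep="\t", index=False)
    write_manifest(outdir, "cluster", {
        "max_spacing": config.max_spacing,
        "min_spacing_complex": config.min_spacing_complex,
        "pi": cs.pi, "callable_length": callable_length,
    }, [outdir / "mutations.tsv"])
    return cl_path


def _load_cluster_set(config: RunConfig) -> clusters.ClusterSet:
    outdir = Path(config.outdir)
    needed = [outdir / "mutations_clustered.tsv", outdir / "clusters.tsv",
              outdir / "manifest_cluster.json"]
    if not all(p.exists() for p in needed):
        raise ConfigError("enrich stage needs the cluster stage outputs; "
                          "run `a3gscan cluster` first")
    with open(needed[2]) as fh:
        params = json.load(fh)["parameters"]
    muts = pd.read_csv(needed[0], sep="\t", dtype={"chrom": str})
    cl = pd.read_csv(needed[1], sep="\t", dtype={"chrom": str})
    return clusters.ClusterSet(muts, cl, int(params["callable_length"]),
                               float(params["pi"]), int(params["max_spacing"]),
                               int(params["min_spacing_complex"]))


def _read_genome(path: Path) -> np.ndarray:
    aln = (io.read_alignment_maf(path) if str(path).endswith(".maf")
           else io.read_alignment_fasta(path))
    return aln.species["target"]


def run_enrich(config: RunConfig, genome_path: Path) -> Path:
    outdir = Path(config.outdir)
    cs = _load_cluster_set(config)
    genome = _read_genome(genome_path)
    cs_f = clusters.filter_by_pvalue(cs, config.p_threshold)
    results = motifs.motif_panel_enrichment(
        cs_f, genome, config.motifs(), background=config.background,
        n_sets=config.n_random_sets, seed=config.seed)
    rows = [dataclasses.asdict(r) for r in results]
    out = outdir / "enrichment.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    scan = motifs.trinucleotide_scan(cs_f, genome)
    scan.to_csv(outdir / "trinucleotide_scan.tsv", sep="\t", index=False)
    conf = motifs.enrichment_vs_confidence(cs, genome, config.confidence_thresholds)
    conf.table.assign(pearson_r=conf.r).to_csv(
        outdir / "enrichment_vs_confidence.tsv", sep="\t", index=False)
    write_manifest(outdir, "enrich", {
        "background": config.background, "p_threshold": config.p_threshold,
        "motifs": config.motif_panel, "seed": config.seed,
    }, [genome_path])
    return out


def run_regions(config: RunConfig, genome_path: Path,
                region_beds: Sequence[Path]) -> Path:
    outdir = Path(config.outdir)
    cs = _load_cluster_set(config)
    cs_f = clusters.filter_by_pvalue(cs, config.p_threshold)
    a3g = clusters.define_a3g_clusters(cs_f)
    a3g_ids = set(a3g.clusters["cluster_id"])
    m = cs.mutations
    a3g_set = m[m["cluster_id"].isin(a3g_ids)]
    control_set = m[~m["cluster_id"].isin(a3g_ids)]
    sets = [regions.RegionSet(Path(p).stem, io.read_bed(p)) for p in region_beds]
    results = regions.region_panel(a3g_set, control_set, sets)
    out = outdir / "region_enrichment.tsv"
    pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
        out, sep="\t", index=False)
    write_manifest(outdir, "regions", {
        "p_threshold": config.p_threshold, "regions": [str(p) for p in region_beds],
    }, [genome_path, *region_beds])
    return out


def run_bootstrap(config: RunConfig, genome_path: Path) -> Path:
    outdir = Path(config.outdir)
    cs = _load_cluster_set(config)
    genome = _read_genome(genome_path)
    cs_f = clusters.filter_by_pvalue(cs, config.p_threshold)
    bg = motifs.genomic_background(genome, motifs.A3G_CCC).ratio
    scheme = bt.make_blocks({cs.mutations["chrom"].iloc[0]: genome.size},
                            config.block_size)
    res = bt.bootstrap_enrichment_se(cs_f, bg, scheme,
                                     n_boot=config.n_boot, seed=config.seed)
    enr = pd.read_csv(outdir / "enrichment.tsv", sep="\t")
    enr.loc[enr["motif"] == motifs.A3G_CCC.label, "se"] = res.se
    enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    write_manifest(outdir, "bootstrap", {
        "block_size": config.block_size, "n_boot": config.n_boot,
        "seed": config.seed, "se": res.se,
        "ci": [res.ci_low, res.ci_high],
    }, [genome_path])
    return outdir / "enrichment.tsv"


def run_all(config: RunConfig) -> dict[str, Path]:
    """End-to-end run on a synthetic dataset defined by the config."""
    paths = run_simulate(config)
    aln = paths["alignment_fasta"]
    mask_beds = [p for k, p in paths.items() if k == "bed_repeat"]
    run_call(config, aln, mask_beds)
    run_cluster(config)
    run_enrich(config, aln)
    region_beds = [p for k, p in paths.items()
                   if k.startswith("bed_") and k != "bed_repeat"]
    if region_beds:
        run_regions(config, aln, region_beds)
    run_bootstrap(config, aln)
    return paths
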