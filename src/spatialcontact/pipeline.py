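"""End-to-end pipeline driver: synthesize -> domains -> expression ->
integrate, with a validated config and a reproducible run manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as sio
from .expression import cluster_de_genes
from .fourc_domains import detect_domains
from .spatial_integration import (
    chip_signal_in_domains,
    cluster_enrichment,
    gene_density,
)
from .synthetic_data import (
    CHIP_TIMEPOINTS,
    CONDITIONS,
    default_scenario,
    simulate_4c_counts,
    simulate_chip,
    simulate_expression,
    simulate_fragment_map,
    simulate_genes,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Tunables and provenance for a full pipeline run.

    The synthetic scenario supplies all inputs; every stochastic step
    derives from ``seed``.
    """

    seed: int = 0
    synthetic: bool = True
    window_bp: int = 100_000
    top_frac_cis: float = 0.10
    top_frac_trans: float = 0.05
    min_run: int = 16
    background: str = "adaptive"
    bait_exclusion_bp: int = 1_000_000
    fdr_permutations: int = 40
    alpha: float = 0.05
    lfc_min: float = 0.5
    k: int = 4
    scale_chip_by_library: bool = True
    domain_condition: str = "0h"

    def validate(self) -> None:
        if not 0 < self.top_frac_cis < 1:
            raise ValueError(f"top_frac_cis={self.top_frac_cis} not in (0, 1)")
        if not 0 < self.top_frac_trans < 1:
            raise ValueError(
                f"top_frac_trans={self.top_frac_trans} not in (0, 1)"
            )
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be non-negative")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.fdr_permutations < 1:
            raise ValueError("fdr_permutations must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.background not in ("uniform", "adaptive"):
            raise ValueError(f"unknown background {self.background!r}")

    @property
    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages in dependency order; return the run manifest.

    Every output file is recorded in the manifest with its sha256.  A
    stage failure raises :class:`PipelineError` naming the stage and
    leaves outputs of completed stages in place.
    """
    config.validate()
    if not config.synthetic:
        raise PipelineError(
            "setup", "file-driven runs go through the individual "
            "subcommands; run_pipeline drives the synthetic scenario"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def record(name: str, path: Path) -> None:
        outputs[name] = str(path.relative_to(outdir))

    scenario = default_scenario(seed=config.seed)

    # -- stage: synth ------------------------------------------------
    try:
        fragmap = simulate_fragment_map(scenario)
        profiles = simulate_4c_counts(scenario, fragmap)
        genes = simulate_genes(scenario, fragmap)
        counts, samples = simulate_expression(scenario, genes)
        chip = simulate_chip(scenario, fragmap)

        sio.write_chrom_sizes(scenario.chrom_lengths, outdir / "chrom.sizes")
        record("chrom_sizes", outdir / "chrom.sizes")
        from .fragment_map import write_fragment_map

        write_fragment_map(fragmap, outdir / "fragments.bed")
        record("fragments_bed", outdir / "fragments.bed")
        for cond, profile in profiles.items():
            p = outdir / f"counts_{cond}.tsv"
            sio.write_site_counts(profile, fragmap, p)
            record(f"counts_{cond}", p)
        sio.write_genes_tsv(genes, outdir / "genes.tsv")
        record("genes", outdir / "genes.tsv")
        counts.to_csv(outdir / "expression_counts.tsv", sep="\t")
        record("expression_counts", outdir / "expression_counts.tsv")
        samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        record("samples", outdir / "samples.tsv")
        for tp, track in chip.items():
            ip_p = outdir / f"chip_ip_{tp}.bedGraph"
            in_p = outdir / f"chip_input_{tp}.bedGraph"
            sio.write_chip_track(track, ip_p, in_p)
            record(f"chip_ip_{tp}", ip_p)
            record(f"chip_input_{tp}", in_p)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("synth", str(exc)) from exc

    # -- stage: domains ----------------------------------------------
    try:
        domain_sets = {}
        for cond, profile in profiles.items():
            dset = detect_domains(
                profile,
                fragmap,
                window_bp=config.window_bp,
                top_frac_cis=config.top_frac_cis,
                top_frac_trans=config.top_frac_trans,
                min_run=config.min_run,
                background=config.background,
                bait_exclusion_bp=config.bait_exclusion_bp,
                n_permutations=config.fdr_permutations,
                seed=config.seed,
            )
            domain_sets[cond] = dset
            bed = outdir / f"domains_{cond}.bed"
            sio.write_domains_bed(dset, bed)
            record(f"domains_{cond}", bed)
            sidecar = outdir / f"domains_{cond}.json"
            sio.write_domain_sidecar(dset, sidecar)
            record(f"domains_{cond}_sidecar", sidecar)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("domains", str(exc)) from exc

    # -- stage: expression -------------------------------------------
    try:
        tidy, labels, centroids = cluster_de_genes(
            counts,
            samples,
            k=config.k,
            seed=config.seed,
            alpha=config.alpha,
            lfc_min=config.lfc_min,
        )
        tidy.to_csv(outdir / "de.tsv", sep="\t", index=False)
        record("de", outdir / "de.tsv")
        labels.rename("cluster").to_frame().to_csv(
            outdir / "clusters.tsv", sep="\t"
        )
        record("clusters", outdir / "clusters.tsv")
        centroids.to_csv(outdir / "cluster_centroids.tsv", sep="\t")
        record("cluster_centroids", outdir / "cluster_centroids.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("expression", str(exc)) from exc

    # -- stage: integrate --------------------------------------------
    try:
        genome_size = sum(scenario.chrom_lengths.values())
        dset = domain_sets[config.domain_condition]
        density = gene_density(dset, genes, genome_size)
        pd.DataFrame(
            [
                {
                    "bait": scenario.bait_id,
                    "condition": config.domain_condition,
                    "density_in_domains": density.density_in_domains,
                    "density_genome": density.density_genome,
                }
            ]
        ).to_csv(outdir / "gene_density.tsv", sep="\t", index=False)
        record("gene_density", outdir / "gene_density.tsv")

        genes_labelled = genes.drop(columns=["cluster"]).merge(
            labels.rename("cluster"),
            left_on="gene_id",
            right_index=True,
            how="left",
        )
        enr = cluster_enrichment({scenario.bait_id: dset}, genes_labelled)
        enr.to_csv(outdir / "cluster_enrichment.tsv", sep="\t", index=False)
        record("cluster_enrichment", outdir / "cluster_enrichment.tsv")

        ratios = chip_signal_in_domains(
            chip, dset, scale_by_library=config.scale_chip_by_library
        )
        ratios.to_csv(outdir / "chip_ratios.tsv", sep="\t", index=False)
        record("chip_ratios", outdir / "chip_ratios.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("integrate", str(exc)) from exc

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash,
        "outputs": outputs,
        "checksums": {
            name: sio.sha256(outdir / rel) for name, rel in outputs.items()
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest


def run_from_manifest(manifest_path: str | Path, outdir: str | Path) -> dict:
    """Replay a run from its manifest alone."""
    manifest = json.loads(Path(manifest_path).read_text())
    config = PipelineConfig(**manifest["config"])
    return run_pipeline(config, outdir)
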