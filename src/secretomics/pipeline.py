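"""End-to-end orchestration with a declarative config and a run manifest.

A run executes the stages in dependency order -- simulate (or load inputs),
normalize, classify secreted proteins, build the differential table, cluster
and render the heatmap, screen the genome for binding motifs, compute ddCt
expression and growth rates -- and writes every output under one run
directory together with a manifest recording parameters, seeds and SHA-256
hashes of all outputs.  Identical config and seed give identical hashes.
Parameters whose defaults are methodological choices rather than data-driven
values are logged with an explicit "assumption" tag.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cluster import clustermap, linkage_frame
from .matrix import DEFAULT_TOTAL, SpectralCountMatrix
from .motifs import read_gff_genes, screen_genome
from .normalize import normalize_counts
from .qpcr import delta_delta_ct, expression_table
from .growth import GrowthCurve, growth_rate
from .secretion import SecretionClassifier, differential_table
from .simulate import (
    GenomeSimConfig,
    SecretomeSimConfig,
    generate_ct_table,
    generate_genome_with_motifs,
    generate_growth_curve,
    generate_secretome_dataset,
    write_secretome_dataset,
)

logger = logging.getLogger(__name__)

ASSUMPTIONS = {
    "ratio_threshold": "support threshold supernatant/cytosol ratio; not stated by the study design",
    "min_conditions": "conditions required for probability 1; not stated by the study design",
    "pseudocount": "cytosol reference for supernatant-only loci; not stated by the study design",
    "detection_floor": "raw spectra needed for presence; integer-count convention",
    "metric": "heatmap distance metric; only the linkage method is prescribed",
    "window": "upstream promoter window in bp; not stated by the study design",
    "max_mismatches": "block-position mismatch budget for motif scanning",
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclasses.dataclass
class PipelineConfig:
    out_dir: str = "run"
    seed: int = 0
    total: float = DEFAULT_TOTAL
    # secretion rule
    ratio_threshold: float = 1.0
    min_conditions: int = 2
    pseudocount: float = 0.5
    detection_floor: float = 1.0
    # clustering
    metric: str = "euclidean"
    # motif screening
    patterns: list[str] = dataclasses.field(
        default_factory=lambda: ["TACTN3AGTA", "TATCACN5GTGATA"]
    )
    window: int = 300
    max_mismatches: int = 2
    # inputs: either simulate=True (synthetic defaults) or explicit paths
    simulate: bool = True
    counts: str | None = None
    samples: str | None = None
    annotations: str | None = None
    genome: str | None = None
    gff: str | None = None
    ct_table: str | None = None
    growth_curve: str | None = None
    # simulation knobs (used when simulate=True)
    n_proteins: int = 200
    secreted_fraction: float = 0.165
    enrichment: float = 8.0
    dropout: float = 0.1
    sim_genome_length: int = 60_000
    # qPCR contrast
    qpcr_condition: str = "treatment"
    qpcr_control: str = "control"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.total <= 0:
            raise ValueError("total must be > 0")
        if self.min_conditions < 1:
            raise ValueError("min_conditions must be >= 1")
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if not self.simulate:
            for key in ("counts", "samples"):
                if getattr(self, key) is None:
                    raise ValueError(f"config requires '{key}' when simulate is false")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key, why in ASSUMPTIONS.items():
        logger.info("assumption: %s=%r (%s)", key, getattr(config, key, None), why)

    stage = "setup"
    outputs: dict[str, Path] = {}
    summary: dict = {}
    try:
        # -- inputs -------------------------------------------------------
        stage = "simulate" if config.simulate else "load-inputs"
        if config.simulate:
            sim = generate_secretome_dataset(
                SecretomeSimConfig(
                    n_proteins=config.n_proteins,
                    secreted_fraction=config.secreted_fraction,
                    enrichment=config.enrichment,
                    dropout=config.dropout,
                    seed=config.seed,
                )
            )
            matrix, annotations = sim.counts, sim.annotations
            outputs.update(write_secretome_dataset(sim, out / "inputs"))
            summary["n_true_secreted"] = int(sim.truth["secreted"].sum())
        else:
            matrix = SpectralCountMatrix.from_tsv(config.counts, config.samples)
            annotations = (
                pd.read_csv(config.annotations, sep="\t", index_col=0)
                if config.annotations
                else None
            )

        # -- normalization ---------------------------------------------
        stage = "normalize"
        normalized = normalize_counts(matrix, total=config.total)
        path = out / "normalized_counts.tsv"
        normalized.counts.to_csv(path, sep="\t", index_label="locus")
        outputs["normalized_counts"] = path

        # -- secretion calls --------------------------------------------
        stage = "secretome"
        clf = SecretionClassifier(
            ratio_threshold=config.ratio_threshold,
            min_conditions=config.min_conditions,
            pseudocount=config.pseudocount,
            detection_floor=config.detection_floor,
            total=config.total,
        ).fit(normalized, annotations=annotations)
        path = out / "secretion_calls.tsv"
        clf.calls_frame().to_csv(path, sep="\t")
        outputs["secretion_calls"] = path
        summary["n_secreted_called"] = clf.n_secreted_

        stage = "differential-table"
        table = differential_table(clf.calls_, normalized)
        path = out / "differential_table.tsv"
        table.to_csv(path, sep="\t", index_label="locus")
        outputs["differential_table"] = path

        # -- clustered heatmap -------------------------------------------
        stage = "heatmap"
        if len(table) >= 2:
            result = clustermap(
                table, metric=config.metric, out_image=out / "heatmap.png"
            )
            result.matrix.to_csv(out / "heatmap_matrix.tsv", sep="\t", index_label="locus")
            linkage_frame(result.row_linkage).to_csv(
                out / "row_linkage.tsv", sep="\t", index=False
            )
            outputs["heatmap_matrix"] = out / "heatmap_matrix.tsv"
            outputs["row_linkage"] = out / "row_linkage.tsv"
            outputs["heatmap_png"] = out / "heatmap.png"

        # -- motif screening ----------------------------------------------
        stage = "motifscan"
        if config.simulate:
            gsim = generate_genome_with_motifs(
                GenomeSimConfig(
                    length=config.sim_genome_length,
                    planted=[
                        ("TATCACN5GTGATA", 10_000, "+", "SYNGENE_0001"),
                        ("TACTN3AGTA", 25_000, "-", "SYNGENE_0002"),
                    ],
                    seed=config.seed,
                )
            )
            genome, genes = gsim.sequences, gsim.genes
            gsim.write(out / "genome.fasta", out / "genes.gff3", out / "motif_truth.tsv")
            outputs["genome"] = out / "genome.fasta"
            outputs["genes"] = out / "genes.gff3"
            outputs["motif_truth"] = out / "motif_truth.tsv"
        elif config.genome and config.gff:
            genome, genes = config.genome, read_gff_genes(config.gff)
        else:
            genome = None
        if genome is not None:
            report = screen_genome(
                genome, genes, config.patterns,
                window=config.window, max_mismatches=config.max_mismatches,
            )
            report.hits_frame().to_csv(out / "motif_hits.tsv", sep="\t", index=False)
            report.per_gene.to_csv(out / "motif_per_gene.tsv", sep="\t")
            outputs["motif_hits"] = out / "motif_hits.tsv"
            outputs["motif_per_gene"] = out / "motif_per_gene.tsv"
            summary["n_motif_hits"] = len(report.hits)

        # -- qPCR ----------------------------------------------------------
        stage = "qpcr"
        if config.simulate:
            ct = generate_ct_table({"SYN_TARGET": 4.0}, sd=0.2, seed=config.seed)
        elif config.ct_table:
            ct = pd.read_csv(config.ct_table, sep="\t")
        else:
            ct = None
        if ct is not None:
            targets = sorted(ct.loc[ct["role"] == "target", "gene"].unique())
            results = [
                delta_delta_ct(ct, t, config.qpcr_condition, config.qpcr_control)
                for t in targets
            ]
            path = out / "expression.tsv"
            expression_table(results).to_csv(path, sep="\t", index=False)
            outputs["expression"] = path

        # -- growth --------------------------------------------------------
        stage = "growth"
        if config.simulate:
            curve = generate_growth_curve(
                n0=1e6, rate=0.79, hours=8.0, noise_cv=0.05, seed=config.seed
            )
        elif config.growth_curve:
            gdf = pd.read_csv(config.growth_curve, sep="\t")
            curve = GrowthCurve(gdf["time_h"].to_numpy(), gdf["cells_per_ml"].to_numpy())
        else:
            curve = None
        if curve is not None:
            gr = growth_rate(curve)
            path = out / "growth_rate.tsv"
            pd.DataFrame(
                [{"rate_per_h": gr.rate, "generation_time_h": gr.generation_time,
                  "window_start_h": gr.window[0], "window_end_h": gr.window[1]}]
            ).to_csv(path, sep="\t", index=False)
            outputs["growth_rate"] = path
            summary["growth_rate_per_h"] = gr.rate
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "assumptions": ASSUMPTIONS,
        "summary": summary,
        "outputs": {
            name: {"path": str(p.relative_to(out)), "sha256": _sha256(p)}
            for name, p in sorted(outputs.items())
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
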