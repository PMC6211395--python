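"""Pipeline orchestration: configuration, stage wiring and report bundle.

A run takes one or more mapped-read libraries plus a genome and annotation
tracks, and produces plain-TSV reports: per-library cluster tables, a class
count table, nucleotide-bias matrices with signature calls, cumulative
structure-significance curves, a genomic-context table and a co-expression
link table.  Every stage parameter and seed is logged; identical
configuration and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

from . import (
    classification,
    clustering,
    coexpression,
    genomic_context,
    io_model,
    read_processing,
    signatures,
    structure,
)

logger = logging.getLogger("srnaclassify")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All stage parameters; serialisable to a plain key = value text file.

    ``reads`` entries are ``name:stage:path``; ``annot`` entries are
    ``element_class=path``.  Both keys may repeat in the file.  Unknown keys
    are rejected.
    """

    reads: list[str] = field(default_factory=list)
    genome: str = ""
    annot: list[str] = field(default_factory=list)
    out_dir: str = "srna_out"
    read_format: str = "tsv"

    max_mappings: int = 50
    rrna_stranded: bool = False

    window: int = 150
    min_distinct: int = 3
    min_cluster_len: int = 51
    hu_threshold: float = 3.0

    preset: str = "nonbilaterian"

    weight_by_count: bool = True
    u1_min: float = signatures.DEFAULT_U1_MIN
    a10_min: float = signatures.DEFAULT_A10_MIN

    n_shuffles: int = 100
    fold_backend: str = "auto"
    local_span: int = 150
    max_fold_span: int = 2000

    min_fraction: float = 0.51
    min_expression: int = 1
    top_n_scaffolds: int = 0  # 0 = all scaffolds

    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        known = {f.name: f for f in fields(cls)}
        kwargs: dict = {"reads": [], "annot": []}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}:{lineno}: expected key = value")
                key, value = (s.strip() for s in line.split("=", 1))
                if key not in known:
                    raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
                f = known[key]
                if key in ("reads", "annot"):
                    kwargs[key].append(value)
                elif f.type in ("int", int):
                    kwargs[key] = int(value)
                elif f.type in ("float", float):
                    kwargs[key] = float(value)
                elif f.type in ("bool", bool):
                    kwargs[key] = value.lower() in ("1", "true", "yes")
                else:
                    kwargs[key] = value
        return cls(**kwargs)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                value = getattr(self, f.name)
                if f.name in ("reads", "annot"):
                    for entry in value:
                        fh.write(f"{f.name} = {entry}\n")
                else:
                    fh.write(f"{f.name} = {value}\n")

    def parsed_reads(self) -> list[tuple[str, str, str]]:
        out = []
        for entry in self.reads:
            parts = entry.split(":", 2)
            if len(parts) != 3:
                raise ConfigError(f"reads entry {entry!r} is not name:stage:path")
            out.append(tuple(parts))
        return out

    def parsed_annot(self) -> dict[str, str]:
        out = {}
        for entry in self.annot:
            if "=" not in entry:
                raise ConfigError(f"annot entry {entry!r} is not class=path")
            cls, path = entry.split("=", 1)
            if cls not in io_model.ELEMENT_CLASSES:
                raise ConfigError(f"unknown annotation class {cls!r}")
            out[cls] = path
        return out


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle; returns output paths."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("configuration: %s", dataclasses.asdict(config))

    class_config = classification.get_preset(config.preset)
    genome = io_model.read_genome(config.genome)
    glens = io_model.genome_lengths(genome)
    tracks = {
        cls: io_model.read_annotation(path, element_class=cls)
        for cls, path in config.parsed_annot().items()
    }

    outputs: dict[str, Path] = {}
    clusters_by_library: dict[str, list] = {}
    clusters_by_stage: dict[str, list] = {}

    for name, stage, path in config.parsed_reads():
        logger.info("library %s (stage %s): %s", name, stage, path)
        raw = io_model.read_mapped_reads(path, config.read_format)
        filtered = read_processing.filter_multimappers(raw, config.max_mappings)
        reads = filtered.all_reads
        if "rRNA" in tracks:
            reads = read_processing.exclude_rrna(
                reads, tracks["rRNA"], config.rrna_stranded
            )
        library = io_model.Library(name, stage, reads)
        depth = library.depth
        clusters = clustering.build_clusters(
            reads, config.window, config.min_distinct, config.min_cluster_len
        )
        classification.classify_clusters(
            clusters, class_config, tracks, config.hu_threshold
        )
        for c in clusters:
            c.ui_normalized = clustering.normalize_ui(c.ui, depth) if depth else None
        clusters_by_library[name] = clusters
        clusters_by_stage[stage] = clusters
        logger.info("library %s: %d reads -> %d clusters", name, len(reads), len(clusters))

    # class table
    table = classification.tabulate_classes(clusters_by_library)
    outputs["class_table"] = out_dir / "class_table.tsv"
    table.to_csv(outputs["class_table"], sep="\t")

    all_clusters = [c for cs in clusters_by_library.values() for c in cs]

    # bias matrices and signature calls per class
    sig_rows = []
    for cls in ("endo_siRNA", "piRNA", "mer25"):
        reads = [r for c in all_clusters if c.label == cls for r in c.reads]
        if not reads:
            continue
        bias = signatures.positional_bias(reads, config.weight_by_count)
        path = out_dir / f"bias_{cls}.tsv"
        signatures.write_bias_matrix(bias, path)
        outputs[f"bias_{cls}"] = path
        pp = signatures.detect_ping_pong(bias, config.u1_min, config.a10_min)
        dg = signatures.detect_downstream_g(bias)
        sig_rows.append(
            {
                "class": cls,
                "ping_pong": pp.positive,
                "u1_pct": round(pp.summary["u1_pct"], 2),
                "a10_pct": round(pp.summary["a10_pct"], 2),
                "downstream_g": dg.positive,
                "g_status": dg.summary.get("status"),
            }
        )
    import pandas as pd

    outputs["signatures"] = out_dir / "signatures.tsv"
    pd.DataFrame(sig_rows).to_csv(outputs["signatures"], sep="\t", index=False)

    # structure: strand-resolved fold + shuffle test per cluster
    backend = structure.resolve_backend(config.fold_backend)
    logger.info("folding backend: %s, %d shuffles", backend, config.n_shuffles)
    for i, c in enumerate(sorted(all_clusters, key=lambda c: (c.scaffold, c.start))):
        if c.span > config.max_fold_span:
            continue
        cluster_seed = (config.seed * 1_000_003 + i) % (2**31)
        structure.fold_cluster(
            c, genome, config.n_shuffles, cluster_seed, config.local_span, backend
        )
    curves = structure.structure_enrichment_curves(all_clusters)
    outputs["structure_curves"] = out_dir / "structure_curves.tsv"
    curves.to_csv(outputs["structure_curves"], sep="\t")

    # genomic context
    masked = genomic_context.mask_genic_by_transposon(tracks)
    by_class: dict[str, list] = {}
    for c in all_clusters:
        assignment = genomic_context.assign_context(c, masked, config.min_fraction)
        by_class.setdefault(c.label or "unclassified", []).append(assignment)
    summary = genomic_context.context_summary(by_class)
    coverage = genomic_context.genome_coverage(
        {k: v for k, v in masked.items() if k in genomic_context.CONTEXT_CLASSES},
        glens,
    )
    outputs["context_table"] = out_dir / "context_table.tsv"
    with open(outputs["context_table"], "w") as fh:
        summary.to_csv(fh, sep="\t")
        fh.write("#genome_coverage\n")
        coverage.to_csv(fh, sep="\t")

    # per-library cluster reports (after fold/context so columns are filled)
    for name, clusters in clusters_by_library.items():
        path = out_dir / f"clusters_{name}.tsv"
        io_model.write_cluster_report(
            sorted(clusters, key=lambda c: (c.scaffold, c.start)), path
        )
        outputs[f"clusters_{name}"] = path

    # co-expression links across stages
    links = coexpression.coexpression_links(
        clusters_by_stage, config.min_expression
    )
    if config.top_n_scaffolds:
        links = coexpression.restrict_to_scaffolds(
            links, glens, config.top_n_scaffolds
        )
    outputs["links"] = out_dir / "links.tsv"
    coexpression.write_links(links, outputs["links"])

    logger.info("wrote %d report files to %s", len(outputs), out_dir)
    return outputs
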