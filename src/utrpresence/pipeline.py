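"""End-to-end pipeline: presence table -> PT_50 -> per-timepoint GSEA ->
random-subset resampling, with a reproducibility manifest.
"""
from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import yaml

from . import __version__, io
from .enrichment import GseaConfig, run_gsea
from .expression import ExpressionMatrix
from .resampling import pt50_significance
from .site_presence import (
    DEFAULT_MIN_EXPRESSED_DEPTH,
    build_pt50,
    classify_bins,
    load_transcripts,
    site_presence,
)
from .types import GeneSet, InputError

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds of one full analysis run."""

    annotation: str = ""
    sites: str = ""
    coverage: str = ""
    expression: str = ""
    samplesheet: str = ""
    presence_calls: str = ""  # optional detection-call matrix
    out_dir: str = "utrpresence_out"
    min_expressed_depth: float = DEFAULT_MIN_EXPRESSED_DEPTH
    pt50_threshold: float = 0.5
    gsea: GseaConfig = field(default_factory=GseaConfig)
    resample_B: int = 1000
    resample_R: int = 20
    resample_timepoint: int = 72
    seed: int = 0

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gsea = GseaConfig(**raw.pop("gsea", {}))
        return cls(gsea=gsea, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gsea"] = self.gsea.to_dict()
        return d


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run presence -> PT_50 -> GSEA -> resampling and write a report bundle.

    Fails before any computation if an input path is missing, and raises
    a reconciliation error when annotation and expression matrices share
    no gene identifiers. Returns the manifest dictionary.
    """
    inputs = {
        "annotation": cfg.annotation,
        "sites": cfg.sites,
        "coverage": cfg.coverage,
        "expression": cfg.expression,
        "samplesheet": cfg.samplesheet,
    }
    if cfg.presence_calls:
        inputs["presence_calls"] = cfg.presence_calls
    for name, path in inputs.items():
        if not path:
            raise InputError(f"pipeline config is missing the {name} path")
        io.file_exists(path)
    os.makedirs(cfg.out_dir, exist_ok=True)

    models, dropped = load_transcripts(cfg.annotation, cfg.sites)
    cov = io.read_bedgraph(cfg.coverage)
    presences = [site_presence(m, cov, cfg.min_expressed_depth) for m in models]
    counts = classify_bins(presences)
    n_expressed = sum(p.expressed for p in presences)
    log.info(
        "presence: %d genes, %d expressed, bins %s, %d dropped sites",
        len(presences), n_expressed, counts, len(dropped),
    )
    presence_path = os.path.join(cfg.out_dir, "presence.tsv")
    io.write_presence_table(presences, presence_path)

    pt = GeneSet("PT", [p.gene_id for p in presences])
    pt50 = build_pt50(presences, cfg.pt50_threshold)
    log.info("PT %d genes -> PT_50 %d genes", len(pt), len(pt50))
    gmt_path = os.path.join(cfg.out_dir, "pt50.gmt")
    io.write_gmt([pt, pt50], gmt_path)

    expr = io.read_expression(
        cfg.expression, cfg.samplesheet, cfg.presence_calls or None
    )
    shared = set(expr.genes) & set(pt.members)
    if not shared:
        examples = sorted(pt.members)[:5]
        raise InputError(
            "no shared gene identifiers between annotation and expression "
            f"universes (e.g. annotation ids {examples})"
        )

    gsea_report = {}
    for tp in expr.timepoints():
        sub = expr.subset_timepoint(tp)
        results = run_gsea(sub, None, [pt, pt50], cfg.gsea, seed=cfg.seed + tp)
        gsea_report[str(tp)] = [r.to_dict() for r in results]
    gsea_path = os.path.join(cfg.out_dir, "gsea.json")
    with open(gsea_path, "w") as fh:
        json.dump(gsea_report, fh, indent=2)

    sub = expr.subset_timepoint(cfg.resample_timepoint)
    outcome = pt50_significance(
        pt, pt50, sub, None, B=cfg.resample_B, R=cfg.resample_R,
        config=cfg.gsea, seed=cfg.seed,
    )
    resample_path = os.path.join(cfg.out_dir, "resample.json")
    with open(resample_path, "w") as fh:
        json.dump(outcome.to_dict(), fh, indent=2)

    manifest = {
        "package": "utrpresence",
        "version": __version__,
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "inputs_sha256": {k: io.sha256_of(v) for k, v in inputs.items()},
        "gene_counts": {
            "total": len(presences),
            "expressed": n_expressed,
            "bins": counts,
            "pt50": len(pt50),
            "dropped_sites": len(dropped),
        },
        "outputs": {
            "presence": presence_path,
            "gene_sets": gmt_path,
            "gsea": gsea_path,
            "resample": resample_path,
        },
    }
    manifest_path = os.path.join(cfg.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
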