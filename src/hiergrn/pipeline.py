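"""End-to-end pipeline: DEG calling -> GRN assembly -> GO enrichment.

A :class:`PipelineConfig` (typically loaded from YAML) names the inputs
and thresholds; :func:`run_pipeline` produces a deterministic artifact
directory (DEG table, network exports, summary JSON, enrichment TSV and
a log recording every threshold and stage count).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as hio
from .deg import call_degs, deg_union
from .enrichment import AnnotationMap, enrich
from .grn import GRNParams, HierarchicalGRNModel, summarize_grn

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All pipeline settings; unknown keys are rejected at load time."""

    expression: str = ""
    tf_list: str = ""
    annotation: str | None = None
    out_dir: str = "hiergrn_out"
    control_time: float = 0.0
    fdr_max: float = 0.05
    fc_up: float = 1.5
    fc_down: float = 0.66
    r_min: float = 0.8
    p_max: float = 0.001
    partial_max: float = 0.3
    use_absolute_r: bool = False
    collapse_replicates: bool = False
    enrichment_mode: str = "central"
    enrichment_fdr: float = 0.05
    go_subset_terms: list[str] = field(default_factory=list)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        # validate thresholds eagerly, before any computation
        GRNParams(r_min=self.r_min, p_max=self.p_max,
                  partial_max=self.partial_max, use_absolute_r=self.use_absolute_r)
        if not (0 < self.fdr_max < 1):
            raise ValueError("fdr_max must be in (0, 1)")
        if self.fc_up <= 1 or not (0 < self.fc_down < 1):
            raise ValueError("require fc_up > 1 and 0 < fc_down < 1")
        if self.enrichment_mode not in ("central", "wallenius"):
            raise ValueError("enrichment_mode must be 'central' or 'wallenius'")
        if self.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ValueError(f"unknown log level {self.log_level!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"{path}: unknown config keys: {unknown}")
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run DEG calling, GRN assembly and (optionally) enrichment.

    Returns the artifact directory.  Outputs are deterministic for a
    fixed config: deg_table.tsv, grn.sif, grn.graphml, grn_edges.tsv,
    summary.json, enrichment.tsv (when annotation given), pipeline.log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("hiergrn")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(getattr(logging, config.log_level.upper()))
    try:
        return _run(config, out)
    finally:
        root.removeHandler(handler)
        root.setLevel(old_level)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> Path:
    stage = "read inputs"
    try:
        matrix = hio.read_expression_tsv(config.expression)
        tf_list = hio.read_gene_list(config.tf_list)
        logger.info("inputs: %d genes x %d samples, %d TFs listed",
                    matrix.n_genes, matrix.n_samples, len(tf_list))

        stage = "differential expression"
        logger.info("DEG thresholds: fdr<%s, fc>%s or fc<%s vs control %sh",
                    config.fdr_max, config.fc_up, config.fc_down, config.control_time)
        deg_table = call_degs(
            matrix, control_time=config.control_time,
            fdr_max=config.fdr_max, fc_up=config.fc_up, fc_down=config.fc_down,
        )
        hio.write_deg_table(deg_table, out / "deg_table.tsv")
        degs = deg_union(deg_table)
        tf_degs = sorted(degs & set(tf_list))
        struct_degs = sorted(degs - set(tf_list))
        logger.info("DEG union: %d genes (%d TFs, %d structural)",
                    len(degs), len(tf_degs), len(struct_degs))

        stage = "GRN assembly"
        logger.info("GRN thresholds: r_min=%s p_max=%s partial_max=%s absolute_r=%s",
                    config.r_min, config.p_max, config.partial_max, config.use_absolute_r)
        model = HierarchicalGRNModel(matrix, tf_degs, struct_degs)
        results = model.fit(
            r_min=config.r_min, p_max=config.p_max, partial_max=config.partial_max,
            use_absolute_r=config.use_absolute_r,
            collapse_replicates=config.collapse_replicates,
        )
        grn = results.network
        for fmt, name in (("sif", "grn.sif"), ("graphml", "grn.graphml"),
                          ("tsv", "grn_edges.tsv")):
            hio.write_network(grn, fmt, out / name)

        stage = "GO enrichment"
        annotation = None
        if config.annotation:
            annotation = AnnotationMap.from_tsv(config.annotation)
            universe = [g for g in matrix.gene_ids if annotation.terms_for(g)]
            enr_degs = [g for g in sorted(degs) if g in set(universe)]
            if enr_degs:
                enr = enrich(enr_degs, universe, annotation,
                             fdr_max=config.enrichment_fdr, mode=config.enrichment_mode)
                enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
                logger.info("enrichment: %d terms tested, %d enriched at fdr<%s",
                            len(enr), int(enr.enriched.sum()), config.enrichment_fdr)

        stage = "summary"
        summary = summarize_grn(
            grn,
            annotation.gene_terms if annotation else None,
            subset_terms=config.go_subset_terms or None,
        )
        payload = summary.to_dict()
        payload["n_degs"] = len(degs)
        payload["n_tf_degs"] = len(tf_degs)
        payload["n_structural_degs"] = len(struct_degs)
        payload["two_layer_warning"] = grn.two_layer_warning
        payload["dropped_tfs"] = sorted(grn.dropped_tfs)
        payload["thresholds"] = {
            "fdr_max": config.fdr_max, "fc_up": config.fc_up, "fc_down": config.fc_down,
            "r_min": config.r_min, "p_max": config.p_max,
            "partial_max": config.partial_max, "use_absolute_r": config.use_absolute_r,
        }
        hio.write_json(payload, out / "summary.json")
        logger.info("network: layers %s/%s/%s, edges %s + %s = %s",
                    summary.n_layer1, summary.n_layer2, summary.n_layer3,
                    summary.n_edges_12, summary.n_edges_23, summary.total_edges)
        return out
    except Exception as exc:
        logger.error("pipeline aborted at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
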