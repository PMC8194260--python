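"""End-to-end workflow: catalog filter → per-study effects → cross-study
combination → covariate regression → direction classification → enrichment →
gene–gene network, with a manifest for reproducibility.

File conventions: the data directory holds ``<dataset_id>.tsv`` (matrix) and
``<dataset_id>_labels.tsv`` per retained catalog entry. All stage outputs
are TSV; networks additionally GraphML.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import yaml

from . import __version__
from .covariates import covariate_table
from .effects import StudyEffect
from .enrichment import (
    build_ggi,
    enrichment_to_frame,
    fisher_enrichment,
    ggi_to_frame,
    write_ggi_graphml,
)
from .io import (
    ExpressionDataset,
    filter_dataset_catalog,
    read_catalog,
    read_expression_matrix,
    read_gmt,
    read_relations,
)
from .mega import MegaAnalysis
from .relations import (
    EXPRESSION,
    EntityVerdict,
    assemble_network,
    classify_expression_direction,
    signed_map,
    verdicts_to_frame,
)

__all__ = ["PipelineConfig", "run_pipeline", "load_pipeline_config"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run."""

    catalog: str
    data_dir: str
    gmt: str | None = None
    relations: str | None = None
    genes: str | None = None  # optional newline-separated gene panel
    alpha: float = 0.05
    fdr_q: float = 0.05
    ggi_threshold: float = 0.001
    ggi_use: str = "p"
    model: str = "auto"
    mlr_mode: str = "univariate"
    resolve_conflicts: str = "error"
    upstream: str = "AD"
    downstream: str = "MDD"
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("alpha", "fdr_q", "ggi_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


def load_pipeline_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__ if f != "extra"}
    kwargs = {k: v for k, v in raw.items() if k in known}
    extra = {k: v for k, v in raw.items() if k not in known}
    return PipelineConfig(**kwargs, extra=extra)


def _load_datasets(cfg: PipelineConfig) -> list[ExpressionDataset]:
    catalog = filter_dataset_catalog(read_catalog(cfg.catalog))
    datasets = []
    for meta in catalog:
        mat = os.path.join(cfg.data_dir, f"{meta.dataset_id}.tsv")
        lab = os.path.join(cfg.data_dir, f"{meta.dataset_id}_labels.tsv")
        datasets.append(
            read_expression_matrix(mat, lab, dataset_id=meta.dataset_id, metadata=meta)
        )
    return datasets


def run_pipeline(cfg: PipelineConfig, out_dir: str) -> dict[str, str]:
    """Run every stage, writing one table per stage into ``out_dir``.

    Returns a mapping stage → output path. Any stage failure is re-raised
    with the stage name attached. Deterministic given inputs and config.
    """
    os.makedirs(out_dir, exist_ok=True)
    outputs: dict[str, str] = {}

    def stage(name: str):
        class _Stage:
            def __enter__(self_inner):
                return None

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                return False

        return _Stage()

    with stage("load"):
        datasets = _load_datasets(cfg)
        panel = None
        if cfg.genes:
            with open(cfg.genes) as fh:
                panel = [ln.strip() for ln in fh if ln.strip()]

    with stage("mega"):
        res = MegaAnalysis(
            datasets, genes=panel, alpha=cfg.alpha, model=cfg.model
        ).fit()
        mega_path = os.path.join(out_dir, "mega_table.tsv")
        res.to_tsv(mega_path)
        outputs["mega"] = mega_path
        sig = res.significant()

    with stage("mlr"):
        metas = [ds.metadata for ds in datasets]
        eff = res.model.effects
        by_gene = {
            g: [
                StudyEffect(r.dataset_id, g, r.lfc, r.variance, int(r.n_case), int(r.n_control))
                for r in grp.itertuples()
            ]
            for g, grp in eff[eff["variance"] > 0].groupby("gene")
            if g in set(sig["gene"])
        }
        mlr = covariate_table(by_gene, metas, mode=cfg.mlr_mode)
        mlr_path = os.path.join(out_dir, "covariates.tsv")
        mlr.to_csv(mlr_path, sep="\t", index=False)
        outputs["mlr"] = mlr_path

    network_genes: set[str] = set(sig["gene"])
    if cfg.relations:
        with stage("classify"):
            relations = read_relations(cfg.relations)
            lit = assemble_network(
                relations,
                upstream=cfg.upstream,
                downstream=cfg.downstream,
                resolve=cfg.resolve_conflicts,
            )
            mdd_signs = signed_map(
                relations,
                role="regulators",
                anchor=cfg.downstream,
                resolve=cfg.resolve_conflicts,
            )
            expr_verdicts = []
            for row in sig.itertuples():
                key = " ".join(str(row.gene).strip().split()).lower()
                if key in mdd_signs and row.effect != 0:
                    sign, etype = mdd_signs[key]
                    expr_verdicts.append(
                        EntityVerdict(
                            row.gene,
                            etype or "gene",
                            1 if row.effect > 0 else -1,
                            sign,
                            classify_expression_direction(row.effect, sign),
                            source=EXPRESSION,
                        )
                    )
            verdicts = lit + expr_verdicts
            vpath = os.path.join(out_dir, "verdicts.tsv")
            verdicts_to_frame(verdicts).to_csv(vpath, sep="\t", index=False)
            outputs["classify"] = vpath
            network_genes |= {
                v.entity for v in verdicts if (v.entity_type or "gene") == "gene"
            }

    if cfg.gmt:
        with stage("pea"):
            collection = read_gmt(cfg.gmt)
            results = fisher_enrichment(network_genes, collection)
            pea_path = os.path.join(out_dir, "pea.tsv")
            enrichment_to_frame(results).to_csv(pea_path, sep="\t", index=False)
            outputs["pea"] = pea_path
        with stage("ggi"):
            edges = build_ggi(results, threshold=cfg.ggi_threshold, use=cfg.ggi_use)
            epath = os.path.join(out_dir, "ggi_edges.tsv")
            ggi_to_frame(edges).to_csv(epath, sep="\t", index=False)
            gpath = os.path.join(out_dir, "ggi.graphml")
            write_ggi_graphml(edges, gpath)
            outputs["ggi"] = epath
            outputs["ggi_graphml"] = gpath

    with stage("manifest"):
        manifest = {
            "version": __version__,
            "config": asdict(cfg),
            "outputs": outputs,
            "n_datasets": len(datasets),
            "n_genes_combined": len(res.table),
            "n_significant": int(len(sig)),
        }
        mpath = os.path.join(out_dir, "manifest.json")
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        outputs["manifest"] = mpath

    return outputs
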