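"""Synthetic multi-study expression data, relation tables and gene-set
collections with recorded ground truth.

The expression generator mirrors the statistical structure the combination
engine assumes: gene g's study-level effect in study i is

    θ_gi = LFC_g + δ_gi,   δ_gi ~ Normal(0, τ²)

and each sample's log2 expression is Normal(baseline + group·θ_gi, σ²),
group being 1 for cases and 0 for controls. Study-level covariates (total
sample size, country drawn from a fixed four-country cycle, study age) can
shift θ_gi linearly to plant covariate signal. By default the nine-study
design (sample sizes, countries, study ages) follows the published
case/control catalog in :mod:`megadeg.datasets`.

Relation-table and gene-set generators plant a known overlap / enrichment
and return the truth alongside the data, so network assembly and
over-representation testing can be checked end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import example_catalog
from .io import CASE, CONTROL, DatasetMeta, ExpressionDataset, GeneSet, RelationRecord

__all__ = [
    "SimulationConfig",
    "simulate_studies",
    "simulate_relations",
    "simulate_genesets",
    "COUNTRY_CYCLE",
]

#: Fixed country cycle used when studies outnumber the published catalog.
COUNTRY_CYCLE = ["United States", "Sweden", "Germany", "Japan"]


@dataclass
class SimulationConfig:
    """Study design and noise model for the expression generator.

    ``true_lfc`` may be a scalar (shared by all genes) or a per-gene vector.
    ``n_case``/``n_control`` may be ints (same for every study) or per-study
    lists; when None, the nine published studies' counts (and their
    countries, ages and ids) are used. ``tau2`` is the between-study effect
    variance, ``sigma`` the per-sample noise SD on the log2 scale.
    ``covariate_effects`` maps covariate name ("n_total", "study_age") to a
    slope added to θ_gi.
    """

    n_studies: int = 9
    n_genes: int = 203
    n_case: int | list[int] | None = None
    n_control: int | list[int] | None = None
    true_lfc: float | np.ndarray = 0.0
    tau2: float = 0.0
    sigma: float = 1.0
    baseline: float = 8.0
    covariate_effects: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def resolve_design(self) -> list[DatasetMeta]:
        """Per-study metadata implied by the config."""
        catalog = example_catalog()
        metas = []
        for i in range(self.n_studies):
            if self.n_case is None and i < len(catalog):
                base = catalog[i]
                n_case, n_control = base.n_case, base.n_control
                country, age, sid = base.country, base.study_age, base.dataset_id
                platform = base.platform
            else:
                n_case = (
                    self.n_case[i] if isinstance(self.n_case, list) else (self.n_case or 10)
                )
                n_control = (
                    self.n_control[i]
                    if isinstance(self.n_control, list)
                    else (self.n_control or 10)
                )
                country = COUNTRY_CYCLE[i % len(COUNTRY_CYCLE)]
                age, sid, platform = float(1 + i), f"SIM{i + 1:03d}", "SIMARRAY"
            if n_case < 2 or n_control < 2:
                raise ValueError("each group needs >=2 samples")
            metas.append(
                DatasetMeta(
                    dataset_id=sid,
                    n_control=n_control,
                    n_case=n_case,
                    country=country,
                    study_age=age,
                    organism="Homo sapiens",
                    platform=platform,
                    data_type="microarray expression profiling",
                    comparison="AD vs healthy controls",
                    downloadable=True,
                )
            )
        return metas

    def resolve_lfc(self) -> np.ndarray:
        lfc = np.asarray(self.true_lfc, dtype=float)
        if lfc.ndim == 0:
            lfc = np.full(self.n_genes, float(lfc))
        if lfc.shape != (self.n_genes,):
            raise ValueError("true_lfc must be scalar or length n_genes")
        return lfc


def simulate_studies(
    cfg: SimulationConfig,
) -> tuple[list[ExpressionDataset], pd.DataFrame]:
    """Generate the multi-study panel and its ground-truth table.

    Returns the datasets and a truth frame with one row per (gene, study):
    gene, dataset_id, true_lfc, theta (the realised study-level effect).
    Reproducible given ``cfg.seed``.
    """
    if cfg.tau2 < 0 or cfg.sigma <= 0:
        raise ValueError("tau2 must be >=0 and sigma > 0")
    rng = np.random.default_rng(cfg.seed)
    metas = cfg.resolve_design()
    lfc = cfg.resolve_lfc()
    genes = [f"G{j + 1:05d}" for j in range(cfg.n_genes)]

    datasets, truth_rows = [], []
    for meta in metas:
        delta = (
            rng.normal(0.0, np.sqrt(cfg.tau2), cfg.n_genes)
            if cfg.tau2 > 0
            else np.zeros(cfg.n_genes)
        )
        theta = lfc + delta
        shift = sum(
            slope * getattr(meta, cov)
            for cov, slope in cfg.covariate_effects.items()
        )
        theta = theta + shift
        n_ca, n_co = meta.n_case, meta.n_control
        ctrl = rng.normal(cfg.baseline, cfg.sigma, size=(cfg.n_genes, n_co))
        case = rng.normal(
            cfg.baseline + theta[:, None], cfg.sigma, size=(cfg.n_genes, n_ca)
        )
        cols = [f"{meta.dataset_id}_ctrl{j + 1}" for j in range(n_co)] + [
            f"{meta.dataset_id}_case{j + 1}" for j in range(n_ca)
        ]
        mat = pd.DataFrame(
            np.hstack([ctrl, case]), index=pd.Index(genes, name="gene_id"), columns=cols
        )
        groups = {c: (CONTROL if "_ctrl" in c else CASE) for c in cols}
        datasets.append(ExpressionDataset(meta.dataset_id, mat, groups, meta))
        truth_rows.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "dataset_id": meta.dataset_id,
                    "true_lfc": lfc,
                    "theta": theta,
                }
            )
        )
    return datasets, pd.concat(truth_rows, ignore_index=True)


def simulate_relations(
    n_entities: int = 60,
    p_polarity_missing: float = 0.2,
    p_favor: float = 15 / 18,
    seed: int = 0,
    n_overlap: int = 18,
    upstream: str = "AD",
    downstream: str = "MDD",
) -> tuple[list[RelationRecord], dict[str, int]]:
    """Random signed relation table with a planted shared-regulator overlap.

    Of ``n_entities`` entities, ``n_overlap`` are planted as both targets of
    the upstream disease and regulators of the downstream one, with
    round(p_favor·n_overlap) of them favoring the downstream disease (sign
    product +1). The remaining entities get one-sided relations as decoys,
    each losing its polarity with probability ``p_polarity_missing``; when
    ``p_polarity_missing`` is 1 every relation, planted included, is
    unsigned. Truth counts report what filter→intersect should recover.
    """
    if not (0 <= p_polarity_missing <= 1 and 0 <= p_favor <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if n_overlap > n_entities:
        raise ValueError("n_overlap cannot exceed n_entities")
    rng = np.random.default_rng(seed)
    types = ["gene", "small molecule", "functional class", "cell"]
    entities = [f"E{j + 1:03d}" for j in range(n_entities)]
    n_favor = int(round(p_favor * n_overlap))
    all_unsigned = p_polarity_missing >= 1.0

    relations: list[RelationRecord] = []
    for j, ent in enumerate(entities):
        etype = types[j % len(types)]
        n_refs = int(rng.integers(1, 30))
        if j < n_overlap:
            ad_sign = int(rng.choice([1, -1]))
            mdd_sign = ad_sign if j < n_favor else -ad_sign
            if all_unsigned:
                ad_sign = mdd_sign = 0
            relations.append(
                RelationRecord(upstream, "disease", ent, ad_sign, n_refs)
            )
            relations.append(
                RelationRecord(ent, etype, downstream, mdd_sign, n_refs)
            )
        else:
            # decoy: one-sided relation, possibly unsigned
            sign = int(rng.choice([1, -1]))
            if all_unsigned or rng.random() < p_polarity_missing:
                sign = 0
            if rng.random() < 0.5:
                relations.append(RelationRecord(upstream, "disease", ent, sign, n_refs))
            else:
                relations.append(RelationRecord(ent, etype, downstream, sign, n_refs))
    truth = {
        "n_overlap": 0 if all_unsigned else n_overlap,
        "n_favor": 0 if all_unsigned else n_favor,
        "n_oppose": 0 if all_unsigned else n_overlap - n_favor,
    }
    return relations, truth


def simulate_genesets(
    n_sets: int = 50,
    set_size_range: tuple[int, int] = (10, 40),
    planted_query: list[str] | None = None,
    planted_sets: int = 0,
    seed: int = 0,
    n_background: int = 1000,
    planted_fraction: float = 0.8,
) -> tuple[list[GeneSet], dict]:
    """Random gene-set collection with optionally planted enrichment.

    The universe holds ``n_background`` genes plus the planted query. The
    first ``planted_sets`` sets receive round(planted_fraction·|query|)
    query genes plus random fillers; the rest are uniform draws. Truth lists
    the planted set ids.
    """
    if planted_sets > n_sets:
        raise ValueError("planted_sets cannot exceed n_sets")
    rng = np.random.default_rng(seed)
    universe = [f"B{j + 1:05d}" for j in range(n_background)]
    query = list(planted_query or [])
    pool = sorted(set(universe) | set(query))
    lo, hi = set_size_range
    sets, planted_ids = [], []
    for s in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        sid = f"SET{s + 1:04d}"
        if s < planted_sets and query:
            n_hit = max(1, int(round(planted_fraction * len(query))))
            n_hit = min(n_hit, len(query), size)
            hits = list(rng.choice(query, size=n_hit, replace=False))
            fillers = [g for g in universe if g not in hits]
            rest = list(
                rng.choice(fillers, size=max(size - n_hit, 0), replace=False)
            )
            members = frozenset(hits + rest)
            planted_ids.append(sid)
        else:
            members = frozenset(rng.choice(pool, size=size, replace=False))
        sets.append(GeneSet(sid, f"simulated set {s + 1}", members))
    truth = {"planted_set_ids": planted_ids, "query": query}
    return sets, truth
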