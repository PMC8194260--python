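"""Per-study, per-gene effect sizes.

The effect size is the log2 fold-change (LFC): mean log2 expression in cases
minus mean log2 expression in controls. Its sampling variance is the
two-sample variance of a difference in means, s²_case/n_case +
s²_control/n_control with unbiased sample variances — the quantity
inverse-variance weighting needs downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CASE, CONTROL, ExpressionDataset

__all__ = [
    "StudyEffect",
    "GeneAbsentError",
    "DegenerateGroupError",
    "study_effect",
    "effects_for_gene",
    "study_effects_table",
    "effects_to_frame",
]


class GeneAbsentError(KeyError):
    """The requested gene is not measured in this dataset."""


class DegenerateGroupError(ValueError):
    """A group has fewer than two non-missing values; no variance estimable."""


@dataclass(frozen=True)
class StudyEffect:
    """One gene's effect in one study.

    ``variance`` may be exactly 0 when both groups are constant; such effects
    are flagged degenerate and excluded from inverse-variance combination.
    """

    dataset_id: str
    gene: str
    lfc: float
    variance: float
    n_case: int
    n_control: int

    @property
    def degenerate(self) -> bool:
        return not self.variance > 0.0


def _group_values(ds: ExpressionDataset, gene: str, group: str) -> np.ndarray:
    vals = ds.matrix.loc[gene, ds.samples_in_group(group)].to_numpy(dtype=float)
    return vals[np.isfinite(vals)]


def study_effect(ds: ExpressionDataset, gene: str) -> StudyEffect:
    """LFC (case − control) and its sampling variance for one gene.

    Raises :class:`GeneAbsentError` when the gene is not in the matrix and
    :class:`DegenerateGroupError` when either group has <2 non-missing
    values. Missing values are ignored within each group.
    """
    if gene not in ds.matrix.index:
        raise GeneAbsentError(gene)
    case = _group_values(ds, gene, CASE)
    ctrl = _group_values(ds, gene, CONTROL)
    if len(case) < 2 or len(ctrl) < 2:
        raise DegenerateGroupError(
            f"{ds.dataset_id}/{gene}: need >=2 non-missing values per group "
            f"(got {len(case)} case, {len(ctrl)} control)"
        )
    lfc = float(case.mean() - ctrl.mean())
    var = float(case.var(ddof=1) / len(case) + ctrl.var(ddof=1) / len(ctrl))
    return StudyEffect(ds.dataset_id, gene, lfc, var, len(case), len(ctrl))


def effects_for_gene(
    datasets: list[ExpressionDataset], gene: str
) -> list[StudyEffect]:
    """One StudyEffect per dataset where the gene is measurable, input order.

    Datasets where the gene is absent or a group is degenerate contribute
    nothing, so the result may be shorter than ``datasets``.
    """
    out = []
    for ds in datasets:
        try:
            out.append(study_effect(ds, gene))
        except (GeneAbsentError, DegenerateGroupError):
            continue
    return out


def study_effects_table(
    ds: ExpressionDataset, genes: list[str] | None = None
) -> pd.DataFrame:
    """Vectorised per-gene effects for one dataset.

    Returns a frame indexed by gene with columns lfc, variance, n_case,
    n_control, covering the genes with >=2 non-missing values in each group.
    Equivalent to calling :func:`study_effect` gene by gene.
    """
    mat = ds.matrix if genes is None else ds.matrix.loc[ds.matrix.index.intersection(genes)]
    case = mat[ds.case_samples].to_numpy(dtype=float)
    ctrl = mat[ds.control_samples].to_numpy(dtype=float)

    def _stats(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n = np.isfinite(x).sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(np.where(np.isfinite(x), x, np.nan), axis=1)
            var = np.nanvar(np.where(np.isfinite(x), x, np.nan), axis=1, ddof=1)
        return n, mean, var

    n_ca, m_ca, v_ca = _stats(case)
    n_co, m_co, v_co = _stats(ctrl)
    ok = (n_ca >= 2) & (n_co >= 2)
    df = pd.DataFrame(
        {
            "lfc": m_ca - m_co,
            "variance": v_ca / np.maximum(n_ca, 1) + v_co / np.maximum(n_co, 1),
            "n_case": n_ca,
            "n_control": n_co,
        },
        index=mat.index,
    )[ok]
    df.insert(0, "dataset_id", ds.dataset_id)
    return df


def effects_to_frame(effects: list[StudyEffect]) -> pd.DataFrame:
    """Flatten StudyEffects to the exportable per-study effect table."""
    return pd.DataFrame(
        [
            {
                "dataset_id": e.dataset_id,
                "gene": e.gene,
                "lfc": e.lfc,
                "variance": e.variance,
                "n_case": e.n_case,
                "n_control": e.n_control,
            }
            for e in effects
        ],
        columns=["dataset_id", "gene", "lfc", "variance", "n_case", "n_control"],
    )
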