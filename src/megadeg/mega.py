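"""Cross-study combination of per-gene effect sizes.

For each gene the per-study log2 fold-changes θ_i with sampling variances v_i
are combined by inverse-variance weighting. Cochran's heterogeneity statistic

    Q = Σ w_i (θ_i − θ̂_fixed)²,  w_i = 1/v_i,  df = k − 1

drives model selection: when Q ≤ df the between-study heterogeneity
percentage ISq = 100·(Q − df)/Q is set to 0 and the fixed-effect estimate is
reported; otherwise a DerSimonian–Laird random-effects model is fitted, with

    τ² = max(0, (Q − df)/C),  C = Σ w_i − Σ w_i² / Σ w_i

and weights 1/(v_i + τ²). Q-p is the upper-tail chi-square probability of Q
on df degrees of freedom — the probability that the observed total variance
arose from within-study variance alone. The combined effect's p-value is the
two-sided normal tail of effect/se.

The module exposes both the per-gene primitives (:func:`fixed_effect_combine`,
:func:`heterogeneity`, :func:`random_effects_combine`, :func:`mega_analyze`)
and a model/results pair (:class:`MegaAnalysis` → :class:`MegaAnalysisResults`)
covering a whole gene panel across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .effects import StudyEffect, study_effects_table
from .io import ExpressionDataset

__all__ = [
    "MegaResult",
    "fixed_effect_combine",
    "heterogeneity",
    "q_p_value",
    "random_effects_combine",
    "mega_analyze",
    "mega_table",
    "MegaAnalysis",
    "MegaAnalysisResults",
    "FIXED",
    "RANDOM",
]

FIXED = "fixed"
RANDOM = "random"


@dataclass(frozen=True)
class MegaResult:
    """Combined result for one gene.

    ``model`` is ``"fixed"`` exactly when Q ≤ df (in which case ISq = 0 and
    τ² = 0). ``p_underflow`` marks p-values that underflowed double
    precision and are reported as 0.
    """

    gene: str
    n_study: int
    effect: float
    se: float
    p_value: float
    Q: float
    df: int
    ISq: float
    Q_p: float
    model: str
    tau2: float

    @property
    def p_underflow(self) -> bool:
        return self.p_value == 0.0

    @property
    def random_flag(self) -> int:
        """1 when the random-effects model was selected, else 0."""
        return int(self.model == RANDOM)


def _weights_and_theta(effects: list[StudyEffect]) -> tuple[np.ndarray, np.ndarray]:
    if not effects:
        raise ValueError("need at least one study effect")
    v = np.array([e.variance for e in effects], dtype=float)
    if np.any(v <= 0):
        bad = [e.dataset_id for e, vv in zip(effects, v) if vv <= 0]
        raise ValueError(f"non-positive effect variance in studies: {bad}")
    theta = np.array([e.lfc for e in effects], dtype=float)
    return 1.0 / v, theta


def _combine(w: np.ndarray, theta: np.ndarray) -> tuple[float, float, float]:
    effect = float(np.sum(w * theta) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    p = float(2.0 * stats.norm.sf(abs(effect) / se))
    return effect, se, p


def fixed_effect_combine(effects: list[StudyEffect]) -> tuple[float, float, float]:
    """Inverse-variance fixed-effect combination: (effect, se, p)."""
    w, theta = _weights_and_theta(effects)
    return _combine(w, theta)


def heterogeneity(
    effects: list[StudyEffect], fixed_effect: float
) -> tuple[float, int, float]:
    """Cochran's Q, its degrees of freedom, and the heterogeneity percent ISq.

    ISq = 100·(Q − df)/Q when Q exceeds df, else 0.
    """
    if len(effects) < 2:
        raise ValueError("heterogeneity needs at least two studies")
    w, theta = _weights_and_theta(effects)
    Q = float(np.sum(w * (theta - fixed_effect) ** 2))
    df = len(effects) - 1
    ISq = 100.0 * (Q - df) / Q if Q > df else 0.0
    return Q, df, ISq


def q_p_value(Q: float, df: int) -> float:
    """Upper-tail chi-square probability of Q on df degrees of freedom."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(Q, df))


def random_effects_combine(
    effects: list[StudyEffect],
) -> tuple[float, float, float, float]:
    """DerSimonian–Laird random-effects combination: (effect, se, p, tau2).

    With τ² = 0 (Q ≤ df) this reduces exactly to the fixed-effect result.
    """
    if len(effects) < 2:
        raise ValueError("random-effects combination needs at least two studies")
    w, theta = _weights_and_theta(effects)
    fe = float(np.sum(w * theta) / np.sum(w))
    Q = float(np.sum(w * (theta - fe) ** 2))
    df = len(effects) - 1
    C = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (Q - df) / C)
    w_star = 1.0 / (1.0 / w + tau2)
    effect, se, p = _combine(w_star, theta)
    return effect, se, p, tau2


def mega_analyze(effects: list[StudyEffect], model: str = "auto") -> MegaResult:
    """Combine one gene's per-study effects under the Q-vs-df switch rule.

    ``model`` may force ``"fixed"`` or ``"random"``; the default ``"auto"``
    selects fixed when Q ≤ df and random otherwise.
    """
    if len(effects) < 2:
        raise ValueError("mega_analyze needs at least two studies")
    fe, fse, fp = fixed_effect_combine(effects)
    Q, df, ISq = heterogeneity(effects, fe)
    Qp = q_p_value(Q, df)
    if model == "auto":
        chosen = FIXED if Q <= df else RANDOM
    elif model in (FIXED, RANDOM):
        chosen = model
    else:
        raise ValueError(f"model must be auto/fixed/random, got {model!r}")
    if chosen == FIXED:
        effect, se, p, tau2 = fe, fse, fp, 0.0
    else:
        effect, se, p, tau2 = random_effects_combine(effects)
    gene = effects[0].gene
    return MegaResult(gene, len(effects), effect, se, p, Q, df, ISq, Qp, chosen, tau2)


# ---------------------------------------------------------------------------
# Panel-level model


class MegaAnalysis:
    """Cross-study combination model for a panel of genes.

    Built either from :class:`~megadeg.io.ExpressionDataset` objects (per-study
    effects are computed internally) or from a precomputed per-study effect
    table via :meth:`from_effects`. ``fit`` returns a
    :class:`MegaAnalysisResults` with one combined estimate per gene that is
    measurable (non-degenerate) in at least ``min_studies`` studies.

    Parameters
    ----------
    datasets
        Studies contributing effects.
    genes
        Panel to analyse; default: every gene present in any dataset.
    alpha
        Significance level for flagging genes (default 0.05).
    model
        "auto" (Q ≤ df → fixed, else random), or force "fixed"/"random".
    min_studies
        Minimum number of contributing studies per gene (>= 2; Q needs
        df ≥ 1).
    """

    def __init__(
        self,
        datasets: list[ExpressionDataset],
        genes: list[str] | None = None,
        alpha: float = 0.05,
        model: str = "auto",
        min_studies: int = 2,
    ) -> None:
        if min_studies < 2:
            raise ValueError("min_studies must be >= 2")
        frames = [study_effects_table(ds, genes) for ds in datasets]
        eff = pd.concat(frames) if frames else pd.DataFrame(
            columns=["dataset_id", "lfc", "variance", "n_case", "n_control"]
        )
        eff = eff.rename_axis("gene").reset_index()
        self._init_from_frame(eff, genes, alpha, model, min_studies)

    @classmethod
    def from_effects(
        cls,
        effects: pd.DataFrame,
        alpha: float = 0.05,
        model: str = "auto",
        min_studies: int = 2,
    ) -> "MegaAnalysis":
        """Build the model from a per-study effect table.

        ``effects`` needs columns gene, dataset_id, lfc, variance (n_case /
        n_control optional).
        """
        self = cls.__new__(cls)
        self._init_from_frame(effects.copy(), None, alpha, model, min_studies)
        return self

    def _init_from_frame(self, eff, genes, alpha, model, min_studies) -> None:
        required = {"gene", "dataset_id", "lfc", "variance"}
        missing = required - set(eff.columns)
        if missing:
            raise ValueError(f"effect table lacks columns: {sorted(missing)}")
        for col in ("n_case", "n_control"):
            if col not in eff.columns:
                eff[col] = 0
        self.effects = eff
        self.genes = genes
        self.alpha = alpha
        self.model = model
        self.min_studies = min_studies

    def fit(self) -> "MegaAnalysisResults":
        usable = self.effects[self.effects["variance"] > 0]
        results: list[MegaResult] = []
        for gene, grp in usable.groupby("gene", sort=True):
            if len(grp) < self.min_studies:
                continue
            effs = [
                StudyEffect(
                    r.dataset_id, gene, r.lfc, r.variance, int(r.n_case), int(r.n_control)
                )
                for r in grp.itertuples()
            ]
            results.append(mega_analyze(effs, model=self.model))
        return MegaAnalysisResults(self, results)


class MegaAnalysisResults:
    """Fitted panel results: per-gene combined effects and diagnostics.

    ``table`` holds one row per gene, sorted by p-value ascending with gene
    id as tie-break, in the export schema: gene, random (0/1), n_study,
    effect, se, p, Q, df, ISq, Q_p, tau2, significant.
    """

    def __init__(self, model: MegaAnalysis, results: list[MegaResult]) -> None:
        self.model = model
        self.results = {r.gene: r for r in results}
        rows = [
            {
                "gene": r.gene,
                "random": r.random_flag,
                "n_study": r.n_study,
                "effect": r.effect,
                "se": r.se,
                "p": r.p_value,
                "Q": r.Q,
                "df": r.df,
                "ISq": r.ISq,
                "Q_p": r.Q_p,
                "tau2": r.tau2,
            }
            for r in results
        ]
        tab = pd.DataFrame(
            rows,
            columns=[
                "gene", "random", "n_study", "effect", "se", "p",
                "Q", "df", "ISq", "Q_p", "tau2",
            ],
        )
        if len(tab):
            tab = tab.sort_values(["p", "gene"], kind="mergesort").reset_index(drop=True)
        tab["significant"] = tab["p"] < model.alpha
        self.table = tab

    def significant(self, alpha: float | None = None, method: str = "none") -> pd.DataFrame:
        """Rows flagged at level alpha, optionally Bonferroni/BH-corrected."""
        a = self.model.alpha if alpha is None else alpha
        t = self.table
        if method == "none":
            return t[t["p"] < a]
        if method == "bonferroni":
            return t[t["p"] < a / max(len(t), 1)]
        if method == "bh":
            from .enrichment import bh_fdr

            q = bh_fdr([max(p, np.nextafter(0, 1)) for p in t["p"]])
            return t[np.array(q) < a]
        raise ValueError(f"unknown correction method {method!r}")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        n_sig = int(self.table["significant"].sum())
        n_rand = int(self.table["random"].sum())
        lines = [
            "Cross-study mega-analysis of differential expression",
            f"genes combined: {len(self.table)}   "
            f"significant at alpha={self.model.alpha:g}: {n_sig}   "
            f"random-effects model selected: {n_rand}",
            "",
            self.table.to_string(
                index=False,
                float_format=lambda x: f"{x:.4g}",
                max_rows=40,
            ),
        ]
        return "\n".join(lines)


def mega_table(
    datasets: list[ExpressionDataset],
    genes: list[str] | None = None,
    alpha: float = 0.05,
    model: str = "auto",
) -> pd.DataFrame:
    """Fit the panel model and return its per-gene table (p-ascending)."""
    return MegaAnalysis(datasets, genes=genes, alpha=alpha, model=model).fit().table
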