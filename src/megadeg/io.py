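"""Readers and writers for expression matrices, study catalogs, gene sets and
signed relation tables.

Expression matrices are delimited text, genes (or probes) in rows with the
identifier in the first column and sample ids in the header. Group labels come
from a separate two-column file (``sample_id,group``) with groups ``case`` /
``control``. Study catalogs mirror the metadata columns a GEO-style survey
table carries (sample counts, country, study age, organism, platform, data
type, comparison, downloadability). Gene sets use the standard GMT dialect.
Relation tables are CSV with a textual polarity column that is mapped onto
{+1, -1, 0}.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "DatasetMeta",
    "GeneSet",
    "RelationRecord",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_labels",
    "write_labels",
    "collapse_probes",
    "read_catalog",
    "write_catalog",
    "filter_dataset_catalog",
    "read_gmt",
    "write_gmt",
    "read_relations",
    "write_relations",
    "LINEAR_SCALE_MAX",
]

#: Matrices whose maximum exceeds this are taken to be on a linear scale and
#: are log2(x+1)-transformed on read. Log2 microarray intensities live well
#: below 30; linear-scale values run into the thousands.
LINEAR_SCALE_MAX = 30.0

CASE = "case"
CONTROL = "control"
_VALID_GROUPS = frozenset({CASE, CONTROL})

_POLARITY_TOKENS = {"positive": 1, "negative": -1, "unknown": 0}


@dataclass
class DatasetMeta:
    """Study-level metadata for one expression dataset."""

    dataset_id: str = ""
    n_control: int = 0
    n_case: int = 0
    country: str = ""
    study_age: float = 0.0
    organism: str = ""
    platform: str = ""
    data_type: str = ""
    comparison: str = ""
    downloadable: bool = True

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_case < 0:
            raise ValueError(
                f"{self.dataset_id}: sample counts must be non-negative"
            )
        if self.study_age < 0:
            raise ValueError(f"{self.dataset_id}: study_age must be >= 0")

    @property
    def n_total(self) -> int:
        return self.n_control + self.n_case


@dataclass
class ExpressionDataset:
    """One study's log2 expression matrix with case/control sample labels.

    ``matrix`` is a genes-by-samples DataFrame; ``sample_groups`` maps every
    column of the matrix to ``"case"`` or ``"control"``.
    """

    dataset_id: str
    matrix: pd.DataFrame
    sample_groups: dict[str, str]
    metadata: DatasetMeta = field(default_factory=DatasetMeta)

    def __post_init__(self) -> None:
        for s in self.matrix.columns:
            if s not in self.sample_groups:
                raise ValueError(
                    f"sample {s!r} in matrix of {self.dataset_id!r} has no group label"
                )
            g = self.sample_groups[s]
            if g not in _VALID_GROUPS:
                raise ValueError(
                    f"sample {s!r}: group must be 'case' or 'control', got {g!r}"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.matrix.columns if self.sample_groups[s] == group]

    @property
    def case_samples(self) -> list[str]:
        return self.samples_in_group(CASE)

    @property
    def control_samples(self) -> list[str]:
        return self.samples_in_group(CONTROL)


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")


@dataclass(frozen=True)
class RelationRecord:
    """A directed, literature-curated regulation relation with a sign.

    ``polarity`` is +1 (activation/positive), -1 (inhibition/negative) or 0
    (relation reported without a sign). ``n_refs`` counts supporting
    references.
    """

    source: str
    source_type: str
    target: str
    polarity: int
    n_refs: int = 0
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.polarity not in (-1, 0, 1):
            raise ValueError(f"polarity must be in {{-1, 0, +1}}, got {self.polarity}")
        if self.n_refs < 0:
            raise ValueError("n_refs must be >= 0")


def _read_delimited(path: str | os.PathLike, index_col: int | None = 0) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=index_col)


def read_labels(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column sample_id,group file (header optional but expected)."""
    df = _read_delimited(path, index_col=None)
    if df.shape[1] < 2:
        raise ValueError(f"labels file {path} needs two columns (sample_id, group)")
    out: dict[str, str] = {}
    for sid, grp in zip(df.iloc[:, 0], df.iloc[:, 1]):
        g = str(grp).strip().lower()
        if g not in _VALID_GROUPS:
            raise ValueError(f"sample {sid!r}: group must be case/control, got {grp!r}")
        out[str(sid)] = g
    return out


def write_labels(groups: dict[str, str], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"sample_id": list(groups), "group": [groups[s] for s in groups]}
    ).to_csv(path, sep="," if str(path).endswith(".csv") else "\t", index=False)


def read_expression_matrix(
    path: str | os.PathLike,
    labels_path: str | os.PathLike,
    dataset_id: str | None = None,
    metadata: DatasetMeta | None = None,
) -> ExpressionDataset:
    """Read a genes-by-samples matrix plus its label file into a dataset.

    Non-numeric cells raise with the offending row/column; samples missing
    from the label file raise naming the sample. Matrices that look
    linear-scale (max value above :data:`LINEAR_SCALE_MAX`) are
    log2(x+1)-transformed so that all downstream effects are log2
    fold-changes.
    """
    raw = _read_delimited(path)
    mat = raw.apply(pd.to_numeric, errors="coerce")
    bad = mat.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {raw.iat[r, c]!r} at gene {mat.index[r]!r}, "
            f"sample {mat.columns[c]!r} in {path}"
        )
    groups = read_labels(labels_path)
    for s in mat.columns:
        if s not in groups:
            raise ValueError(f"sample {s!r} in matrix {path} is absent from labels")
    finite = mat.to_numpy()[np.isfinite(mat.to_numpy())]
    if finite.size and finite.max() > LINEAR_SCALE_MAX:
        mat = np.log2(mat + 1.0)
    if dataset_id is None:
        dataset_id = os.path.splitext(os.path.basename(str(path)))[0]
    meta = metadata or DatasetMeta(dataset_id=dataset_id)
    return ExpressionDataset(dataset_id, mat, {s: groups[s] for s in mat.columns}, meta)


def write_expression_matrix(ds: ExpressionDataset, path: str | os.PathLike) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    ds.matrix.to_csv(path, sep=sep, index_label="gene_id")


def collapse_probes(
    ds: ExpressionDataset,
    probe_map: dict[str, str] | pd.DataFrame,
    method: str = "max_mean",
) -> ExpressionDataset:
    """Collapse probe-level rows to one row per gene.

    ``max_mean`` keeps, per gene, the probe with the highest mean expression
    (ties broken lexicographically by probe id); ``average`` takes the
    per-sample mean across a gene's probes. Probes absent from the map are
    dropped.
    """
    if isinstance(probe_map, pd.DataFrame):
        probe_map = dict(zip(probe_map.iloc[:, 0].astype(str), probe_map.iloc[:, 1].astype(str)))
    mapped = [p for p in ds.matrix.index if p in probe_map]
    if not mapped:
        raise ValueError(
            f"{ds.dataset_id}: no probe in the matrix is covered by the probe map"
        )
    sub = ds.matrix.loc[mapped]
    gene_of = pd.Series([probe_map[p] for p in mapped], index=sub.index)
    if method == "max_mean":
        means = sub.mean(axis=1)
        rows = []
        for gene, probes in gene_of.groupby(gene_of):
            # highest mean wins; among ties the lexicographically first probe
            cand = sorted(probes.index, key=lambda p: (-means[p], p))
            rows.append((gene, cand[0]))
        rows.sort(key=lambda t: t[0])
        out = sub.loc[[p for _, p in rows]]
        out.index = pd.Index([g for g, _ in rows], name=ds.matrix.index.name)
    elif method == "average":
        out = sub.groupby(gene_of).mean()
        out = out.sort_index()
        out.index.name = ds.matrix.index.name
    else:
        raise ValueError(f"unknown collapse method {method!r}")
    return replace(ds, matrix=out)


_CATALOG_COLUMNS = [
    "dataset_id",
    "n_control",
    "n_case",
    "country",
    "study_age",
    "organism",
    "platform",
    "data_type",
    "comparison",
    "downloadable",
]


def read_catalog(path: str | os.PathLike) -> list[DatasetMeta]:
    df = _read_delimited(path, index_col=None)
    missing = [c for c in _CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"catalog {path} lacks columns: {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            DatasetMeta(
                dataset_id=str(row["dataset_id"]),
                n_control=int(row["n_control"]),
                n_case=int(row["n_case"]),
                country=str(row["country"]),
                study_age=float(row["study_age"]),
                organism=str(row["organism"]),
                platform=str(row["platform"]),
                data_type=str(row["data_type"]),
                comparison=str(row["comparison"]),
                downloadable=str(row["downloadable"]).strip().lower()
                in ("true", "1", "yes"),
            )
        )
    return out


def write_catalog(catalog: list[DatasetMeta], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [{c: getattr(m, c) for c in _CATALOG_COLUMNS} for m in catalog]
    ).to_csv(path, index=False)


#: Canonical values the inclusion criteria match against (case-insensitive).
INCLUSION_ORGANISM = "homo sapiens"
INCLUSION_DATA_TYPE = "microarray expression profiling"
INCLUSION_COMPARISON = "ad vs healthy controls"


def filter_dataset_catalog(catalog: list[DatasetMeta]) -> list[DatasetMeta]:
    """Apply the four study-inclusion criteria, preserving input order.

    A study is retained when it profiled Homo sapiens, is microarray
    expression profiling, compares disease cases against healthy controls,
    and its data were downloadable.
    """

    def keep(m: DatasetMeta) -> bool:
        return (
            m.organism.strip().lower() == INCLUSION_ORGANISM
            and m.data_type.strip().lower() == INCLUSION_DATA_TYPE
            and m.comparison.strip().lower() == INCLUSION_COMPARISON
            and m.downloadable
        )

    return [m for m in catalog if keep(m)]


def read_gmt(path: str | os.PathLike) -> list[GeneSet]:
    """Read a GMT gene-set collection (set_id TAB description TAB members...)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            sets.append(
                GeneSet(fields[0], fields[1], frozenset(f for f in fields[2:] if f))
            )
    return sets


def write_gmt(sets: list[GeneSet], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.name, *sorted(s.members)]) + "\n")


def read_relations(path: str | os.PathLike) -> list[RelationRecord]:
    """Read a signed relation table (CSV).

    Required columns: source, source_type, target, polarity, n_refs. The
    polarity column uses the tokens positive/negative/unknown; anything else
    raises. Extra columns are ignored except ``evidence``, which is carried
    through when present.
    """
    df = pd.read_csv(path)
    required = ["source", "source_type", "target", "polarity", "n_refs"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"relations file {path} lacks columns: {missing}")
    out = []
    for i, row in df.iterrows():
        token = str(row["polarity"]).strip().lower()
        if token not in _POLARITY_TOKENS:
            raise ValueError(
                f"{path} row {i}: unknown polarity token {row['polarity']!r}"
            )
        out.append(
            RelationRecord(
                source=str(row["source"]),
                source_type=str(row["source_type"]),
                target=str(row["target"]),
                polarity=_POLARITY_TOKENS[token],
                n_refs=int(row["n_refs"]),
                evidence=str(row["evidence"]) if "evidence" in df.columns else "",
            )
        )
    return out


def write_relations(relations: list[RelationRecord], path: str | os.PathLike) -> None:
    inv = {1: "positive", -1: "negative", 0: "unknown"}
    pd.DataFrame(
        [
            {
                "source": r.source,
                "source_type": r.source_type,
                "target": r.target,
                "polarity": inv[r.polarity],
                "n_refs": r.n_refs,
                "evidence": r.evidence,
            }
            for r in relations
        ]
    ).to_csv(path, index=False)
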