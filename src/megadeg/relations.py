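"""Assembly of the signed disease→entity→disease regulator network.

From a literature-curated relation table, keep only signed relations, build
two signed maps — entities the upstream disease (e.g. atopic dermatitis)
regulates, and entities that regulate the downstream disease (e.g. major
depressive disorder) — and intersect them. The direction of each shared
entity is the sign product: when the upstream disease pushes an entity in
the same direction as the entity pushes the downstream disease (both
positive, or both negative — deactivating an inhibitor), the change favors
the downstream disease; otherwise it opposes it.

The same sign-product rule classifies expression-derived evidence: a gene's
combined log2 fold-change in cases supplies the upstream sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .io import RelationRecord

__all__ = [
    "FAVORS",
    "OPPOSES",
    "EntityVerdict",
    "ConflictingPolarityError",
    "UndefinedDirectionError",
    "filter_polarity",
    "signed_map",
    "intersect_regulators",
    "classify_expression_direction",
    "assemble_network",
    "verdicts_to_frame",
    "verdicts_to_graph",
]

FAVORS = "favors_MDD"
OPPOSES = "opposes_MDD"

LITERATURE = "literature"
EXPRESSION = "expression"


class ConflictingPolarityError(ValueError):
    """An entity carries both polarities within one map."""


class UndefinedDirectionError(ValueError):
    """A zero effect size carries no direction."""


@dataclass(frozen=True)
class EntityVerdict:
    """One shared entity's direction of influence.

    ``ad_sign`` is the upstream disease's effect on the entity, ``mdd_sign``
    the entity's effect on the downstream disease; the verdict favors the
    downstream disease exactly when the signs agree.
    """

    entity: str
    entity_type: str
    ad_sign: int
    mdd_sign: int
    direction: str
    source: str = LITERATURE

    def __post_init__(self) -> None:
        if self.ad_sign not in (-1, 1) or self.mdd_sign not in (-1, 1):
            raise ValueError("signs must be +1 or -1")
        expected = FAVORS if self.ad_sign * self.mdd_sign == 1 else OPPOSES
        if self.direction != expected:
            raise ValueError(
                f"{self.entity}: direction {self.direction!r} inconsistent with signs"
            )


def filter_polarity(relations: list[RelationRecord]) -> list[RelationRecord]:
    """Drop relations without a sign (polarity 0), preserving order."""
    return [r for r in relations if r.polarity != 0]


def _canon(entity: str) -> str:
    """Case-insensitive, whitespace-normalised matching key."""
    return " ".join(entity.strip().split()).lower()


def signed_map(
    relations: list[RelationRecord],
    *,
    role: str,
    anchor: str,
    resolve: str = "error",
) -> dict[str, tuple[int, str]]:
    """Signed entity map from relations anchored at a disease.

    ``role="targets"`` collects entities the anchor regulates (anchor is the
    relation source); ``role="regulators"`` collects entities regulating the
    anchor (anchor is the target). Returns canonical entity key → (sign,
    entity_type); unsigned relations are ignored. Conflicting signs for one
    entity raise by default; ``resolve="majority"`` keeps the sign with the
    larger total reference count (ties raise).
    """
    if role not in ("targets", "regulators"):
        raise ValueError("role must be 'targets' or 'regulators'")
    anchor_key = _canon(anchor)
    votes: dict[str, dict[int, int]] = {}
    types: dict[str, str] = {}
    names: dict[str, str] = {}
    for r in filter_polarity(relations):
        if role == "targets":
            if _canon(r.source) != anchor_key:
                continue
            entity, etype = r.target, ""
        else:
            if _canon(r.target) != anchor_key:
                continue
            entity, etype = r.source, r.source_type
        key = _canon(entity)
        votes.setdefault(key, {1: 0, -1: 0})[r.polarity] += max(r.n_refs, 1)
        names.setdefault(key, entity)
        if etype:
            types.setdefault(key, etype)
    out: dict[str, tuple[int, str]] = {}
    conflicts = []
    for key, v in votes.items():
        if v[1] and v[-1]:
            if resolve == "majority" and v[1] != v[-1]:
                sign = 1 if v[1] > v[-1] else -1
            else:
                conflicts.append(names[key])
                continue
        else:
            sign = 1 if v[1] else -1
        out[key] = (sign, types.get(key, ""))
    if conflicts:
        raise ConflictingPolarityError(
            f"conflicting polarities for entities: {sorted(conflicts)}"
        )
    return out


def intersect_regulators(
    ad_targets: dict[str, int | tuple[int, str]],
    mdd_regulators: dict[str, int | tuple[int, str]],
) -> list[EntityVerdict]:
    """Verdicts for entities both regulated by the upstream disease and
    regulating the downstream one, ordered by entity id.

    Accepts plain sign maps (entity → ±1) or maps carrying (sign, type).
    """

    def norm(m):
        out = {}
        for k, v in m.items():
            sign, etype = (v, "") if isinstance(v, int) else v
            if sign not in (-1, 1):
                raise ValueError(f"{k!r}: sign must be +1 or -1, got {sign}")
            key = _canon(k)
            if key in out and out[key][0] != sign:
                raise ConflictingPolarityError(
                    f"conflicting duplicate signs for entity {k!r}"
                )
            out[key] = (sign, etype, k)
        return out

    a, b = norm(ad_targets), norm(mdd_regulators)
    verdicts = []
    for key in sorted(a.keys() & b.keys()):
        ad_sign, etype_a, name = a[key]
        mdd_sign, etype_b, _ = b[key]
        direction = FAVORS if ad_sign * mdd_sign == 1 else OPPOSES
        verdicts.append(
            EntityVerdict(name, etype_a or etype_b, ad_sign, mdd_sign, direction)
        )
    return verdicts


def classify_expression_direction(lfc: float, mdd_sign: int) -> str:
    """Direction of an expression change with respect to the downstream
    disease: favors it when sign(lfc) × mdd_sign = +1."""
    if mdd_sign not in (-1, 1):
        raise ValueError("mdd_sign must be +1 or -1")
    if lfc == 0:
        raise UndefinedDirectionError("zero log2 fold-change has no direction")
    return FAVORS if (1 if lfc > 0 else -1) * mdd_sign == 1 else OPPOSES


def assemble_network(
    relations: list[RelationRecord],
    upstream: str = "AD",
    downstream: str = "MDD",
    resolve: str = "error",
) -> list[EntityVerdict]:
    """Full assembly: polarity filter → signed maps → intersection."""
    ad_targets = signed_map(relations, role="targets", anchor=upstream, resolve=resolve)
    mdd_regs = signed_map(
        relations, role="regulators", anchor=downstream, resolve=resolve
    )
    return intersect_regulators(ad_targets, mdd_regs)


def verdicts_to_frame(verdicts: list[EntityVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "entity": v.entity,
                "entity_type": v.entity_type,
                "ad_sign": v.ad_sign,
                "mdd_sign": v.mdd_sign,
                "direction": v.direction,
                "source": v.source,
            }
            for v in verdicts
        ],
        columns=["entity", "entity_type", "ad_sign", "mdd_sign", "direction", "source"],
    )


def verdicts_to_graph(
    verdicts: list[EntityVerdict],
    upstream: str = "AD",
    downstream: str = "MDD",
) -> nx.DiGraph:
    """Bipartite signed graph upstream → entity → downstream."""
    g = nx.DiGraph()
    g.add_node(upstream, kind="disease")
    g.add_node(downstream, kind="disease")
    for v in verdicts:
        g.add_node(v.entity, kind=v.entity_type or "entity", direction=v.direction)
        g.add_edge(upstream, v.entity, sign=v.ad_sign)
        g.add_edge(v.entity, downstream, sign=v.mdd_sign)
    return g
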