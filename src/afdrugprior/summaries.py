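"""Summary structures behind the figures: the indication co-occurrence
matrix (chord-diagram input), the action-type dendrogram for high-priority
drugs, and the drugged-target trait partition.

Co-occurrence is counted at drug granularity — a drug indicated for two
specialties contributes one to their off-diagonal cell regardless of how
many trials back each indication — and diagonals count drugs per
specialty, so every entry is bounded by the smaller of its two diagonals.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field

from .types import (
    DrugTargetLink,
    IndicationRecord,
    PriorityScores,
    TargetProfile,
    Trait,
)


class IndicationAdjacency(BaseModel):
    """Square symmetric drug-count matrix over indication specialties."""

    categories: list[str]
    matrix: list[list[int]]

    def to_array(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=int)


class ActionTreeNode(BaseModel):
    """Node of the action-type dendrogram (root → action → class → target → drug)."""

    name: str
    kind: str  # root | action_type | target_class | target | drug
    children: list["ActionTreeNode"] = Field(default_factory=list)

    def leaves(self) -> list["ActionTreeNode"]:
        if not self.children:
            return [self] if self.kind == "drug" else []
        out = []
        for child in self.children:
            out.extend(child.leaves())
        return out


def indication_adjacency(
    indications: Sequence[IndicationRecord],
    drug_to_parent: Optional[Mapping[str, str]] = None,
) -> IndicationAdjacency:
    """Adjacency matrix of overlapping indications.

    ``drug_to_parent`` optionally collapses drug forms to parents before
    counting. Categories are ordered by descending diagonal count, then
    alphabetically; the matrix is symmetric with diagonal (i, i) equal to
    the number of drugs carrying specialty i.
    """
    specialties_by_drug: dict[str, set[str]] = defaultdict(set)
    for row in indications:
        if not row.specialty:
            continue
        drug = (drug_to_parent or {}).get(row.drug_id, row.drug_id)
        specialties_by_drug[drug].add(row.specialty)

    diag: Counter[str] = Counter()
    pair: Counter[tuple[str, str]] = Counter()
    for cats in specialties_by_drug.values():
        for c in cats:
            diag[c] += 1
        for a, b in combinations(sorted(cats), 2):
            pair[(a, b)] += 1

    categories = sorted(diag, key=lambda c: (-diag[c], c))
    idx = {c: i for i, c in enumerate(categories)}
    n = len(categories)
    mat = np.zeros((n, n), dtype=int)
    for c, count in diag.items():
        mat[idx[c], idx[c]] = count
    for (a, b), count in pair.items():
        mat[idx[a], idx[b]] = count
        mat[idx[b], idx[a]] = count
    return IndicationAdjacency(categories=categories, matrix=mat.tolist())


def action_dendrogram(
    links: Sequence[DrugTargetLink],
    scores: Mapping[str, PriorityScores],
    drug_names: Optional[Mapping[str, str]] = None,
) -> ActionTreeNode:
    """Dendrogram of drug actions for high-priority targets.

    The tree nests action type → target class → target → drug and is
    restricted to links whose target has gene priority. Leaf count equals
    the number of included (drug, target, action) triples.
    """
    tree = ActionTreeNode(name="drugs", kind="root")
    index: dict[tuple, ActionTreeNode] = {}

    def child(parent: ActionTreeNode, key: tuple, name: str, kind: str) -> ActionTreeNode:
        node = index.get(key)
        if node is None:
            node = ActionTreeNode(name=name, kind=kind)
            index[key] = node
            parent.children.append(node)
        return node

    for link in sorted(
        links, key=lambda l: (l.action_type, l.target_class, l.ensembl_id, l.drug_id)
    ):
        score = scores.get(link.ensembl_id)
        if score is None or not score.gene_priority:
            continue
        action = child(tree, (link.action_type,), link.action_type or "unknown", "action_type")
        klass = child(
            action,
            (link.action_type, link.target_class),
            link.target_class or "unclassified",
            "target_class",
        )
        symbol = score.hgnc_symbol or link.ensembl_id
        target = child(
            klass, (link.action_type, link.target_class, link.ensembl_id), symbol, "target"
        )
        name = (drug_names or {}).get(link.drug_id, link.drug_id)
        leaf_key = (link.action_type, link.target_class, link.ensembl_id, link.drug_id)
        if leaf_key not in index:
            index[leaf_key] = ActionTreeNode(name=name, kind="drug")
            target.children.append(index[leaf_key])
    return tree


def action_leaf_counts(tree: ActionTreeNode) -> dict[str, int]:
    """Number of drug leaves under each action-type branch."""
    return {node.name: len(node.leaves()) for node in tree.children}


def to_newick(tree: ActionTreeNode) -> str:
    """Newick-like text serialisation of the dendrogram."""

    def esc(name: str) -> str:
        return name.replace(" ", "_").replace("(", "").replace(")", "").replace(",", "")

    def render(node: ActionTreeNode) -> str:
        if not node.children:
            return esc(node.name)
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}){esc(node.name)}"

    return render(tree) + ";"


def partition_by_trait(
    profiles: Iterable[TargetProfile],
    drugged_ids: Optional[set[str]] = None,
) -> dict[frozenset[Trait], int]:
    """Mutually exclusive counts of (drugged) targets by trait combination.

    Returns counts over the 7 non-empty subsets of {AF, PR indices, LA
    indices} plus the empty set for targets with no scored trait; cells
    sum to the number of targets counted.
    """
    counts: dict[frozenset[Trait], int] = {}
    scored = {Trait.AF, Trait.PR_INDICES, Trait.LA_INDICES}
    for prof in profiles:
        if drugged_ids is not None and prof.ensembl_id not in drugged_ids:
            continue
        combo = frozenset(prof.traits & scored)
        counts[combo] = counts.get(combo, 0) + 1
    return counts


def format_trait_partition(counts: Mapping[frozenset[Trait], int]) -> dict[str, int]:
    """Stable string-keyed view of a trait partition (for JSON output)."""
    out = {}
    for combo in sorted(counts, key=lambda c: (len(c), sorted(t.value for t in c))):
        key = "+".join(sorted(t.value for t in combo)) or "none"
        out[key] = counts[combo]
    return out
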