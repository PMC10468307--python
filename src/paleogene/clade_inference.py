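"""Clade status assignment and emergence dating.

For every gene and every clade of the timetree one of three statuses is
assigned: *existent* when the gene is detected in more than a majority
fraction (default 80%) of the clade's species, *absent* when it is undetected
in more than that fraction, and *unknown* otherwise.  Emergence candidates are
internal nodes with an existent child clade facing an absent sibling clade;
when several candidates exist, the oldest one is taken.  The presence
character is treated as reversible (Wagner-style: loss and re-gain both
produce contrasts), so re-gain patterns are not suppressed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

from .timetree import Clade, TimeTree, TreeNode, enumerate_clades

__all__ = [
    "Status",
    "CladeRuleConfig",
    "CladeStatusTable",
    "EmergenceEstimate",
    "assign_clade_status",
    "status_table",
    "find_candidate_nodes",
    "estimate_emergence",
    "date_all_genes",
    "estimates_to_frame",
]


class Status(enum.Enum):
    EXISTENT = "existent"
    ABSENT = "absent"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class CladeRuleConfig:
    """Majority rule for per-clade status (strict inequality)."""

    majority_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not 0.5 <= self.majority_fraction < 1.0:
            raise ValueError(
                f"majority_fraction must be in [0.5, 1), got "
                f"{self.majority_fraction}"
            )


def assign_clade_status(
    detected_count: int, clade_size: int, cfg: CladeRuleConfig = CladeRuleConfig()
) -> Status:
    """Three-way status for one (gene, clade) cell.

    Existent iff detected in strictly more than the majority fraction of the
    clade's species; absent iff undetected in strictly more than that
    fraction; unknown otherwise.  Note that at the default 0.8 a 4-of-5 clade
    is *unknown*: 0.8 is not strictly greater than 0.8.
    """
    if clade_size < 1:
        raise ValueError("clade_size must be >= 1")
    if not 0 <= detected_count <= clade_size:
        raise ValueError(
            f"detected_count {detected_count} outside [0, {clade_size}]"
        )
    if detected_count / clade_size > cfg.majority_fraction:
        return Status.EXISTENT
    if (clade_size - detected_count) / clade_size > cfg.majority_fraction:
        return Status.ABSENT
    return Status.UNKNOWN


@dataclass
class CladeStatusTable:
    """Per (gene, clade) statuses with the underlying detection counts."""

    clades: list[Clade]
    #: genes × clade node_ids, values are Status
    statuses: pd.DataFrame
    #: genes × clade node_ids, integer detected counts
    detected_counts: pd.DataFrame

    def status(self, gene: str, node_id: int) -> Status:
        return self.statuses.loc[gene, node_id]

    def gene_statuses(self, gene: str) -> dict[int, Status]:
        return self.statuses.loc[gene].to_dict()


def status_table(
    presence: pd.DataFrame,
    clades: Sequence[Clade],
    cfg: CladeRuleConfig = CladeRuleConfig(),
) -> CladeStatusTable:
    """Apply the majority rule over all genes × clades of a presence matrix."""
    species = set(presence.columns)
    for clade in clades:
        missing = clade.leaves - species
        if missing:
            raise KeyError(
                f"clade at node {clade.node_id} contains taxa absent from the "
                f"presence matrix: {sorted(missing)}"
            )
    counts = pd.DataFrame(
        {
            clade.node_id: presence[list(clade.leaves)].sum(axis=1)
            for clade in clades
        },
        index=presence.index,
    )
    statuses = pd.DataFrame(
        {
            clade.node_id: [
                assign_clade_status(int(c), clade.size, cfg)
                for c in counts[clade.node_id]
            ]
            for clade in clades
        },
        index=presence.index,
    )
    return CladeStatusTable(
        clades=list(clades), statuses=statuses, detected_counts=counts
    )


@dataclass
class EmergenceEstimate:
    """Dated emergence of one gene, or the reason none could be dated.

    Categories: ``dated`` (a contrast node was found; ``age`` is the oldest
    candidate's), ``pre_root`` (existent at the root with no contrast — the
    gene predates the tree), ``undetected`` (no species carries it), and
    ``no_signal`` (detected somewhere but every clade contrast is unknown).
    """

    gene: str
    category: str
    node_id: int | None = None
    node_name: str | None = None
    age: float | None = None
    age_range: tuple[float, float] | None = None
    candidate_ages: list[float] = field(default_factory=list)
    root_status: Status | None = None


def find_candidate_nodes(
    tree: TimeTree, gene_statuses: Mapping[int, Status]
) -> list[tuple[int, float]]:
    """Internal nodes where one child clade is existent and a sibling absent.

    All unordered child pairs are examined (polytomies included); a pair with
    any unknown member contributes nothing; each node appears at most once.
    Returned sorted by decreasing age, ties by the clade ordering key.
    """
    rank = {c.node_id: i for i, c in enumerate(enumerate_clades(tree))}
    out: list[tuple[int, float]] = []
    for node in tree.nodes():
        if node.is_leaf:
            continue
        found = False
        for a, b in combinations(node.children, 2):
            pair = {gene_statuses[a.id], gene_statuses[b.id]}
            if pair == {Status.EXISTENT, Status.ABSENT}:
                found = True
                break
        if found:
            out.append((node.id, node.age))
    out.sort(key=lambda item: (-item[1], rank[item[0]]))
    return out


def estimate_emergence(
    gene: str,
    candidates: Sequence[tuple[int, float]],
    root_status: Status,
    detected_any: bool,
    *,
    tree: TimeTree | None = None,
) -> EmergenceEstimate:
    """Reduce candidate nodes to one dated emergence per gene.

    With several candidates the earliest (maximum-age) one is used; equal-age
    ties go to the candidate whose clade ordering key is smallest.  ``tree``
    is only needed to decorate the estimate with the node's label and age
    range.
    """
    if candidates:
        ordered = list(candidates)
        if tree is not None:
            rank = {c.node_id: i for i, c in enumerate(enumerate_clades(tree))}
            ordered.sort(key=lambda item: (-item[1], rank[item[0]]))
        else:
            ordered.sort(key=lambda item: (-item[1], item[0]))
        node_id, age = ordered[0]
        name = None
        age_range = None
        if tree is not None:
            node = next(n for n in tree.nodes() if n.id == node_id)
            name = node.name
            age_range = node.age_range
        return EmergenceEstimate(
            gene=gene,
            category="dated",
            node_id=node_id,
            node_name=name,
            age=age,
            age_range=age_range,
            candidate_ages=[a for _, a in ordered],
            root_status=root_status,
        )
    if root_status is Status.EXISTENT:
        return EmergenceEstimate(gene=gene, category="pre_root",
                                 root_status=root_status)
    if not detected_any:
        return EmergenceEstimate(gene=gene, category="undetected",
                                 root_status=root_status)
    return EmergenceEstimate(gene=gene, category="no_signal",
                             root_status=root_status)


def date_all_genes(
    tree: TimeTree,
    presence: pd.DataFrame,
    cfg: CladeRuleConfig = CladeRuleConfig(),
) -> list[EmergenceEstimate]:
    """Full dating pipeline: status table → contrasts → one estimate per gene."""
    clades = enumerate_clades(tree)
    table = status_table(presence, clades, cfg)
    root_id = tree.root.id
    estimates = []
    for gene in presence.index:
        statuses = table.gene_statuses(gene)
        candidates = find_candidate_nodes(tree, statuses)
        estimates.append(
            estimate_emergence(
                gene,
                candidates,
                root_status=statuses[root_id],
                detected_any=bool(presence.loc[gene].any()),
                tree=tree,
            )
        )
    return estimates


def estimates_to_frame(estimates: Sequence[EmergenceEstimate]) -> pd.DataFrame:
    """Tabular form of the estimates (the pipeline's per-gene TSV)."""
    rows = []
    for e in estimates:
        lo, hi = e.age_range if e.age_range else (None, None)
        rows.append(
            {
                "gene": e.gene,
                "category": e.category,
                "node_label": e.node_name or "",
                "age_mya": e.age,
                "age_min": lo,
                "age_max": hi,
                "n_candidates": len(e.candidate_ages),
                "candidate_ages": ";".join(f"{a:g}" for a in e.candidate_ages),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "category", "node_label", "age_mya", "age_min", "age_max",
            "n_candidates", "candidate_ages",
        ],
    )
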