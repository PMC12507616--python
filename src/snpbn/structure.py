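"""Bayesian-network structure learning: Cramér's V edge screening + K2 search.

The candidate skeleton is screened first: for every pair of nodes, Cramér's V

    phi_c = sqrt( chi^2 / (n * min(k - 1, r - 1)) )

is computed from their pairwise contingency table, and only pairs at or above
a strength cutoff remain admissible. Domain knowledge enters as whitelist
edges (always present) and blacklist edges (never present). The K2 greedy
search then walks a fixed node ordering, adding for each node the admissible
predecessor that maximally improves the Cooper-Herskovits score, which keeps
the result acyclic by construction.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from math import lgamma
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np

from .association import ContingencyTable, pearson_chi_square
from .data import GenotypeDataset
from .discrete import DISEASE_NODE, DiscreteData
from .importance import ImportanceReport

Edge = tuple[str, str]


def cramers_v(t: ContingencyTable) -> float:
    """Cramér's V of an r x k contingency table, clipped to [0, 1].

    For a 3 x 2 genotype-by-phenotype table min(k-1, r-1) = 1, so phi_c
    reduces to sqrt(chi^2 / n).
    """
    t = t.drop_empty()
    r, k = t.counts.shape
    if r < 2 or k < 2:
        raise ValueError("degenerate table: fewer than 2 non-empty rows or columns")
    chi2 = pearson_chi_square(t).statistic
    v = np.sqrt(chi2 / (t.n * min(k - 1, r - 1)))
    return float(np.clip(v, 0.0, 1.0))


@dataclass(frozen=True)
class ScreeningMatrix:
    """Pairwise Cramér's V values and the induced candidate-adjacency mask."""

    node_ids: tuple[str, ...]
    v_values: np.ndarray  # symmetric, diagonal NaN
    threshold: float
    candidate_mask: np.ndarray  # boolean, symmetric

    def allowed(self, a: str, b: str) -> bool:
        i, j = self.node_ids.index(a), self.node_ids.index(b)
        return bool(self.candidate_mask[i, j])

    def candidate_pairs(self) -> list[Edge]:
        out = []
        for i, a in enumerate(self.node_ids):
            for j in range(i + 1, len(self.node_ids)):
                if self.candidate_mask[i, j]:
                    out.append((a, self.node_ids[j]))
        return out


def screen_edges(
    data: DiscreteData | GenotypeDataset,
    threshold: float = 0.1,
    whitelist: Sequence[Edge] = (),
    blacklist: Sequence[Edge] = (),
    loci: Sequence[str] | None = None,
) -> ScreeningMatrix:
    """Cramér's V over all node pairs; mask = {phi_c >= threshold} ∪ whitelist,
    minus pairs blacklisted in both directions.

    Accepts either a complete-case :class:`DiscreteData` or a raw
    :class:`~snpbn.data.GenotypeDataset` (optionally restricted to ``loci``;
    the disease node is always included); with a genotype dataset each pair
    is tabulated over its own complete cases, so a missing call at one locus
    does not discard a subject from other pairs.
    """
    if isinstance(data, DiscreteData):
        ids = data.node_ids
        values = data.values
        cards = data.cardinalities
    else:  # GenotypeDataset with possible missing calls
        lids = list(loci) if loci is not None else [l.locus_id for l in data.loci]
        cols = [data.locus_index(l) for l in lids]
        values = np.column_stack(
            [data.genotypes[:, cols].astype(np.int64),
             data.phenotype.astype(np.int64)]
        )
        ids = (*lids, DISEASE_NODE)
        cards = (*([3] * len(lids)), 2)
    m = len(ids)
    if m < 2:
        raise ValueError("need at least 2 nodes to screen")
    v = np.full((m, m), np.nan)
    mask = np.zeros((m, m), dtype=bool)
    for i in range(m):
        for j in range(i + 1, m):
            keep = (values[:, i] >= 0) & (values[:, j] >= 0)
            table = _pair_table(values[keep, i], values[keep, j], cards[i], cards[j])
            try:
                vij = cramers_v(table)
            except ValueError:
                vij = 0.0  # a constant column carries no association signal
            v[i, j] = v[j, i] = vij
            mask[i, j] = mask[j, i] = vij >= threshold
    wl = {frozenset(e) for e in whitelist}
    bl_pairs = set(map(tuple, blacklist))
    for pair in wl:
        a, b = tuple(pair)
        i, j = ids.index(a), ids.index(b)
        mask[i, j] = mask[j, i] = True
    # a pair blacklisted in both directions can never carry an edge
    for a, b in bl_pairs:
        if (b, a) in bl_pairs and frozenset((a, b)) not in wl:
            i, j = ids.index(a), ids.index(b)
            mask[i, j] = mask[j, i] = False
    return ScreeningMatrix(ids, v, threshold, mask)


def _pair_table(
    vi: np.ndarray, vj: np.ndarray, ri: int, rj: int
) -> ContingencyTable:
    counts = np.zeros((ri, rj), dtype=np.int64)
    np.add.at(counts, (vi, vj), 1)
    return ContingencyTable(
        tuple(map(str, range(ri))), tuple(map(str, range(rj))), counts
    )


@dataclass
class NetworkStructure:
    """A DAG over locus nodes plus the disease node."""

    node_ids: tuple[str, ...]
    edges: list[Edge] = field(default_factory=list)
    ordering: tuple[str, ...] | None = None
    max_parents: int = 3
    node_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("structure contains a directed cycle")
        for child in self.node_ids:
            if len(self.parents(child)) > self.max_parents:
                raise ValueError(f"node {child!r} exceeds max_parents")

    def parents(self, child: str) -> list[str]:
        return [a for a, b in self.edges if b == child]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from(self.edges)
        return g

    def skeleton(self) -> set[frozenset]:
        return {frozenset(e) for e in self.edges}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "nodes": list(self.node_ids),
            "edges": [list(e) for e in self.edges],
            "ordering": list(self.ordering) if self.ordering else None,
            "max_parents": self.max_parents,
            "node_scores": self.node_scores,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NetworkStructure":
        raw = json.loads(Path(path).read_text())
        return cls(
            tuple(raw["nodes"]),
            [tuple(e) for e in raw["edges"]],
            tuple(raw["ordering"]) if raw.get("ordering") else None,
            raw.get("max_parents", 3),
            raw.get("node_scores", {}),
        )

    def to_dot(self) -> str:
        lines = ["digraph bn {"]
        for n in self.node_ids:
            lines.append(f'  "{n}";')
        for a, b in self.edges:
            lines.append(f'  "{a}" -> "{b}";')
        lines.append("}")
        return "\n".join(lines)


def read_edge_list(path: str | Path) -> list[Edge]:
    """Two-column CSV (parent, child), optional header."""
    edges: list[Edge] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().lower() in ("parent", ""):
                continue
            edges.append((row[0].strip(), row[1].strip()))
    return edges


def k2_score(
    data: DiscreteData, child: str, parents: Sequence[str] = ()
) -> float:
    """Log Cooper-Herskovits score of one node given a parent set.

    log prod_j [ (r-1)! / (N_j + r - 1)! * prod_k N_jk! ] over parent
    configurations j, with r the child's state count. Unobserved
    configurations contribute log 1 = 0.
    """
    if child in parents:
        raise ValueError("child cannot be its own parent")
    jc = data.column(child)
    r = data.cardinalities[jc]
    child_vals = data.values[:, jc]
    if data.n == 0:
        return 0.0
    if parents:
        cols = [data.column(p) for p in parents]
        cards = [data.cardinalities[c] for c in cols]
        config = np.ravel_multi_index(
            tuple(data.values[:, c] for c in cols), dims=cards
        )
        n_cfg = int(np.prod(cards))
    else:
        config = np.zeros(data.n, dtype=np.int64)
        n_cfg = 1
    counts = np.zeros((n_cfg, r), dtype=np.int64)
    np.add.at(counts, (config, child_vals), 1)
    nj = counts.sum(axis=1)
    score = 0.0
    lg_r = lgamma(r)
    for j in range(n_cfg):
        if nj[j] == 0:
            continue
        score += lg_r - lgamma(nj[j] + r)
        score += sum(lgamma(c + 1) for c in counts[j])
    return score


def k2_search(
    data: DiscreteData,
    ordering: Sequence[str],
    mask: ScreeningMatrix | None = None,
    max_parents: int = 3,
    whitelist: Sequence[Edge] = (),
    blacklist: Sequence[Edge] = (),
) -> NetworkStructure:
    """Greedy K2 structure search along a fixed node ordering.

    For each node, whitelisted parent edges are forced first; then the
    admissible predecessor (screen-allowed, not blacklisted, within
    ``max_parents``) that maximally improves the Cooper-Herskovits score is
    added until no addition improves. Only predecessors in the ordering may
    become parents, so the result is acyclic by construction.
    """
    ordering = tuple(ordering)
    if set(ordering) != set(data.node_ids):
        raise ValueError("ordering must cover exactly the data's nodes")
    bl = set(map(tuple, blacklist))
    wl = set(map(tuple, whitelist))
    pos = {n: i for i, n in enumerate(ordering)}
    for a, b in wl:
        if pos[a] >= pos[b]:
            raise ValueError(
                f"whitelist edge {a}->{b} violates the ordering and cannot "
                "be represented"
            )
    edges: list[Edge] = []
    scores: dict[str, float] = {}
    for idx, child in enumerate(ordering):
        parents: list[str] = [a for a, b in wl if b == child]
        candidates = [
            p
            for p in ordering[:idx]
            if p not in parents
            and (p, child) not in bl
            and (mask is None or mask.allowed(p, child))
        ]
        current = k2_score(data, child, parents)
        while len(parents) < max_parents and candidates:
            trial = [(k2_score(data, child, parents + [p]), p) for p in candidates]
            best_score, best_p = max(trial, key=lambda t: (t[0], t[1]))
            if best_score <= current:
                break
            parents.append(best_p)
            candidates.remove(best_p)
            current = best_score
        edges.extend((p, child) for p in parents)
        scores[child] = current
    return NetworkStructure(
        tuple(data.node_ids), edges, ordering, max_parents, scores
    )


def default_ordering(
    report: ImportanceReport,
    phenotype_position: Literal["first", "last"] = "last",
    loci: Sequence[str] | None = None,
) -> tuple[str, ...]:
    """K2 node ordering: loci by descending aggregate importance (ties
    lexicographic), the disease node first or last. Placing disease last lets
    every locus be a candidate parent of disease."""
    ids = list(loci) if loci is not None else list(report.locus_importances)
    ranked = sorted(ids, key=lambda l: (-report.locus_importances.get(l, 0.0), l))
    if phenotype_position == "first":
        return (DISEASE_NODE, *ranked)
    return (*ranked, DISEASE_NODE)
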