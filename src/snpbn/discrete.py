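"""Shared container for discrete node data used by structure and parameter
learning: modeled loci (ternary) plus the binary disease node."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import GenotypeDataset, complete_cases

DISEASE_NODE = "disease"


@dataclass(frozen=True)
class DiscreteData:
    """n x m matrix of discrete states with per-node cardinalities."""

    node_ids: tuple[str, ...]
    cardinalities: tuple[int, ...]
    values: np.ndarray  # (n, m) int, no missing

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.int64)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 2 or vals.shape[1] != len(self.node_ids):
            raise ValueError("values shape disagrees with node list")
        for j, card in enumerate(self.cardinalities):
            col = vals[:, j]
            if len(col) and (col.min() < 0 or col.max() >= card):
                raise ValueError(
                    f"node {self.node_ids[j]!r}: state outside [0, {card})"
                )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def column(self, node_id: str) -> int:
        try:
            return self.node_ids.index(node_id)
        except ValueError:
            raise KeyError(f"node {node_id!r} not in data") from None

    def cardinality(self, node_id: str) -> int:
        return self.cardinalities[self.column(node_id)]


def dataset_to_discrete(
    ds: GenotypeDataset,
    loci: Sequence[str] | None = None,
    include_disease: bool = True,
) -> DiscreteData:
    """Complete-case discrete matrix over the modeled loci (+ disease node)."""
    ids = list(loci) if loci is not None else [l.locus_id for l in ds.loci]
    cc = complete_cases(ds, ids)
    cols = [cc.locus_index(l) for l in ids]
    values = cc.genotypes[:, cols].astype(np.int64)
    node_ids = list(ids)
    cards = [3] * len(ids)
    if include_disease:
        values = np.column_stack([values, cc.phenotype.astype(np.int64)])
        node_ids.append(DISEASE_NODE)
        cards.append(2)
    return DiscreteData(tuple(node_ids), tuple(cards), values)
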