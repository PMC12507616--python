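"""Random-forest feature importance for locus selection.

Genotypes are one-hot encoded (three indicator columns per locus, so 27 loci
give 81 features), scored with Gini mean-decrease-impurity from a random
forest, and aggregated back to loci by summing each locus's feature scores:
I_i = sum_j x_ij. Loci whose aggregate importance exceeds a cutoff (0.05 by
default) are selected, optionally unioned with externally flagged loci
(association-significant or literature-reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .data import MISSING, GenotypeDataset


@dataclass(frozen=True)
class ForestSettings:
    """Hyperparameters of the importance forest (none are critical; the
    defaults favour stable rankings over raw accuracy)."""

    n_estimators: int = 500
    max_features: str | float = "sqrt"
    seed: int = 0
    class_weight: str | None = None


@dataclass(frozen=True)
class OneHotDesign:
    """Maps (locus_id, state index) to a feature column."""

    locus_ids: tuple[str, ...]
    feature_index: Mapping[tuple[str, int], int]

    @property
    def n_features(self) -> int:
        return 3 * len(self.locus_ids)

    def locus_columns(self, locus_id: str) -> list[int]:
        return [self.feature_index[(locus_id, s)] for s in range(3)]


@dataclass(frozen=True)
class ImportanceReport:
    feature_importances: np.ndarray  # per one-hot feature, sums to 1
    locus_importances: dict[str, float]  # I_i = sum_j x_ij
    threshold: float

    @property
    def ranking(self) -> list[str]:
        """Loci in descending aggregate importance, ties lexicographic."""
        return sorted(self.locus_importances, key=lambda l: (-self.locus_importances[l], l))

    @property
    def selected_loci(self) -> list[str]:
        return [l for l in self.ranking if self.locus_importances[l] > self.threshold]


def one_hot_encode(ds: GenotypeDataset) -> tuple[OneHotDesign, np.ndarray]:
    """Binary design matrix with one indicator per (locus, state).

    Column order is locus order x state order; every subject has exactly one
    1 among each locus's three columns. Missing genotypes are an error —
    apply :func:`snpbn.data.complete_cases` first.
    """
    miss = np.argwhere(ds.genotypes == MISSING)
    if len(miss):
        i, j = miss[0]
        raise ValueError(
            f"missing genotype at subject {ds.subjects[i]!r}, "
            f"locus {ds.loci[j].locus_id!r}; drop incomplete subjects first"
        )
    n, m = ds.genotypes.shape
    X = np.zeros((n, 3 * m), dtype=np.int8)
    rows = np.arange(n)
    for j in range(m):
        X[rows, 3 * j + ds.genotypes[:, j]] = 1
    index = {
        (loc.locus_id, s): 3 * j + s
        for j, loc in enumerate(ds.loci)
        for s in range(3)
    }
    return OneHotDesign(tuple(l.locus_id for l in ds.loci), index), X


def rf_importance(
    features: np.ndarray,
    phenotype: np.ndarray,
    settings: ForestSettings = ForestSettings(),
) -> np.ndarray:
    """Gini mean-decrease-impurity scores, normalised to sum to 1."""
    phenotype = np.asarray(phenotype)
    if len(np.unique(phenotype)) < 2:
        raise ValueError("phenotype must contain both classes")
    forest = RandomForestClassifier(
        n_estimators=settings.n_estimators,
        max_features=settings.max_features,
        class_weight=settings.class_weight,
        random_state=settings.seed,
        n_jobs=1,
    )
    forest.fit(features, phenotype)
    imp = forest.feature_importances_
    return imp / imp.sum()


def aggregate_importance(
    design: OneHotDesign, scores: np.ndarray, threshold: float = 0.05
) -> ImportanceReport:
    """Sum per-feature scores within each locus: I_i = sum_j x_ij."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (design.n_features,):
        raise ValueError(
            f"expected {design.n_features} scores, got {scores.shape}"
        )
    locus_imp = {
        lid: float(scores[design.locus_columns(lid)].sum())
        for lid in design.locus_ids
    }
    return ImportanceReport(scores, locus_imp, threshold)


def select_loci(
    report: ImportanceReport,
    threshold: float | None = None,
    extra: Sequence[str] = (),
) -> list[str]:
    """Loci with aggregate importance strictly above threshold, unioned with
    externally supplied loci; ordered by descending importance, extras last."""
    thr = report.threshold if threshold is None else threshold
    chosen = [l for l in report.ranking if report.locus_importances[l] > thr]
    for lid in extra:
        if lid not in chosen:
            chosen.append(lid)
    return chosen


def write_importance_tsv(
    design: OneHotDesign, report: ImportanceReport, path: str | Path
) -> None:
    rows = [
        {
            "locus": lid,
            "state": s,
            "feature_importance": report.feature_importances[
                design.feature_index[(lid, s)]
            ],
            "locus_importance": report.locus_importances[lid],
        }
        for lid in design.locus_ids
        for s in range(3)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
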