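"""Per-locus association testing and Hardy-Weinberg checks.

Each locus yields a 3 x 2 genotype-by-phenotype contingency table over its
complete cases. Loci whose expected counts are all at least 5 are tested with
the Pearson chi-square statistic (no continuity correction); loci with any
smaller expected cell use the Fisher-Freeman-Halton exact test, the r x k
generalisation of Fisher's 2 x 2 test.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import MISSING, GenotypeDataset, Locus


@dataclass(frozen=True)
class ContingencyTable:
    """An r x k count table (genotype rows, phenotype columns)."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels and count matrix shapes disagree")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def drop_empty(self) -> "ContingencyTable":
        """Drop all-zero rows and columns (empty genotype categories)."""
        rows = self.counts.sum(axis=1) > 0
        cols = self.counts.sum(axis=0) > 0
        return ContingencyTable(
            tuple(l for l, k in zip(self.row_labels, rows) if k),
            tuple(l for l, k in zip(self.col_labels, cols) if k),
            self.counts[np.ix_(rows, cols)],
        )

    def expected(self) -> np.ndarray:
        """Expected counts under independence with the observed margins."""
        r = self.counts.sum(axis=1, keepdims=True)
        c = self.counts.sum(axis=0, keepdims=True)
        if (r == 0).any() or (c == 0).any():
            raise ValueError("zero row or column total; drop empty categories first")
        return r * c / self.n


@dataclass(frozen=True)
class AssociationResult:
    locus_id: str
    test_used: Literal["pearson-chi-square", "fisher-freeman-halton", "degenerate"]
    statistic: float | None
    df: int | None
    p_value: float
    min_expected: float | None
    error: str | None = None


@dataclass(frozen=True)
class HweResult:
    locus_id: str
    allele_frequency: float  # major (first-listed homozygote) allele
    statistic: float
    df: int
    p_value: float


def genotype_contingency(ds: GenotypeDataset, locus: Locus | str) -> ContingencyTable:
    """3 x 2 genotype-by-phenotype counts over complete cases at one locus.

    Rows follow the locus's declared state order; columns are (case, control).
    """
    j = ds.locus_index(locus if isinstance(locus, str) else locus.locus_id)
    loc = ds.loci[j]
    g = ds.genotypes[:, j]
    ok = g != MISSING
    if not ok.any():
        raise ValueError(f"locus {loc.locus_id!r}: all genotypes missing")
    counts = np.zeros((3, 2), dtype=np.int64)
    for state in range(3):
        sel = ok & (g == state)
        counts[state, 0] = int((ds.phenotype[sel] == 1).sum())
        counts[state, 1] = int((ds.phenotype[sel] == 0).sum())
    return ContingencyTable(loc.state_labels, ("case", "control"), counts)


def pearson_chi_square(t: ContingencyTable, locus_id: str = "") -> AssociationResult:
    """Pearson chi-square test of independence, no continuity correction."""
    t = t.drop_empty()
    r, k = t.counts.shape
    if r < 2 or k < 2:
        raise ValueError("need at least a 2 x 2 table after dropping empty categories")
    exp = t.expected()
    stat = float(((t.counts - exp) ** 2 / exp).sum())
    df = (r - 1) * (k - 1)
    p = float(stats.chi2.sf(stat, df))
    return AssociationResult(
        locus_id, "pearson-chi-square", stat, df, p, float(exp.min())
    )


def _log_table_prob(counts: np.ndarray, lg_margins: float, lg_n: float) -> float:
    # multivariate hypergeometric: (prod ri! prod cj!) / (n! prod nij!)
    return lg_margins - lg_n - sum(lgamma(v + 1) for v in counts.flat)


def fisher_freeman_halton(
    t: ContingencyTable, locus_id: str = "", max_tables: int = 2_000_000
) -> AssociationResult:
    """Exact conditional test for an r x k table with fixed margins.

    Enumerates every table with the observed margins and sums the
    probabilities (multivariate hypergeometric null) of tables no more
    probable than the observed one — the classical two-sided Fisher rule,
    generalised beyond 2 x 2.
    """
    t = t.drop_empty()
    counts = t.counts
    r, k = counts.shape
    if r < 2 or k < 2:
        raise ValueError("need at least a 2 x 2 table after dropping empty categories")
    if k > r:  # enumerate over the smaller column dimension
        counts = counts.T
        r, k = counts.shape
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    n = int(counts.sum())
    lg_n = lgamma(n + 1)
    lg_margins = sum(lgamma(v + 1) for v in rows) + sum(lgamma(v + 1) for v in cols)
    log_p_obs = _log_table_prob(counts, lg_margins, lg_n)

    # rough cap: product over rows of the number of weak compositions of the
    # row total into k parts bounds the enumeration size
    est = 1.0
    for ri in rows:
        comb = 1.0
        for d in range(1, k):
            comb *= (ri + d) / d
        est *= comb
        if est > max_tables:
            raise ValueError(
                f"exact enumeration would exceed {max_tables} tables; "
                "use the chi-square test instead"
            )

    tol = 1e-9 * abs(log_p_obs) + 1e-12  # observed table always counts
    total = 0.0

    table = np.zeros((r, k), dtype=np.int64)

    def recurse(i: int, col_rem: np.ndarray, log_acc: float) -> None:
        nonlocal total
        if i == r - 1:
            if (col_rem < 0).any():
                return
            lp = log_acc - sum(lgamma(v + 1) for v in col_rem)
            if lp <= log_p_obs + tol:
                total += np.exp(lp)
            return
        ri = rows[i]
        # enumerate the row as weak compositions of ri into k cells, bounded
        # by the remaining column totals
        row = np.zeros(k, dtype=np.int64)

        def fill(j: int, rem: int, lacc: float) -> None:
            if j == k - 1:
                if rem > col_rem[j]:
                    return
                row[j] = rem
                recurse(
                    i + 1, col_rem - row, lacc - lgamma(rem + 1)
                )
                return
            for v in range(min(rem, int(col_rem[j])) + 1):
                row[j] = v
                fill(j + 1, rem - v, lacc - lgamma(v + 1))
            row[j] = 0

        fill(0, int(ri), log_acc)

    recurse(0, cols.copy(), lg_margins - lg_n)
    p = float(min(total, 1.0))
    return AssociationResult(locus_id, "fisher-freeman-halton", None, None, p, None)


def association_scan(
    ds: GenotypeDataset,
    alpha: float = 0.05,
    loci: Sequence[str] | None = None,
    bonferroni: bool = False,
) -> list[AssociationResult]:
    """Per-locus genotype-phenotype test with automatic branch selection.

    Uses the exact Fisher-Freeman-Halton test whenever any expected cell
    count is below 5, otherwise the Pearson chi-square. Degenerate loci
    (fewer than two genotype categories observed) yield a ``degenerate``
    result and the scan continues. P-values are raw by default; pass
    ``bonferroni=True`` to scale them by the number of testable loci.
    """
    ids = loci if loci is not None else [l.locus_id for l in ds.loci]
    results: list[AssociationResult] = []
    for lid in ids:
        try:
            table = genotype_contingency(ds, lid).drop_empty()
            exp = table.expected()
            if (exp < 5).any():
                res = fisher_freeman_halton(table, lid)
                res = AssociationResult(
                    lid, res.test_used, res.statistic, res.df, res.p_value,
                    float(exp.min()),
                )
            else:
                res = pearson_chi_square(table, lid)
        except ValueError as exc:
            results.append(
                AssociationResult(lid, "degenerate", None, None, float("nan"),
                                  None, error=str(exc))
            )
            continue
        results.append(res)
    if bonferroni:
        m = sum(r.test_used != "degenerate" for r in results)
        results = [
            r if r.test_used == "degenerate" else
            AssociationResult(r.locus_id, r.test_used, r.statistic, r.df,
                              min(1.0, r.p_value * m), r.min_expected)
            for r in results
        ]
    return results


def flagged_loci(results: Iterable[AssociationResult], alpha: float = 0.05) -> list[str]:
    return [
        r.locus_id
        for r in results
        if r.test_used != "degenerate" and r.p_value < alpha
    ]


def hwe_test(
    ds: GenotypeDataset,
    locus: Locus | str,
    cohort: Literal["pooled", "controls-only"] = "pooled",
) -> HweResult:
    """One-degree-of-freedom chi-square test of Hardy-Weinberg proportions.

    Allele counts come from genotype counts (each homozygote contributes two
    copies of its allele, the heterozygote one of each); expected genotype
    counts are (p^2, 2pq, q^2) x n. A monomorphic locus returns statistic 0,
    p = 1.
    """
    j = ds.locus_index(locus if isinstance(locus, str) else locus.locus_id)
    loc = ds.loci[j]
    g = ds.genotypes[:, j]
    keep = g != MISSING
    if cohort == "controls-only":
        keep &= ds.phenotype == 0
    g = g[keep]
    if len(g) == 0:
        raise ValueError(f"locus {loc.locus_id!r}: no complete cases in cohort")
    counts = np.bincount(g, minlength=3).astype(float)
    return hwe_from_counts(counts, loc)


def hwe_from_counts(genotype_counts: Sequence[float], locus: Locus) -> HweResult:
    """HWE test from (state0, state1, state2) genotype counts in locus order."""
    counts = np.asarray(genotype_counts, dtype=float)
    het = locus.heterozygote_index()
    homs = [i for i in range(3) if i != het]
    n = counts.sum()
    a1 = 2 * counts[homs[0]] + counts[het]
    a2 = 2 * counts[homs[1]] + counts[het]
    p = a1 / (a1 + a2)
    if p in (0.0, 1.0):
        return HweResult(locus.locus_id, float(p), 0.0, 1, 1.0)
    exp = np.empty(3)
    exp[homs[0]] = p * p * n
    exp[het] = 2 * p * (1 - p) * n
    exp[homs[1]] = (1 - p) ** 2 * n
    stat = float(((counts - exp) ** 2 / exp).sum())
    return HweResult(locus.locus_id, float(p), stat, 1, float(stats.chi2.sf(stat, 1)))


def write_association_tsv(
    results: Iterable[AssociationResult], path: str | Path, alpha: float = 0.05
) -> None:
    """TSV report mirroring the per-locus P-value layout of a study table."""
    rows = [
        {
            "locus": r.locus_id,
            "test": r.test_used,
            "statistic": "" if r.statistic is None else f"{r.statistic:.4f}",
            "df": "" if r.df is None else r.df,
            "p_value": "" if np.isnan(r.p_value) else f"{r.p_value:.4g}",
            "min_expected": "" if r.min_expected is None else f"{r.min_expected:.2f}",
            "flagged": (not np.isnan(r.p_value)) and r.p_value < alpha,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
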