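"""Published per-locus genotype-by-phenotype counts and their expansion to
individual-level fixtures.

The study cohort (490 breast-cancer cases, 490 matched controls from
Southwest China, 27 SNP loci typed by mass spectrometry) is not publicly
deposited; what is published is the per-locus univariate table: for each
locus, genotype counts split by case/control plus the reported P-value.
``build_table1_fixture`` expands those counts into per-locus individual-level
datasets whose contingency tables reproduce the published counts exactly.
Only marginals are published, so no joint dataset across loci is fabricated:
each locus expands independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import GenotypeDataset, Locus

# Per locus: (state labels in published row order,
#             case counts per state, control counts per state,
#             published P-value)
TABLE1_COUNTS: dict[str, tuple[tuple[str, str, str], tuple[int, int, int], tuple[int, int, int], float]] = {
    "rs1042522":  (("C", "CG", "G"), (147, 215, 96), (146, 224, 92), 0.880),
    "rs11559040": (("A", "G", "GA"), (6, 363, 89), (5, 362, 95), 0.873),
    "rs1537514":  (("C", "CG", "G"), (4, 65, 389), (2, 76, 384), 0.474),
    "rs1537516":  (("A", "G", "GA"), (4, 389, 65), (2, 384, 76), 0.474),
    "rs17884306": (("C", "CT", "T"), (387, 70, 1), (384, 73, 5), 0.309),
    "rs1800629":  (("A", "G", "GA"), (3, 409, 46), (3, 408, 51), 0.900),
    "rs1801131":  (("G", "GT", "T"), (14, 136, 308), (15, 147, 300), 0.760),
    "rs1801133":  (("A", "AG", "G"), (18, 370, 70), (24, 331, 107), 0.005),
    "rs1801394":  (("A", "AG", "G"), (278, 153, 27), (258, 174, 30), 0.327),
    "rs1805087":  (("A", "G", "GA"), (366, 0, 92), (370, 5, 87), 0.079),
    "rs4968187":  (("C", "T", "TC"), (378, 2, 78), (384, 2, 76), 0.916),
    "rs6853":     (("A", "AG", "G"), (438, 19, 1), (444, 18, 0), 0.823),
    "rs7744":     (("A", "G", "GA"), (200, 63, 195), (178, 73, 211), 0.269),
    "rs9651118":  (("C", "CT", "T"), (69, 208, 181), (82, 206, 174), 0.535),
    "rs1994798":  (("A", "G", "GA"), (296, 22, 140), (284, 18, 160), 0.375),
    "rs2066462":  (("A", "G", "GA"), (4, 390, 64), (2, 386, 74), 0.550),
    "rs2066470":  (("A", "AG", "G"), (4, 65, 389), (2, 81, 379), 0.369),
    "rs2184227":  (("C", "CT", "T"), (388, 66, 4), (384, 76, 2), 0.452),
    "rs2274976":  (("C", "CT", "T"), (389, 65, 4), (385, 75, 2), 0.492),
    "rs3737964":  (("C", "T", "TC"), (363, 6, 89), (361, 5, 96), 0.842),
    "rs3737965":  (("A", "G", "GA"), (4, 389, 65), (2, 379, 81), 0.321),
    "rs3737966":  (("C", "CT", "T"), (21, 140, 297), (19, 151, 292), 0.763),
    "rs3737967":  (("A", "AG", "G"), (5, 64, 389), (2, 76, 384), 0.335),
    "rs4846048":  (("A", "AG", "G"), (353, 97, 8), (353, 104, 5), 0.632),
    "rs56221660": (("A", "AG", "G"), (387, 67, 4), (366, 94, 2), 0.049),
    "rs72640221": (("A", "G", "GA"), (4, 390, 64), (3, 384, 75), 0.636),
    "rs7851696":  (("G", "GT", "T"), (303, 138, 17), (304, 141, 17), 0.992),
}

#: gene annotations for the loci discussed by name in the study
GENE_LABELS = {
    "rs1042522": "TP53",
    "rs17884306": "TP53",
    "rs1801133": "MTHFR",
    "rs56221660": "MTHFR",
    "rs9651118": "MTHFR",
    "rs1801394": "MTRR",
    "rs1805087": "MTR",
    "rs7744": "MYD88",
}

#: the nine loci carried into the network model (importance-selected plus the
#: association-flagged rs56221660)
MODELED_LOCI = (
    "rs7744", "rs1042522", "rs1801133", "rs1801394", "rs7851696",
    "rs1805087", "rs17884306", "rs9651118", "rs56221660",
)


def table1_locus(locus_id: str) -> Locus:
    states = TABLE1_COUNTS[locus_id][0]
    return Locus(locus_id, states, GENE_LABELS.get(locus_id))


@dataclass(frozen=True)
class Table1Fixture:
    """Per-locus individual-level expansions of the published counts."""

    datasets: dict[str, GenotypeDataset]  # one single-locus dataset per locus

    def published_p(self, locus_id: str) -> float:
        return TABLE1_COUNTS[locus_id][3]

    @property
    def locus_ids(self) -> list[str]:
        return list(self.datasets)


def expand_locus_counts(
    locus_id: str,
    case_counts: tuple[int, int, int] | None = None,
    control_counts: tuple[int, int, int] | None = None,
) -> GenotypeDataset:
    """Individual-level single-locus dataset reproducing published counts.

    Rows are cases first then controls, states in published order; the
    arrangement within a phenotype class carries no information because only
    the per-locus margin is published.
    """
    states, cases, controls, _ = TABLE1_COUNTS[locus_id]
    if case_counts is not None:
        cases = case_counts
    if control_counts is not None:
        controls = control_counts
    if min(cases) < 0 or min(controls) < 0:
        raise ValueError(f"locus {locus_id!r}: negative genotype count")
    geno = []
    phen = []
    for phenotype, counts in ((1, cases), (0, controls)):
        for state, k in enumerate(counts):
            geno.extend([state] * k)
            phen.extend([phenotype] * k)
    n = len(geno)
    return GenotypeDataset(
        subjects=[f"{locus_id}_{i:04d}" for i in range(n)],
        loci=[table1_locus(locus_id)],
        genotypes=np.array(geno, dtype=np.int8).reshape(-1, 1),
        phenotype=np.array(phen, dtype=np.int8),
    )


def build_table1_fixture() -> Table1Fixture:
    """Expand every published locus block; tallies equal the printed counts
    exactly (validated by construction and re-checked in the test suite)."""
    return Table1Fixture(
        {lid: expand_locus_counts(lid) for lid in TABLE1_COUNTS}
    )
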