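"""Chi-square / exact association tests and Hardy-Weinberg checks."""

import itertools
from math import lgamma

import numpy as np
import pytest
from scipy.stats import fisher_exact

import snpbn as s

from conftest import make_dataset


def table(counts):
    counts = np.asarray(counts)
    return s.ContingencyTable(
        tuple(f"r{i}" for i in range(counts.shape[0])),
        tuple(f"c{j}" for j in range(counts.shape[1])),
        counts,
    )


class TestGenotypeContingency:
    def test_published_counts_rs1042522(self, table1):
        t = s.genotype_contingency(table1.datasets["rs1042522"], "rs1042522")
        assert t.counts.tolist() == [[147, 146], [215, 224], [96, 92]]
        assert t.col_labels == ("case", "control")

    def test_single_case_single_state(self):
        ds = make_dataset([[0]], [1])
        t = s.genotype_contingency(ds, "rs0")
        assert t.counts.tolist() == [[1, 0], [0, 0], [0, 0]]

    def test_matches_tally_oracle(self):
        rng = np.random.default_rng(2)
        geno = rng.integers(0, 3, size=(100, 1))
        phen = rng.integers(0, 2, size=100)
        t = s.genotype_contingency(make_dataset(geno, phen), "rs0")
        for state in range(3):
            for col, cls in ((0, 1), (1, 0)):
                expected = sum(
                    1 for g, p in zip(geno[:, 0], phen) if g == state and p == cls
                )
                assert t.counts[state, col] == expected


class TestPearsonChiSquare:
    @pytest.mark.parametrize(
        "locus,p3",
        [
            ("rs1042522", 0.880),
            ("rs1801133", 0.005),
            ("rs1994798", 0.375),
            ("rs7744", 0.269),
            ("rs7851696", 0.992),
        ],
    )
    def test_reproduces_published_p_values(self, table1, locus, p3):
        t = s.genotype_contingency(table1.datasets[locus], locus)
        res = s.pearson_chi_square(t, locus)
        assert res.p_value == pytest.approx(p3, abs=1e-3)

    def test_statistic_hand_computed_rs1801133(self, table1):
        # sum (obs-exp)^2/exp over the published 3x2 block = 10.744, df 2
        t = s.genotype_contingency(table1.datasets["rs1801133"], "rs1801133")
        res = s.pearson_chi_square(t)
        assert res.statistic == pytest.approx(10.744, abs=2e-3)
        assert res.df == 2

    def test_proportional_table_gives_zero(self):
        res = s.pearson_chi_square(table([[10, 10], [20, 20]]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_invariant_to_permutation_and_label_swap(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(5, 40, size=(3, 2))
        base = s.pearson_chi_square(table(counts)).statistic
        assert s.pearson_chi_square(table(counts[::-1])).statistic == pytest.approx(base)
        assert s.pearson_chi_square(table(counts[:, ::-1])).statistic == pytest.approx(base)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            table([[0, 0], [5, 5]]).expected()


def exact_p_oracle(counts):
    """Brute-force Fisher-Freeman-Halton p by enumerating all tables with the
    observed margins (independent of the package's recursive routine)."""
    counts = np.asarray(counts)
    rows, cols = counts.sum(1), counts.sum(0)
    n = counts.sum()
    lg = lambda v: lgamma(v + 1)
    const = sum(map(lg, rows)) + sum(map(lg, cols)) - lg(n)

    def prob(t):
        return np.exp(const - sum(lg(v) for v in np.ravel(t)))

    p_obs = prob(counts)
    total = 0.0
    # small-table enumeration: iterate over all free-cell grids directly
    grids = [range(int(rows[i]) + 1) for i in range(len(rows)) for _ in range(len(cols) - 1)]
    k = len(cols)
    for flat in itertools.product(*grids):
        t = np.zeros_like(counts)
        ok = True
        for i in range(len(rows)):
            row = list(flat[i * (k - 1):(i + 1) * (k - 1)])
            last = rows[i] - sum(row)
            if last < 0:
                ok = False
                break
            t[i, :-1] = row
            t[i, -1] = last
        if not ok or not np.array_equal(t.sum(0), cols):
            continue
        p = prob(t)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


class TestFisherFreemanHalton:
    def test_two_by_two_matches_classical_fisher(self):
        t = [[1, 9], [11, 3]]
        res = s.fisher_freeman_halton(table(t))
        assert res.p_value == pytest.approx(fisher_exact(t)[1], rel=1e-9)

    @pytest.mark.parametrize(
        "counts",
        [
            [[2, 0], [1, 1], [0, 2]],
            [[5, 1], [2, 4], [1, 3]],
            [[3, 0, 1], [0, 3, 1]],
        ],
    )
    def test_matches_enumeration_oracle(self, counts):
        res = s.fisher_freeman_halton(table(counts))
        assert res.p_value == pytest.approx(exact_p_oracle(counts), rel=1e-9)

    def test_empty_category_invariance(self):
        full = [[4, 1], [0, 0], [2, 5]]
        reduced = [[4, 1], [2, 5]]
        assert s.fisher_freeman_halton(table(full)).p_value == pytest.approx(
            s.fisher_freeman_halton(table(reduced)).p_value
        )

    def test_enumeration_cap(self):
        big = [[500, 480], [490, 510], [505, 495]]
        with pytest.raises(ValueError, match="chi-square"):
            s.fisher_freeman_halton(table(big), max_tables=100)


class TestAssociationScan:
    def test_flags_rs1801133_on_published_counts(self, table1):
        results = {
            lid: s.association_scan(table1.datasets[lid])[0]
            for lid in ("rs1801133", "rs1042522")
        }
        assert results["rs1801133"].p_value < 0.05
        assert results["rs1042522"].p_value > 0.05
        assert s.flagged_loci([results["rs1801133"]]) == ["rs1801133"]

    def test_small_cells_route_to_exact_branch(self, table1):
        # rs17884306 has expected counts ~2.99 < 5 from the published margins
        res = s.association_scan(table1.datasets["rs17884306"])[0]
        assert res.test_used == "fisher-freeman-halton"
        assert res.min_expected < 5

    def test_large_cells_route_to_chi_square(self, table1):
        res = s.association_scan(table1.datasets["rs1042522"])[0]
        assert res.test_used == "pearson-chi-square"

    def test_degenerate_locus_reported_and_scan_continues(self):
        geno = np.column_stack([np.zeros(20, dtype=int), np.tile([0, 1, 2, 1], 5)])
        ds = make_dataset(geno, [1, 0] * 10)
        results = s.association_scan(ds)
        assert results[0].test_used == "degenerate"
        assert results[0].error is not None
        assert results[1].test_used != "degenerate"

    def test_bonferroni_scales_p(self, table1):
        ds = table1.datasets["rs1801133"]
        raw = s.association_scan(ds)[0].p_value
        adj = s.association_scan(ds, bonferroni=True)[0].p_value
        assert adj == pytest.approx(raw)  # single locus: m = 1

    def test_report_tsv(self, tmp_path, table1):
        results = s.association_scan(table1.datasets["rs1042522"])
        out = tmp_path / "assoc.tsv"
        from snpbn.association import write_association_tsv

        write_association_tsv(results, out)
        assert "rs1042522" in out.read_text()


class TestHwe:
    def test_pooled_rs1042522_near_equilibrium(self):
        loc = s.table1_locus("rs1042522")
        res = s.hwe_from_counts([293, 439, 188], loc)
        assert res.statistic == pytest.approx(1.01, abs=0.01)
        assert res.p_value > 0.05
        assert res.allele_frequency == pytest.approx(1025 / 1840)

    def test_pooled_rs7744_near_equilibrium(self):
        loc = s.table1_locus("rs7744")
        res = s.hwe_from_counts([378, 136, 406], loc)  # A, G, GA row order
        assert res.statistic == pytest.approx(2.47, abs=0.01)
        assert res.p_value > 0.05

    def test_exact_hwe_counts_give_zero_statistic(self):
        # p = 0.5, n = 400: (100, 200, 100)
        loc = s.Locus("rsX", ("A", "AG", "G"))
        res = s.hwe_from_counts([100, 200, 100], loc)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_monomorphic_locus(self):
        loc = s.Locus("rsX", ("A", "AG", "G"))
        res = s.hwe_from_counts([50, 0, 0], loc)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_cohort_selection(self):
        rng = np.random.default_rng(4)
        geno = rng.integers(0, 3, size=(200, 1))
        phen = np.array([1, 0] * 100)
        ds = make_dataset(geno, phen)
        pooled = s.hwe_test(ds, "rs0", cohort="pooled")
        controls = s.hwe_test(ds, "rs0", cohort="controls-only")
        # different cohorts, generally different statistics
        assert pooled.locus_id == controls.locus_id == "rs0"
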