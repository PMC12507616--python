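"""CPT estimation, exact inference and MAP combination search."""

import numpy as np
import pytest

import snpbn as s
from snpbn.discrete import DISEASE_NODE

from conftest import make_dataset, random_ternary_network


def binary_chain(p_a=0.6, p_b_given=((0.9, 0.1), (0.2, 0.8))):
    """Two-node network a -> b with binary nodes."""
    cpts = {
        "a": s.NodeCPT("a", (), (), np.array([[p_a, 1 - p_a]])),
        "b": s.NodeCPT("b", ("a",), (2,), np.array(p_b_given)),
    }
    return s.CPTSet(("a", "b"), cpts)


class TestFitCpts:
    def test_parentless_binary_smoothing(self):
        data = s.DiscreteData(("x",), (2,), np.array([[0]] * 7 + [[1]] * 3))
        st = s.NetworkStructure(("x",), [])
        cpts = s.fit_cpts(st, data, alpha=1.0)
        assert cpts.cpts["x"].table[0].tolist() == pytest.approx([8 / 12, 4 / 12])

    def test_unobserved_configuration_uniform(self):
        # parent state 2 never observed -> prior-only row
        values = np.array([[0, 0], [0, 1], [1, 2]])
        data = s.DiscreteData(("p", "c"), (3, 3), values)
        st = s.NetworkStructure(("p", "c"), [("p", "c")])
        cpts = s.fit_cpts(st, data, alpha=1.0)
        assert cpts.cpts["c"].table[2].tolist() == pytest.approx([1 / 3] * 3)

    def test_alpha_zero_is_maximum_likelihood(self):
        data = s.DiscreteData(("x",), (3,), np.array([[0]] * 6 + [[1]] * 3 + [[2]]))
        st = s.NetworkStructure(("x",), [])
        cpts = s.fit_cpts(st, data, alpha=0.0)
        assert cpts.cpts["x"].table[0].tolist() == pytest.approx([0.6, 0.3, 0.1])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        data = s.DiscreteData(
            ("a", "b", "c"), (3, 3, 3), rng.integers(0, 3, size=(50, 3))
        )
        st = s.NetworkStructure(("a", "b", "c"), [("a", "b"), ("a", "c")])
        cpts = s.fit_cpts(st, data)
        for node in st.node_ids:
            assert cpts.cpts[node].table.sum(axis=1) == pytest.approx(
                np.ones(cpts.cpts[node].table.shape[0])
            )

    def test_available_case_uses_per_family_rows(self):
        rng = np.random.default_rng(1)
        geno = rng.integers(0, 3, size=(400, 2)).astype(np.int8)
        geno[:200, 1] = -1  # locus rs1 half-missing; rs0 fully observed
        ds = make_dataset(geno, rng.integers(0, 2, 400))
        st = s.NetworkStructure(("rs0", "rs1", DISEASE_NODE),
                                [("rs0", DISEASE_NODE)])
        cpts = s.fit_cpts_available_case(st, ds)
        # rs0's marginal must match all 400 rows, not the 200 complete ones
        counts = np.bincount(geno[:, 0], minlength=3)
        expect = (counts + 1) / (400 + 3)
        assert cpts.cpts["rs0"].table[0] == pytest.approx(expect)


class TestJointProbability:
    def test_single_node(self):
        cpts = s.CPTSet(("a",), {"a": s.NodeCPT("a", (), (), np.array([[0.6, 0.4]]))})
        assert s.joint_probability(cpts, {"a": 0}) == pytest.approx(0.6)

    def test_independent_nodes_multiply(self):
        cpts = s.CPTSet(
            ("a", "b"),
            {
                "a": s.NodeCPT("a", (), (), np.array([[0.6, 0.4]])),
                "b": s.NodeCPT("b", (), (), np.array([[0.3, 0.7]])),
            },
        )
        assert s.joint_probability(cpts, {"a": 1, "b": 0}) == pytest.approx(0.12)

    def test_four_node_chain_rule(self):
        rng = np.random.default_rng(2)
        net = random_ternary_network(rng, 4)
        assignment = {n: int(rng.integers(3)) for n in net.nodes}
        manual = 1.0
        for n in net.nodes:
            c = net.cpts[n]
            j = c.config_index([assignment[p] for p in c.parents])
            manual *= c.table[j, assignment[n]]
        assert s.joint_probability(cpts=net, assignment=assignment) == pytest.approx(manual)

    def test_incomplete_assignment_rejected(self):
        cpts = binary_chain()
        with pytest.raises(ValueError, match="missing"):
            s.joint_probability(cpts, {"a": 0})


class TestPosterior:
    def test_no_evidence_gives_prior_marginal(self):
        cpts = binary_chain()
        # P(b=0) = 0.6*0.9 + 0.4*0.2
        assert s.posterior(cpts, "b")[0] == pytest.approx(0.62)

    def test_all_parents_observed_returns_cpt_row(self):
        cpts = binary_chain()
        assert s.posterior(cpts, "b", {"a": 1}).tolist() == pytest.approx([0.2, 0.8])

    def test_matches_enumeration_on_random_networks(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            net = random_ternary_network(rng, int(rng.integers(3, 7)))
            nodes = list(net.nodes)
            q = nodes[int(rng.integers(len(nodes)))]
            others = [n for n in nodes if n != q]
            n_ev = int(rng.integers(0, len(others) + 1))
            ev = {
                n: int(rng.integers(3))
                for n in rng.choice(others, size=n_ev, replace=False)
            }
            ve = s.posterior(net, q, ev)
            brute = s.posterior_enumerate(net, q, ev)
            assert np.abs(ve - brute).max() < 1e-10

    def test_d_separated_evidence_is_irrelevant(self):
        # c independent of (a -> b): conditioning on c leaves P(b | a) alone
        cpts = s.CPTSet(
            ("a", "b", "c"),
            {
                "a": s.NodeCPT("a", (), (), np.array([[0.6, 0.4]])),
                "b": s.NodeCPT("b", ("a",), (2,), np.array([[0.9, 0.1], [0.2, 0.8]])),
                "c": s.NodeCPT("c", (), (), np.array([[0.5, 0.5]])),
            },
        )
        base = s.posterior(cpts, "b", {"a": 0})
        with_c = s.posterior(cpts, "b", {"a": 0, "c": 1})
        assert with_c == pytest.approx(base)

    def test_impossible_evidence_raises(self):
        cpts = s.CPTSet(
            ("a", "b"),
            {
                "a": s.NodeCPT("a", (), (), np.array([[1.0, 0.0]])),
                "b": s.NodeCPT("b", ("a",), (2,), np.array([[0.5, 0.5], [0.5, 0.5]])),
            },
        )
        with pytest.raises(ValueError, match="impossible|zero"):
            s.posterior(cpts, "b", {"a": 1})

    def test_query_in_evidence_rejected(self):
        with pytest.raises(ValueError):
            s.posterior(binary_chain(), "a", {"a": 0})


class TestCptSerialisation:
    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        net = random_ternary_network(rng, 5)
        path = tmp_path / "cpts.json"
        net.to_json(path)
        back = s.CPTSet.from_json(path)
        assert back.nodes == net.nodes
        for n in net.nodes:
            assert back.cpts[n].table == pytest.approx(net.cpts[n].table)

    def test_evidence_csv(self, tmp_path):
        from snpbn.bn import read_evidence_csv

        path = tmp_path / "ev.csv"
        path.write_text("node,state\nrs1042522,1\nrs7744,0\n")
        assert read_evidence_csv(path) == {"rs1042522": 1, "rs7744": 0}


def disease_network(seed=0, n_loci=3):
    """Small loci -> disease network for MAP tests."""
    rng = np.random.default_rng(seed)
    loci = tuple(f"l{i}" for i in range(n_loci))
    cpts = {
        l: s.NodeCPT(l, (), (), rng.dirichlet(np.ones(3))[None, :]) for l in loci
    }
    tab = rng.dirichlet(np.ones(2), size=3 ** n_loci)
    cpts[DISEASE_NODE] = s.NodeCPT(DISEASE_NODE, loci, (3,) * n_loci, tab)
    return s.CPTSet((*loci, DISEASE_NODE), cpts)


class TestMapSearch:
    def test_enumeration_size_and_normalisation(self):
        net = disease_network(n_loci=3)
        res = s.map_search(net, evidence_state=1)
        assert res.n_enumerated == 27
        assert res.posterior.sum() == pytest.approx(1.0, abs=1e-12)

    def test_independent_binary_symmetry(self):
        cpts = s.CPTSet(
            ("l0", DISEASE_NODE),
            {
                "l0": s.NodeCPT("l0", (), (), np.array([[0.5, 0.5]])),
                DISEASE_NODE: s.NodeCPT(
                    DISEASE_NODE, (), (), np.array([[0.4, 0.6]])
                ),
            },
        )
        res = s.map_search(cpts, loci=("l0",), evidence_state=1)
        assert res.posterior.tolist() == pytest.approx([0.5, 0.5])

    def test_ranking_matches_enumeration_oracle(self):
        net = disease_network(seed=5, n_loci=3)
        res = s.map_search(net, evidence_state=1)
        # oracle: joint probabilities on the disease = 1 slice
        loci = res.loci
        joint = {}
        for flat in range(27):
            states = np.unravel_index(flat, (3, 3, 3))
            assignment = dict(zip(loci, map(int, states)))
            assignment[DISEASE_NODE] = 1
            joint[tuple(states)] = s.joint_probability(net, assignment)
        z = sum(joint.values())
        expect = sorted(joint, key=lambda k: (-joint[k] / z, k))
        assert [tuple(row) for row in res.states] == expect
        assert res.posterior[0] == pytest.approx(joint[expect[0]] / z)

    def test_disease_given_combo_reported(self):
        net = disease_network(seed=6, n_loci=2)
        res = s.map_search(net, evidence_state=1)
        top = res.top()
        manual = s.posterior(net, DISEASE_NODE, top)[1]
        assert res.disease_given_combo[0] == pytest.approx(manual)

    def test_cap_enforced(self):
        net = disease_network(n_loci=3)
        with pytest.raises(ValueError, match="cap"):
            s.map_search(net, max_enumeration=10)


class TestPredictDisease:
    def test_empty_evidence_is_prior(self):
        net = disease_network(seed=7, n_loci=2)
        assert s.predict_disease(net, {}) == pytest.approx(
            s.posterior(net, DISEASE_NODE)[1]
        )

    def test_deterministic_network_gives_certainty(self):
        cpts = s.CPTSet(
            ("l0", DISEASE_NODE),
            {
                "l0": s.NodeCPT("l0", (), (), np.array([[0.5, 0.3, 0.2]])),
                DISEASE_NODE: s.NodeCPT(
                    DISEASE_NODE, ("l0",), (3,),
                    np.array([[0.0, 1.0], [1.0, 0.0], [1.0, 0.0]]),
                ),
            },
        )
        assert s.predict_disease(cpts, {"l0": 0}) == pytest.approx(1.0)

    def test_matches_enumeration_on_partial_evidence(self):
        net = disease_network(seed=8, n_loci=3)
        ev = {"l0": 1}
        assert s.predict_disease(net, ev) == pytest.approx(
            s.posterior_enumerate(net, DISEASE_NODE, ev)[1]
        )


class TestParameterRecovery:
    def test_fitted_cells_converge_to_truth(self, scenario):
        spec = s.SyntheticSpec(
            scenario.structure, scenario.cpts,
            n_cases=2500, n_controls=2500, missing_rate=0.06, seed=101,
        )
        report = s.recovery_experiment(spec)
        assert report.max_cpt_error < 0.05
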