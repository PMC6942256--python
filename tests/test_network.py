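import itertools

import numpy as np
import pytest
from scipy import stats
from hypothesis import given, settings, strategies as st

from gutnet import (build_network, expected_intra_fraction,
                    extract_condition_subnetwork, generate_dataset,
                    intra_phylum_fraction, pearson_edge, random_null)
from gutnet.differential import (DifferentialRecord, AbundantFamilySet,
                                 differential_table, top_abundant_families)
from gutnet.network import (CoAbundanceNetwork, EdgeStat, NodeAttrs,
                            ZeroVarianceError, pearson_t_pvalue)
from gutnet.simulate import SyntheticSpec

from conftest import make_table


def toy_network(nodes, edges, r=0.9):
    attrs = {f: NodeAttrs(p, 0.1) for f, p in nodes.items()}
    stats_ = [EdgeStat(u, v, r, 1e-12, 100) for u, v in edges]
    return CoAbundanceNetwork(attrs, stats_)


class TestPearsonEdge:
    def test_perfect_correlation(self):
        e = pearson_edge([1, 2, 3], [1, 2, 3])
        assert e.r == pytest.approx(1.0) and e.p == 0.0

    def test_perfect_anticorrelation(self):
        assert pearson_edge([1, 2, 3], [3, 2, 1]).r == pytest.approx(-1.0)

    def test_hand_computed_r_and_t(self):
        e = pearson_edge([1, 2, 3, 4], [1, 3, 2, 4])
        assert e.r == pytest.approx(0.8, abs=1e-12)
        t = e.r * np.sqrt(2 / (1 - e.r ** 2))
        assert t == pytest.approx(1.8856, abs=1e-4)
        assert e.p == pytest.approx(2 * stats.t.sf(t, 2), abs=1e-12)

    def test_zero_variance_marked_untestable(self):
        with pytest.raises(ZeroVarianceError):
            pearson_edge([1, 1, 1], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            pearson_edge([1, 2, 3], [1, 2])

    def test_matches_scipy_on_fuzzed_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(5, 201))
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            e = pearson_edge(x, y)
            ref_r, ref_p = stats.pearsonr(x, y)
            assert abs(e.r - ref_r) < 1e-12
            assert abs(e.p - ref_p) < 1e-10

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5), seed=st.integers(0, 100))
    @settings(derandomize=True, deadline=None, max_examples=30)
    def test_r_invariant_under_positive_affine_rescaling(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = pearson_edge(x, y)
        scaled = pearson_edge(a * x + b, y)
        assert scaled.r == pytest.approx(base.r, abs=1e-9)


class TestBuildNetwork:
    def test_boundary_r_excluded(self):
        # r_min set to the pair's realized r: strict '>' must drop the edge
        rng = np.random.default_rng(0)
        f = rng.normal(size=2000)
        x = 0.7 * f + rng.normal(size=2000)
        y = 0.7 * f + rng.normal(size=2000)
        rel = make_table(np.vstack([_pos(x), _pos(y),
                                    _pos(rng.normal(size=2000))]),
                         ["FA", "FB", "FC"], ["P", "P", "Q"],
                         sample_ids=[f"s{i}" for i in range(2000)]).to_relative()
        fam = rel.aggregate_to_rank("family")
        realized = pearson_edge(fam.values.loc["FA"].to_numpy(),
                                fam.values.loc["FB"].to_numpy()).r
        at = build_network(rel, r_min=realized, min_prevalence=1)
        below = build_network(rel, r_min=realized - 1e-9, min_prevalence=1)
        assert ("FA", "FB") not in at.edge_pairs()
        assert ("FA", "FB") in below.edge_pairs()

    def test_planted_latent_pair_connected(self):
        rng = np.random.default_rng(3)
        f = rng.normal(size=2000)
        rho = 0.9
        x = rho * f + np.sqrt(1 - rho ** 2) * rng.normal(size=2000)
        y = rho * f + np.sqrt(1 - rho ** 2) * rng.normal(size=2000)
        table = make_table(np.vstack([_pos(x), _pos(y), _pos(rng.normal(size=2000))]),
                           ["FA", "FB", "FC"], ["P", "P", "Q"],
                           sample_ids=[f"s{i}" for i in range(2000)])
        net = build_network(table.to_relative(), min_prevalence=1)
        assert ("FA", "FB") in net.edge_pairs()

    def test_unclassified_families_excluded_by_default(self, six_family_table):
        net = build_network(six_family_table.to_relative(), r_min=0.0,
                            p_max=1.0, min_prevalence=1)
        assert "unclassified" not in net.nodes

    def test_edges_match_per_pair_pearson(self, six_family_table):
        rel = six_family_table.to_relative()
        net = build_network(rel, r_min=0.0, p_max=1.0, min_prevalence=1)
        fam = rel.aggregate_to_rank("family")
        for e in net.edges:
            ref = pearson_edge(fam.values.loc[e.family_u].to_numpy(),
                               fam.values.loc[e.family_v].to_numpy())
            assert e.r == pytest.approx(ref.r, abs=1e-10)
            assert e.p == pytest.approx(ref.p, abs=1e-10)

    def test_invariant_to_sample_and_taxon_order(self):
        spec = SyntheticSpec(seed=9, n_studies=1, samples_per_study=80,
                             phyla=(("P1", 4), ("P2", 4)))
        table, _ = generate_dataset(spec)
        rel = table.to_relative()
        net = build_network(rel, min_prevalence=1)
        rng = np.random.default_rng(1)
        cols = list(rng.permutation(rel.sample_ids))
        rows = rng.permutation(len(rel.taxon_ids))
        from gutnet import RelativeAbundanceTable
        shuffled = RelativeAbundanceTable(
            rel.values.iloc[rows][cols],
            [rel.lineages[i] for i in rows],
            rel.metadata.loc[cols])
        net2 = build_network(shuffled, min_prevalence=1)
        assert net.edge_pairs() == net2.edge_pairs()

    def test_too_few_eligible_families_rejected(self):
        table = make_table([[1, 2, 3], [2, 3, 4]], ["F1", "F2"], ["P", "P"])
        with pytest.raises(ValueError, match="eligible"):
            build_network(table.to_relative(), min_prevalence=10)


class TestIntraPhylumFraction:
    def test_enumerated_example(self):
        net = toy_network({"A1": "P", "A2": "P", "B1": "Q"},
                          [("A1", "A2"), ("A1", "B1")])
        assert intra_phylum_fraction(net) == pytest.approx(0.5)

    def test_single_phylum_is_one(self):
        net = toy_network({"A": "P", "B": "P"}, [("A", "B")])
        assert intra_phylum_fraction(net) == 1.0

    def test_empty_edge_set_undefined(self):
        net = toy_network({"A": "P", "B": "Q"}, [])
        with pytest.raises(ValueError, match="undefined"):
            intra_phylum_fraction(net)

    @given(seed=st.integers(0, 500))
    @settings(derandomize=True, deadline=None, max_examples=30)
    def test_matches_brute_force_edge_scan(self, seed):
        rng = np.random.default_rng(seed)
        families = [f"F{i}" for i in range(12)]
        phyla = {f: f"P{rng.integers(0, 3)}" for f in families}
        pairs = list(itertools.combinations(families, 2))
        chosen = [pairs[i] for i in rng.choice(len(pairs), size=10, replace=False)]
        net = toy_network(phyla, chosen)
        brute = sum(phyla[u] == phyla[v] for u, v in chosen) / len(chosen)
        assert intra_phylum_fraction(net) == pytest.approx(brute)


class TestRandomNull:
    def test_analytic_enumeration_small(self):
        # phylum sizes {3, 2}: 10 pairs, 3 + 1 intra -> 0.4
        assert expected_intra_fraction(["P"] * 3 + ["Q"] * 2) == pytest.approx(0.4)

    def test_single_phylum_expectation_one(self):
        summary = random_null(["P"] * 5, n_edges=3, n_reps=10, seed=0)
        assert summary.expected_fraction_analytic == 1.0
        assert (summary.null_fractions == 1.0).all()

    def test_monte_carlo_converges_to_analytic(self):
        summary = random_null(["P"] * 3 + ["Q"] * 2, n_edges=4,
                              n_reps=10_000, seed=7)
        assert abs(summary.null_mean - 0.4) < 0.01

    def test_reproducible_given_seed(self):
        a = random_null(["P", "P", "Q", "Q"], 2, n_reps=50, seed=11)
        b = random_null(["P", "P", "Q", "Q"], 2, n_reps=50, seed=11)
        assert np.array_equal(a.null_fractions, b.null_fractions)

    def test_too_many_edges_rejected(self):
        with pytest.raises(ValueError, match="n_edges"):
            random_null(["P", "Q"], n_edges=2, n_reps=5, seed=0)


def _record(taxon, fold, direction, mean_b=0.1):
    return DifferentialRecord(taxon, "family", "CD", "healthy",
                              mean_a=mean_b * fold, mean_b=mean_b,
                              fold=fold, direction=direction)


class TestSubnetwork:
    def setup_method(self):
        self.net = toy_network({"F1": "P", "F2": "P", "F3": "Q"},
                               [("F1", "F2"), ("F2", "F3")])

    def test_rule_application(self):
        diff = [_record("F1", 2.0, "increased_in_a"),
                _record("F2", 1.0, "unchanged"),
                _record("F3", 1.0, "unchanged")]
        abundant = [AbundantFamilySet("CD", ("F1",), 1)]
        sub = extract_condition_subnetwork(self.net, diff, abundant)
        assert sub.edge_pairs() == {("F1", "F2")}
        assert set(sub.nodes) == {"F1", "F2"}
        assert sub.nodes["F1"].direction == "increased_in_a"
        assert sub.nodes["F1"].healthy_mean == pytest.approx(0.1)

    def test_no_fold_exceeds_threshold_gives_empty(self):
        diff = [_record(f, 1.2, "unchanged") for f in ("F1", "F2", "F3")]
        abundant = [AbundantFamilySet("CD", ("F1", "F2", "F3"), 3)]
        sub = extract_condition_subnetwork(self.net, diff, abundant)
        assert sub.n_edges == 0 and sub.n_nodes == 0

    def test_label_mismatch_lists_families(self):
        diff = [_record("F1", 2.0, "increased_in_a")]
        with pytest.raises(ValueError, match="F2.*F3"):
            extract_condition_subnetwork(self.net, diff, [])

    def test_subnetwork_edges_subset_of_network(self, ibd_cohort):
        table, _ = ibd_cohort
        rel = table.to_relative()
        net = build_network(rel)
        diff = differential_table(rel, "CD", "healthy")
        abundant = [top_abundant_families(rel, c) for c in ("CD", "healthy")]
        sub = extract_condition_subnetwork(net, diff, abundant)
        assert sub.edge_pairs() <= net.edge_pairs()

    def test_matches_brute_force_filter(self):
        spec = SyntheticSpec(seed=3, n_studies=1, samples_per_study=300,
                             phyla=(("P1", 5), ("P2", 5), ("P3", 5), ("P4", 5)),
                             condition_effects={"CD": {"P1_f01": 2.5,
                                                       "P2_f01": 1 / 3.0,
                                                       "P3_f02": 4.0}},
                             conditions=("CD", "healthy"))
        table, _ = generate_dataset(spec)
        rel = table.to_relative()
        net = build_network(rel)
        diff = differential_table(rel, "CD", "healthy")
        abundant = [top_abundant_families(rel, c, k=8) for c in ("CD", "healthy")]
        sub = extract_condition_subnetwork(net, diff, abundant)

        by_taxon = {r.taxon: r for r in diff}
        members = set(abundant[0].families) | set(abundant[1].families)
        brute = {e.pair for e in net.edges
                 if ({e.family_u, e.family_v} & members)
                 and (by_taxon[e.family_u].fold > 1.5
                      or by_taxon[e.family_v].fold > 1.5)}
        assert sub.edge_pairs() == brute


def _pos(x):
    """Shift a real vector into positive count-like territory."""
    x = np.asarray(x)
    return np.round((x - x.min() + 0.1) * 100).astype(int) + 1
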