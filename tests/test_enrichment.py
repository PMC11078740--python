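import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import causalprox as cp
from causalprox.enrichment import (
    ContingencyTable,
    extend_pathway_membership,
    fisher_enrichment_p,
    ora,
    phenotype_enrichment_random_lists,
    phenotype_enrichment_ttest,
    ppa,
)
from causalprox.proxpath import ProximityRecord
from causalprox.synthetic import SyntheticSpec, generate, null_spec
from conftest import make_graph


def hypergeom_tail_oracle(k, n, K, N):
    """Exact upper-tail P(X >= k) by integer-arithmetic enumeration."""
    total = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i)
               for i in range(k, min(n, K) + 1)) / total


class TestFisher:
    def test_point_mass_when_query_equals_term(self):
        t = ContingencyTable(k=5, n=5, K=5, N=100)
        assert fisher_enrichment_p(t) == pytest.approx(1 / comb(100, 5), rel=1e-12)

    def test_empty_term_gives_p_one(self):
        assert fisher_enrichment_p(ContingencyTable(k=0, n=10, K=0, N=100)) == 1.0

    def test_example_table_matches_tail_sum(self):
        t = ContingencyTable(k=8, n=10, K=20, N=100)
        assert fisher_enrichment_p(t) == pytest.approx(
            hypergeom_tail_oracle(8, 10, 20, 100), abs=1e-12)

    @given(st.integers(min_value=1, max_value=200), st.data())
    @settings(max_examples=200, deadline=None)
    def test_matches_oracle_for_random_tables(self, N, data):
        K = data.draw(st.integers(min_value=0, max_value=N))
        n = data.draw(st.integers(min_value=0, max_value=N))
        k_min, k_max = max(0, n + K - N), min(n, K)
        k = data.draw(st.integers(min_value=k_min, max_value=k_max))
        t = ContingencyTable(k=k, n=n, K=K, N=N)
        assert fisher_enrichment_p(t) == pytest.approx(
            hypergeom_tail_oracle(k, n, K, N), abs=1e-12)

    def test_invalid_table_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(k=6, n=5, K=10, N=100)


class TestOra:
    def test_bonferroni_is_exact_min_of_one(self):
        bg = [f"G{i}" for i in range(50)]
        sets = {"t1": set(bg[:5]), "t2": set(bg[5:10]), "t3": set(bg[10:30])}
        res = ora(bg[:5], sets, bg, correction="bonferroni")
        for r in res:
            assert r.p_adj == pytest.approx(min(1.0, 3 * r.p_raw))

    def test_bh_preserves_order(self):
        bg = [f"G{i}" for i in range(60)]
        sets = {f"t{j}": set(bg[j * 5:(j + 1) * 5]) for j in range(6)}
        res = ora(bg[:7], sets, bg, correction="bh")
        ps = [r.p_raw for r in sorted(res, key=lambda r: r.p_raw)]
        padj = [r.p_adj for r in sorted(res, key=lambda r: r.p_raw)]
        assert padj == sorted(padj)
        assert all(a >= p for a, p in zip(padj, ps))

    def test_query_outside_background_dropped_and_empty_errors(self):
        bg = ["A", "B", "C"]
        with pytest.raises(ValueError):
            ora(["Z"], {"t": {"A"}}, bg)


class TestExtension:
    def test_member_always_in_extended_set(self, default_net):
        g, truth = default_net
        members = truth.pathway_memberships["PW0"]
        ext = extend_pathway_membership(g, members)
        assert members <= ext.members

    def test_isolated_protein_never_added(self):
        g = make_graph([("A", "B", 1, 0.9), ("C", "B", 1, 0.2),
                        ("D", "B", 1, 0.5), ("E", "Z", 1, 0.5)])
        ext = extend_pathway_membership(g, {"B"})
        assert "E" not in ext.members

    def test_degenerate_distribution_flagged(self):
        g = make_graph([("A", "B", 1, 0.5)])
        ext = extend_pathway_membership(g, {"B"})
        assert ext.degenerate and ext.members == {"B"}

    def test_satellite_regulator_recovered(self, default_net):
        g, truth = default_net
        ext = extend_pathway_membership(g, truth.pathway_memberships["PW0"])
        assert truth.satellite_regulators["PW0"] <= ext.added


class TestPpa:
    def test_reduces_to_ora_without_extension(self):
        # star graph with a degenerate pathway distribution: no extension
        g = make_graph([("A", "B", 1, 0.5)])
        bg = ["A", "B", "C"]
        res_ppa = ppa(["A"], {"t": {"A"}}, g, background=bg)
        res_ora = ora(["A"], {"t": {"A"}}, bg)
        assert res_ppa[0].p_raw == res_ora[0].p_raw

    def test_proximity_added_hits_raise_k(self, default_net):
        g, truth = default_net
        q = truth.satellite_regulators["PW0"]
        sets = truth.pathway_memberships
        k_ora = {r.term: r.table.k for r in ora(q, sets, g.proteins)}
        res = ppa(q, sets, g)
        k_ppa = {r.term: r.table.k for r in res}
        assert k_ppa["PW0"] > k_ora["PW0"]
        hit = {r.term: r for r in res}["PW0"]
        assert hit.n_extended_hits == len(q) and hit.n_curated_hits == 0

    def test_planted_satellites_significant_only_under_ppa(self, default_net):
        g, truth = default_net
        q = truth.satellite_regulators["PW0"]
        sets = truth.pathway_memberships
        p_ora = {r.term: r.p_adj for r in ora(q, sets, g.proteins)}
        p_ppa = {r.term: r.p_adj for r in ppa(q, sets, g)}
        assert p_ppa["PW0"] < 0.05 <= p_ora["PW0"]


def fake_records(target, z_by_source, sign=1):
    return [
        ProximityRecord(source=s, target=target, best_distance=0.5, z=z,
                        net_sign=sign, significant=z < -1.96, n_paths=1)
        for s, z in z_by_source.items()
    ]


class TestPhenotypeTtest:
    def test_shifted_query_is_highly_significant(self):
        rng = np.random.default_rng(0)
        bg = {f"B{i}": float(z) for i, z in enumerate(rng.normal(0, 1, 60))}
        q = {f"Q{i}": float(z) for i, z in enumerate(rng.normal(-3, 1, 10))}
        recs = fake_records("P", {**bg, **q})
        res = phenotype_enrichment_ttest(recs, q.keys())
        assert res[0].p_raw < 1e-4

    def test_direction_up_when_all_query_signs_positive(self):
        recs = fake_records("P", {f"S{i}": float(i) for i in range(10)}, sign=1)
        res = phenotype_enrichment_ttest(recs, ["S0", "S1", "S2"])
        assert res[0].direction == "up"

    def test_small_groups_skipped(self):
        recs = fake_records("P", {"A": 0.0, "B": 1.0, "C": 2.0, "D": 3.0})
        assert phenotype_enrichment_ttest(recs, ["A", "B"]) == []

    def test_null_calibration(self):
        # uniform random queries: rejection rate at alpha=0.05 stays within
        # the binomial band around 0.05
        spec = null_spec(SyntheticSpec(seed=23, background_edge_density=0.016))
        g, _ = generate(spec)
        res = cp.proximity_scores(g, g.phenotypes)
        rng = np.random.default_rng(99)
        prots = np.array(g.proteins)
        rej = n = 0
        for _ in range(40):
            q = set(prots[rng.choice(len(prots), size=100, replace=False)])
            for r in phenotype_enrichment_ttest(res, q):
                n += 1
                rej += r.p_raw <= 0.05
        rate = rej / n
        band = 2 * math.sqrt(0.05 * 0.95 / n)
        assert abs(rate - 0.05) <= band


class TestRandomLists:
    def test_observed_zero_gives_p_one(self, default_net):
        g, _ = default_net
        # query of isolated-from-PHEN_0 sources: choose phenotype nodes' ids absent
        q = [p for p in g.proteins if p.startswith("P04")][:5]
        res = phenotype_enrichment_random_lists(
            g, q, phenotypes=["PHEN_3"], n_lists=100, seed=1)
        r = res[0]
        if r.statistic == 0:
            assert r.p_raw == 1.0

    def test_top_query_hits_floor_p(self, default_net):
        g, truth = default_net
        q = sorted(truth.planted_proximal["PHEN_0"])
        res = phenotype_enrichment_random_lists(
            g, q, phenotypes=["PHEN_0"], n_lists=200, seed=2)
        assert res[0].p_raw == pytest.approx(1 / 201)

    def test_pseudocount_bounds_and_monotonicity(self):
        from causalprox.topology import _empirical_p
        nulls = np.arange(100)
        ps = [_empirical_p(nulls, obs) for obs in (0, 50, 99, 150)]
        assert all(1 / 101 <= p <= 1 for p in ps)
        assert ps == sorted(ps, reverse=True)

    def test_oversized_query_rejected(self, default_net):
        g, _ = default_net
        with pytest.raises(ValueError):
            phenotype_enrichment_random_lists(g, g.proteins + ["X"] * 10,
                                              n_lists=100)

    def test_null_calibration(self):
        spec = null_spec(SyntheticSpec(seed=23, background_edge_density=0.016))
        g, _ = generate(spec)
        res = cp.proximity_scores(g, g.phenotypes)
        rng = np.random.default_rng(7)
        prots = np.array(g.proteins)
        rej = n = 0
        for rep in range(40):
            q = list(prots[rng.choice(len(prots), size=150, replace=False)])
            for r in phenotype_enrichment_random_lists(
                    g, q, n_lists=200, seed=3000 + rep, records=res.records):
                n += 1
                rej += r.p_raw <= 0.05
        rate = rej / n
        band = 2 * math.sqrt(0.05 * 0.95 / n)
        assert abs(rate - 0.05) <= band
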