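"""Degree distributions, scale-free threshold selection, and the iGRN."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ernascape.intervals import GenomicInterval
from ernascape.network import (
    FitUndefinedError,
    build_igrn,
    build_network,
    degree_distribution,
    network_summary,
    pearson_r,
    scale_free_fit,
    select_threshold,
)


class TestPearson:
    def test_exact_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 3) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_example(self):
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_zero_variance_signalled(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestDegreeDistribution:
    def test_path_graph(self):
        assert degree_distribution(nx.path_graph(4)) == {1: 0.5, 2: 0.5}

    def test_complete_graph(self):
        assert degree_distribution(nx.complete_graph(5)) == {4: 1.0}

    def test_star_graph(self):
        got = degree_distribution(nx.star_graph(5))  # 6 nodes
        assert got[1] == pytest.approx(5 / 6) and got[5] == pytest.approx(1 / 6)

    def test_sums_to_one_with_isolated_nodes(self):
        g = nx.path_graph(4)
        g.add_nodes_from(["iso1", "iso2"])
        assert sum(degree_distribution(g).values()) == pytest.approx(1.0)


class TestScaleFreeFit:
    def test_exact_power_law(self):
        ks = np.arange(1, 11)
        pk = {int(k): float(k**-2.0) for k in ks}
        norm = sum(pk.values())
        pk = {k: v / norm for k, v in pk.items()}
        slope, r2 = scale_free_fit(pk)
        assert slope == pytest.approx(-2.0)
        assert r2 == pytest.approx(1.0)

    def test_uniform_distribution_no_signal(self):
        slope, r2 = scale_free_fit({k: 0.1 for k in range(1, 11)})
        assert slope == pytest.approx(0.0) and r2 == 0.0

    def test_too_few_degrees_undefined(self):
        with pytest.raises(FitUndefinedError):
            scale_free_fit({1: 0.5, 2: 0.5})

    def test_preferential_attachment_fits_power_law(self):
        g = nx.barabasi_albert_graph(1000, 2, seed=42)
        _, r2 = scale_free_fit(degree_distribution(g))
        assert r2 >= 0.8


def module_matrix(n_modules=40, size=5, n_samples=12, r=0.95, seed=3):
    rng = np.random.default_rng(seed)
    sd = np.sqrt(1 / r - 1)
    rows, names = [], []
    for m in range(n_modules):
        latent = rng.normal(0, 1, n_samples)
        for j in range(size):
            rows.append(latent + rng.normal(0, sd, n_samples))
            names.append(f"m{m}_f{j}")
    return pd.DataFrame(rows, index=names)


class TestSelectThreshold:
    def test_module_data_selects_near_construction_r(self):
        # uniform clique sizes cannot reach a power-law fit, but the best
        # candidate must still sit near the construction correlation
        sel = select_threshold(module_matrix(), target_r2=0.95)
        assert 0.85 <= sel.threshold <= 0.97

    def test_candidate_r2_trace_recorded(self):
        sel = select_threshold(module_matrix(), target_r2=0.95)
        assert set(sel.r2_by_candidate) >= {0.5, 0.9}
        defined = [v for v in sel.r2_by_candidate.values() if v == v]
        assert defined and all(0.0 <= v <= 1.0 for v in defined)

    def test_pure_noise_flags_non_convergence(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, (60, 12)),
                            index=[f"f{i}" for i in range(60)])
        sel = select_threshold(expr, target_r2=0.95)
        assert not sel.converged

    def test_single_candidate_meeting_target(self):
        sel = select_threshold(module_matrix(), candidates=[0.9], target_r2=0.5)
        assert sel.converged and sel.threshold == 0.9


class TestBuildNetwork:
    def test_raising_threshold_never_adds_edges(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, (30, 10)),
                            index=[f"f{i}" for i in range(30)])
        low = set(build_network(expr, 0.3).edges())
        high = set(build_network(expr, 0.6).edges())
        assert high <= low

    def test_edges_invariant_under_sample_permutation(self, rng):
        expr = module_matrix(n_modules=5)
        perm = rng.permutation(expr.shape[1])
        shuffled = expr.iloc[:, perm]
        assert set(build_network(expr, 0.9).edges()) == \
            set(build_network(shuffled, 0.9).edges())

    def test_no_self_edges(self):
        g = build_network(module_matrix(n_modules=3), 0.5)
        assert all(a != b for a, b in g.edges())


class TestBuildIgrn:
    @pytest.fixture()
    def planted(self):
        rng = np.random.default_rng(9)
        sd = np.sqrt(1 / 0.98 - 1)
        latent = rng.normal(0, 1, 12)
        rows = {"e1": latent + rng.normal(0, sd, 12)}
        for j in range(6):
            rows[f"g{j}"] = latent + rng.normal(0, sd, 12)
        rows["far_gene"] = rng.normal(0, 1, 12)
        expr = pd.DataFrame.from_dict(rows, orient="index")
        enh = [GenomicInterval("c", 100_000, 100_400, ".", "e1")]
        genes = [GenomicInterval("c", 150_000 + 40_000 * j, 152_000 + 40_000 * j,
                                 "+", f"g{j}") for j in range(6)]
        return enh, genes, expr

    def test_module_edges_recovered_at_high_threshold(self, planted):
        enh, genes, expr = planted
        g = build_igrn(enh, {"e1": 2}, genes, expr, threshold=0.95)
        assert g.degree("e1") >= 5

    def test_enhancer_without_wbox_excluded(self, planted):
        enh, genes, expr = planted
        g = build_igrn(enh, {"e1": 0}, genes, expr, threshold=0.5)
        assert "e1" not in g

    def test_one_megabase_boundary(self, planted):
        enh, _, expr = planted
        at_limit = GenomicInterval("c", 1_100_400, 1_102_000, "+", "g0")
        beyond = GenomicInterval("c", 1_100_401, 1_102_000, "+", "g1")
        g = build_igrn(enh, {"e1": 1}, [at_limit, beyond], expr, threshold=0.0)
        assert g.has_edge("e1", "g0")
        assert "g1" not in g

    def test_summary_matches_brute_force_recount(self, planted):
        enh, genes, expr = planted
        g = build_igrn(enh, {"e1": 3}, genes, expr, threshold=0.9,
                       wrky_ids={"g0"})
        s = network_summary(g)
        edges = list(g.edges())
        assert s["n_edges"] == len(edges)
        assert s["genes_per_enhancer"]["e1"] == sum(1 for a, b in edges
                                                    if "e1" in (a, b))
        assert s["n_wrky"] == sum(1 for n in g if g.nodes[n].get("kind") == "wrky_gene")
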