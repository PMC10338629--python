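"""Network inference: node models, trimming, and the three-network consensus."""

import numpy as np
import pandas as pd
import pytest

from tolnet.network import (
    MultiOmicNetwork,
    consensus,
    fit_node_model,
    infer_network,
    trim_network,
)
from tolnet.priors import PriorSet, _canon
from tolnet.sgl import solve_sparse_group_lasso
from tolnet.simulate import SimulationConfig, generate_priors, simulate_timecourse


def _edges(rows):
    return pd.DataFrame(rows, columns=["source", "target", "beta", "r2"])


class TestFitNodeModel:
    def test_single_perfect_predictor(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"x": x})
        model = fit_node_model(2.0 * x, X, ["protein"], seed=0, target="y")
        assert model.selected() and model.selected()[0][0] == "x"
        # final fit sits at the bottom of the penalty grid, so R^2 is 1 up to
        # the residual shrinkage of lam = 0.01 * lam_max
        assert model.r2 == pytest.approx(1.0, abs=1e-3)

    def test_no_candidates_gives_empty_model(self):
        model = fit_node_model(np.ones(10), pd.DataFrame(index=range(10)), [], target="y")
        assert model.r2 == 0.0 and not model.selected()

    def test_pure_noise_candidates_rarely_selected(self):
        counts = []
        for seed in range(20):
            r = np.random.default_rng(1000 + seed)
            X = pd.DataFrame(r.normal(size=(24, 8)), columns=[f"x{i}" for i in range(8)])
            y = r.normal(size=24)
            model = fit_node_model(y, X, ["a"] * 4 + ["b"] * 4, seed=seed)
            counts.append(len(model.selected()))
        assert np.mean(counts) <= 1.0

    def test_planted_pair_with_decoys(self):
        """x1 (+) and x2 (-) recovered with correct signs in most replicates."""
        ok = 0
        for seed in range(20):
            r = np.random.default_rng(2000 + seed)
            x1, x2 = r.normal(size=20), r.normal(size=20)
            y = 0.8 * x1 - 0.8 * x2 + 0.3 * r.normal(size=20)
            cols = {"x1": x1, "x2": x2}
            cols.update({f"d{i}": r.normal(size=20) for i in range(10)})
            X = pd.DataFrame(cols)
            model = fit_node_model(y, X, ["a", "a"] + ["b"] * 10, seed=seed)
            sel = dict(model.selected())
            if sel.get("x1", 0) > 0 and sel.get("x2", 0) < 0:
                ok += 1
        assert ok >= 16  # 80% of 20 replicates

    def test_too_few_samples_for_cv(self):
        X = pd.DataFrame({"x": np.arange(3.0)})
        with pytest.raises(ValueError, match="cross-validation"):
            fit_node_model(np.arange(3.0), X, ["a"], cv_folds=5)


@pytest.fixture(scope="module")
def tiny_noiseless():
    cfg = SimulationConfig(
        n_genes=10, n_proteins=8, n_clinical=2, n_true_edges=10,
        noise_sd=0.0, prior_coverage=1.0, decoy_prior_edges=0,
        n_de_unique={"initiation": 0, "progression": 0, "tolerance": 0}, n_de_shared=10,
        missingness_midpoint=-60.0,  # effectively no dropout
        seed=4,
    )
    dataset, truth = simulate_timecourse(cfg)
    priors = generate_priors(cfg, truth)
    return cfg, dataset, truth, priors


def test_noiseless_low_penalty_recovers_superset(tiny_noiseless):
    """With no noise and complete priors, tiny penalties keep every true edge.

    Oracle: per-node OLS — in the noiseless system each target is an exact
    linear function of its true parents, so the regression at lam -> 0 must
    assign them nonzero weight.
    """
    cfg, dataset, truth, priors = tiny_noiseless
    rows = {f: dataset.transcript.loc[f].to_numpy() for f in dataset.transcript.index}
    prot = np.log2(dataset.protein_raw.drop(columns="REF"))
    rows.update({f: prot.loc[f].to_numpy() for f in prot.index})
    for target in prot.index:
        # only features that actually vary can carry signal in the noiseless system
        parents = [s for s, t, _ in truth.true_edges
                   if t == target and rows[s].std() > 1e-9]
        if not parents or rows[target].std() < 1e-9:
            continue
        cand = sorted(
            priors.genes_of_protein(target) | priors.ppi_partners(target)
        )
        X = np.column_stack([rows[c] for c in cand])
        sd = X.std(axis=0)
        Xs = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        y = rows[target] - rows[target].mean()
        beta = solve_sparse_group_lasso(y, Xs, np.zeros(len(cand), dtype=int),
                                        1e-6, 0.5, tol=1e-10)
        selected = {c for c, b in zip(cand, beta) if abs(b) > 1e-6}
        assert set(parents) <= selected


def test_infer_network_empty_priors(small_dataset):
    dataset, _, _ = small_dataset
    mats = {
        "transcript": dataset.transcript,
        "protein": np.log2(dataset.protein_raw.drop(columns="REF")).fillna(0.0),
        "clinical": dataset.clinical,
    }
    net = infer_network(mats, PriorSet(), "protein", seed=1)
    # clinical covariates are design-given candidates, not prior-derived, so
    # only molecular predictors must vanish with empty priors
    assert all(s.startswith("C") for s in net.edges["source"])
    assert set(net.nodes) >= set(dataset.transcript.index)


def test_infer_network_rejects_misaligned_layers(small_dataset):
    dataset, _, priors = small_dataset
    mats = {
        "transcript": dataset.transcript.iloc[:, ::-1],
        "protein": np.log2(dataset.protein_raw.drop(columns="REF")).fillna(0.0),
        "clinical": dataset.clinical,
    }
    with pytest.raises(ValueError, match="misaligned"):
        infer_network(mats, priors, "transcript", seed=1)


class TestTrim:
    NODES = {c: "protein" for c in "abcdxy"}

    def test_low_r2_models_dropped(self):
        net = MultiOmicNetwork("protein", dict(self.NODES),
                               _edges([("a", "b", 0.5, 0.05), ("c", "d", 0.5, 0.5)]))
        out = trim_network(net)
        assert out.pairs() == {("c", "d")}
        assert set(out.nodes) == {"c", "d"}  # isolated nodes removed

    def test_beta_boundary_kept_below_removed(self):
        net = MultiOmicNetwork("protein", dict(self.NODES),
                               _edges([("a", "b", 0.001, 0.9), ("c", "d", 0.002, 0.9)]))
        out = trim_network(net)
        assert out.pairs() == {("c", "d")}

    def test_zero_thresholds_identity(self):
        edges = _edges([("a", "b", 0.0005, 0.01), ("c", "d", 0.9, 0.99)])
        net = MultiOmicNetwork("protein", dict(self.NODES), edges)
        out = trim_network(net, r2_min=0.0, beta_min=0.0)
        assert out.pairs() == net.pairs()

    def test_monotone_under_stricter_thresholds(self, rng):
        rows = [(f"a{i}", f"b{i}", float(rng.normal()), float(rng.uniform())) for i in range(50)]
        nodes = {n: "protein" for r in rows for n in r[:2]}
        net = MultiOmicNetwork("protein", nodes, _edges(rows))
        loose = trim_network(net, 0.1, 0.002)
        for r2m, bm in [(0.3, 0.002), (0.1, 0.5), (0.4, 0.6)]:
            strict = trim_network(net, r2m, bm)
            assert strict.pairs() <= loose.pairs()

    def test_self_edges_rejected(self):
        with pytest.raises(ValueError, match="self-edges"):
            MultiOmicNetwork("protein", {"a": "protein"}, _edges([("a", "a", 1.0, 1.0)]))


class TestConsensus:
    LAYERS = {"g1": "transcript", "p1": "protein", "p2": "protein",
              "c1": "clinical", "c2": "clinical"}

    def _nets(self, t_edges, p_edges, c_edges):
        return [
            MultiOmicNetwork("transcript", dict(self.LAYERS), _edges(t_edges)),
            MultiOmicNetwork("protein", dict(self.LAYERS), _edges(p_edges)),
            MultiOmicNetwork("clinical", dict(self.LAYERS), _edges(c_edges)),
        ]

    def test_pair_in_all_eligible_networks_kept(self):
        nets = self._nets([("p1", "g1", 0.5, 0.9)], [("g1", "p1", 0.4, 0.8)], [])
        cons = consensus(nets)
        assert cons.pairs() == {("g1", "p1")}
        assert cons.edges["beta"].iloc[0] == pytest.approx(0.45)

    def test_pair_missing_from_one_eligible_network_dropped(self):
        nets = self._nets([("p1", "g1", 0.5, 0.9)], [], [])
        assert consensus(nets).pairs() == set()

    def test_sign_conflict_dropped(self):
        nets = self._nets([("p1", "g1", 0.5, 0.9)], [("g1", "p1", -0.4, 0.8)], [])
        assert consensus(nets).pairs() == set()

    def test_protein_pair_needs_only_protein_network(self):
        nets = self._nets([], [("p1", "p2", 0.3, 0.7)], [])
        assert consensus(nets).pairs() == {("p1", "p2")}

    def test_clinical_pair_needs_both_hosting_networks(self):
        nets = self._nets([("c1", "g1", 0.2, 0.9)], [], [("g1", "c1", 0.3, 0.9)])
        assert consensus(nets).pairs() == {("c1", "g1")}
        nets = self._nets([("c1", "g1", 0.2, 0.9)], [], [])
        assert consensus(nets).pairs() == set()

    def test_strict_mode_is_triple_intersection(self, rng):
        def rand_edges(n):
            pool = list(self.LAYERS)
            rows = []
            for _ in range(n):
                a, b = rng.choice(pool, size=2, replace=False)
                rows.append((a, b, float(rng.choice([-1, 1]) * rng.uniform(0.1, 1)), 0.9))
            return rows

        nets = self._nets(rand_edges(8), rand_edges(8), rand_edges(8))
        cons = consensus(nets, mode="strict")
        # oracle: brute-force intersection over unordered sign-consistent pairs
        per_net = []
        for net in nets:
            d = {}
            for r in net.edges.itertuples(index=False):
                d.setdefault(_canon(r.source, r.target), set()).add(np.sign(r.beta))
            per_net.append(d)
        expected = {
            pair
            for pair in set(per_net[0]) & set(per_net[1]) & set(per_net[2])
            if len(per_net[0][pair] | per_net[1][pair] | per_net[2][pair]) == 1
        }
        assert cons.pairs() == expected

    def test_same_network_thrice_is_projection(self):
        edges = [("g1", "p1", 0.5, 0.9), ("p1", "p2", -0.2, 0.8)]
        nets = [MultiOmicNetwork("protein", dict(self.LAYERS), _edges(edges))
                for _ in range(3)]
        cons = consensus(nets)
        assert cons.pairs() == {("g1", "p1"), ("p1", "p2")}

    def test_consensus_subset_of_union(self, rng):
        nets = self._nets([("p1", "g1", 0.5, 0.9)], [("g1", "p1", 0.4, 0.8),
                                                     ("p1", "p2", 0.2, 0.9)], [])
        cons = consensus(nets)
        union = set().union(*(n.pairs() for n in nets))
        assert cons.pairs() <= union

    def test_requires_three_networks(self):
        nets = self._nets([], [], [])
        with pytest.raises(ValueError, match="three"):
            consensus(nets[:2])
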