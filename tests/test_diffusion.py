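"""Biased random walk with restart: transition operator and profiles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from herbwalk import (
    DiffusionProfile,
    EmptySeedError,
    MultiscaleNetwork,
    SeedSet,
    WalkParameters,
    build_transition_operator,
    compute_diffusion_profile,
    read_profile,
    top_mass_fraction,
    write_profile,
)

from conftest import random_multiscale_network


def dense_profile_oracle(net, seeds: SeedSet, params: WalkParameters) -> dict:
    """Closed-form solve r = a (I - (1-a) T')^-1 s with dangling rows := s."""
    nodes = sorted(net.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    s = np.zeros(n)
    for node, w in seeds.restrict_to(nodes).weights.items():
        s[idx[node]] = w
    T = np.zeros((n, n))
    for i, u in enumerate(nodes):
        acc = {}
        for v, cls in net.neighbors(u):
            w = params.weight(cls)
            if w > 0:
                acc[v] = acc.get(v, 0.0) + w
        z = sum(acc.values())
        if z > 0:
            for v, w in acc.items():
                T[i, idx[v]] = w / z
        else:
            T[i, :] = s
    a = params.restart_probability
    r = a * np.linalg.solve(np.eye(n) - (1 - a) * T.T, s)
    return dict(zip(nodes, r))


class TestTransitionOperator:
    def test_direct_normalization(self):
        """P with a ppi neighbor (w=1) and an annotation neighbor (w=2)
        steps to them with probabilities 1/3 and 2/3."""
        net = MultiscaleNetwork.from_edges(
            ppi=[("P", "Q")], annotations=[("P", "F")], hierarchy=[]
        )
        params = WalkParameters(w_pp=1.0, w_pf=2.0)
        op = build_transition_operator(net, params)
        row = op.matrix[op.index["P"]].toarray().ravel()
        assert row[op.index["Q"]] == pytest.approx(1 / 3)
        assert row[op.index["F"]] == pytest.approx(2 / 3)

    def test_function_up_down_split(self):
        net = MultiscaleNetwork.from_edges(
            ppi=[], annotations=[], hierarchy=[("F", "G"), ("H", "F")]
        )
        params = WalkParameters(w_up=1.0, w_down=1.0, w_fp=0.0)
        op = build_transition_operator(net, params)
        row = op.matrix[op.index["F"]].toarray().ravel()
        assert row[op.index["G"]] == pytest.approx(0.5)
        assert row[op.index["H"]] == pytest.approx(0.5)

    def test_zero_function_weights_reduce_to_ppi_walk(self):
        """With all function-related weights at zero, transition rows over
        proteins equal those of the operator built on the PPI layer alone."""
        rng = np.random.default_rng(5)
        net = random_multiscale_network(rng)
        ppi_only = MultiscaleNetwork.from_edges(
            ppi=[(e.source, e.target) for e in net.edges_by_layer("ppi")],
            annotations=[],
            hierarchy=[],
            extra_proteins=net.proteins,
        )
        params = WalkParameters(w_pf=0.0, w_fp=0.0, w_up=0.0, w_down=0.0)
        op_full = build_transition_operator(net, params)
        op_ppi = build_transition_operator(ppi_only, WalkParameters())
        for p in sorted(net.proteins):
            full_row = op_full.matrix[op_full.index[p]].toarray().ravel()
            ppi_row = op_ppi.matrix[op_ppi.index[p]].toarray().ravel()
            got = {op_full.node_order[j]: v for j, v in enumerate(full_row) if v}
            want = {op_ppi.node_order[j]: v for j, v in enumerate(ppi_row) if v}
            assert got == pytest.approx(want)

    def test_rows_sum_to_one_or_dangling(self):
        rng = np.random.default_rng(17)
        net = random_multiscale_network(rng)
        op = build_transition_operator(net, WalkParameters())
        sums = np.asarray(op.matrix.sum(axis=1)).ravel()
        for i in range(op.n_nodes):
            if op.dangling[i]:
                assert sums[i] == 0.0
            else:
                assert sums[i] == pytest.approx(1.0)

    def test_all_zero_classes_make_node_dangling(self):
        net = MultiscaleNetwork.from_edges(
            ppi=[], annotations=[("P", "F")], hierarchy=[]
        )
        params = WalkParameters(w_pf=0.0, w_fp=1.0)
        op = build_transition_operator(net, params)
        assert op.dangling[op.index["P"]]
        assert not op.dangling[op.index["F"]]


class TestProfiles:
    def test_restart_only_returns_seeds(self, tiny_net):
        seeds = SeedSet.uniform(["A", "C"])
        prof = compute_diffusion_profile(
            tiny_net, seeds, WalkParameters(restart_probability=1.0)
        )
        assert prof.frequencies["A"] == pytest.approx(0.5)
        assert prof.frequencies["C"] == pytest.approx(0.5)
        assert prof.frequencies["B"] == 0.0

    def test_single_node_network(self):
        net = MultiscaleNetwork.from_edges([], [], [], extra_proteins=["P"])
        prof = compute_diffusion_profile(net, SeedSet.uniform(["P"]), WalkParameters())
        assert prof.frequencies["P"] == pytest.approx(1.0)

    def test_disjoint_seed_set_raises_with_ids(self, tiny_net):
        with pytest.raises(EmptySeedError, match="ZZ"):
            compute_diffusion_profile(tiny_net, SeedSet.uniform(["ZZ"]), WalkParameters())

    def test_matches_dense_solve(self, tiny_net):
        params = WalkParameters(restart_probability=0.3)
        seeds = SeedSet.uniform(["A"])
        prof = compute_diffusion_profile(tiny_net, seeds, params)
        oracle = dense_profile_oracle(tiny_net, seeds, params)
        for node in oracle:
            assert prof.frequencies[node] == pytest.approx(oracle[node], abs=1e-9)

    def test_mass_conservation(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            net = random_multiscale_network(rng)
            seeds = SeedSet.uniform(
                rng.choice(sorted(net.proteins), size=2, replace=False)
            )
            prof = compute_diffusion_profile(net, seeds, WalkParameters())
            assert prof.total_mass() == pytest.approx(1.0, abs=1e-9)

    def test_monotone_restart(self, tiny_net):
        """As alpha -> 1 the profile approaches the seed distribution
        monotonically in L1 on a fixed network."""
        seeds = SeedSet.uniform(["A"])
        nodes = sorted(tiny_net.nodes)
        s = np.array([seeds.weights.get(n, 0.0) for n in nodes])
        dists = []
        for alpha in (0.1, 0.3, 0.5, 0.7, 0.9, 0.99):
            prof = compute_diffusion_profile(
                tiny_net, seeds, WalkParameters(restart_probability=alpha)
            )
            dists.append(float(np.abs(prof.as_vector(nodes) - s).sum()))
        assert all(a > b for a, b in zip(dists, dists[1:]))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(31)
        net = random_multiscale_network(rng, max_nodes=20)
        mapping = {n: f"Z{n[::-1]}" for n in net.nodes}
        renamed = MultiscaleNetwork.from_edges(
            ppi=[(mapping[e.source], mapping[e.target]) for e in net.edges_by_layer("ppi")],
            annotations=[
                (mapping[e.source], mapping[e.target])
                for e in net.edges_by_layer("annotation")
            ],
            hierarchy=[
                (mapping[e.source], mapping[e.target])
                for e in net.edges_by_layer("hierarchy")
            ],
            extra_proteins=[mapping[p] for p in net.proteins],
            extra_functions=[mapping[f] for f in net.functions],
        )
        seed_ids = sorted(net.proteins)[:3]
        params = WalkParameters()
        prof = compute_diffusion_profile(net, SeedSet.uniform(seed_ids), params)
        prof2 = compute_diffusion_profile(
            renamed, SeedSet.uniform([mapping[s] for s in seed_ids]), params
        )
        for node, freq in prof.frequencies.items():
            assert prof2.frequencies[mapping[node]] == pytest.approx(freq, abs=1e-12)

    def test_seed_locality_lower_bound(self):
        rng = np.random.default_rng(37)
        net = random_multiscale_network(rng)
        seeds = SeedSet.uniform(sorted(net.proteins)[:4])
        params = WalkParameters(restart_probability=0.25)
        prof = compute_diffusion_profile(net, seeds, params)
        for node, w in prof.seeds.weights.items():
            assert prof.frequencies[node] > 0
            assert prof.frequencies[node] >= params.restart_probability * w - 1e-12

    def test_deterministic_repeat(self, tiny_net):
        seeds = SeedSet.uniform(["A", "B"])
        p1 = compute_diffusion_profile(tiny_net, seeds, WalkParameters())
        p2 = compute_diffusion_profile(tiny_net, seeds, WalkParameters())
        assert p1.frequencies == p2.frequencies


class TestTopMassFraction:
    def test_uniform_profile(self):
        prof = DiffusionProfile(
            {f"N{i}": 0.1 for i in range(10)}, SeedSet.uniform(["N0"]),
            WalkParameters(), 1, 0.0,
        )
        assert top_mass_fraction(prof, 5) == pytest.approx(0.5)

    def test_k_beyond_support(self):
        prof = DiffusionProfile(
            {"A": 0.6, "B": 0.4}, SeedSet.uniform(["A"]), WalkParameters(), 1, 0.0
        )
        assert top_mass_fraction(prof, 99) == pytest.approx(1.0)

    @given(st.integers(min_value=0, max_value=2**31 - 1), st.integers(1, 12))
    def test_matches_sort_and_sum(self, seed, k):
        rng = np.random.default_rng(seed)
        vals = rng.dirichlet(np.ones(8))
        freqs = {f"N{i}": float(v) for i, v in enumerate(vals)}
        prof = DiffusionProfile(freqs, SeedSet.uniform(["N0"]), WalkParameters(), 1, 0.0)
        expected = sum(sorted(freqs.values(), reverse=True)[:k])
        assert top_mass_fraction(prof, k) == pytest.approx(expected)


class TestParameters:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"restart_probability": 0.0},
            {"restart_probability": 1.5},
            {"w_pp": -1.0},
            {"w_pp": 0, "w_pf": 0, "w_fp": 0, "w_up": 0, "w_down": 0},
            {"tolerance": 0.0},
            {"max_iterations": 0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            WalkParameters(**kwargs)

    def test_seed_weights_must_normalize(self):
        with pytest.raises(ValueError):
            SeedSet({"A": 0.5, "B": 0.2})
        ss = SeedSet.normalized({"A": 2.0, "B": 2.0})
        assert ss.weights == {"A": 0.5, "B": 0.5}


def test_profile_round_trip(tmp_path, tiny_net):
    prof = compute_diffusion_profile(tiny_net, SeedSet.uniform(["A"]), WalkParameters())
    tsv = tmp_path / "prof.tsv"
    write_profile(prof, tsv, tmp_path / "prof.json")
    loaded = read_profile(tsv)
    assert loaded == pytest.approx(prof.frequencies)
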