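"""Hill activities, production rates, and redundant-model construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emps import (ACTIVATOR, REPRESSOR, GeneNetwork, RegulatoryPath,
                  activator_activity, build_redundant_model,
                  production_rate, repressor_activity)
from emps.networks import canonical_path_id
from emps.statespace import NetworkDynamics


@pytest.mark.parametrize("K,n,x,expected", [
    (0.0, 2.0, 5.0, 0.0),            # K=0: no activator activity, exactly
    (1.0, 1.0, 1.0, 0.5),            # half-saturation point
    (2.0, 4.0, 3.0, 6.0 ** 4 / (1 + 6.0 ** 4)),
])
def test_activator_activity(K, n, x, expected):
    assert activator_activity(K, n, x) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("K,n,x,expected", [
    (0.0, 3.0, 7.0, 1.0),            # K=0: no repressor activity, exactly
    (1.0, 1.0, 1.0, 0.5),
    (1.0, 2.0, 10.0, 1.0 / 101.0),
])
def test_repressor_activity(K, n, x, expected):
    assert repressor_activity(K, n, x) == pytest.approx(expected, abs=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(K=st.floats(0.0, 10.0), n=st.floats(1.0, 8.0),
       x1=st.floats(0.0, 10.0), x2=st.floats(0.0, 10.0))
def test_activity_monotone_in_x(K, n, x1, x2):
    """Activator activity is nondecreasing and repressor nonincreasing in x."""
    lo, hi = sorted((x1, x2))
    assert activator_activity(K, n, lo) <= activator_activity(K, n, hi) + 1e-15
    assert repressor_activity(K, n, lo) >= repressor_activity(K, n, hi) - 1e-15


@settings(max_examples=60, deadline=None, derandomize=True)
@given(K1=st.floats(0.0, 10.0), K2=st.floats(0.0, 10.0),
       n=st.floats(1.0, 8.0), x=st.floats(0.01, 10.0))
def test_activity_monotone_in_K(K1, K2, n, x):
    lo, hi = sorted((K1, K2))
    assert activator_activity(lo, n, x) <= activator_activity(hi, n, x) + 1e-15
    assert repressor_activity(lo, n, x) >= repressor_activity(hi, n, x) - 1e-15


def test_production_rate_zero_without_activators():
    """All-zero activator K gives zero production whatever the repressors."""
    paths = [RegulatoryPath(0, 1, ACTIVATOR, K=0.0, n=2, a=5.0),
             RegulatoryPath(2, 1, REPRESSOR, K=1.0, n=2)]
    assert production_rate(paths, [3.0, 1.0, 2.0]) == 0.0


def test_production_rate_single_activator():
    paths = [RegulatoryPath(0, 1, ACTIVATOR, K=1.0, n=1.0, a=2.0)]
    assert production_rate(paths, [1.0, 0.0]) == pytest.approx(1.0)


def test_production_rate_matches_termwise_oracle():
    """Two activators and two repressors: term-by-term hand evaluation."""
    x = np.array([0.7, 1.9, 0.4, 2.3])
    paths = [
        RegulatoryPath(0, 0, ACTIVATOR, K=1.2, n=2.0, a=1.5),
        RegulatoryPath(1, 0, ACTIVATOR, K=0.6, n=3.0, a=2.5),
        RegulatoryPath(2, 0, REPRESSOR, K=2.0, n=1.5),
        RegulatoryPath(3, 0, REPRESSOR, K=0.9, n=4.0),
    ]
    u = lambda K, n, v: (K * v) ** n
    expected = (1.5 * u(1.2, 2, 0.7) / (1 + u(1.2, 2, 0.7))
                + 2.5 * u(0.6, 3, 1.9) / (1 + u(0.6, 3, 1.9)))
    expected *= 1.0 / (1 + u(2.0, 1.5, 0.4)) * 1.0 / (1 + u(0.9, 4, 2.3))
    assert production_rate(paths, x) == pytest.approx(expected, rel=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.floats(0.0, 5.0), st.floats(0.0, 5.0), st.floats(0.0, 5.0))
def test_production_rate_bounded_by_amplitude_sum(x0, x1, x2):
    paths = [RegulatoryPath(0, 0, ACTIVATOR, K=1.0, n=2, a=2.0),
             RegulatoryPath(1, 0, ACTIVATOR, K=0.5, n=3, a=1.0),
             RegulatoryPath(2, 0, REPRESSOR, K=0.3, n=2)]
    assert production_rate(paths, [x0, x1, x2]) <= 3.0 + 1e-12


@pytest.mark.parametrize("G,expected", [(1, 2), (2, 8), (3, 18)])
def test_redundant_model_path_count(G, expected):
    """The redundant model over G genes has exactly 2*G^2 candidate paths."""
    net = build_redundant_model(G)
    assert net.n_paths == expected
    assert sorted(p.path_id for p in net.paths) == list(range(1, expected + 1))


def test_redundant_path_numbering_targets_major():
    net = build_redundant_model(3)
    p1 = net.paths[0]
    assert (p1.target, p1.source, p1.sign, p1.path_id) == (0, 0, ACTIVATOR, 1)
    # the repressor of the same pair follows immediately
    assert net.paths[1].sign == REPRESSOR and net.paths[1].path_id == 2
    assert canonical_path_id(3, 2, 2, REPRESSOR) == 18


def test_rhs_pure_decay():
    """All paths silent (K=0), no basal: dx/dt = -d*x."""
    net = build_redundant_model(2, K=0.0, basal=0.0, degradation=0.7)
    x = np.array([1.5, 3.0])
    np.testing.assert_allclose(net.rhs(x), -0.7 * x, rtol=1e-12)


def test_zero_K_is_equivalent_to_deleting_the_path(three_gene_truth):
    """K=0 silences a path exactly: trajectories match the pruned model.

    This is the structural premise of the L1 pruning strategy.
    """
    full = three_gene_truth.copy()
    # add a silenced spurious path and compare dynamics with the original
    full.paths.append(RegulatoryPath(0, 2, REPRESSOR, K=0.0, n=3.0))
    full.__post_init__()
    dyn_a = NetworkDynamics(three_gene_truth, nsub=4)
    dyn_b = NetworkDynamics(full, nsub=4)
    x = np.array([[1.0, 0.5, 2.0], [0.2, 1.4, 0.9]])
    for _ in range(30):
        x_a = dyn_a.f_batch(x, 1.0)
        x_b = dyn_b.f_batch(x, 1.0)
        np.testing.assert_array_equal(x_a, x_b)
        x = x_a


def test_true_circuit_embeds_in_redundant_model(three_gene_truth):
    """The 3-path circuit inside the 18-path model follows identical
    trajectories when all other association constants are zero."""
    red = build_redundant_model(["X", "Y", "Z"], K=0.0, basal=0.0)
    by_id = {p.path_id: p for p in red.paths}
    for p in three_gene_truth.paths:
        q = by_id[p.path_id]
        assert (q.source, q.target, q.sign) == (p.source, p.target, p.sign)
        q.K, q.n = p.K, p.n
        if p.is_activator:
            q.a = p.a
    red.degradation = three_gene_truth.degradation.copy()
    red.basal = three_gene_truth.basal.copy()
    dyn_true = NetworkDynamics(three_gene_truth, nsub=4)
    dyn_red = NetworkDynamics(red, nsub=4)
    x = np.array([[1.0, 1.0, 1.0]])
    for _ in range(40):
        x_t = dyn_true.f_batch(x, 1.0)
        x_r = dyn_red.f_batch(x, 1.0)
        np.testing.assert_allclose(x_r, x_t, rtol=1e-12, atol=1e-12)
        x = x_t


def test_theta_roundtrip(three_gene_truth):
    """Flatten-then-rebuild leaves the vector field unchanged."""
    net = three_gene_truth.copy()
    theta = net.theta()
    assert len(theta) == net.n_theta == len(net.theta_names())
    rebuilt = net.with_theta(theta)
    rng = np.random.default_rng(0)
    for _ in range(5):
        x = rng.uniform(0, 3, net.n_genes)
        np.testing.assert_array_equal(rebuilt.rhs(x), net.rhs(x))
    np.testing.assert_array_equal(rebuilt.theta(), theta)


def test_k_indices_address_association_constants(three_gene_truth):
    theta = three_gene_truth.theta()
    names = three_gene_truth.theta_names()
    for i in three_gene_truth.k_indices():
        assert names[i].startswith("K_")
    ks = [p.K for p in three_gene_truth.paths]
    np.testing.assert_array_equal(theta[three_gene_truth.k_indices()], ks)


def test_json_roundtrip(tmp_path, two_gene_truth):
    path = tmp_path / "model.json"
    two_gene_truth.to_json(path)
    back = GeneNetwork.from_json(path)
    np.testing.assert_array_equal(back.theta(), two_gene_truth.theta())
    assert back.genes == two_gene_truth.genes
    assert [p.path_id for p in back.paths] == \
        [p.path_id for p in two_gene_truth.paths]
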