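"""HMM correctness: brute-force path-enumeration oracles, EM behaviour,
F_HBD and segment summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hbdkit.hbd import (
    HbdModelSpec,
    autozygosity_horizon_generations,
    expand_emissions,
    f_hbd,
    fit_mixing_coefficients,
    forward_backward,
    segment_summaries,
    segments_from_path,
    viterbi_path,
    HbdDecoding,
    HbdModelError,
)


# ----------------------------------------------------------------------
# independent oracle: exhaustive enumeration over all state paths
# ----------------------------------------------------------------------

def transition_matrix(model, d):
    p = np.exp(-model.all_rates * d)
    return np.diag(p) + (1 - p)[:, None] * model.mix[None, :]


def enumerate_paths(emissions, model, distances):
    """Posteriors, loglik and best path by summing over every state path."""
    n, S = emissions.shape
    probs = {}
    for path in itertools.product(range(S), repeat=n):
        p = model.mix[path[0]] * emissions[0, path[0]]
        for t in range(n - 1):
            p *= transition_matrix(model, distances[t])[path[t], path[t + 1]] * emissions[
                t + 1, path[t + 1]
            ]
        probs[path] = p
    total = sum(probs.values())
    post = np.zeros((n, S))
    for path, p in probs.items():
        for t, s in enumerate(path):
            post[t, s] += p
    best = max(probs, key=probs.get)
    return post / total, np.log(total), np.array(best)


def toy_model(n_hbd_classes=2, mix=None, error=0.001):
    rates = np.array([16.0, 256.0][:n_hbd_classes])
    return HbdModelSpec(rates=rates, nonhbd_rate=512.0, mix=mix, error=error)


def toy_emissions(model, dosages, freqs):
    from hbdkit.hbd import emission_likelihoods

    em2 = emission_likelihoods(np.asarray(dosages), np.asarray(freqs), model)
    return expand_emissions(em2, model.n_states)


@pytest.mark.parametrize(
    "dosages,freqs,distances",
    [
        ([0, 2, 2, 0], [0.3, 0.6, 0.5, 0.2], [0.01, 0.002, 0.05]),
        ([2, 1, 2, 0], [0.7, 0.4, 0.9, 0.1], [0.0, 0.02, 0.004]),
        ([0, 0, 2, 2, 1, 0], [0.5, 0.3, 0.8, 0.6, 0.5, 0.4], [0.01] * 5),
    ],
)
def test_forward_backward_matches_enumeration(dosages, freqs, distances):
    model = toy_model(mix=np.array([0.2, 0.3, 0.5]))
    em = toy_emissions(model, dosages, freqs)
    dec = forward_backward(em, model, np.asarray(distances))
    post_ref, ll_ref, _ = enumerate_paths(em, model, np.asarray(distances))
    np.testing.assert_allclose(dec.posteriors, post_ref, atol=1e-10)
    assert dec.loglik == pytest.approx(ll_ref, abs=1e-10)


@pytest.mark.parametrize(
    "dosages,freqs",
    [
        ([0, 2, 2, 0, 1, 2], [0.3, 0.6, 0.5, 0.2, 0.5, 0.8]),
        ([2, 2, 2, 0, 0, 0], [0.9, 0.8, 0.7, 0.3, 0.2, 0.1]),
    ],
)
def test_viterbi_matches_enumeration(dosages, freqs):
    model = toy_model(mix=np.array([0.25, 0.25, 0.5]))
    distances = np.array([0.01, 0.03, 0.002, 0.02, 0.01])
    em = toy_emissions(model, dosages, freqs)
    path = viterbi_path(em, model, distances)
    _, _, best = enumerate_paths(em, model, distances)
    np.testing.assert_array_equal(path, best)


def test_posteriors_sum_to_one(rng):
    model = HbdModelSpec()
    dosages = rng.integers(0, 3, 50)
    freqs = rng.uniform(0.05, 0.95, 50)
    em = toy_emissions(model, dosages, freqs)[:, :2]  # exercise compact form
    dec = forward_backward(
        np.stack([em[:, 0]] * 13 + [em[:, 1]], axis=1), model, rng.uniform(0, 0.01, 49)
    )
    np.testing.assert_allclose(dec.posteriors.sum(axis=1), 1.0, atol=1e-9)


def test_single_uninformative_marker_recovers_prior():
    model = toy_model(mix=np.array([0.1, 0.2, 0.7]))
    em = np.ones((1, 3))
    dec = forward_backward(em, model, np.array([]))
    np.testing.assert_allclose(dec.posteriors[0], model.mix, atol=1e-12)


def test_zero_distance_freezes_class_composition():
    """With all genetic distances 0 the chain cannot transition."""
    model = toy_model(mix=np.array([0.3, 0.3, 0.4]))
    rng = np.random.default_rng(7)
    em = toy_emissions(model, rng.integers(0, 3, 12), rng.uniform(0.2, 0.8, 12))
    dec = forward_backward(em, model, np.zeros(11))
    # joint collapses to a single shared state: posterior ratios at every
    # marker equal the (prior x product-of-emissions) ratios, i.e. the
    # posterior is identical at all markers up to emission reweighting
    joint = model.mix * np.prod(em, axis=0)
    np.testing.assert_allclose(dec.posteriors[0], joint / joint.sum(), atol=1e-10)
    np.testing.assert_allclose(
        dec.posteriors, np.tile(dec.posteriors[0], (len(dec.posteriors), 1)), atol=1e-10
    )


def test_empty_observations_error():
    model = toy_model()
    with pytest.raises(HbdModelError):
        forward_backward(np.empty((0, 3)), model, np.array([]))


# ----------------------------------------------------------------------
# EM fitting
# ----------------------------------------------------------------------

def test_em_loglik_monotone_and_recovery(rng):
    """EM recovers planted mixing weights and never decreases the loglik."""
    model = HbdModelSpec(rates=np.array([64.0]), nonhbd_rate=8192.0, error=0.001)
    true_mix = np.array([0.2, 0.8])
    n = 20000
    freqs = rng.uniform(0.1, 0.9, n)
    distances = np.full(n - 1, 5e-4)
    # simulate from the model itself
    states = np.empty(n, dtype=int)
    states[0] = rng.choice(2, p=true_mix)
    stay = np.exp(-np.array([64.0, 8192.0]) * 5e-4)
    for t in range(1, n):
        if rng.random() < stay[states[t - 1]]:
            states[t] = states[t - 1]
        else:
            states[t] = rng.choice(2, p=true_mix)
    dosages = np.where(
        states == 0,
        np.where(rng.random(n) < freqs, 2, 0),
        rng.binomial(2, freqs),
    )
    from hbdkit.hbd import emission_likelihoods

    em = emission_likelihoods(dosages, freqs, model)
    fitted, info = fit_mixing_coefficients(em, model, distances, tol=1e-4, max_iter=60)
    ll = np.asarray(info["loglik"])
    assert (np.diff(ll) >= -1e-6).all()
    assert abs(fitted.mix[0] - 0.2) < 0.05


def test_em_single_state_degenerate():
    single = HbdModelSpec(rates=np.array([]), mix=np.array([1.0]))
    fitted, info = fit_mixing_coefficients(np.ones((4, 1)), single, np.zeros(3))
    assert fitted.mix[0] == 1.0
    assert info["converged"]


# ----------------------------------------------------------------------
# segments and summaries
# ----------------------------------------------------------------------

def test_forced_hbd_yields_single_spanning_segment():
    model = toy_model(mix=np.array([0.3, 0.3, 0.4]))
    em = np.zeros((5, 3))
    em[:, 0] = 1.0  # only class 0 can emit
    path = viterbi_path(em, model, np.full(4, 0.01))
    segs = segments_from_path(path, np.array([100, 200, 300, 400, 500]), "s1", model)
    assert len(segs) == 1
    assert segs.loc[0, "start"] == 99 and segs.loc[0, "end"] == 500
    assert segs.loc[0, "class_rate"] == model.rates[0]


def test_segments_sorted_nonoverlapping(rng):
    model = toy_model(mix=np.array([0.3, 0.3, 0.4]))
    em = toy_emissions(model, rng.integers(0, 3, 200), rng.uniform(0.2, 0.8, 200))
    path = viterbi_path(em, model, rng.uniform(0, 0.02, 199))
    pos = np.arange(1, 201) * 50
    segs = segments_from_path(path, pos, "s1", model)
    if len(segs) > 1:
        assert (segs["start"].to_numpy()[1:] >= segs["end"].to_numpy()[:-1]).all()
    assert (segs["start"] < segs["end"]).all()


def test_f_hbd_extremes_and_monotonicity():
    rates = np.array([2.0, 64.0, 2048.0])
    post_all_first = np.zeros((10, 4))
    post_all_first[:, 0] = 1.0
    dec = HbdDecoding(posteriors=post_all_first, loglik=0.0)
    assert f_hbd(dec, rates, T=1024) == 1.0
    post_non = np.zeros((10, 4))
    post_non[:, -1] = 1.0
    assert f_hbd(HbdDecoding(post_non, 0.0), rates, T=1024) == 0.0
    # monotone non-decreasing in T
    rng = np.random.default_rng(0)
    post = rng.dirichlet(np.ones(4), size=10)
    dec = HbdDecoding(post, 0.0)
    values = [f_hbd(dec, rates, T=t) for t in (1, 2, 64, 2048, 8192)]
    assert (np.diff(values) >= 0).all()


def test_f_hbd_warns_below_smallest_rate():
    dec = HbdDecoding(np.ones((3, 4)) / 4, 0.0)
    with pytest.warns(UserWarning):
        assert f_hbd(dec, np.array([2.0, 4.0, 8.0]), T=1) == 0.0


def test_autozygosity_horizon_default_is_512_generations():
    """T=1024 corresponds to coalescence within the last 512 generations."""
    assert autozygosity_horizon_generations(1024.0) == 512.0


def test_segment_summaries_arithmetic_and_threshold():
    segs = pd.DataFrame(
        {
            "scaffold": ["s1"] * 4,
            "start": [0, 5_000_000, 10_000_000, 20_000_000],
            "end": [1_000_000, 8_000_000, 10_500_000, 21_000_000],
            "class_rate": [64.0, 64.0, 2048.0, 512.0],
        }
    )
    out = segment_summaries(segs, T=1024)
    # rate-2048 segment excluded everywhere
    assert out["n_hbd"] == 3
    assert out["s_hbd"] == pytest.approx((1_000_000 + 3_000_000 + 1_000_000) / 3)
    assert out["class_lengths"] == {64.0: 4_000_000.0, 512.0: 1_000_000.0}
    two = segment_summaries(segs.iloc[:2], T=1024)
    assert two["n_hbd"] == 2 and two["s_hbd"] == pytest.approx(2_000_000)
    empty = segment_summaries(segs.iloc[:0], T=1024)
    assert empty == {"n_hbd": 0, "s_hbd": 0.0, "class_lengths": {}}
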