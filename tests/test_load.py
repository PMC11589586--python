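"""Minor-allele calling, load counts, L/R statistics, jackknife, rank tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hbdkit.load import (
    LoadStatsError,
    call_minor_alleles,
    group_compare,
    individual_load_counts,
    jackknife_se,
    l_terms,
    rxy,
    rxy_with_jackknife,
)
from hbdkit.panel import MISSING

from conftest import make_panel


def _panel_two_pops(dosages, **kw):
    n = dosages.shape[0]
    pops = ["popA"] * (n // 2) + ["popB"] * (n - n // 2)
    groups = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    return make_panel(dosages, populations=pops, groups=groups, **kw)


def _unrelated(panel):
    out = {}
    for pop in panel.individuals["population"].unique():
        ids = panel.individuals.loc[panel.individuals["population"] == pop, "id"]
        out[pop] = list(ids)
    return out


# ----------------------------------------------------------------------
# minor-allele calls
# ----------------------------------------------------------------------

def test_clear_minor_called_with_full_vote(rng):
    dos = rng.binomial(2, 0.4, (20, 1)).astype(np.int8)
    while not 0.25 < dos.mean() / 2 < 0.45:  # keep ALT clearly minor
        dos = rng.binomial(2, 0.4, (20, 1)).astype(np.int8)
    panel = _panel_two_pops(dos)
    calls = call_minor_alleles(panel, _unrelated(panel), reps=200, seed=0)
    assert calls.minor_is_alt[0]
    assert calls.vote[0] > 0.9
    assert calls.informative[0]


def test_tie_rule_all_monomorphic_flagged():
    dos = np.zeros((6, 2), dtype=np.int8)
    dos[:, 1] = 1  # site 2 all het -> freq exactly 0.5 every replicate
    panel = _panel_two_pops(dos)
    calls = call_minor_alleles(panel, _unrelated(panel), reps=50, seed=1)
    assert not calls.informative[0]  # monomorphic in every replicate
    assert calls.informative[1]
    assert calls.minor_is_alt[1]  # exact 0.5 -> ALT by the tie rule
    assert calls.vote[1] == 1.0


def test_calls_invariant_to_allele_relabelling(rng):
    dos = rng.binomial(2, rng.uniform(0.1, 0.9, 40), (16, 40)).astype(np.int8)
    panel = _panel_two_pops(dos)
    calls = call_minor_alleles(panel, _unrelated(panel), reps=100, seed=3)
    flipped = _panel_two_pops((2 - dos).astype(np.int8))
    calls_f = call_minor_alleles(flipped, _unrelated(flipped), reps=100, seed=3)
    # the physical minor allele is the same; its ref/alt label swaps
    freq = dos.mean(axis=0) / 2
    clear = np.abs(freq - 0.5) > 0.1  # away from the tie rule's asymmetry
    np.testing.assert_array_equal(
        calls.minor_is_alt[clear], ~calls_f.minor_is_alt[clear]
    )


def test_empty_unrelated_sets_error():
    panel = _panel_two_pops(np.zeros((4, 2), dtype=np.int8))
    with pytest.raises(LoadStatsError):
        call_minor_alleles(panel, {}, reps=10, seed=0)


# ----------------------------------------------------------------------
# load counts
# ----------------------------------------------------------------------

def test_individual_load_counts_hand_enumeration():
    # 4 sites: categories high, high, neutral, intergenic
    dos = np.array(
        [
            [1, 2, 0, 1],  # ind0: het high, hom high, none, het intergenic
            [0, 0, 1, 0],
        ],
        dtype=np.int8,
    )
    panel = _panel_two_pops(
        dos, categories=["high", "high", "neutral", "intergenic"]
    )
    calls = call_minor_alleles(panel, _unrelated(panel), reps=10, seed=0)
    # ALT is minor everywhere here (freqs < 0.5 except site checked)
    counts = individual_load_counts(panel, calls)
    ind0_high = counts[(counts["id"] == "ind0") & (counts["category"] == "high")].iloc[0]
    assert ind0_high["minor_copies"] == 3
    assert ind0_high["hom_minor_sites"] == 1
    # normalisation: ind0 carries minor alleles at 3 sites
    assert ind0_high["polymorphic_sites"] == 3
    assert ind0_high["minor_copies_norm"] == pytest.approx(1.0)


def test_load_counts_sum_over_categories_is_total(rng):
    dos = rng.binomial(2, rng.uniform(0.1, 0.5, 30), (8, 30)).astype(np.int8)
    cats = rng.choice(["intergenic", "neutral", "low", "moderate", "high"], 30)
    panel = _panel_two_pops(dos, categories=list(cats))
    calls = call_minor_alleles(panel, _unrelated(panel), reps=20, seed=2)
    counts = individual_load_counts(panel, calls)
    minor_dos = np.where(calls.minor_is_alt[None, :], dos, 2 - dos)
    for ind_id, sub in counts.groupby("id"):
        i = int(ind_id.replace("ind", ""))
        assert sub["minor_copies"].sum() == minor_dos[i].sum()


# ----------------------------------------------------------------------
# L / R statistics
# ----------------------------------------------------------------------

def test_l_terms_two_site_toy():
    """Direct evaluation of the L sum and the R ratio."""
    d_x = [2, 0]
    n_x = [10, 10]
    d_y = [0, 4]
    n_y = [10, 10]
    l1, _ = l_terms(d_x, n_x, d_y, n_y)
    l1r, _ = l_terms(d_y, n_y, d_x, n_x)
    assert l1.sum() == pytest.approx(0.2)
    assert l1r.sum() == pytest.approx(0.4)
    assert l1.sum() / l1r.sum() == pytest.approx(0.5)


def test_l2_literal_reduces_to_2d_over_n():
    d = np.array([3.0])
    n = np.array([10.0])
    _, l2 = l_terms(d, n, np.array([0.0]), np.array([10.0]), l2_form="literal")
    assert l2[0] == pytest.approx(2 * 3 / 10)
    _, l2d = l_terms(d, n, np.array([0.0]), np.array([10.0]), l2_form="dodds")
    assert l2d[0] == pytest.approx(3 * 2 / (10 * 9))


def test_rxy_symmetry_inverse(rng):
    dos = rng.binomial(2, rng.uniform(0.1, 0.9, 60), (20, 60)).astype(np.int8)
    cats = ["neutral"] * 30 + ["intergenic"] * 30
    panel = _panel_two_pops(dos, categories=cats)
    calls = call_minor_alleles(panel, _unrelated(panel), reps=50, seed=4)
    ab = rxy(panel, calls, "A", "B", "neutral")
    ba = rxy(panel, calls, "B", "A", "neutral")
    assert ab.r_xy * ba.r_xy == pytest.approx(1.0)
    assert ab.r2_xy * ba.r2_xy == pytest.approx(1.0)


def test_rxy_identical_groups_is_one():
    rng = np.random.default_rng(6)
    half = rng.binomial(2, rng.uniform(0.1, 0.9, 40), (10, 40)).astype(np.int8)
    dos = np.vstack([half, half])  # group B mirrors group A exactly
    cats = ["neutral"] * 20 + ["intergenic"] * 20
    panel = _panel_two_pops(dos, categories=cats)
    calls = call_minor_alleles(panel, _unrelated(panel), reps=50, seed=5)
    res = rxy(panel, calls, "A", "B", "neutral")
    assert res.r_xy == pytest.approx(1.0)
    assert res.r_prime == pytest.approx(1.0)


def test_rxy_zero_denominator_errors():
    dos = np.zeros((8, 4), dtype=np.int8)
    dos[:4, 0] = 1  # minor alleles only in group A
    cats = ["neutral", "neutral", "intergenic", "intergenic"]
    panel = _panel_two_pops(dos, categories=cats)
    calls = call_minor_alleles(panel, _unrelated(panel), reps=10, seed=0)
    with pytest.raises(LoadStatsError):
        rxy(panel, calls, "A", "B", "neutral")


# ----------------------------------------------------------------------
# jackknife
# ----------------------------------------------------------------------

def test_jackknife_identical_blocks_se_zero():
    num = np.full(12, 2.0)
    den = np.full(12, 4.0)
    ratio, se = jackknife_se(num, den)
    assert ratio == pytest.approx(0.5)
    assert se == pytest.approx(0.0)


def test_jackknife_matches_closed_form_three_blocks():
    num = np.array([1.0, 2.0, 3.0])
    den = np.array([2.0, 2.0, 2.0])
    ratio, se = jackknife_se(num, den, min_blocks=3)
    loo = np.array([(2 + 3) / 4, (1 + 3) / 4, (1 + 2) / 4])
    var = 2 / 3 * ((loo - loo.mean()) ** 2).sum()
    assert ratio == pytest.approx(1.0)
    assert se == pytest.approx(np.sqrt(var))


def test_jackknife_too_few_blocks_errors():
    with pytest.raises(LoadStatsError):
        jackknife_se(np.ones(3), np.ones(3), min_blocks=10)


# ----------------------------------------------------------------------
# group comparison
# ----------------------------------------------------------------------

def test_identical_groups_p_one_effect_zero():
    res = group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res["p_value"] == pytest.approx(1.0, abs=0.05)
    assert res["effect_size"] == pytest.approx(0.0, abs=1e-9)


def test_w_statistic_matches_exhaustive_enumeration():
    """W equals the count of (a, b) pairs with a > b (plus half-ties)."""
    a = np.array([1.0, 2.0, 3.0])
    b = np.array([4.0, 5.0, 6.0])
    res = group_compare(a, b)
    w_ref = sum(
        1.0 if x > y else (0.5 if x == y else 0.0) for x, y in itertools.product(a, b)
    )
    assert res["w"] == w_ref == 0.0
    a2 = np.array([5.0, 2.0, 7.0, 7.0])
    b2 = np.array([4.0, 7.0, 1.0])
    w_ref2 = sum(
        1.0 if x > y else (0.5 if x == y else 0.0) for x, y in itertools.product(a2, b2)
    )
    assert group_compare(a2, b2)["w"] == pytest.approx(w_ref2)


def test_effect_size_labels():
    assert group_compare([1] * 3, [2] * 3)["label"] in {"small", "moderate", "large", "negligible"}
    # the conventional cut-offs
    from hbdkit.load import EFFECT_LABELS

    lookup = dict((name, cut) for cut, name in EFFECT_LABELS)
    assert lookup["large"] == 0.5  # 0.525 -> "large"
    assert lookup["moderate"] == 0.3
    assert lookup["small"] == 0.1


def test_empty_group_errors():
    with pytest.raises(LoadStatsError):
        group_compare([], [1.0])
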