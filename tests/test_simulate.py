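"""Synthetic-panel generator: tract statistics, determinism, load shifts."""

import numpy as np
import pytest
from scipy import stats

from hbdkit.simulate import (
    SimConfig,
    SimulationError,
    apply_load_asymmetry,
    generate_panel,
    plant_hbd_tracts,
)


def test_no_autozygous_weight_gives_no_tracts(rng):
    assert plant_hbd_tracts(10.0, [64.0], [0.0], rng) == []


def test_negative_genetic_length_errors(rng):
    with pytest.raises(SimulationError):
        plant_hbd_tracts(-1.0, [64.0], [0.5], rng)


def test_tract_lengths_exponential_mean(rng):
    """Monte-Carlo mean tract length for a single class R=64 is ~1/64 M."""
    lengths = []
    while len(lengths) < 10_000:
        for a, b, _ in plant_hbd_tracts(100.0, [64.0], [0.3], rng):
            if b < 100.0:  # exclude boundary-truncated tracts
                lengths.append(b - a)
    lengths = np.asarray(lengths[:10_000])
    se = (1 / 64) / np.sqrt(len(lengths))  # exponential: sd == mean
    assert abs(lengths.mean() - 1 / 64) < 2 * se


def test_tract_length_distribution_ks():
    """Planted lengths pass a KS test against Exponential(1/R) in most seeds."""
    passes = 0
    n_seeds = 20
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        lengths = []
        while len(lengths) < 2000:
            for a, b, _ in plant_hbd_tracts(50.0, [32.0], [0.3], rng):
                if b < 50.0:
                    lengths.append(b - a)
        p = stats.kstest(lengths, "expon", args=(0, 1 / 32)).pvalue
        passes += p > 0.01
    assert passes >= int(0.95 * n_seeds)


def test_planted_fraction_matches_weights(rng):
    """Long-genome coverage approaches the summed autozygous weights."""
    covered = total = 0.0
    for _ in range(60):
        g = 30.0
        tracts = plant_hbd_tracts(g, [2.0, 64.0], [0.3, 0.2], rng)
        covered += sum(b - a for a, b, _ in tracts)
        total += g
    assert covered / total == pytest.approx(0.5, abs=0.02)


def test_generate_panel_deterministic():
    cfg = SimConfig(seed=42, n_sites_per_scaffold=300, n_scaffolds=1,
                    hbd_class_weights={"pop1": {64: 0.2}}, sib_pair_count=1)
    p1, t1 = generate_panel(cfg)
    p2, t2 = generate_panel(cfg)
    np.testing.assert_array_equal(p1.dosages, p2.dosages)
    np.testing.assert_array_equal(p1.depths, p2.depths)
    assert t1.tracts.equals(t2.tracts)
    assert (t1.true_f == t2.true_f).all()


def test_zero_error_full_tract_coverage_has_no_hets():
    cfg = SimConfig(
        seed=7,
        n_individuals={"pop1": 3},
        group_of={"pop1": "g"},
        n_scaffolds=1,
        n_sites_per_scaffold=400,
        genotype_error=0.0,
        # weight ~1 on the slowest class: tracts cover essentially everything
        hbd_class_weights={"pop1": {2: 0.999}},
        recomb_rate_per_bp=1e-8,
    )
    panel, truth = generate_panel(cfg)
    pos = panel.sites["pos"].to_numpy()
    ids = list(panel.individuals["id"])
    checked = 0
    for ind, sub in truth.tracts.groupby("individual"):
        row = panel.dosages[ids.index(ind)]
        for _, t in sub.iterrows():
            inside = (pos - 1 >= t["start"]) & (pos - 1 < t["end"])
            checked += int(inside.sum())
            assert (row[inside] != 1).all()
    assert checked > 100


def test_truth_fraction_consistent_with_tracts():
    cfg = SimConfig(seed=3, n_sites_per_scaffold=200, n_scaffolds=2,
                    hbd_class_weights={"pop1": {16: 0.3}}, recomb_rate_per_bp=1e-6)
    panel, truth = generate_panel(cfg)
    genome_bp = cfg.n_scaffolds * cfg.scaffold_length
    for ind, sub in truth.tracts.groupby("individual"):
        frac_bp = (sub["end"] - sub["start"]).sum() / genome_bp
        assert frac_bp == pytest.approx(truth.true_f[ind], abs=1e-3)
        # tracts non-overlapping and sorted within scaffold
        for _, ssub in sub.groupby("scaffold"):
            s = ssub.sort_values("start")
            assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()


def test_category_fractions_within_sampling_error():
    cfg = SimConfig(seed=11, n_sites_per_scaffold=20_000, n_scaffolds=1)
    panel, truth = generate_panel(cfg)
    counts = truth.site_categories.value_counts(normalize=True)
    for cat, frac in cfg.category_fractions.items():
        se = np.sqrt(frac * (1 - frac) / 20_000)
        assert abs(counts.get(cat, 0.0) - frac) < 5 * se


def test_sib_pairs_have_elevated_relatedness():
    from hbdkit.inbreeding import allele_sharing_matrix

    cfg = SimConfig(
        seed=5,
        n_individuals={"pop1": 12},
        group_of={"pop1": "g"},
        n_scaffolds=1,
        n_sites_per_scaffold=20_000,
        sib_pair_count=1,
        divergence=0.0,
    )
    panel, truth = generate_panel(cfg)
    mat = allele_sharing_matrix(panel)
    beta = mat.beta()
    ids = list(panel.individuals["id"])
    (a, b) = truth.sib_pairs[0]
    ia, ib = ids.index(a), ids.index(b)
    assert beta[ia, ib] > 0.05
    unrelated = beta[:12, :12][~np.eye(12, dtype=bool)]
    assert abs(unrelated.mean()) < 0.02


# ----------------------------------------------------------------------
# load asymmetry
# ----------------------------------------------------------------------

def test_load_shift_identity():
    rng = np.random.default_rng(0)
    freqs = rng.uniform(0.05, 0.95, (2, 50))
    cats = np.array(["high"] * 25 + ["intergenic"] * 25)
    minor = freqs.mean(axis=0) <= 0.5
    out = apply_load_asymmetry(freqs, cats, minor, ["A", "B"], {("B", "high"): 1.0})
    np.testing.assert_array_equal(out, freqs)


def test_load_shift_clamps_to_one():
    freqs = np.array([[0.4]])
    out = apply_load_asymmetry(
        freqs, np.array(["high"]), np.array([True]), ["B"], {("B", "high"): 5.0}
    )
    assert out[0, 0] == 1.0


def test_load_shift_intergenic_never_shifted():
    freqs = np.array([[0.4, 0.4]])
    cats = np.array(["intergenic", "high"])
    out = apply_load_asymmetry(
        freqs, cats, np.array([True, True]), ["B"], {("B", "intergenic"): 0.5, ("B", "high"): 0.5}
    )
    assert out[0, 0] == 0.4
    assert out[0, 1] == pytest.approx(0.2)


def test_load_shift_invalid_factor():
    with pytest.raises(SimulationError):
        apply_load_asymmetry(
            np.array([[0.4]]), np.array(["high"]), np.array([True]), ["B"], {("B", "high"): 0.0}
        )


def test_load_shift_respects_minor_allele_side():
    """When REF is the minor allele the REF frequency is shifted."""
    freqs = np.array([[0.8]])  # ALT major, REF minor at 0.2
    out = apply_load_asymmetry(
        np.array(freqs), np.array(["high"]), np.array([False]), ["B"], {("B", "high"): 0.5}
    )
    assert out[0, 0] == pytest.approx(0.9)  # REF freq 0.2 -> 0.1
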