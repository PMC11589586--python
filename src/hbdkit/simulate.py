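"""Synthetic genotype panels with planted homozygosity-by-descent tracts.

The generator emulates the statistical structure a multi-population
resequencing panel presents to the downstream analyses:

* per-individual HBD tracts whose lengths are exponential in genetic distance
  with class-specific rates ``R_k`` (mean ``1/R_k`` Morgans) and whose
  per-class genome coverage matches configured mixing weights;
* Hardy–Weinberg genotypes outside tracts and forced homozygosity (up to a
  genotyping-error probability) inside them;
* population groups with Balding–Nichols divergence from shared ancestral
  frequencies;
* full-sib pairs appended after the unrelated individuals;
* group- and category-specific multiplicative shifts of minor-allele
  frequencies, imposing a selection-efficiency asymmetry on the panel.

Everything is driven by a single integer seed: identical configurations give
byte-identical panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import CATEGORIES, MISSING, GenotypePanel

DEFAULT_RATES = (2, 4, 8, 16, 32, 64, 128, 256, 512, 1024, 2048, 4096, 8192)


class SimulationError(ValueError):
    """Invalid simulation configuration or arguments."""


def _default_category_fractions() -> dict:
    # intergenic-heavy genome with a thin tail of high-impact sites
    return {"intergenic": 0.40, "neutral": 0.30, "low": 0.15, "moderate": 0.10, "high": 0.05}


@dataclass
class SimConfig:
    """Configuration of a synthetic panel.

    ``hbd_class_weights`` maps population -> {class rate -> weight}; the
    remaining weight (to 1) is the non-HBD share. ``load_shift`` maps
    ``(group, category)`` -> multiplicative factor applied to minor-allele
    frequencies of that category in populations of that group (intergenic
    sites are never shifted). ``divergence`` is a per-population F_ST-like
    drift parameter of the Balding–Nichols construction.
    """

    n_individuals: dict = field(default_factory=lambda: {"pop1": 10, "pop2": 10})
    group_of: dict = field(default_factory=lambda: {"pop1": "continent", "pop2": "island"})
    n_scaffolds: int = 2
    scaffold_length: int = 10_000_000
    n_sites_per_scaffold: int = 5000
    ancestral_beta: float = 0.8
    divergence: dict | float = 0.05
    hbd_class_rates: tuple = DEFAULT_RATES
    hbd_class_weights: dict = field(default_factory=dict)
    genotype_error: float = 0.001
    category_fractions: dict = field(default_factory=_default_category_fractions)
    load_shift: dict = field(default_factory=dict)
    sib_pair_count: dict | int = 0
    recomb_rate_per_bp: float = 2e-8
    mean_depth: float = 16.0
    seed: int = 0

    # ------------------------------------------------------------------
    @property
    def populations(self) -> list:
        return list(self.n_individuals)

    def divergence_of(self, pop) -> float:
        if isinstance(self.divergence, dict):
            return float(self.divergence.get(pop, 0.0))
        return float(self.divergence)

    def sib_pairs_of(self, pop) -> int:
        if isinstance(self.sib_pair_count, dict):
            return int(self.sib_pair_count.get(pop, 0))
        return int(self.sib_pair_count)

    def weights_of(self, pop) -> dict:
        return {float(r): float(w) for r, w in self.hbd_class_weights.get(pop, {}).items()}

    def validate(self) -> None:
        rates = np.asarray(self.hbd_class_rates, dtype=float)
        if not ((rates > 0).all() and (np.diff(rates) > 0).all()):
            raise SimulationError("hbd_class_rates must be positive and strictly increasing")
        if not 0 <= self.genotype_error < 1:
            raise SimulationError("genotype_error must be in [0, 1)")
        fr = self.category_fractions
        if set(fr) - set(CATEGORIES):
            raise SimulationError(f"unknown categories: {set(fr) - set(CATEGORIES)}")
        if abs(sum(fr.values()) - 1.0) > 1e-12:
            raise SimulationError("category_fractions must sum to 1")
        for pop in self.populations:
            w = self.weights_of(pop)
            if any(wt < 0 for wt in w.values()) or sum(w.values()) > 1 + 1e-12:
                raise SimulationError(f"invalid HBD class weights for {pop}")
            unknown = set(w) - set(float(r) for r in self.hbd_class_rates)
            if unknown:
                raise SimulationError(f"weights reference unknown class rates {unknown}")
            if not 0 <= self.divergence_of(pop) < 1:
                raise SimulationError("divergence must be in [0, 1)")
        for (grp, cat), s in self.load_shift.items():
            if s <= 0:
                raise SimulationError(f"load shift for {(grp, cat)} must be positive")
        if self.n_scaffolds < 1 or self.scaffold_length < 2 or self.n_sites_per_scaffold < 1:
            raise SimulationError("genome dimensions must be positive")


@dataclass
class TruthSet:
    """Planted ground truth accompanying a synthetic panel.

    ``tracts`` is a table (individual, scaffold, start, end, class_rate) with
    0-based half-open bp coordinates; ``true_f`` the per-individual planted
    autozygous genome fraction; ``sib_pairs`` a list of (id, id) tuples.
    """

    tracts: pd.DataFrame
    true_f: pd.Series
    site_categories: pd.Series
    sib_pairs: list


# ----------------------------------------------------------------------
# tract planting
# ----------------------------------------------------------------------

def plant_hbd_tracts(genetic_length, class_rates, class_weights, rng) -> list:
    """Plant HBD tracts along one scaffold of ``genetic_length`` Morgans.

    Tract lengths are exponential with mean ``1/R_k`` Morgans for class
    ``k``; tracts alternate with exponential non-HBD gaps whose mean is set
    so that the expected fraction of the scaffold covered by class ``k``
    equals its weight (class of each tract drawn with probability
    proportional to ``w_k * R_k``).

    Returns a list of ``(start_m, end_m, class_index)`` tuples in Morgans,
    non-overlapping and sorted.
    """
    if genetic_length <= 0:
        raise SimulationError("genetic length must be positive")
    rates = np.asarray(class_rates, dtype=float)
    weights = np.asarray(class_weights, dtype=float)
    if len(weights) != len(rates):
        raise SimulationError("one weight per class rate required")
    if (weights < 0).any() or weights.sum() > 1 + 1e-12:
        raise SimulationError("class weights must be nonnegative and sum to <= 1")
    w_tot = weights.sum()
    if w_tot <= 0:
        return []
    # class choice ∝ w_k R_k so per-class coverage share is ∝ w_k
    pick = weights * rates
    pick = pick / pick.sum()
    mean_tract = float((pick / rates).sum())
    mean_gap = mean_tract * (1.0 - w_tot) / w_tot
    tracts = []
    # random phase: start inside a gap of residual exponential length
    x = rng.exponential(mean_gap) if mean_gap > 0 else 0.0
    while x < genetic_length:
        k = int(rng.choice(len(rates), p=pick))
        end = x + rng.exponential(1.0 / rates[k])
        tracts.append((x, min(end, genetic_length), k))
        x = end
        if mean_gap > 0:
            x += rng.exponential(mean_gap)
    return tracts


# ----------------------------------------------------------------------
# frequency machinery
# ----------------------------------------------------------------------

def _ancestral_frequencies(cfg: SimConfig, rng, n_sites: int) -> np.ndarray:
    a = cfg.ancestral_beta
    p = rng.beta(a, a, size=n_sites)
    return np.clip(p, 0.01, 0.99)


def _population_frequencies(p_anc: np.ndarray, fst: float, rng) -> np.ndarray:
    """Balding–Nichols draw of population frequencies around the ancestor."""
    if fst <= 0:
        return p_anc.copy()
    c = (1.0 - fst) / fst
    f = rng.beta(p_anc * c, (1.0 - p_anc) * c)
    return np.clip(f, 0.005, 0.995)


def apply_load_asymmetry(frequencies, categories, minor_is_alt, groups, load_shift) -> np.ndarray:
    """Multiply minor-allele frequencies by group/category shifts.

    Parameters
    ----------
    frequencies
        ``(n_populations, n_sites)`` ALT-allele frequencies.
    categories
        Per-site category labels.
    minor_is_alt
        Per-site bool, which allele is (globally) minor.
    groups
        Group label per population (row of ``frequencies``).
    load_shift
        Mapping ``(group, category) -> factor``; intergenic never shifted.

    Shifted minor frequencies are clamped to [0, 1].
    """
    freqs = np.array(frequencies, dtype=float)
    if not load_shift:
        return freqs
    categories = np.asarray(categories)
    minor_is_alt = np.asarray(minor_is_alt, dtype=bool)
    for (grp, cat), s in load_shift.items():
        if s <= 0:
            raise SimulationError("load shift factors must be positive")
        if cat == "intergenic" or s == 1.0:
            continue
        site_mask = categories == cat
        if not site_mask.any():
            continue
        for i, g in enumerate(groups):
            if g != grp:
                continue
            alt_m = site_mask & minor_is_alt
            ref_m = site_mask & ~minor_is_alt
            freqs[i, alt_m] = np.clip(freqs[i, alt_m] * s, 0.0, 1.0)
            freqs[i, ref_m] = 1.0 - np.clip((1.0 - freqs[i, ref_m]) * s, 0.0, 1.0)
    return freqs


# ----------------------------------------------------------------------
# panel generation
# ----------------------------------------------------------------------

def _genotypes_for_individual(freqs, tract_mask, error, rng) -> np.ndarray:
    """Dosages for one individual given per-site ALT freqs and a tract mask."""
    n = len(freqs)
    hw = rng.binomial(2, freqs)
    dos = hw.astype(np.int8)
    if tract_mask.any():
        # inside a tract the two copies descend from one founder haplotype
        hom = np.where(rng.random(tract_mask.sum()) < freqs[tract_mask], 2, 0).astype(np.int8)
        dos[tract_mask] = hom
        if error > 0:
            err = tract_mask & (rng.random(n) < error)
            dos[err] = rng.binomial(2, freqs[err]).astype(np.int8)
    return dos


def _sib_genotypes(freqs, rng) -> tuple[np.ndarray, np.ndarray]:
    """Two full sibs: Mendelian transmission from two simulated parents."""
    pa = rng.binomial(2, freqs)
    pb = rng.binomial(2, freqs)

    def child():
        ga = np.where(pa == 1, rng.integers(0, 2, len(freqs)), pa // 2)
        gb = np.where(pb == 1, rng.integers(0, 2, len(freqs)), pb // 2)
        return (ga + gb).astype(np.int8)

    return child(), child()


def generate_panel(config: SimConfig) -> tuple[GenotypePanel, TruthSet]:
    """Generate a genotype panel and its planted truth from ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_scaf = config.n_scaffolds
    n_per = config.n_sites_per_scaffold
    n_sites = n_scaf * n_per
    scaffolds = [f"scaffold_{i + 1}" for i in range(n_scaf)]
    rate_bp = config.recomb_rate_per_bp
    genetic_len = config.scaffold_length * rate_bp  # Morgans per scaffold

    # site coordinates: evenly spaced, 1-based
    pos_one = np.linspace(1, config.scaffold_length, n_per).round().astype(np.int64)
    pos_one = np.unique(pos_one)
    if len(pos_one) != n_per:
        raise SimulationError("scaffold too short for the requested site count")
    site_scaf = np.repeat(scaffolds, n_per)
    site_pos = np.tile(pos_one, n_scaf)

    # categories
    cats = np.array(CATEGORIES)
    fr = np.array([config.category_fractions.get(c, 0.0) for c in CATEGORIES])
    site_cat = rng.choice(cats, size=n_sites, p=fr / fr.sum())

    # frequencies
    p_anc = _ancestral_frequencies(config, rng, n_sites)
    pops = config.populations
    pop_freqs = np.stack(
        [_population_frequencies(p_anc, config.divergence_of(p), rng) for p in pops]
    )
    minor_is_alt = p_anc <= 0.5
    groups = [config.group_of.get(p, p) for p in pops]
    pop_freqs = apply_load_asymmetry(pop_freqs, site_cat, minor_is_alt, groups, config.load_shift)

    rates = np.asarray(config.hbd_class_rates, dtype=float)
    genome_len_m = genetic_len * n_scaf

    dosage_rows, ind_rows, tract_rows, true_f, sib_pairs = [], [], [], [], []
    for ip, pop in enumerate(pops):
        weights = config.weights_of(pop)
        wvec = np.array([weights.get(float(r), 0.0) for r in rates])
        freqs = pop_freqs[ip]
        for j in range(config.n_individuals[pop]):
            ind_id = f"{pop}_{j + 1:03d}"
            tract_mask = np.zeros(n_sites, dtype=bool)
            planted = 0.0
            for si, scaf in enumerate(scaffolds):
                tracts = plant_hbd_tracts(genetic_len, rates, wvec, rng)
                lo = si * n_per
                gp = (pos_one - 1) * rate_bp
                for (a, b, k) in tracts:
                    in_tract = (gp >= a) & (gp < b)
                    tract_mask[lo:lo + n_per] |= in_tract
                    start_bp = int(round(a / rate_bp))
                    end_bp = int(round(b / rate_bp))
                    if end_bp > start_bp:
                        tract_rows.append((ind_id, scaf, start_bp, end_bp, float(rates[k])))
                        planted += (b - a)
            dosage_rows.append(
                _genotypes_for_individual(freqs, tract_mask, config.genotype_error, rng)
            )
            ind_rows.append((ind_id, pop, config.group_of.get(pop, pop)))
            true_f.append(planted / genome_len_m)
        for j in range(config.sib_pairs_of(pop)):
            c1, c2 = _sib_genotypes(freqs, rng)
            ids = (f"{pop}_sib{j + 1}a", f"{pop}_sib{j + 1}b")
            for ind_id, dos in zip(ids, (c1, c2)):
                dosage_rows.append(dos)
                ind_rows.append((ind_id, pop, config.group_of.get(pop, pop)))
                true_f.append(0.0)
            sib_pairs.append(ids)

    dosages = np.vstack(dosage_rows)
    depths = rng.poisson(config.mean_depth, size=dosages.shape).astype(np.int32)
    individuals = pd.DataFrame(ind_rows, columns=["id", "population", "group"])
    sites = pd.DataFrame(
        {
            "scaffold": site_scaf,
            "pos": site_pos,
            "ref": "A",
            "alt": "T",
            "genetic_pos": np.tile((pos_one - 1) * rate_bp, n_scaf),
            "category": site_cat,
        }
    )
    panel = GenotypePanel(dosages=dosages, sites=sites, individuals=individuals, depths=depths)
    tracts = pd.DataFrame(
        tract_rows, columns=["individual", "scaffold", "start", "end", "class_rate"]
    )
    truth = TruthSet(
        tracts=tracts,
        true_f=pd.Series(true_f, index=individuals["id"].to_numpy(), name="true_f"),
        site_categories=pd.Series(site_cat, name="category"),
        sib_pairs=sib_pairs,
    )
    return panel, truth
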