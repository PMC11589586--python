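"""Minor-allele load statistics and the R_XY family of ratios.

The globally rarer (minor) allele serves as a proxy for the derived — and
potentially deleterious — allele. Minor alleles are determined by a seeded
bootstrap over unrelated individuals (1000 replicates by default, an equal
number of draws per population so no population dominates the call), with
majority vote across replicates.

For two groups of genomes X and Y, the frequency-weighted excess of minor
alleles present in X but not Y is

    L_XnotY = Σ_i (d_X/n_X) (1 − d_Y/n_Y)

summed over sites of one functional category, with d the minor-allele count
among the n non-missing haploid genomes of the group at site i. The ratio
R_XY = L_XnotY / L_YnotX measures the asymmetry; dividing a category's
ratio by the ratio of intergenic sites (R′_XY) controls for demography.
R′_XY < 1 indicates enrichment of that category's minor alleles in Y
relative to intergenic expectation (reduced selection efficiency in Y);
values below ~0.8 have been read as purging signals. The homozygosity
analogue L²/R²/R′² uses the expected-homozygote weighting; its printed form
reduces algebraically to 2d/n and a switch substitutes the classical
d(d−1)/(n(n−1)) form. Uncertainty comes from a delete-one weighted block
jackknife over contiguous physical blocks (5 Mb default); a ratio is
flagged significant when its SE interval excludes 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import CATEGORIES, MISSING, GenotypePanel

DEFAULT_REPS = 1000
DEFAULT_BLOCK_BP = 5_000_000


class LoadStatsError(ValueError):
    """Invalid input to a load-statistics operation."""


# ----------------------------------------------------------------------
# minor-allele determination
# ----------------------------------------------------------------------

@dataclass
class MinorAlleleCall:
    """Bootstrap minor-allele call per site.

    ``minor_is_alt[i]`` is True when the ALT allele is the global minor
    allele at site ``i``; ``vote`` the fraction of replicates agreeing with
    the call; ``informative`` False where every replicate saw the site
    monomorphic.
    """

    minor_is_alt: np.ndarray
    vote: np.ndarray
    informative: np.ndarray
    reps: int


def call_minor_alleles(
    panel: GenotypePanel,
    unrelated_sets: dict,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    per_population_draws: int | None = None,
) -> MinorAlleleCall:
    """Determine the global minor allele per site by bootstrap majority vote.

    Each replicate draws, with replacement, an equal number of individuals
    from every population's unrelated set (default: the smallest set size),
    counts alleles globally, and votes for the rarer allele; a replicate
    frequency of exactly 0.5 votes for the ALT allele, as does a tie across
    replicates. ``unrelated_sets`` maps population -> list of individual ids.
    """
    if not unrelated_sets:
        raise LoadStatsError("unrelated_sets must cover at least one population")
    ids = panel.individuals["id"].to_numpy()
    id_pos = {i: p for p, i in enumerate(ids)}
    sets = {}
    for pop, members in unrelated_sets.items():
        pos = [id_pos[i] for i in members if i in id_pos]
        if not pos:
            raise LoadStatsError(f"unrelated set for {pop!r} matches no panel individual")
        sets[pop] = np.asarray(pos)
    k = per_population_draws or min(len(v) for v in sets.values())
    rng = np.random.default_rng(seed)

    n_sites = panel.n_sites
    alt_votes = np.zeros(n_sites, dtype=np.int32)
    informative = np.zeros(n_sites, dtype=bool)
    # multinomial sampling weights turn resampling into one matrix product
    d_tot = np.zeros((reps, n_sites))
    m_tot = np.zeros((reps, n_sites))
    for pop, pos in sets.items():
        dos = panel.dosages[pos]
        ok = dos != MISSING
        alt = np.where(ok, dos, 0).astype(np.float64)
        copies = (2 * ok).astype(np.float64)
        counts = rng.multinomial(k, np.full(len(pos), 1.0 / len(pos)), size=reps).astype(float)
        d_tot += counts @ alt
        m_tot += counts @ copies
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(m_tot > 0, d_tot / np.maximum(m_tot, 1.0), np.nan)
    poly = (d_tot > 0) & (d_tot < m_tot)
    alt_votes = (freq <= 0.5).sum(axis=0)  # ties vote ALT
    informative = poly.any(axis=0)
    minor_is_alt = alt_votes >= (reps / 2.0)  # across-replicate ties → ALT
    vote = np.where(minor_is_alt, alt_votes, reps - alt_votes) / float(reps)
    return MinorAlleleCall(
        minor_is_alt=minor_is_alt, vote=vote, informative=informative, reps=reps
    )


# ----------------------------------------------------------------------
# per-individual load counts
# ----------------------------------------------------------------------

def individual_load_counts(panel: GenotypePanel, calls: MinorAlleleCall) -> pd.DataFrame:
    """Per-individual, per-category minor-allele load counts.

    Copies count the minor allele (het = 1, hom = 2); the homozygous count
    is the number of sites homozygous for the minor allele; the polymorphic
    site count (per individual, all categories) is the number of non-missing
    sites where the individual carries at least one minor allele, and is the
    denominator of the normalised columns. Missing genotypes are skipped;
    sites lacking a category fall under "unclassified" and are excluded from
    category sums but reported.
    """
    dos = panel.dosages
    ok = dos != MISSING
    minor_dosage = np.where(
        calls.minor_is_alt[None, :], dos, 2 - dos
    )
    minor_dosage = np.where(ok, minor_dosage, 0)
    hom_minor = ok & (minor_dosage == 2)
    carrier = ok & (minor_dosage >= 1)
    poly_sites = carrier.sum(axis=1).astype(float)  # per-individual polymorphic sites
    cats = panel.sites["category"].to_numpy()
    rows = []
    for b, ind in panel.individuals.iterrows():
        for cat in list(CATEGORIES) + ["unclassified"]:
            cmask = cats == cat
            if not cmask.any():
                continue
            copies = int(minor_dosage[b, cmask].sum())
            hom = int(hom_minor[b, cmask].sum())
            denom = poly_sites[b] if poly_sites[b] > 0 else np.nan
            rows.append(
                {
                    "id": ind["id"],
                    "population": ind["population"],
                    "group": ind["group"],
                    "category": cat,
                    "minor_copies": copies,
                    "hom_minor_sites": hom,
                    "n_category_sites": int(cmask.sum()),
                    "polymorphic_sites": int(poly_sites[b]),
                    "minor_copies_norm": copies / denom,
                    "hom_minor_norm": hom / denom,
                }
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# L and R statistics
# ----------------------------------------------------------------------

def _group_counts(panel: GenotypePanel, calls: MinorAlleleCall, index: np.ndarray):
    """Per-site minor-allele count d and haploid genome count n for a group."""
    dos = panel.dosages[index]
    ok = dos != MISSING
    alt = np.where(ok, dos, 0).sum(axis=0).astype(float)
    n = (2 * ok).sum(axis=0).astype(float)
    d = np.where(calls.minor_is_alt, alt, n - alt)
    return d, n


def l_terms(d_x, n_x, d_y, n_y, l2_form: str = "literal"):
    """Per-site L_XnotY and L²_XnotY terms from minor-allele counts.

    ``l2_form`` selects the homozygosity weighting of L²: "literal" keeps
    the printed form 2d(n−d)/(n(n−d)) (which reduces to 2d/n), "dodds" uses
    the expected-homozygote form d(d−1)/(n(n−1)). Sites with n == 0 in
    either group contribute 0.
    """
    d_x, n_x, d_y, n_y = (np.asarray(a, dtype=float) for a in (d_x, n_x, d_y, n_y))
    ok = (n_x > 0) & (n_y > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fx = np.where(ok, d_x / np.maximum(n_x, 1.0), 0.0)
        fy = np.where(ok, d_y / np.maximum(n_y, 1.0), 0.0)
        l1 = fx * (1.0 - fy)
        if l2_form == "literal":
            hx = 2.0 * fx
            hy = 2.0 * fy
        elif l2_form == "dodds":
            hx = np.where(n_x > 1, d_x * (d_x - 1) / np.maximum(n_x * (n_x - 1), 1.0), 0.0)
            hy = np.where(n_y > 1, d_y * (d_y - 1) / np.maximum(n_y * (n_y - 1), 1.0), 0.0)
        else:
            raise LoadStatsError(f"unknown l2_form {l2_form!r}")
        l2 = hx * (1.0 - hy)
    l1[~ok] = 0.0
    l2[~ok] = 0.0
    return l1, l2


@dataclass
class RxyResult:
    """R_XY statistics for one functional category (X vs Y groups)."""

    category: str
    l_xnoty: float
    l_ynotx: float
    l2_xnoty: float
    l2_ynotx: float
    r_xy: float
    r2_xy: float
    r_prime: float | None = None
    r2_prime: float | None = None
    se_r: float | None = None
    se_r2: float | None = None
    se_r_prime: float | None = None
    se_r2_prime: float | None = None
    significant_r_prime: bool | None = None
    significant_r2_prime: bool | None = None
    n_sites: int = 0
    l2_form: str = "literal"
    extras: dict = field(default_factory=dict)


def _category_mask(panel, category):
    return (panel.sites["category"].to_numpy() == category)


def rxy(
    panel: GenotypePanel,
    calls: MinorAlleleCall,
    group_x,
    group_y,
    category,
    intergenic_category: str = "intergenic",
    l2_form: str = "literal",
    informative_only: bool = True,
) -> RxyResult:
    """R_XY, R²_XY and their intergenic-normalised R′ forms for one category.

    ``group_x`` / ``group_y`` are group labels of the panel's individuals
    (disjoint). Raises when a denominator L term is zero.
    """
    idx_x = panel.individuals_in(group=group_x)
    idx_y = panel.individuals_in(group=group_y)
    if len(idx_x) == 0 or len(idx_y) == 0:
        raise LoadStatsError("both groups must be non-empty")
    if set(idx_x) & set(idx_y):
        raise LoadStatsError("groups X and Y overlap")
    d_x, n_x = _group_counts(panel, calls, idx_x)
    d_y, n_y = _group_counts(panel, calls, idx_y)
    l1, l2 = l_terms(d_x, n_x, d_y, n_y, l2_form)
    l1r, l2r = l_terms(d_y, n_y, d_x, n_x, l2_form)
    use = np.ones(panel.n_sites, dtype=bool)
    if informative_only:
        use &= calls.informative

    def sums(mask):
        m = use & mask
        return l1[m].sum(), l1r[m].sum(), l2[m].sum(), l2r[m].sum(), int(m.sum())

    sx, sy, s2x, s2y, n_sites = sums(_category_mask(panel, category))
    if sy == 0 or s2y == 0:
        raise LoadStatsError(f"L_YnotX is zero for category {category!r}: ratio undefined")
    r = sx / sy
    r2 = s2x / s2y
    ix, iy, i2x, i2y, _ = sums(_category_mask(panel, intergenic_category))
    r_prime = r2_prime = None
    if iy > 0 and ix > 0 and i2y > 0 and i2x > 0:
        r_prime = r / (ix / iy)
        r2_prime = r2 / (i2x / i2y)
    return RxyResult(
        category=str(category),
        l_xnoty=float(sx),
        l_ynotx=float(sy),
        l2_xnoty=float(s2x),
        l2_ynotx=float(s2y),
        r_xy=float(r),
        r2_xy=float(r2),
        r_prime=None if r_prime is None else float(r_prime),
        r2_prime=None if r2_prime is None else float(r2_prime),
        n_sites=n_sites,
        l2_form=l2_form,
    )


# ----------------------------------------------------------------------
# block jackknife
# ----------------------------------------------------------------------

def jackknife_se(num_blocks, den_blocks, min_blocks: int = 10) -> tuple[float, float]:
    """Delete-one-block jackknife SE of a ratio Σnum / Σden.

    ``num_blocks`` and ``den_blocks`` are per-block contributions to the
    numerator and denominator sums. Returns ``(ratio, se)``; the caller
    flags significance when ``|ratio − 1| > se``.
    """
    num = np.asarray(num_blocks, dtype=float)
    den = np.asarray(den_blocks, dtype=float)
    b = len(num)
    if b < min_blocks:
        raise LoadStatsError(
            f"only {b} blocks (< {min_blocks}); use smaller blocks for the jackknife"
        )
    tot_n, tot_d = num.sum(), den.sum()
    if tot_d == 0:
        raise LoadStatsError("zero denominator in jackknife")
    loo_d = tot_d - den
    if (loo_d == 0).any():
        raise LoadStatsError("a delete-one denominator is zero")
    loo = (tot_n - num) / loo_d
    mean = loo.mean()
    var = (b - 1) / b * ((loo - mean) ** 2).sum()
    return float(tot_n / tot_d), float(np.sqrt(var))


def _ratio_jackknife(num_fn, blocks, min_blocks):
    """Jackknife over arbitrary per-block statistics via a ratio callable."""
    b = len(blocks)
    if b < min_blocks:
        raise LoadStatsError(f"only {b} blocks (< {min_blocks})")
    full = num_fn(np.ones(b, dtype=bool))
    loo = np.array([num_fn(np.arange(b) != i) for i in range(b)])
    mean = loo.mean()
    var = (b - 1) / b * ((loo - mean) ** 2).sum()
    return float(full), float(np.sqrt(var))


def rxy_with_jackknife(
    panel: GenotypePanel,
    calls: MinorAlleleCall,
    group_x,
    group_y,
    category,
    intergenic_category: str = "intergenic",
    l2_form: str = "literal",
    block_bp: int = DEFAULT_BLOCK_BP,
    min_blocks: int = 10,
    informative_only: bool = True,
) -> RxyResult:
    """R_XY / R′_XY for one category with delete-one-block jackknife SEs.

    Contiguous physical blocks of ``block_bp`` are the resampling unit; the
    SE of each ratio comes from its jackknife variance and the significance
    flag tests whether the ±SE interval around R′ excludes 1.
    """
    res = rxy(
        panel, calls, group_x, group_y, category, intergenic_category, l2_form, informative_only
    )
    idx_x = panel.individuals_in(group=group_x)
    idx_y = panel.individuals_in(group=group_y)
    d_x, n_x = _group_counts(panel, calls, idx_x)
    d_y, n_y = _group_counts(panel, calls, idx_y)
    l1, l2 = l_terms(d_x, n_x, d_y, n_y, l2_form)
    l1r, l2r = l_terms(d_y, n_y, d_x, n_x, l2_form)
    use = calls.informative if informative_only else np.ones(panel.n_sites, dtype=bool)
    cat_mask = _category_mask(panel, category) & use
    int_mask = _category_mask(panel, intergenic_category) & use

    scaf = panel.sites["scaffold"].to_numpy()
    pos = panel.sites["pos"].to_numpy()
    labels = np.empty(panel.n_sites, dtype=np.int64)
    nxt = 0
    for s in pd.unique(scaf):
        m = scaf == s
        labels[m] = nxt + (pos[m] - 1) // block_bp
        nxt = labels[m].max() + 1
    blocks = np.unique(labels)
    order = np.searchsorted(blocks, labels)

    def block_sums(values, mask):
        return np.bincount(order, weights=np.where(mask, values, 0.0), minlength=len(blocks))

    b_cat = {
        "l1": block_sums(l1, cat_mask),
        "l1r": block_sums(l1r, cat_mask),
        "l2": block_sums(l2, cat_mask),
        "l2r": block_sums(l2r, cat_mask),
    }
    b_int = {
        "l1": block_sums(l1, int_mask),
        "l1r": block_sums(l1r, int_mask),
        "l2": block_sums(l2, int_mask),
        "l2r": block_sums(l2r, int_mask),
    }

    _, res.se_r = _ratio_jackknife(
        lambda keep: b_cat["l1"][keep].sum() / b_cat["l1r"][keep].sum(), blocks, min_blocks
    )
    _, res.se_r2 = _ratio_jackknife(
        lambda keep: b_cat["l2"][keep].sum() / b_cat["l2r"][keep].sum(), blocks, min_blocks
    )
    if res.r_prime is not None:
        _, res.se_r_prime = _ratio_jackknife(
            lambda keep: (b_cat["l1"][keep].sum() / b_cat["l1r"][keep].sum())
            / (b_int["l1"][keep].sum() / b_int["l1r"][keep].sum()),
            blocks,
            min_blocks,
        )
        _, res.se_r2_prime = _ratio_jackknife(
            lambda keep: (b_cat["l2"][keep].sum() / b_cat["l2r"][keep].sum())
            / (b_int["l2"][keep].sum() / b_int["l2r"][keep].sum()),
            blocks,
            min_blocks,
        )
        res.significant_r_prime = abs(res.r_prime - 1.0) > res.se_r_prime
        res.significant_r2_prime = abs(res.r2_prime - 1.0) > res.se_r2_prime
    return res


def rxy_table(
    panel: GenotypePanel,
    calls: MinorAlleleCall,
    group_x,
    group_y,
    categories=("neutral", "low", "moderate", "high"),
    **kwargs,
) -> pd.DataFrame:
    """R_XY/R′_XY with jackknife SEs for several categories at once."""
    rows = []
    for cat in categories:
        res = rxy_with_jackknife(panel, calls, group_x, group_y, cat, **kwargs)
        rows.append(
            {
                "category": res.category,
                "r_xy": res.r_xy,
                "r2_xy": res.r2_xy,
                "r_prime": res.r_prime,
                "r2_prime": res.r2_prime,
                "se_r_prime": res.se_r_prime,
                "se_r2_prime": res.se_r2_prime,
                "significant_r_prime": res.significant_r_prime,
                "significant_r2_prime": res.significant_r2_prime,
                "n_sites": res.n_sites,
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# group comparison
# ----------------------------------------------------------------------

EFFECT_LABELS = ((0.5, "large"), (0.3, "moderate"), (0.1, "small"))


def group_compare(values_a, values_b) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of two groups.

    Returns W (the rank-sum statistic of the first sample, as R's
    ``wilcox.test`` reports), the normal-approximation p-value with tie
    correction, the effect size r = |Z|/√(n_A + n_B) and its conventional
    label (small/moderate/large at 0.1/0.3/0.5).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise LoadStatsError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    u = float(res.statistic)
    n1, n2 = len(a), len(b)
    mean_u = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1.0)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * (n + 1.0 - tie_term)
    z = 0.0 if sigma2 == 0 else (u - mean_u) / np.sqrt(sigma2)
    effect = abs(z) / np.sqrt(n)
    label = "negligible"
    for cut, name in EFFECT_LABELS:
        if effect >= cut:
            label = name
            break
    return {
        "w": u,
        "p_value": float(res.pvalue),
        "effect_size": float(effect),
        "label": label,
        "z": float(z),
    }
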