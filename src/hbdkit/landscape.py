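"""Genome-wide autozygosity landscape.

Averages each SNP's posterior probability of lying in an HBD segment across
individuals, summarises the per-SNP track in overlapping sliding windows
(100 kb width, 20 kb step by default; scaffolds with fewer than 10,000 SNPs
are dropped), flags HBD islands and deserts as the extreme 2.5% tails of the
window distribution, and relates window HBD probability to gene density via
a Spearman rank correlation with a seeded permutation p-value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_WIDTH = 100_000
DEFAULT_STEP = 20_000
DEFAULT_MIN_SCAFFOLD_SNPS = 10_000
DEFAULT_TAIL = 0.025


class LandscapeError(ValueError):
    """Invalid landscape computation input."""


def per_snp_hbd_probability(decodings, rates=None, T=None) -> np.ndarray:
    """Mean per-SNP HBD probability across individuals.

    Each decoding contributes the sum of its HBD-class posteriors at every
    SNP (equivalently ``1 − P(non-HBD)``); with ``T`` set, only classes of
    rate ≤ T are summed (the "recent-coalescence" variant). All decodings
    must share the same site set.
    """
    if not decodings:
        raise LandscapeError("no decodings supplied")
    n = decodings[0].posteriors.shape[0]
    acc = np.zeros(n)
    for dec in decodings:
        if dec.posteriors.shape[0] != n:
            raise LandscapeError("decodings do not share a common site set")
        acc += dec.hbd_probability(rates=rates, T=T)
    return acc / len(decodings)


def window_average(
    sites: pd.DataFrame,
    track: np.ndarray,
    width: int = DEFAULT_WIDTH,
    step: int = DEFAULT_STEP,
    min_scaffold_snps: int = DEFAULT_MIN_SCAFFOLD_SNPS,
    scaffold_lengths: dict | None = None,
) -> pd.DataFrame:
    """Sliding-window mean of a per-SNP track.

    Windows are physical, left-aligned at scaffold start (0-based half-open,
    fixed ``width`` and ``step``); the last partial window is kept. Scaffolds
    with fewer than ``min_scaffold_snps`` SNPs are dropped entirely. Windows
    without SNPs are emitted with a missing (NaN) mean.
    """
    if step > width:
        raise LandscapeError("step must not exceed width")
    track = np.asarray(track, dtype=float)
    scaf_arr = sites["scaffold"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    rows = []
    for s in pd.unique(scaf_arr):
        mask = scaf_arr == s
        if mask.sum() < min_scaffold_snps:
            continue
        pos = pos_arr[mask]
        vals = track[mask]
        length = (scaffold_lengths or {}).get(s, int(pos.max()))
        starts = np.arange(0, max(length - 1, 1), step)
        p0 = pos - 1  # 0-based site coordinates
        cum = np.concatenate([[0.0], np.cumsum(vals)])
        for st in starts:
            en = min(st + width, length)
            lo = np.searchsorted(p0, st, side="left")
            hi = np.searchsorted(p0, en, side="left")
            n_snp = hi - lo
            mean = (cum[hi] - cum[lo]) / n_snp if n_snp else np.nan
            rows.append((s, int(st), int(en), mean, int(n_snp)))
            if en >= length:
                break
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "hbd_prob", "n_snps"])


def hbd_islands_deserts(windows: pd.DataFrame, tail: float = DEFAULT_TAIL) -> pd.DataFrame:
    """Flag the extreme tails of the window HBD-probability distribution.

    The top ``tail`` share of non-missing windows become islands and the
    bottom share deserts (k = ceil(tail × n) each). Ties at a tail boundary
    that would over-fill it are not flagged, keeping flag assignment
    deterministic in position order; a window can never be both.
    """
    if not 0 <= tail < 0.5:
        raise LandscapeError("tail must be in [0, 0.5)")
    out = windows.copy()
    vals = out["hbd_prob"].to_numpy(dtype=float)
    valid = ~np.isnan(vals)
    if not valid.any():
        raise LandscapeError("all windows missing: nothing to flag")
    out["flag"] = "none"
    n = int(valid.sum())
    k = int(np.ceil(tail * n)) if tail > 0 else 0
    if k == 0:
        return out
    v = vals[valid]
    hi_sorted = np.sort(v)[::-1]
    lo_sorted = np.sort(v)
    hi_bound = hi_sorted[k - 1]
    lo_bound = lo_sorted[k - 1]
    island = valid & (vals >= hi_bound)
    desert = valid & (vals <= lo_bound)
    if island.sum() > k:  # boundary tie over-fills: keep strictly inside the tail
        island = valid & (vals > hi_bound)
    if desert.sum() > k:
        desert = valid & (vals < lo_bound)
    both = island & desert
    island &= ~both
    desert &= ~both
    out.loc[island, "flag"] = "island"
    out.loc[desert, "flag"] = "desert"
    return out


def gene_counts_per_window(windows: pd.DataFrame, genes: pd.DataFrame) -> np.ndarray:
    """Number of genes overlapping each window (half-open intervals).

    A gene spanning several windows is counted in every window it touches.
    """
    counts = np.zeros(len(windows), dtype=np.int64)
    gscaf = genes["scaffold"].to_numpy()
    for i, (scaf, start, end) in enumerate(
        zip(windows["scaffold"], windows["start"], windows["end"])
    ):
        m = gscaf == scaf
        if not m.any():
            continue
        gs = genes["start"].to_numpy()[m]
        ge = genes["end"].to_numpy()[m]
        counts[i] = int(((gs < end) & (ge > start)).sum())
    return counts


def gene_density_association(
    windows: pd.DataFrame,
    genes: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Spearman association between window gene count and HBD probability.

    Returns the correlation, its permutation p-value (two-sided, label
    shuffling of the probability track, ``n_permutations`` seeded shuffles)
    and the per-window gene counts.
    """
    if len(genes) == 0:
        raise LandscapeError("no genes supplied: correlation undefined")
    counts = gene_counts_per_window(windows, genes)
    vals = windows["hbd_prob"].to_numpy(dtype=float)
    ok = ~np.isnan(vals)
    if ok.sum() < 3:
        raise LandscapeError("fewer than 3 windows with data")
    x = counts[ok].astype(float)
    y = vals[ok]
    rho = float(stats.spearmanr(x, y).statistic)
    # permutation null on precomputed ranks (Pearson of ranks == Spearman)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    n = len(rx)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = rx @ rng.permutation(ry) / n
    obs = rx @ ry / n
    p = float((np.abs(null) >= abs(obs)).sum() + 1) / (n_permutations + 1)
    return {"rho": rho, "p_value": p, "gene_counts": counts, "n_windows": int(ok.sum())}
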