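"""Multi-class homozygosity-by-descent hidden Markov model.

The model describes an individual's genome as a mosaic of HBD segments from
``K`` age classes plus a non-HBD background. Class ``k`` has a per-Morgan
exit rate ``R_k`` (default 2, 4, ..., 8192 for 13 HBD classes, and 8192 for
the non-HBD class); segment lengths are therefore exponential with mean
``1/R_k`` Morgans, and ``R_k`` equals twice the expected number of
generations since the coalescence event that produced the segment. Across a
genetic distance ``d`` the chain stays in its current state with probability
``exp(-R_k d)``; on leaving, it re-enters state ``l`` (possibly the same)
with mixing probability ``M_l``. The initial distribution is ``M``.

Emissions condition on the population ALT-allele frequency ``f`` at each
marker. In an HBD state the two allele copies descend from one founder
haplotype, so ``P(g) = (1-e)·[1-f, 0, f][g] + e·HWE(g)`` with genotyping
error ``e``; the non-HBD state emits Hardy–Weinberg probabilities
``[(1-f)^2, 2f(1-f), f^2]``. Missing genotypes emit likelihood 1 everywhere.

Provided here: scaled forward–backward posteriors, EM estimation of the
mixing coefficients (rates stay fixed), Viterbi segment calling, the
inbreeding coefficient F_HBD (mean posterior mass in classes with rate ≤ T),
and per-individual segment summaries N_HBD / S_HBD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel

DEFAULT_RATES = (
    2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0, 256.0, 512.0, 1024.0, 2048.0, 4096.0, 8192.0,
)
DEFAULT_NONHBD_RATE = 8192.0
DEFAULT_T = 1024.0


class HbdModelError(ValueError):
    """Invalid model specification or observations."""


@dataclass
class HbdModelSpec:
    """Layered HBD model: class rates, mixing coefficients, error rate.

    ``rates`` are the K HBD class rates (strictly increasing, positive);
    ``nonhbd_rate`` the exit rate of the non-HBD state. ``mix`` holds K+1
    mixing coefficients (HBD classes first, non-HBD last) summing to 1;
    uninformative (uniform) by default.
    """

    rates: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_RATES))
    nonhbd_rate: float = DEFAULT_NONHBD_RATE
    mix: np.ndarray | None = None
    error: float = 0.001

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if (self.rates <= 0).any() or (np.diff(self.rates) <= 0).any():
            raise HbdModelError("class rates must be positive and strictly increasing")
        if self.nonhbd_rate <= 0:
            raise HbdModelError("non-HBD rate must be positive")
        if not 0 <= self.error < 1:
            raise HbdModelError("error rate must be in [0, 1)")
        k = len(self.rates)
        if self.mix is None:
            self.mix = np.full(k + 1, 1.0 / (k + 1))
        self.mix = np.asarray(self.mix, dtype=float)
        if len(self.mix) != k + 1:
            raise HbdModelError("mix must have one entry per class plus non-HBD")
        if (self.mix < 0).any() or abs(self.mix.sum() - 1.0) > 1e-12:
            raise HbdModelError("mixing coefficients must be nonnegative and sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.rates) + 1

    @property
    def all_rates(self) -> np.ndarray:
        """Exit rates of every state, non-HBD last."""
        return np.append(self.rates, self.nonhbd_rate)


@dataclass
class HbdDecoding:
    """Posterior decoding of one individual on one site set.

    ``posteriors`` is ``(n_markers, K+1)`` with the non-HBD state last;
    ``loglik`` the total log-likelihood; ``viterbi`` an optional per-marker
    state path.
    """

    posteriors: np.ndarray
    loglik: float
    viterbi: np.ndarray | None = None

    def hbd_probability(self, rates=None, T=None) -> np.ndarray:
        """Per-marker probability of lying in an HBD segment.

        With ``T`` given, only classes with rate ≤ T are summed (``rates``
        required); otherwise all HBD classes count.
        """
        hbd = self.posteriors[:, :-1]
        if T is None:
            return hbd.sum(axis=1)
        if rates is None:
            raise HbdModelError("rates required to apply an age threshold")
        return hbd[:, np.asarray(rates) <= T].sum(axis=1)


# ----------------------------------------------------------------------
# emissions
# ----------------------------------------------------------------------

def emission_likelihoods(dosages, freqs, model: HbdModelSpec) -> np.ndarray:
    """Per-marker emission likelihoods, shape ``(..., n_markers, 2)``.

    Column 0 is the shared HBD-state likelihood, column 1 the non-HBD
    (Hardy–Weinberg) likelihood; all HBD classes share emissions, so two
    columns suffice and :func:`expand_emissions` broadcasts them to K+1
    states.
    """
    dosages = np.asarray(dosages)
    f = np.asarray(freqs, dtype=float)
    if ((f <= 0) | (f >= 1)).any():
        raise HbdModelError("allele frequencies must be strictly inside (0, 1)")
    hwe = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1)
    ibd = np.stack([1 - f, np.zeros_like(f), f], axis=-1)
    e = model.error
    hbd_like = (1 - e) * ibd + e * hwe
    g = np.clip(dosages, 0, 2)
    hbd_col = np.take_along_axis(hbd_like, g[..., None], axis=-1)[..., 0]
    non_col = np.take_along_axis(hwe, g[..., None], axis=-1)[..., 0]
    out = np.stack([hbd_col, non_col], axis=-1)
    out[dosages == MISSING] = 1.0  # missing genotypes are uninformative
    return out


def expand_emissions(em2: np.ndarray, n_states: int) -> np.ndarray:
    """Broadcast (..., 2) HBD/non-HBD emissions to (..., K+1) states."""
    idx = np.zeros(n_states, dtype=int)
    idx[-1] = 1
    return em2[..., idx]


def _as_state_emissions(emissions, model):
    emissions = np.asarray(emissions, dtype=float)
    if emissions.shape[-1] == 2 and model.n_states != 2:
        emissions = expand_emissions(emissions, model.n_states)
    if emissions.shape[-1] != model.n_states:
        raise HbdModelError("emission matrix does not match the model's state count")
    return emissions


# ----------------------------------------------------------------------
# forward-backward (batched across individuals)
# ----------------------------------------------------------------------

def _stay_probabilities(model: HbdModelSpec, distances) -> np.ndarray:
    """(n-1, K+1) per-interval stay probabilities exp(-R_k d)."""
    distances = np.asarray(distances, dtype=float)
    if (distances < 0).any():
        raise HbdModelError("genetic distances must be nonnegative")
    return np.exp(-np.outer(distances, model.all_rates))


def _forward_backward_batch(emissions, model, distances, mix=None, want_em_stats=False):
    """Scaled forward–backward over a batch of individuals.

    ``emissions``: (B, n, S); ``mix``: optional per-individual mixing
    coefficients (B, S), defaulting to the model's shared vector. Returns
    ``(posteriors (B, n, S), loglik (B,), em_num (B, S) or None)``.

    ``em_num`` is the EM numerator of the mixing-coefficient update:
    expected occupancy at the first marker plus the expected number of jump
    entries into each state (an apparent stay may be an exit followed by
    re-entry into the same class, which the closed-form transition
    ``p_k δ_kl + (1-p_k) M_l`` marginalises out; the E-step reweights by the
    jump share ``(1-p_k) M_l`` of each transition).
    """
    B, n, S = emissions.shape
    if n < 1:
        raise HbdModelError("empty observation sequence")
    M = np.broadcast_to(model.mix if mix is None else np.asarray(mix, float), (B, S))
    stay = _stay_probabilities(model, distances) if n > 1 else np.empty((0, S))
    if n > 1 and stay.shape[0] != n - 1:
        raise HbdModelError("need one genetic distance per adjacent marker pair")
    alpha = np.empty((B, n, S))
    scale = np.empty((B, n))
    a = M * emissions[:, 0]
    c = a.sum(axis=1)
    if (c <= 0).any():
        raise HbdModelError("zero likelihood at first marker")
    alpha[:, 0] = a / c[:, None]
    scale[:, 0] = c
    for t in range(n - 1):
        p = stay[t]
        a = alpha[:, t]
        leave = (a * (1 - p)).sum(axis=1)
        a_next = (a * p + leave[:, None] * M) * emissions[:, t + 1]
        c = a_next.sum(axis=1)
        if (c <= 0).any():
            raise HbdModelError(f"zero likelihood at marker {t + 1}")
        alpha[:, t + 1] = a_next / c[:, None]
        scale[:, t + 1] = c
    beta_next = np.ones((B, S))
    post = np.empty((B, n, S))
    post[:, n - 1] = alpha[:, n - 1]
    em_num = np.zeros((B, S)) if want_em_stats else None
    for t in range(n - 2, -1, -1):
        p = stay[t]
        u = emissions[:, t + 1] * beta_next / scale[:, t + 1][:, None]
        mu = (u * M).sum(axis=1)
        beta_t = p[None, :] * u + (1 - p)[None, :] * mu[:, None]
        g = alpha[:, t] * beta_t
        post[:, t] = g / g.sum(axis=1, keepdims=True)
        if want_em_stats:
            leave = (alpha[:, t] * (1 - p)).sum(axis=1)
            em_num += leave[:, None] * M * u
        beta_next = beta_t
    loglik = np.log(scale).sum(axis=1)
    if want_em_stats:
        em_num += post[:, 0]
    return post, loglik, em_num


def forward_backward(emissions, model: HbdModelSpec, distances) -> HbdDecoding:
    """Exact scaled posteriors for one individual.

    ``emissions`` is ``(n_markers, K+1)`` state likelihoods (or the compact
    ``(n_markers, 2)`` HBD/non-HBD form); ``distances`` the ``n_markers - 1``
    genetic gaps in Morgans. Per-marker posteriors sum to 1.
    """
    emissions = _as_state_emissions(emissions, model)
    if emissions.ndim != 2 or emissions.shape[0] == 0:
        raise HbdModelError("emissions must be a non-empty (n_markers, states) array")
    post, loglik, _ = _forward_backward_batch(emissions[None], model, distances)
    return HbdDecoding(posteriors=post[0], loglik=float(loglik[0]))


def fit_mixing_coefficients(
    emissions,
    model: HbdModelSpec,
    distances,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[HbdModelSpec, dict]:
    """EM estimation of the mixing coefficients with fixed class rates.

    E-step: expected first-marker occupancy plus expected jump entries into
    each state; M-step: renormalise. The log-likelihood is non-decreasing;
    iteration stops at ``|Δloglik| < tol`` or ``max_iter`` (non-convergence
    is flagged in the info dict, not raised).
    """
    emissions = _as_state_emissions(emissions, model)
    if emissions.ndim == 2:
        emissions = emissions[None]
    if model.n_states == 1:
        return replace(model, mix=np.array([1.0])), {"loglik": [], "converged": True}
    logliks: list[float] = []
    converged = False
    current = model
    for _ in range(max_iter):
        _, ll, em_num = _forward_backward_batch(
            emissions, current, distances, want_em_stats=True
        )
        ll_total = float(ll.sum())
        if logliks and abs(ll_total - logliks[-1]) < tol:
            logliks.append(ll_total)
            converged = True
            break
        logliks.append(ll_total)
        num = em_num.sum(axis=0)
        if num.sum() <= 0:
            break
        current = replace(current, mix=num / num.sum())
    return current, {"loglik": logliks, "converged": converged}


# ----------------------------------------------------------------------
# Viterbi
# ----------------------------------------------------------------------

def viterbi_path(emissions, model: HbdModelSpec, distances, mix=None) -> np.ndarray:
    """Most probable state path (log-space Viterbi). Non-HBD is the last state."""
    emissions = _as_state_emissions(emissions, model)
    n, S = emissions.shape
    M = model.mix if mix is None else np.asarray(mix, dtype=float)
    stay = _stay_probabilities(model, distances) if n > 1 else np.empty((0, S))
    with np.errstate(divide="ignore"):
        log_e = np.log(emissions)
        v = np.log(M) + log_e[0]
    back = np.empty((max(n - 1, 0), S), dtype=np.int32)
    for t in range(n - 1):
        p = stay[t]
        with np.errstate(divide="ignore"):
            # transition matrix T[k, l] = p_k δ_kl + (1 - p_k) M_l
            trans = np.log((1 - p)[:, None] * M[None, :] + np.diag(p))
        cand = v[:, None] + trans
        back[t] = np.argmax(cand, axis=0)
        v = cand[back[t], np.arange(S)] + log_e[t + 1]
    path = np.empty(n, dtype=np.int32)
    path[-1] = int(np.argmax(v))
    for t in range(n - 2, -1, -1):
        path[t] = back[t][path[t + 1]]
    return path


def segments_from_path(path, positions, scaffold, model: HbdModelSpec) -> pd.DataFrame:
    """Merge consecutive same-class HBD markers into segments.

    ``positions`` are 1-based bp; segments are reported 0-based half-open
    (start = first marker pos - 1, end = last marker pos), labelled by class
    rate. Sorted and non-overlapping by construction.
    """
    path = np.asarray(path)
    positions = np.asarray(positions)
    nonhbd = model.n_states - 1
    rows = []
    start = None
    for i, s in enumerate(path):
        if start is None:
            if s != nonhbd:
                start = i
        elif s != path[start]:
            rows.append(
                (scaffold, positions[start] - 1, positions[i - 1], model.rates[path[start]])
            )
            start = i if s != nonhbd else None
    if start is not None:
        rows.append((scaffold, positions[start] - 1, positions[-1], model.rates[path[start]]))
    df = pd.DataFrame(rows, columns=["scaffold", "start", "end", "class_rate"])
    df["length"] = df["end"] - df["start"]
    return df


# ----------------------------------------------------------------------
# summaries
# ----------------------------------------------------------------------

def f_hbd(decoding: HbdDecoding, rates, T: float = DEFAULT_T, strict_inequality=False) -> float:
    """Inbreeding coefficient: mean per-marker autozygosity probability.

    Averages, over markers, the summed posterior of HBD classes with rate
    ``<= T`` (or ``< T`` with ``strict_inequality``); ``T=1024`` with the
    default rates counts coalescence events within the last 512 generations.
    Returns 0 with a warning if no class passes the threshold.
    """
    rates = np.asarray(rates, dtype=float)
    keep = rates < T if strict_inequality else rates <= T
    if not keep.any():
        warnings.warn("T below the smallest class rate: F_HBD is identically 0")
        return 0.0
    return float(decoding.posteriors[:, :-1][:, keep].sum(axis=1).mean())


def autozygosity_horizon_generations(T: float = DEFAULT_T) -> float:
    """Age horizon implied by ``T``: a class rate is twice the expected number
    of generations since coalescence, so classes with rate ≤ T span the last
    ``T/2`` generations."""
    return T / 2.0


def segment_summaries(segments: pd.DataFrame, T: float = DEFAULT_T, strict_inequality=False) -> dict:
    """N_HBD, S_HBD and per-class summed length for one individual.

    Only segments in autozygous classes (rate ≤ T, or < T when strict) are
    counted; an empty segment set yields N_HBD = 0 and S_HBD = 0.
    """
    empty = {"n_hbd": 0, "s_hbd": 0.0, "class_lengths": {}}
    if len(segments) == 0:
        return empty
    rate = segments["class_rate"].to_numpy(dtype=float)
    keep = rate < T if strict_inequality else rate <= T
    sub = segments.loc[keep]
    if len(sub) == 0:
        return empty
    lengths = (sub["end"] - sub["start"]).to_numpy(dtype=float)
    class_lengths = {
        float(r): float(lengths[(sub["class_rate"] == r).to_numpy()].sum())
        for r in np.unique(sub["class_rate"])
    }
    return {"n_hbd": int(len(sub)), "s_hbd": float(lengths.mean()), "class_lengths": class_lengths}


# ----------------------------------------------------------------------
# panel-level driver
# ----------------------------------------------------------------------

@dataclass
class PanelDecoding:
    """Decodings, fitted models and Viterbi segments for a whole panel."""

    decodings: list
    models: list
    segments: list  # per individual: DataFrame over all scaffolds
    site_index: pd.DataFrame

    def f_hbd_values(self, T: float = DEFAULT_T) -> np.ndarray:
        return np.array(
            [f_hbd(dec, mod.rates, T=T) for dec, mod in zip(self.decodings, self.models)]
        )


def decode_panel(
    panel: GenotypePanel,
    model: HbdModelSpec | None = None,
    freq_scope: str = "population",
    fit: bool = True,
    viterbi: bool = True,
    tol: float = 1e-3,
    max_iter: int = 25,
) -> PanelDecoding:
    """Run the HBD model on every individual of a panel.

    Each scaffold is decoded as an independent chain re-initialised at the
    mixing distribution; mixing coefficients are fitted by EM per individual
    (batched across individuals) when ``fit`` is true. Genetic positions
    must be present — interpolate the map first. Emission allele frequencies
    are estimated from the panel, per population by default.
    """
    if model is None:
        model = HbdModelSpec()
    gen = panel.sites["genetic_pos"].to_numpy(dtype=float)
    if np.isnan(gen).any():
        raise HbdModelError("genetic positions missing: interpolate the map first")
    freqs = panel.allele_frequencies(scope=freq_scope)
    scaf = panel.sites["scaffold"].to_numpy()
    chunks = []
    for s in pd.unique(scaf):
        idx = np.flatnonzero(scaf == s)
        chunks.append((s, idx, np.diff(gen[idx])))

    B = panel.n_individuals
    S = model.n_states
    em_all = emission_likelihoods(panel.dosages, freqs, model)  # (B, n, 2)

    mix = np.broadcast_to(model.mix, (B, S)).copy()
    if fit:
        prev_ll = None
        for _ in range(max_iter):
            total_ll = np.zeros(B)
            num = np.zeros((B, S))
            for s, idx, dist in chunks:
                em = expand_emissions(em_all[:, idx], S)
                _, ll, em_num = _forward_backward_batch(
                    em, model, dist, mix=mix, want_em_stats=True
                )
                total_ll += ll
                num += em_num
            if prev_ll is not None and np.abs(total_ll - prev_ll).max() < tol:
                break
            prev_ll = total_ll
            mix = num / num.sum(axis=1, keepdims=True)

    decodings = [None] * B
    models = [replace(model, mix=mix[b].copy()) for b in range(B)]
    posts = [[] for _ in range(B)]
    logliks = np.zeros(B)
    seg_frames: list[list] = [[] for _ in range(B)]
    for s, idx, dist in chunks:
        em = expand_emissions(em_all[:, idx], S)
        post, ll, _ = _forward_backward_batch(em, model, dist, mix=mix)
        logliks += ll
        for b in range(B):
            posts[b].append(post[b])
            if viterbi:
                path = viterbi_path(em[b], models[b], dist, mix=mix[b])
                seg_frames[b].append(
                    segments_from_path(path, panel.sites["pos"].to_numpy()[idx], s, models[b])
                )
    empty_cols = ["scaffold", "start", "end", "class_rate", "length"]
    for b in range(B):
        decodings[b] = HbdDecoding(posteriors=np.vstack(posts[b]), loglik=float(logliks[b]))
    segments = [
        pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=empty_cols)
        for frames in seg_frames
    ]
    return PanelDecoding(
        decodings=decodings,
        models=models,
        segments=segments,
        site_index=panel.sites[["scaffold", "pos"]].copy(),
    )
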