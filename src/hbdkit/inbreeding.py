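"""Allele-sharing inbreeding statistics and the inbreeding-origin contrast.

The allele-sharing matrix records, for every pair of individuals, the mean
per-locus allele matching: with ALT dosages ``x ∈ {0, 1, 2}`` the matching
of a pair at one locus is ``(x_i·x_j + (2−x_i)(2−x_j)) / 4`` — the
probability that one allele drawn from each individual matches. On the
diagonal this is 1 at a homozygous locus and 0.5 at a heterozygous one.

Standardising an entry by the mean between-individual matching M̄_B of the
population gives a coancestry coefficient β = (M − M̄_B)/(1 − M̄_B): off the
diagonal this is the pairwise relatedness used for the unrelated-set filter
(β < 0.05; ≈0.25 for full sibs), and on the diagonal it estimates the
self-coancestry (1+F)/2, so the allele-sharing inbreeding coefficient is
F_AS = 2β_ii − 1. Contrasting F_HBD with F_AS diagnoses the
origin of inbreeding: F_HBD > F_AS points to ancient coalescence (small
long-term effective size), F_AS > F_HBD to recent consanguinity or
population structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel


class InbreedingError(ValueError):
    """Invalid input to an inbreeding-statistics operation."""


@dataclass
class AlleleSharingMatrix:
    """Symmetric matrix of mean per-locus allele matching.

    ``values[i, j]`` is the average matching over loci non-missing in both
    individuals; ``counts[i, j]`` the number of such loci (entries with zero
    shared loci are NaN). ``ids`` labels rows/columns.
    """

    values: np.ndarray
    counts: np.ndarray
    ids: list

    def mean_between(self, subset: np.ndarray | None = None) -> float:
        """Mean off-diagonal sharing, optionally over a subset of indices."""
        m = self.values if subset is None else self.values[np.ix_(subset, subset)]
        n = m.shape[0]
        if n < 2:
            raise InbreedingError("need at least two individuals for between-sharing")
        off = m[~np.eye(n, dtype=bool)]
        if np.isnan(off).any():
            raise InbreedingError("pairs with no shared loci present")
        return float(off.mean())

    def beta(self, subset: np.ndarray | None = None) -> np.ndarray:
        """Pairwise relatedness β = (M_ij − M̄_B)/(1 − M̄_B) on a subset."""
        m = self.values if subset is None else self.values[np.ix_(subset, subset)]
        mb = self.mean_between(subset)
        if mb >= 1.0:
            raise InbreedingError("monomorphic panel: mean between-sharing is 1")
        return (m - mb) / (1.0 - mb)


def allele_sharing_matrix(panel: GenotypePanel, individual_index=None) -> AlleleSharingMatrix:
    """Compute the allele-sharing matrix of a panel (or a subset of it)."""
    if individual_index is None:
        dos = panel.dosages
        ids = list(panel.individuals["id"])
    else:
        individual_index = np.asarray(individual_index)
        dos = panel.dosages[individual_index]
        ids = list(panel.individuals["id"].to_numpy()[individual_index])
    if dos.shape[0] < 1:
        raise InbreedingError("empty individual set")
    ok = (dos != MISSING).astype(float)
    x = np.where(dos != MISSING, dos, 0).astype(float)
    y = (2.0 - x) * ok
    x = x * ok
    counts = ok @ ok.T
    sums = (x @ x.T + y @ y.T) / 4.0
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return AlleleSharingMatrix(values=values, counts=counts.astype(np.int64), ids=ids)


def unrelated_set(matrix: AlleleSharingMatrix, threshold: float = 0.05) -> list:
    """Greedy maximal subset with all pairwise relatedness β < threshold.

    β is standardised once from the full matrix. While any pair violates
    the threshold, the individual involved in the most violating pairs is
    removed (ties broken by removing the lowest id). Returns surviving ids.
    """
    n = matrix.values.shape[0]
    if n == 0:
        raise InbreedingError("empty population")
    if n == 1:
        return list(matrix.ids)
    beta = matrix.beta()
    np.fill_diagonal(beta, 0.0)
    alive = np.ones(n, dtype=bool)
    ids = np.asarray(matrix.ids, dtype=object)
    while True:
        sub = np.flatnonzero(alive)
        viol = (beta[np.ix_(sub, sub)] >= threshold)
        counts = viol.sum(axis=1)
        if counts.max(initial=0) == 0:
            break
        worst = counts == counts.max()
        cand = sub[worst]
        # ties: remove the lexicographically lowest id
        drop = cand[np.argsort(ids[cand].astype(str))[0]]
        alive[drop] = False
    return list(ids[alive])


def f_as(
    panel: GenotypePanel,
    population,
    reference_ids=None,
    matrix: AlleleSharingMatrix | None = None,
) -> pd.Series:
    """Allele-sharing inbreeding coefficient for every individual of a population.

    F_AS,i = 2·β_ii − 1 with β_ii = (M_ii − M̄_B)/(1 − M̄_B), where M̄_B is
    the mean between-individual sharing over the reference set (default: all
    individuals of the population). β_ii standardises the self-sharing and
    estimates the self-coancestry (1+F)/2, hence the 2β−1 conversion: under
    random mating F_AS averages 0, a fully homozygous individual scores 1
    against M̄_B = 0.5, and individuals matching less than random pairs go
    negative. Individuals excluded from the reference still receive a
    coefficient.
    """
    idx = panel.individuals_in(population=population)
    if len(idx) < 2:
        raise InbreedingError(f"population {population!r} needs at least 2 individuals")
    if matrix is None:
        matrix = allele_sharing_matrix(panel, idx)
    ids = np.asarray(matrix.ids, dtype=object)
    if reference_ids is None:
        ref_pos = np.arange(len(ids))
    else:
        wanted = set(reference_ids)
        ref_pos = np.flatnonzero([i in wanted for i in ids])
        if len(ref_pos) < 2:
            raise InbreedingError("reference set must contain at least 2 individuals")
    mb = matrix.mean_between(ref_pos)
    if mb >= 1.0:
        raise InbreedingError("monomorphic panel: mean between-sharing is 1, F_AS undefined")
    # the diagonal matching (1 hom / 0.5 het) samples the individual's two
    # alleles with replacement, so its standardised value estimates the
    # self-coancestry (1+F)/2; the inbreeding coefficient is 2β_ii − 1
    beta_self = (np.diag(matrix.values) - mb) / (1.0 - mb)
    vals = 2.0 * beta_self - 1.0
    return pd.Series(vals, index=ids, name="f_as")


ORIGIN_ANCIENT = "ancient"
ORIGIN_RECENT = "recent/structured"
ORIGIN_ONLINE = "on-line"


def inbreeding_contrast(records: pd.DataFrame, delta: float = 0.01) -> pd.DataFrame:
    """Label each individual's inbreeding origin from F_HBD vs F_AS.

    "ancient" when F_HBD − F_AS > δ (autozygosity from old coalescence,
    the island signature), "recent/structured" when F_AS − F_HBD > δ
    (consanguineous mating or unaccounted structure), otherwise "on-line"
    (on the identity line).
    """
    records = records.copy()
    diff = records["f_hbd"] - records["f_as"]
    records["origin"] = np.select(
        [diff > delta, -diff > delta], [ORIGIN_ANCIENT, ORIGIN_RECENT], default=ORIGIN_ONLINE
    )
    return records


def inbreeding_table(
    panel: GenotypePanel,
    f_hbd_values: np.ndarray,
    segment_stats: list | None = None,
    relatedness_threshold: float = 0.05,
    delta: float = 0.01,
) -> pd.DataFrame:
    """Per-individual inbreeding record table.

    Combines F_HBD (from the HBD decoding, panel order), F_AS computed per
    population with an unrelated reference set (relatedness < threshold),
    and optional per-individual segment summaries (dicts with ``n_hbd`` and
    ``s_hbd``); adds origin labels.
    """
    ind = panel.individuals
    out = ind.copy()
    out["f_hbd"] = np.asarray(f_hbd_values, dtype=float)
    fas = np.full(len(ind), np.nan)
    for pop in pd.unique(ind["population"]):
        idx = panel.individuals_in(population=pop)
        if len(idx) < 2:
            continue
        mat = allele_sharing_matrix(panel, idx)
        ref = unrelated_set(mat, threshold=relatedness_threshold)
        if len(ref) < 2:
            ref = None
        vals = f_as(panel, pop, reference_ids=ref, matrix=mat)
        fas[idx] = vals.to_numpy()
    out["f_as"] = fas
    if segment_stats is not None:
        out["n_hbd"] = [s["n_hbd"] for s in segment_stats]
        out["s_hbd"] = [s["s_hbd"] for s in segment_stats]
    return inbreeding_contrast(out, delta=delta)
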