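"""Genotype panel container.

A :class:`GenotypePanel` holds an individuals × sites dosage matrix (counting
copies of the ALT allele: 0, 1, 2, with ``-1`` as the missing sentinel)
together with per-site metadata (scaffold, physical position, alleles,
genetic position in Morgans, functional category) and per-individual metadata
(id, population, group). Every downstream stage — QC, HBD decoding,
inbreeding coefficients, diversity, landscape and load statistics — consumes
this container.

Coordinates are 1-based inclusive on the VCF surface and 0-based half-open
internally (BED-style) wherever intervals are manipulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: Functional site categories (SnpEff-impact-like), plus "unclassified" for
#: sites absent from the category table.
CATEGORIES = ("intergenic", "neutral", "low", "moderate", "high")
UNCLASSIFIED = "unclassified"

SITE_COLUMNS = ("scaffold", "pos", "ref", "alt", "genetic_pos", "category")
INDIVIDUAL_COLUMNS = ("id", "population", "group")


class PanelError(ValueError):
    """Invalid panel construction or operation."""


@dataclass
class GenotypePanel:
    """Individuals × sites dosage matrix with metadata.

    Parameters
    ----------
    dosages
        ``(n_individuals, n_sites)`` integer array of ALT-allele dosages in
        ``{0, 1, 2}`` with ``-1`` marking missing genotypes.
    sites
        Per-site table with columns ``scaffold, pos, ref, alt, genetic_pos,
        category``. Positions must be strictly increasing within scaffold.
    individuals
        Per-individual table with columns ``id, population, group``.
    depths
        Optional per-genotype sequencing depth, same shape as ``dosages``.
    """

    dosages: np.ndarray
    sites: pd.DataFrame
    individuals: pd.DataFrame
    depths: np.ndarray | None = None
    dropped_records: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise PanelError("dosage matrix must be 2-D (individuals x sites)")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise PanelError("dosages must be 0/1/2 or the missing sentinel -1")
        n_ind, n_sites = self.dosages.shape
        if len(self.individuals) != n_ind:
            raise PanelError("individual table does not match dosage rows")
        if len(self.sites) != n_sites:
            raise PanelError("site table does not match dosage columns")
        for col in ("scaffold", "pos"):
            if col not in self.sites.columns:
                raise PanelError(f"site table lacks required column {col!r}")
        for col in ("genetic_pos", "category", "ref", "alt"):
            if col not in self.sites.columns:
                self.sites = self.sites.copy()
                if col == "genetic_pos":
                    self.sites[col] = np.nan
                elif col == "category":
                    self.sites[col] = UNCLASSIFIED
                else:
                    self.sites[col] = "A" if col == "ref" else "T"
        for col in INDIVIDUAL_COLUMNS:
            if col not in self.individuals.columns:
                raise PanelError(f"individual table lacks required column {col!r}")
        if self.depths is not None:
            self.depths = np.asarray(self.depths)
            if self.depths.shape != self.dosages.shape:
                raise PanelError("depth matrix shape mismatch")
        self._check_positions()
        self.sites = self.sites.reset_index(drop=True)
        self.individuals = self.individuals.reset_index(drop=True)

    def _check_positions(self) -> None:
        pos = self.sites["pos"].to_numpy()
        scaf = self.sites["scaffold"].to_numpy()
        for s in pd.unique(scaf):
            p = pos[scaf == s]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise PanelError(f"positions not strictly increasing on {s}")

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    @property
    def scaffolds(self) -> list:
        return list(pd.unique(self.sites["scaffold"]))

    def scaffold_mask(self, scaffold) -> np.ndarray:
        return (self.sites["scaffold"] == scaffold).to_numpy()

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    # ------------------------------------------------------------------
    def subset_sites(self, mask: np.ndarray) -> "GenotypePanel":
        """Return a panel restricted to sites where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return GenotypePanel(
            dosages=self.dosages[:, mask].copy(),
            sites=self.sites.loc[mask].reset_index(drop=True),
            individuals=self.individuals.copy(),
            depths=None if self.depths is None else self.depths[:, mask].copy(),
        )

    def subset_individuals(self, index: np.ndarray) -> "GenotypePanel":
        """Return a panel restricted to the individuals in ``index``.

        ``index`` may be a boolean mask or integer positions.
        """
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypePanel(
            dosages=self.dosages[index].copy(),
            sites=self.sites.copy(),
            individuals=self.individuals.iloc[index].reset_index(drop=True),
            depths=None if self.depths is None else self.depths[index].copy(),
        )

    def individuals_in(self, population=None, group=None) -> np.ndarray:
        """Integer indices of individuals in a population and/or group."""
        keep = np.ones(self.n_individuals, dtype=bool)
        if population is not None:
            keep &= (self.individuals["population"] == population).to_numpy()
        if group is not None:
            keep &= (self.individuals["group"] == group).to_numpy()
        return np.flatnonzero(keep)

    # ------------------------------------------------------------------
    def allele_counts(self, individual_index=None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site ALT-allele count and number of non-missing allele copies.

        Returns ``(d, m)`` where ``d`` is the ALT copy count and ``m`` the
        count of non-missing haploid genomes at each site.
        """
        dos = self.dosages if individual_index is None else self.dosages[individual_index]
        ok = dos != MISSING
        d = np.where(ok, dos, 0).sum(axis=0)
        m = 2 * ok.sum(axis=0)
        return d.astype(np.int64), m.astype(np.int64)

    def allele_frequencies(
        self, scope: str = "population", eps: float | None = None
    ) -> np.ndarray:
        """ALT-allele frequency per site for each individual's population.

        Returns an ``(n_individuals, n_sites)`` array: each row holds the
        frequency estimated in that individual's population (``scope=
        "population"``) or across the whole panel (``scope="global"``).
        Frequencies are clipped away from 0 and 1 (``eps`` defaults to
        ``1/(m+2)`` with ``m`` the allele-copy count) so that emission
        likelihoods stay finite at sites monomorphic in a population.
        """
        if scope not in ("population", "global"):
            raise PanelError("scope must be 'population' or 'global'")
        out = np.empty(self.dosages.shape, dtype=float)
        if scope == "global":
            d, m = self.allele_counts()
            f = _clipped_freq(d, m, eps)
            out[:] = f[None, :]
            return out
        pops = self.individuals["population"].to_numpy()
        for pop in pd.unique(pops):
            idx = np.flatnonzero(pops == pop)
            d, m = self.allele_counts(idx)
            out[idx] = _clipped_freq(d, m, eps)[None, :]
        return out


def _clipped_freq(d: np.ndarray, m: np.ndarray, eps: float | None) -> np.ndarray:
    m_safe = np.maximum(m, 1)
    f = d / m_safe
    if eps is None:
        e = 1.0 / (m_safe + 2)
    else:
        e = np.full_like(f, float(eps))
    return np.clip(f, e, 1.0 - e)
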