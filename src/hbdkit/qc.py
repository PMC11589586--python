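"""Genotype- and site-level quality control, and genetic-map interpolation.

The filters implement the common resequencing-panel rules: per-genotype
depth masking (GD < 5, or above the individual's mean depth plus three
standard deviations), site removal at minor allele count < 3 or missing
fraction > 0.10, and linear interpolation of genetic positions from a sparse
recombination map with a constant-rate fallback (2e-8 Morgans/bp) for
unmapped scaffolds. Boundary conventions are strict inequalities: a depth
exactly at mean+3·SD is retained, a missing fraction of exactly 0.10 is
retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel, PanelError

DEFAULT_RATE_PER_BP = 2e-8  # Morgans per bp for scaffolds absent from the map


@dataclass
class GeneticMap:
    """Sparse genetic map: per scaffold, sorted (bp, Morgans) anchor pairs."""

    anchors: dict  # scaffold -> (bp array, genetic position array in Morgans)
    default_rate: float = DEFAULT_RATE_PER_BP

    def __post_init__(self) -> None:
        for scaf, (bp, gen) in self.anchors.items():
            bp = np.asarray(bp, dtype=float)
            gen = np.asarray(gen, dtype=float)
            if len(bp) != len(gen) or len(bp) == 0:
                raise PanelError(f"malformed map anchors for {scaf}")
            if (np.diff(bp) <= 0).any():
                raise PanelError(f"map positions not sorted on {scaf}")
            if (np.diff(gen) < 0).any():
                raise PanelError(f"genetic positions decrease on {scaf}")
            self.anchors[scaf] = (bp, gen)

    @classmethod
    def from_table(cls, df: pd.DataFrame, default_rate: float = DEFAULT_RATE_PER_BP):
        """Build from a CHROM/POS/cM table (cM converted to Morgans)."""
        anchors = {}
        for scaf, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("pos")
            anchors[scaf] = (sub["pos"].to_numpy(float), sub["cm"].to_numpy(float) / 100.0)
        return cls(anchors=anchors, default_rate=default_rate)

    def interpolate(self, scaffold, positions: np.ndarray) -> np.ndarray:
        """Genetic positions (Morgans) for physical ``positions`` on a scaffold.

        Linear between anchors; beyond the outermost anchors the map is
        extended at ``default_rate``; scaffolds without anchors use
        ``default_rate`` from position 0.
        """
        positions = np.asarray(positions, dtype=float)
        if scaffold not in self.anchors:
            return positions * self.default_rate
        bp, gen = self.anchors[scaffold]
        out = np.interp(positions, bp, gen)
        left = positions < bp[0]
        right = positions > bp[-1]
        out[left] = gen[0] - (bp[0] - positions[left]) * self.default_rate
        out[right] = gen[-1] + (positions[right] - bp[-1]) * self.default_rate
        return out


@dataclass
class FilterReport:
    """Counts of data removed by each QC rule."""

    genotypes_masked_low_depth: int = 0
    genotypes_masked_high_depth: int = 0
    sites_removed_mac: int = 0
    sites_removed_missing: int = 0
    extras: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("genotypes_masked_low_depth", self.genotypes_masked_low_depth),
            ("genotypes_masked_high_depth", self.genotypes_masked_high_depth),
            ("sites_removed_mac", self.sites_removed_mac),
            ("sites_removed_missing", self.sites_removed_missing),
        ] + list(self.extras.items())
        return pd.DataFrame(rows, columns=["rule", "count"])


def mask_by_depth(
    panel: GenotypePanel,
    min_depth: int = 5,
    sd_multiplier: float = 3.0,
    report: FilterReport | None = None,
) -> GenotypePanel:
    """Mask genotypes with outlying depth.

    A genotype is set to missing when its depth is below ``min_depth`` or
    strictly above the individual's mean depth plus ``sd_multiplier`` times
    the individual's depth standard deviation (both computed over that
    individual's non-missing genotypes, before any masking).
    """
    if panel.depths is None:
        raise PanelError("panel has no per-genotype depths; cannot apply depth rule")
    dos = panel.dosages.copy()
    depths = panel.depths
    present = dos != MISSING
    dp = np.where(present, depths, np.nan).astype(float)
    mean = np.nanmean(dp, axis=1, keepdims=True)
    sd = np.nanstd(dp, axis=1, keepdims=True)
    low = present & (depths < min_depth)
    high = present & (depths > mean + sd_multiplier * sd)
    dos[low | high] = MISSING
    if report is not None:
        report.genotypes_masked_low_depth += int(low.sum())
        report.genotypes_masked_high_depth += int(high.sum())
    return GenotypePanel(
        dosages=dos,
        sites=panel.sites.copy(),
        individuals=panel.individuals.copy(),
        depths=panel.depths.copy(),
    )


def filter_sites(
    panel: GenotypePanel,
    min_mac: int = 3,
    max_missing: float = 0.10,
    report: FilterReport | None = None,
) -> GenotypePanel:
    """Remove sites with MAC < ``min_mac`` or missing fraction > ``max_missing``.

    The minor allele is defined within the panel at each site. Site order is
    preserved; the operation is idempotent.
    """
    d, m = panel.allele_counts()
    mac = np.minimum(d, m - d)
    missing_frac = (panel.dosages == MISSING).mean(axis=0)
    drop_mac = mac < min_mac
    drop_miss = missing_frac > max_missing
    if report is not None:
        report.sites_removed_mac += int(drop_mac.sum())
        report.sites_removed_missing += int((drop_miss & ~drop_mac).sum())
    return panel.subset_sites(~(drop_mac | drop_miss))


def interpolate_genetic_positions(panel: GenotypePanel, gmap: GeneticMap) -> GenotypePanel:
    """Assign each SNP a genetic position (Morgans) from the map.

    Linear interpolation between anchors; scaffolds absent from the map, and
    positions beyond the anchored range, use the map's constant default rate.
    Genetic positions are non-decreasing within scaffold afterwards.
    """
    gen = np.empty(panel.n_sites, dtype=float)
    scaf = panel.sites["scaffold"].to_numpy()
    pos = panel.sites["pos"].to_numpy()
    for s in pd.unique(scaf):
        mask = scaf == s
        gen[mask] = gmap.interpolate(s, pos[mask])
    panel.sites = panel.sites.copy()
    panel.sites["genetic_pos"] = gen
    return panel


def run_qc(
    panel: GenotypePanel,
    min_depth: int = 5,
    sd_multiplier: float = 3.0,
    min_mac: int = 3,
    max_missing: float = 0.10,
    gmap: GeneticMap | None = None,
) -> tuple[GenotypePanel, FilterReport]:
    """Depth masking, site filtering and map interpolation in one pass."""
    report = FilterReport()
    if panel.depths is not None:
        panel = mask_by_depth(panel, min_depth, sd_multiplier, report)
    panel = filter_sites(panel, min_mac, max_missing, report)
    if gmap is not None:
        panel = interpolate_genetic_positions(panel, gmap)
    return panel, report
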