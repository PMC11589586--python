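"""Reading and writing panels and their sidecar files.

VCF 4.2 is the genotype exchange format (GT plus per-genotype DP). Sample to
population/group assignment comes from a 3-column TSV sidecar. Genetic maps,
functional-category tables, truth tracts and gene intervals travel as plain
TSV/BED text.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .panel import MISSING, UNCLASSIFIED, GenotypePanel, PanelError

logger = logging.getLogger(__name__)

_SNP_ALLELES = frozenset("ACGT")


def read_population_table(path) -> pd.DataFrame:
    """Read a sample→population/group TSV (columns: sample, population, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "population", "group"}
    if not required <= set(df.columns):
        raise PanelError(f"population table must have columns {sorted(required)}")
    return df


def read_genotypes(vcf_path, population_table) -> GenotypePanel:
    """Read a multi-sample VCF into a :class:`GenotypePanel`.

    Only biallelic SNP records are retained (the count of dropped records is
    logged and stored on the panel); missing genotypes map to the sentinel.
    ``population_table`` is a path or DataFrame mapping every sample to a
    population and group.
    """
    from cyvcf2 import VCF

    if not isinstance(population_table, pd.DataFrame):
        population_table = read_population_table(population_table)
    pop_of = dict(zip(population_table["sample"], population_table["population"]))
    grp_of = dict(zip(population_table["sample"], population_table["group"]))

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in pop_of]
    if unknown:
        raise PanelError(f"samples missing from population table: {unknown}")

    dosage_cols, depth_cols, rows = [], [], []
    dropped = 0
    have_depth = True
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            dropped += 1
            continue
        gt = np.asarray(var.gt_types, dtype=np.int8)  # 0/1/2 dosage, 3=missing
        gt[gt == 3] = MISSING
        dosage_cols.append(gt)
        dp = var.format("DP")
        if dp is None:
            have_depth = False
        else:
            depth_cols.append(np.asarray(dp, dtype=np.int32).reshape(-1))
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
    vcf.close()
    if not rows:
        raise PanelError(f"no biallelic SNP records in {vcf_path}")
    if dropped:
        logger.info("read_genotypes: dropped %d non-biallelic-SNP records", dropped)

    sites = pd.DataFrame(rows, columns=["scaffold", "pos", "ref", "alt"])
    sites["genetic_pos"] = np.nan
    sites["category"] = UNCLASSIFIED
    individuals = pd.DataFrame(
        {
            "id": samples,
            "population": [pop_of[s] for s in samples],
            "group": [grp_of[s] for s in samples],
        }
    )
    panel = GenotypePanel(
        dosages=np.column_stack(dosage_cols),
        sites=sites,
        individuals=individuals,
        depths=np.column_stack(depth_cols) if have_depth and depth_cols else None,
    )
    panel.dropped_records = dropped
    return panel


def write_genotypes(panel: GenotypePanel, path) -> None:
    """Write a panel as an uncompressed VCF 4.2 file with GT (and DP)."""
    has_dp = panel.depths is not None
    fmt = "GT:DP" if has_dp else "GT"
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hbdkit\n")
        scaf_sizes = panel.sites.groupby("scaffold", sort=False)["pos"].max()
        for scaf, size in scaf_sizes.items():
            fh.write(f"##contig=<ID={scaf},length={int(size)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        header += list(panel.individuals["id"])
        fh.write("\t".join(header) + "\n")
        sites = panel.sites
        for j in range(panel.n_sites):
            fields = [
                str(sites.at[j, "scaffold"]),
                str(int(sites.at[j, "pos"])),
                ".",
                str(sites.at[j, "ref"]),
                str(sites.at[j, "alt"]),
                ".",
                ".",
                ".",
                fmt,
            ]
            col = panel.dosages[:, j]
            if has_dp:
                dpcol = panel.depths[:, j]
                fields += [f"{gt_str[int(g)]}:{int(dp)}" for g, dp in zip(col, dpcol)]
            else:
                fields += [gt_str[int(g)] for g in col]
            fh.write("\t".join(fields) + "\n")


def write_population_table(panel: GenotypePanel, path) -> None:
    df = panel.individuals.rename(columns={"id": "sample"})
    df.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# sidecar tables
# ----------------------------------------------------------------------

def read_genetic_map(path) -> pd.DataFrame:
    """Read a genetic map TSV with columns CHROM, POS, cM."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    if not {"chrom", "pos", "cm"} <= set(df.columns):
        raise PanelError("genetic map must have columns CHROM, POS, cM")
    return df


def write_genetic_map(panel: GenotypePanel, path) -> None:
    """Write the panel's genetic positions as a CHROM/POS/cM TSV."""
    df = pd.DataFrame(
        {
            "CHROM": panel.sites["scaffold"],
            "POS": panel.sites["pos"],
            "cM": panel.sites["genetic_pos"] * 100.0,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_categories(path) -> pd.DataFrame:
    """Read a per-site functional category TSV (CHROM, POS, CATEGORY)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    if not {"chrom", "pos", "category"} <= set(df.columns):
        raise PanelError("category table must have columns CHROM, POS, CATEGORY")
    return df


def assign_categories(panel: GenotypePanel, categories: pd.DataFrame) -> GenotypePanel:
    """Attach functional categories to panel sites (unmatched → unclassified)."""
    key = pd.MultiIndex.from_frame(categories[["chrom", "pos"]])
    lookup = pd.Series(categories["category"].to_numpy(), index=key)
    site_key = pd.MultiIndex.from_frame(panel.sites[["scaffold", "pos"]])
    panel.sites["category"] = (
        lookup.reindex(site_key).fillna(UNCLASSIFIED).to_numpy()
    )
    return panel


def write_categories(panel: GenotypePanel, path) -> None:
    df = pd.DataFrame(
        {
            "CHROM": panel.sites["scaffold"],
            "POS": panel.sites["pos"],
            "CATEGORY": panel.sites["category"],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_genes(path) -> pd.DataFrame:
    """Read gene intervals from BED (0-based half-open) or GFF3 (gene rows).

    Returns a DataFrame with columns scaffold, start, end (0-based half-open).
    """
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) >= 5 and f[2] == "gene":
                    rows.append((f[0], int(f[3]) - 1, int(f[4])))
        return pd.DataFrame(rows, columns=["scaffold", "start", "end"])
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["scaffold", "start", "end"]
    return df


def write_truth_bed(truth_tracts: pd.DataFrame, path) -> None:
    """Write planted tracts as BED (name = class rate)."""
    bed = truth_tracts[["scaffold", "start", "end", "class_rate"]].copy()
    bed.to_csv(path, sep="\t", index=False, header=False)
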