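"""End-to-end pipeline: simulate/ingest → QC → HBD → inbreeding →
diversity → landscape → load, driven by one YAML config with a global seed.

Every enabled stage writes its tables under ``<outdir>/<stage>/`` together
with a ``manifest.json`` recording the stage name, parameters, input file
hashes and the seed, so a rerun with the same config and seed reproduces
every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as div
from . import hbd as hbdmod
from . import inbreeding as inb
from . import io as hio
from . import landscape as lsc
from . import load as loadmod
from . import qc as qcmod
from .panel import GenotypePanel
from .simulate import SimConfig, generate_panel

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "qc", "hbd", "inbreeding", "diversity", "landscape", "load")


class PipelineError(ValueError):
    """Invalid pipeline configuration or missing stage dependency."""


@dataclass
class PipelineConfig:
    """Pipeline configuration: real inputs or a simulation block, stage
    toggles, per-stage parameter blocks, a global seed and an output dir."""

    outdir: Path
    seed: int = 0
    stages: tuple = ALL_STAGES
    inputs: dict = field(default_factory=dict)  # vcf, populations, map, categories, genes
    sim: dict | None = None
    params: dict = field(default_factory=dict)  # per-stage parameter blocks

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            outdir=Path(raw.get("outdir", "hbdkit_out")),
            seed=int(raw.get("seed", 0)),
            stages=tuple(raw.get("stages", ALL_STAGES)),
            inputs=raw.get("inputs", {}) or {},
            sim=raw.get("sim"),
            params=raw.get("params", {}) or {},
        )

    def validate(self) -> None:
        if self.sim is None and not self.inputs.get("vcf"):
            raise PipelineError("either a sim block or an input VCF is required")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(stage_dir: Path, stage: str, params: dict, seed: int, inputs: dict) -> None:
    manifest = {
        "stage": stage,
        "parameters": params,
        "seed": seed,
        "input_hashes": {k: _hash_file(v) for k, v in inputs.items() if Path(v).exists()},
    }
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the report
    bundle (stage -> primary in-memory result)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    stages = list(config.stages)
    seed = config.seed

    panel: GenotypePanel | None = None
    truth = None

    if "simulate" in stages:
        sdir = out / "simulate"
        sdir.mkdir(exist_ok=True)
        sim_kwargs = dict(config.sim or {})
        sim_kwargs.setdefault("seed", seed)
        sc = SimConfig(**sim_kwargs)
        panel, truth = generate_panel(sc)
        hio.write_genotypes(panel, sdir / "panel.vcf")
        hio.write_population_table(panel, sdir / "populations.tsv")
        hio.write_categories(panel, sdir / "categories.tsv")
        hio.write_genetic_map(panel, sdir / "genetic_map.tsv")
        truth.tracts.to_csv(sdir / "truth_tracts.tsv", sep="\t", index=False)
        truth.true_f.rename_axis("id").reset_index().to_csv(
            sdir / "truth_summary.tsv", sep="\t", index=False
        )
        _write_manifest(sdir, "simulate", sim_kwargs, seed, {})
        bundle["simulate"] = {"panel": panel, "truth": truth}
        logger.info("simulate: %d individuals x %d sites", panel.n_individuals, panel.n_sites)
    elif config.inputs.get("vcf"):
        panel = hio.read_genotypes(config.inputs["vcf"], config.inputs["populations"])
        if config.inputs.get("categories"):
            panel = hio.assign_categories(panel, hio.read_categories(config.inputs["categories"]))

    if panel is None:
        if set(stages) - {"simulate"}:
            raise PipelineError("downstream stages enabled but no panel available")
        return bundle

    if "qc" in stages:
        qdir = out / "qc"
        qdir.mkdir(exist_ok=True)
        p = config.params.get("qc", {})
        gmap = None
        if config.inputs.get("map"):
            gmap = qcmod.GeneticMap.from_table(
                hio.read_genetic_map(config.inputs["map"]),
                default_rate=p.get("default_rate", qcmod.DEFAULT_RATE_PER_BP),
            )
        panel, report = qcmod.run_qc(
            panel,
            min_depth=p.get("min_gd", 5),
            sd_multiplier=p.get("sd_mult", 3.0),
            min_mac=p.get("min_mac", 3),
            max_missing=p.get("max_missing", 0.10),
            gmap=gmap,
        )
        report.to_frame().to_csv(qdir / "filter_report.tsv", sep="\t", index=False)
        hio.write_genotypes(panel, qdir / "filtered.vcf")
        _write_manifest(qdir, "qc", p, seed, config.inputs)
        bundle["qc"] = {"panel": panel, "report": report}
        logger.info("qc: %d sites retained", panel.n_sites)

    decoding = None
    if "hbd" in stages:
        hdir = out / "hbd"
        hdir.mkdir(exist_ok=True)
        p = config.params.get("hbd", {})
        if np.isnan(panel.sites["genetic_pos"].to_numpy(dtype=float)).any():
            raise PipelineError("hbd stage requires genetic positions (qc stage with a map)")
        model = hbdmod.HbdModelSpec(
            rates=np.asarray(p.get("rates", hbdmod.DEFAULT_RATES), dtype=float),
            error=p.get("error", 0.001),
        )
        decoding = hbdmod.decode_panel(
            panel,
            model,
            freq_scope=p.get("freq_scope", "population"),
            fit=p.get("fit", True),
            max_iter=p.get("max_iter", 25),
        )
        T = p.get("T", hbdmod.DEFAULT_T)
        fvals = decoding.f_hbd_values(T=T)
        per_ind = panel.individuals.copy()
        per_ind["f_hbd"] = fvals
        per_ind["loglik"] = [d.loglik for d in decoding.decodings]
        per_ind.to_csv(hdir / "f_hbd.tsv", sep="\t", index=False)
        seg_all = []
        for ind_id, segs in zip(panel.individuals["id"], decoding.segments):
            if len(segs) == 0:
                continue
            s = segs.copy()
            s.insert(0, "id", ind_id)
            seg_all.append(s)
        seg_cols = ["id", "scaffold", "start", "end", "class_rate", "length"]
        seg_df = (
            pd.concat(seg_all, ignore_index=True) if seg_all else pd.DataFrame(columns=seg_cols)
        )
        seg_df.to_csv(hdir / "segments.tsv", sep="\t", index=False)
        _write_manifest(hdir, "hbd", p, seed, {})
        bundle["hbd"] = {"decoding": decoding, "f_hbd": fvals, "T": T}

    if "inbreeding" in stages:
        if decoding is None:
            raise PipelineError("inbreeding stage requires the hbd stage")
        idir = out / "inbreeding"
        idir.mkdir(exist_ok=True)
        p = config.params.get("inbreeding", {})
        T = bundle["hbd"]["T"]
        stats = [hbdmod.segment_summaries(s, T=T) for s in decoding.segments]
        table = inb.inbreeding_table(
            panel,
            bundle["hbd"]["f_hbd"],
            segment_stats=stats,
            relatedness_threshold=p.get("relatedness_threshold", 0.05),
            delta=p.get("delta", 0.01),
        )
        table.to_csv(idir / "inbreeding.tsv", sep="\t", index=False)
        _write_manifest(idir, "inbreeding", p, seed, {})
        bundle["inbreeding"] = {"table": table}

    unrelated_sets = {}
    for pop in pd.unique(panel.individuals["population"]):
        idx = panel.individuals_in(population=pop)
        if len(idx) < 2:
            unrelated_sets[pop] = list(panel.individuals["id"].to_numpy()[idx])
            continue
        mat = inb.allele_sharing_matrix(panel, idx)
        unrelated_sets[pop] = inb.unrelated_set(mat)

    if "diversity" in stages:
        ddir = out / "diversity"
        ddir.mkdir(exist_ok=True)
        p = config.params.get("diversity", {})
        table = div.diversity_table(
            panel,
            block_bp=p.get("block_bp", 1_000_000),
            reps=p.get("reps", 1000),
            seed=seed,
            mu=p.get("mu", div.DEFAULT_MU),
            unrelated_sets=unrelated_sets if p.get("unrelated_only", True) else None,
        )
        table.to_csv(ddir / "diversity.tsv", sep="\t", index=False)
        _write_manifest(ddir, "diversity", p, seed, {})
        bundle["diversity"] = {"table": table}

    if "landscape" in stages:
        if decoding is None:
            raise PipelineError("landscape stage requires the hbd stage")
        ldir = out / "landscape"
        ldir.mkdir(exist_ok=True)
        p = config.params.get("landscape", {})
        track = lsc.per_snp_hbd_probability(decoding.decodings)
        windows = lsc.window_average(
            panel.sites,
            track,
            width=p.get("width", lsc.DEFAULT_WIDTH),
            step=p.get("step", lsc.DEFAULT_STEP),
            min_scaffold_snps=p.get("min_scaffold_snps", lsc.DEFAULT_MIN_SCAFFOLD_SNPS),
        )
        windows = lsc.hbd_islands_deserts(windows, tail=p.get("tail", lsc.DEFAULT_TAIL))
        assoc = None
        if config.inputs.get("genes"):
            genes = hio.read_genes(config.inputs["genes"])
            assoc = lsc.gene_density_association(windows, genes, seed=seed)
            windows["gene_count"] = assoc["gene_counts"]
        windows.to_csv(ldir / "windows.tsv", sep="\t", index=False)
        _write_manifest(ldir, "landscape", p, seed, {})
        bundle["landscape"] = {"windows": windows, "association": assoc}

    if "load" in stages:
        ldir = out / "load"
        ldir.mkdir(exist_ok=True)
        p = config.params.get("load", {})
        calls = loadmod.call_minor_alleles(
            panel, unrelated_sets, reps=p.get("reps", 1000), seed=seed
        )
        counts = loadmod.individual_load_counts(panel, calls)
        counts.to_csv(ldir / "load_counts.tsv", sep="\t", index=False)
        groups = p.get("groups")
        if groups is None:
            uniq = list(pd.unique(panel.individuals["group"]))
            groups = uniq[:2] if len(uniq) >= 2 else None
        rxy_df = comparisons = None
        if groups:
            gx, gy = groups
            rxy_df = loadmod.rxy_table(
                panel,
                calls,
                gx,
                gy,
                block_bp=p.get("block_bp", loadmod.DEFAULT_BLOCK_BP),
                min_blocks=p.get("min_blocks", 10),
                l2_form=p.get("l2_form", "literal"),
            )
            rxy_df.to_csv(ldir / "rxy.tsv", sep="\t", index=False)
            rows = []
            for cat in ("neutral", "low", "moderate", "high"):
                sub = counts[counts["category"] == cat]
                a = sub.loc[sub["group"] == gx, "minor_copies"].to_numpy()
                b = sub.loc[sub["group"] == gy, "minor_copies"].to_numpy()
                if len(a) and len(b):
                    cmp = loadmod.group_compare(a, b)
                    cmp["category"] = cat
                    rows.append(cmp)
            comparisons = pd.DataFrame(rows)
            comparisons.to_csv(ldir / "group_comparisons.tsv", sep="\t", index=False)
        _write_manifest(ldir, "load", p, seed, {})
        bundle["load"] = {"calls": calls, "counts": counts, "rxy": rxy_df, "comparisons": comparisons}

    return bundle
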