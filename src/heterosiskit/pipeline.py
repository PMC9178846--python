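"""Pipeline orchestration: simulate or load → normalize/filter → DE →
inheritance classification → heterosis → co-expression, with a manifest
of every setting so each report is traceable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .de import deg_counts, run_cross_contrasts
from .eld import classify_table, encode_calls, overlap_sets, summarize_classes
from .expression import (
    compute_size_factors,
    compute_tpm,
    filter_expressed,
    sample_correlation_matrix,
)
from .network import CoexpressionNetwork
from .phenotype import heterosis_table
from .synthetic import (
    SimulationConfig,
    simulate_gene_lengths,
    simulate_phenotypes,
    simulate_triplet_counts,
)

logger = logging.getLogger(__name__)

_SIM_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)}


@dataclass
class PipelineConfig:
    """Inputs, thresholds and seed of one pipeline run.

    Either the four input paths or a ``simulation`` block must be present
    (simulation wins when both are given for counts).
    """

    counts: str | None = None
    sample_sheet: str | None = None
    gene_lengths: str | None = None
    phenotypes: str | None = None
    simulation: dict | None = None
    alpha: float = 0.05
    lfc_min: float = 1.0
    expressed_threshold: int = 30
    kme_min: float = 0.90
    kme_p_max: float = 1e-6
    min_module_size: int = 30
    soft_threshold: int | None = None
    merge_cor: float = 0.75
    cut_height_fraction: float = 0.99
    seed: int = 0
    outdir: str = "results"

    def validate(self) -> None:
        if self.simulation is None and self.counts is None:
            raise ValueError("config needs either input paths or a simulation block")
        if self.simulation is not None:
            unknown = set(self.simulation) - _SIM_KEYS
            if unknown:
                raise ValueError(f"unknown simulation keys: {sorted(unknown)}")


def parse_config(path) -> PipelineConfig:
    """Parse a YAML key-value config file; unknown keys are rejected."""
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ValueError(f"malformed config {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a key-value mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg


def serialize_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        sim = SimulationConfig(**{**config.simulation, "seed": config.simulation.get("seed", config.seed)})
        counts, sheet, truth = simulate_triplet_counts(sim)
        lengths = simulate_gene_lengths(list(counts.index), seed=sim.seed + 1)
        phenotypes = (
            io.read_phenotypes(config.phenotypes)
            if config.phenotypes
            else simulate_phenotypes(
                n_reps=3,
                female_mean=1.2,
                male_mean=0.8,
                mph_target=40.0,
                cv=0.05,
                seed=sim.seed + 2,
                cross=sim.cross,
            )
        )
        return counts, sheet, lengths, phenotypes, truth
    counts = io.read_counts(config.counts)
    sheet = io.read_sample_sheet(config.sample_sheet)
    lengths = (
        io.read_gene_lengths(config.gene_lengths)
        if config.gene_lengths
        else pd.Series(1000, index=counts.index, name="length")
    )
    phenotypes = io.read_phenotypes(config.phenotypes) if config.phenotypes else None
    return counts, sheet, lengths, phenotypes, None


def _sample_trait_vector(sheet: pd.DataFrame, phenotypes: pd.DataFrame) -> pd.Series | None:
    """Per-sample trait vector: each sample gets its genotype's mean value."""
    if phenotypes is None or phenotypes.empty:
        return None
    trait = phenotypes["trait"].iloc[0]
    sub = phenotypes[phenotypes["trait"] == trait]
    means = sub.groupby(["cross", "role"])["value"].mean()
    values = []
    for row in sheet.itertuples(index=False):
        values.append(means.get((row.cross, row.role), np.nan))
    out = pd.Series(values, index=sheet["sample_id"], name=trait)
    return None if out.isna().all() else out


def run_pipeline(config: PipelineConfig, outdir: str | None = None) -> dict:
    """Execute all stages in order and write the report bundle.

    Returns a dict with every table plus the manifest. All randomness
    flows from ``config.seed``. A stage failure writes a FAILED marker
    naming the stage and re-raises.
    """
    config.validate()
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    bundle: dict = {}
    try:
        counts, sheet, lengths, phenotypes, truth = _load_inputs(config)
        io.write_counts(counts, out / "counts.tsv")
        io.write_sample_sheet(sheet, out / "sample_sheet.tsv")
        io.write_gene_lengths(lengths, out / "gene_lengths.tsv")
        if truth is not None:
            io.write_table(truth, out / "truth.tsv")
        if phenotypes is not None:
            io.write_table(phenotypes, out / "phenotypes.tsv", index=False)

        stage = "normalization"
        size_factors = compute_size_factors(counts)
        io.write_table(size_factors.to_frame(), out / "size_factors.tsv")
        tpm = compute_tpm(counts, lengths)
        io.write_table(tpm.rename_axis("gene_id"), out / "tpm.tsv")
        expressed = filter_expressed(counts, sheet, config.expressed_threshold)
        corr = sample_correlation_matrix(tpm, expressed)
        io.write_table(corr, out / "sample_correlation.tsv")
        bundle["size_factors"] = size_factors
        bundle["tpm"] = tpm
        bundle["expressed"] = expressed
        bundle["sample_correlation"] = corr

        stage = "differential-expression"
        de_results: dict = {}
        de_summary: dict = {}
        for (cross, tp), _ in sheet.groupby(["cross", "timepoint"], sort=False):
            res = run_cross_contrasts(
                counts, sheet, cross, tp,
                alpha=config.alpha, lfc_min=config.lfc_min,
                expressed_threshold=config.expressed_threshold,
            )
            de_results[(cross, tp)] = res
            de_summary[f"{cross}_{tp}"] = deg_counts(res).to_dict("index")
            for label, table in res.items():
                io.write_table(table, out / f"de_{cross}_{tp}_{label}.tsv")
        with open(out / "de_summary.json", "w") as fh:
            json.dump(de_summary, fh, indent=2)
        bundle["de_results"] = de_results
        bundle["de_summary"] = de_summary

        stage = "classification"
        assignments = []
        class_summary = {}
        venn = {}
        for (cross, tp), res in de_results.items():
            calls = encode_calls(res["HvsF"], res["HvsM"], res["FvsM"])
            assigned = classify_table(calls)
            assigned.insert(0, "cross", cross)
            assigned.insert(1, "timepoint", tp)
            assignments.append(assigned)
            class_summary[f"{cross}_{tp}"] = summarize_classes(assigned)
            deg_sets = {
                label: set(t.index[t["call"] != "ns"]) for label, t in res.items()
            }
            venn[f"{cross}_{tp}"] = overlap_sets(deg_sets)
        assignments = pd.concat(assignments).rename_axis("gene_id")
        io.write_table(assignments, out / "eld_assignments.tsv")
        with open(out / "class_summary.json", "w") as fh:
            json.dump(class_summary, fh, indent=2)
        with open(out / "venn_regions.json", "w") as fh:
            json.dump(venn, fh, indent=2)
        bundle["assignments"] = assignments
        bundle["class_summary"] = class_summary
        bundle["venn"] = venn

        stage = "heterosis"
        if phenotypes is not None:
            het = heterosis_table(phenotypes)
            io.write_table(het, out / "heterosis.tsv", index=False)
            bundle["heterosis"] = het

        stage = "coexpression"
        deg_union = sorted(
            set().union(
                *(
                    set(t.index[t["call"] != "ns"])
                    for res in de_results.values()
                    for t in res.values()
                )
            )
        )
        if len(deg_union) >= max(20, config.min_module_size):
            expr = np.log2(tpm.loc[deg_union].T + 1.0)
            net = CoexpressionNetwork(
                beta=config.soft_threshold,
                min_module_size=config.min_module_size,
                cut_height_fraction=config.cut_height_fraction,
                merge_cor=config.merge_cor,
            ).fit(expr)
            io.write_table(net.labels_.rename_axis("gene_id").to_frame(), out / "modules.tsv")
            io.write_table(net.eigengenes_.rename_axis("sample_id"), out / "eigengenes.tsv")
            io.write_table(net.kme_, out / "kme.tsv")
            hubs = net.hub_genes(config.kme_min, config.kme_p_max)
            io.write_table(hubs, out / "hub_genes.tsv")
            bundle["network"] = net
            bundle["hub_genes"] = hubs
            trait = _sample_trait_vector(sheet, phenotypes)
            if trait is not None and trait.notna().all() and trait.std() > 0:
                mt = net.trait_correlation(trait.reindex(net.eigengenes_.index))
                io.write_table(mt, out / "module_trait.tsv")
                bundle["module_trait"] = mt
        else:
            logger.warning("coexpression skipped: only %d DEGs", len(deg_union))

        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "thresholds": {
                "alpha": config.alpha,
                "lfc_min": config.lfc_min,
                "expressed_threshold": config.expressed_threshold,
                "kme_min": config.kme_min,
                "kme_p_max": config.kme_p_max,
                "min_module_size": config.min_module_size,
            },
            "n_genes": int(counts.shape[0]),
            "n_samples": int(counts.shape[1]),
            "n_expressed": int(len(expressed)),
            "n_deg_union": len(deg_union),
            "coexpression_run": "network" in bundle,
            "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        bundle["manifest"] = manifest
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return bundle
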