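"""End-to-end orchestration: simulate → QC → DE → classify → sets →
heterosis → enrichment, with a machine-readable run report.

The report mirrors the bookkeeping a trio heterosis study tabulates:
DE counts per contrast, PAV/mode counts per trio x condition, all named
response-set sizes, reset/persistent fractions, the heterosis table, top
enrichment rows, and — because the input is simulated with known truth —
a truth-comparison block (per-class sensitivities, DE sensitivity and
empirical FDR, recovered reset fraction).  Every stage output is written
as TSV next to the JSON report, with a manifest of content hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, enrichment, inheritance, response_sets
from .data_io import TrioExpressionSet, write_counts, write_gene_sets, write_gmt
from .simulate import (PhenotypeSpec, SimConfig, SimTruth, TrioSpec, simulate,
                       simulate_annotation, simulate_phenotypes)
from .heterosis import heterosis_indices

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """One config drives the whole chain; all thresholds recorded."""

    sim: SimConfig = field(default_factory=SimConfig)
    tau: float = 1.0
    min_reps: int = 2
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    alpha_mode: str = "shared_mom"
    phenotypes: list | None = None  # list of PhenotypeSpec
    annotation_terms: int = 0
    annotation_enriched_fraction: float = 0.3

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        if "trios" in sim_raw:
            sim_raw["trios"] = tuple(TrioSpec(**t) for t in sim_raw["trios"])
        for key in ("conditions", "baseline_logmean_range"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        pheno_raw = raw.pop("phenotypes", None)
        phenotypes = None
        if pheno_raw:
            phenotypes = [PhenotypeSpec(**{**p, "means": {
                c: tuple(v) for c, v in p["means"].items()}})
                for p in pheno_raw]
        return cls(sim=SimConfig(**sim_raw), phenotypes=phenotypes, **raw)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["trios"] = [dataclasses.asdict(t) for t in self.sim.trios]
        if self.phenotypes:
            d["phenotypes"] = [dataclasses.asdict(p) for p in self.phenotypes]
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _de_phase(eset, trio, role, genotype, phase, alpha_mode, fc, fdr):
    num_cond, den_cond = (("WD", "WW") if phase == "drought" else ("RW", "WD"))
    contrast = diffexpr.Contrast(
        f"{genotype}_{num_cond}_vs_{genotype}_{den_cond}",
        (trio, role, num_cond), (trio, role, den_cond))
    res = diffexpr.nb_test(eset, contrast, alpha_mode=alpha_mode)
    return diffexpr.call_de(res, fc_threshold=fc, fdr_threshold=fdr)


def _truth_block(truth: SimTruth, calls: pd.DataFrame, de_by_cell: dict,
                 reset_table: pd.DataFrame | None) -> dict:
    """Score classification and DE calls against the generator's truth.

    Mode and PAV sensitivities are evaluated at the WW condition, where
    the baseline mode construction applies without the condition-response
    scaling."""
    block: dict = {"mode_sensitivity": {}, "pav_sensitivity": {},
                   "mode_confusion": {}}
    label_map = {"additive": "additive", "high_dom": "high_dominance",
                 "low_dom": "low_dominance", "overdominant": "overdominant",
                 "underdominant": "underdominant",
                 "pav_I": "I", "pav_II": "II", "pav_III": "III",
                 "pav_IV": "IV"}
    trios = [t.trio_id for t in truth.config.trios]
    ww = calls[calls["condition"] == "WW"]
    for truth_mode, called_label in label_map.items():
        hits, totals = 0, 0
        for trio_id in trios:
            modes = truth.modes(trio_id)
            genes = modes.index[modes == truth_mode]
            if len(genes) == 0:
                continue
            sub = ww[(ww["trio_id"] == trio_id)
                     & (ww["gene_id"].isin(genes))]
            col = "pav_type" if truth_mode.startswith("pav") else "mode"
            hits += int((sub[col] == called_label).sum())
            totals += len(genes)
        if totals == 0:
            continue
        key = ("pav_sensitivity" if truth_mode.startswith("pav")
               else "mode_sensitivity")
        block[key][truth_mode] = {"sensitivity": hits / totals, "n": totals}
    # confusion matrix for type-V modes, pooled over trios, at WW
    conf: dict = {}
    for trio_id in trios:
        modes = truth.modes(trio_id)
        sub = ww[ww["trio_id"] == trio_id].set_index("gene_id")
        for truth_mode in ("additive", "high_dom", "low_dom", "overdominant",
                           "underdominant"):
            genes = modes.index[modes == truth_mode]
            called = sub.loc[sub.index.intersection(genes), "mode"]
            for label, count in called.value_counts().items():
                conf.setdefault(truth_mode, {})
                conf[truth_mode][label] = conf[truth_mode].get(label, 0) \
                    + int(count)
    block["mode_confusion"] = conf

    # DE recovery for the hybrids' drought contrasts
    de_block = {}
    responders = {"up": set(truth.genes.loc[truth.genes["response"] == "up_WD",
                                            "gene_id"]),
                  "down": set(truth.genes.loc[
                      truth.genes["response"] == "down_WD", "gene_id"])}
    for (trio_id, phase), de in de_by_cell.items():
        if phase != "drought":
            continue
        # detectable = nonzero hybrid baseline mean
        mu_f1 = truth.mu[(trio_id, "hybrid", "WW")]
        detectable = set(mu_f1.index[mu_f1 > 0])
        calls_up = set(de.loc[de["call"] == "up", "gene_id"])
        calls_down = set(de.loc[de["call"] == "down", "gene_id"])
        true_up = responders["up"] & detectable
        true_down = responders["down"] & detectable
        tp = len(calls_up & true_up) + len(calls_down & true_down)
        called = len(calls_up) + len(calls_down)
        truth_n = len(true_up) + len(true_down)
        de_block[trio_id] = {
            "sensitivity": tp / truth_n if truth_n else float("nan"),
            "empirical_fdr": 1 - tp / called if called else float("nan"),
            "n_true": truth_n, "n_called": called,
        }
    block["de_drought_recovery"] = de_block

    if reset_table is not None:
        block["reset_fraction"] = {
            "up": float(reset_table.loc["reset_up_down", "fraction"]),
            "down": float(reset_table.loc["reset_down_up", "fraction"]),
            "generating_probability": truth.config.reset_probability,
        }
    return block


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full chain on a simulated experiment; returns the report.

    Deterministic given the config (all randomness flows from
    ``config.sim.seed``).  Writes all intermediate TSVs, the report JSON
    and a manifest of sha256 content hashes under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.echo()}

    # 1. simulate
    eset, truth = simulate(config.sim)
    write_counts(eset, outdir / "counts.tsv", outdir / "samples.tsv")
    truth.genes.to_csv(outdir / "truth.tsv", sep="\t", index=False)

    # 2. replicate QC: Pearson r within each design cell
    norm = diffexpr.normalized_counts(eset)
    corr = diffexpr.replicate_correlation(norm)
    within = []
    for trio_id in eset.sheet.trios():
        for role in ("hybrid", "parent1", "parent2"):
            for cond in eset.sheet.conditions():
                ids = eset.sheet.samples(trio_id, role, cond)
                for i in range(len(ids)):
                    for j in range(i + 1, len(ids)):
                        within.append(corr.loc[ids[i], ids[j]])
    report["replicate_correlation"] = {
        "min": float(np.min(within)), "median": float(np.median(within))}

    # 3. DE per genotype per phase
    phases = []
    conds = set(eset.sheet.conditions())
    if {"WW", "WD"} <= conds:
        phases.append("drought")
    if {"WD", "RW"} <= conds:
        phases.append("rewatering")
    de_by_cell: dict = {}  # hybrids, used for set building and truth scoring
    de_counts = {}
    de_frames = []
    for trio in config.sim.trios:
        for role, geno in (("hybrid", trio.hybrid), ("parent1", trio.parent1),
                           ("parent2", trio.parent2)):
            for phase in phases:
                de = _de_phase(eset, trio.trio_id, role, geno, phase,
                               config.alpha_mode, config.fc_threshold,
                               config.fdr_threshold)
                de_frames.append(de)
                de_counts[de["contrast"].iloc[0]] = {
                    "up": int((de["call"] == "up").sum()),
                    "down": int((de["call"] == "down").sum())}
                if role == "hybrid":
                    de_by_cell[(trio.trio_id, phase)] = de
    pd.concat(de_frames, ignore_index=True).to_csv(
        outdir / "de_results.tsv", sep="\t", index=False)
    report["de_counts"] = de_counts

    # 4. inheritance classification
    calls = inheritance.classify_all(
        eset, tau=config.tau, min_reps=config.min_reps,
        fc_threshold=config.fc_threshold, fdr_threshold=config.fdr_threshold,
        alpha_mode=config.alpha_mode)
    calls.to_csv(outdir / "inheritance_calls.tsv", sep="\t", index=False)
    summary = inheritance.summarize_calls(calls)
    summary.to_csv(outdir / "inheritance_summary.tsv", sep="\t", index=False)
    report["inheritance_counts"] = {
        f"{r.trio_id}_{r.condition}_{r.layer}_{r.label}": int(r.count)
        for r in summary.itertuples()}

    # 5. set algebra
    rs = response_sets.ResponseSets()
    hybrid_labels = {}
    for trio in config.sim.trios:
        hybrid_labels[trio.trio_id] = trio.hybrid
        for phase in phases:
            up, down = response_sets.response_genes(
                de_by_cell[(trio.trio_id, phase)], trio.hybrid, phase)
            rs.add(up)
            rs.add(down)
    reset_table = None
    if len(config.sim.trios) >= 2:
        t1, t2 = config.sim.trios[0], config.sim.trios[1]
        h1, h2 = t1.hybrid, t2.hybrid
        if "drought" in phases:
            rs.add(response_sets.conserved(
                rs[f"DRG_{h1}_up"], rs[f"DRG_{h2}_up"], "CDRG_up"))
            rs.add(response_sets.conserved(
                rs[f"DRG_{h1}_down"], rs[f"DRG_{h2}_down"], "CDRG_down"))
        if "rewatering" in phases:
            rs.add(response_sets.conserved(
                rs[f"RRG_{h1}_up"], rs[f"RRG_{h2}_up"], "CRRG_up"))
            rs.add(response_sets.conserved(
                rs[f"RRG_{h1}_down"], rs[f"RRG_{h2}_down"], "CRRG_down"))
        for cond, tag in (("WD", "WD"), ("RW", "RW")):
            if cond not in conds:
                continue
            for trio in (t1, t2):
                rs.add(response_sets.GeneSet(
                    f"overdominant_{trio.trio_id}_{tag}", "both",
                    inheritance.merged_overdominant(calls, trio.trio_id, cond),
                    ("leaf", f"inheritance:{trio.trio_id}:{cond}:merged_overdominant")))
                rs.add(response_sets.GeneSet(
                    f"underdominant_{trio.trio_id}_{tag}", "both",
                    inheritance.mode_gene_set(calls, trio.trio_id, cond,
                                              "underdominant"),
                    ("leaf", f"inheritance:{trio.trio_id}:{cond}:underdominant")))
            rs.derive(f"common_overdominant_{tag}", "intersection",
                      (f"overdominant_{t1.trio_id}_{tag}",
                       f"overdominant_{t2.trio_id}_{tag}"), "both")
            rs.derive(f"common_underdominant_{tag}", "intersection",
                      (f"underdominant_{t1.trio_id}_{tag}",
                       f"underdominant_{t2.trio_id}_{tag}"), "both")
        if "drought" in phases and "WD" in conds:
            response_sets.conserved_dominance_overlap(
                rs, "CDRG_up", "CDRG_down", "common_overdominant_WD",
                "common_underdominant_WD", "drought")
        if "rewatering" in phases and "RW" in conds:
            response_sets.conserved_dominance_overlap(
                rs, "CRRG_up", "CRRG_down", "common_overdominant_RW",
                "common_underdominant_RW", "rewatering")
        if "drought" in phases and "rewatering" in phases:
            reset_table = response_sets.reset_accounting(
                rs, "CDRG_up", "CDRG_down", "CRRG_up", "CRRG_down")
            reset_table.to_csv(outdir / "reset_accounting.tsv", sep="\t")
            report["reset_accounting"] = {
                name: {"count": int(row["count"]),
                       "fraction": float(row["fraction"])}
                for name, row in reset_table.iterrows()}
    rs.audit()
    write_gene_sets(rs, outdir / "gene_sets.tsv", outdir / "gene_sets.json")
    report["set_sizes"] = rs.summary()

    # 6. heterosis (optional)
    if config.phenotypes:
        pheno = simulate_phenotypes(config.phenotypes, config.sim.seed)
        pheno.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
        geno_to_trio = {t.hybrid: t for t in config.sim.trios}
        het_rows = []
        for spec in config.phenotypes:
            trio = geno_to_trio.get(spec.hybrid)
            trio_id = trio.trio_id if trio else spec.hybrid
            for cond in spec.means:
                res = heterosis_indices(pheno, spec.trait, trio_id,
                                        spec.hybrid, spec.parent1,
                                        spec.parent2, cond)
                het_rows.append(dataclasses.asdict(res))
        het = pd.DataFrame(het_rows)
        het.to_csv(outdir / "heterosis.tsv", sep="\t", index=False)
        report["heterosis"] = het_rows

    # 7. enrichment (optional): headline sets against detected-gene universe
    if config.annotation_terms:
        amap = simulate_annotation(truth, config.annotation_terms,
                                   config.annotation_enriched_fraction,
                                   config.sim.seed)
        write_gmt(amap, outdir / "annotation.gmt")
        detected = frozenset(
            calls.loc[calls["pav_type"] != "not_detected", "gene_id"])
        enr_summary = {}
        for set_name in ("DODG", "DUDG", "RODG", "RUDG"):
            if set_name not in rs:
                continue
            query = rs[set_name].genes & detected
            if not query:
                continue
            rows = enrichment.enrich(query, amap, detected)
            rows.to_csv(outdir / f"enrichment_{set_name}.tsv", sep="\t",
                        index=False)
            top = rows.head(5)
            enr_summary[set_name] = top[
                ["term_id", "term_name", "k", "K", "p_value", "fdr"]
            ].to_dict("records")
        report["enrichment_top"] = enr_summary

    # 8. truth comparison
    report["truth_comparison"] = _truth_block(truth, calls, de_by_cell,
                                              reset_table)

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
    manifest = {p.name: _sha256(p) for p in sorted(outdir.iterdir())
                if p.name != "manifest.json"}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return report
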