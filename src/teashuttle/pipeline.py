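"""End-to-end orchestration: simulate -> screen -> deg -> overlap -> hub
-> enrich -> electro -> assay, from one config, with a hashed manifest.

Every stage reads its inputs from and writes its outputs to the run
directory, so stages can be toggled independently across runs; a stage
whose inputs are missing raises a dependency error naming the stage that
should have produced them.  Re-running an identical configuration
reproduces byte-identical outputs (the manifest records a SHA-256 per
file).  All thresholds of the screening and network stages are surfaced
as named config fields with the study defaults (70% PPI confidence,
top-15 hubs, p < 0.05, FC beyond +-1.5, 10%/60%/90% target-probability
rules, bioavailability >= 0.55, HIA < 0.3, 2.00-fold ES amplification).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import assay as assay_mod
from . import deg as deg_mod
from . import electrochem, enrichment, io, network, screen, simulate
from .errors import StageDependencyError

ALL_STAGES = ("simulate", "screen", "deg", "overlap", "hub", "enrich",
              "electro", "assay")

DIRECTIONS = ("up", "down")


@dataclass
class PipelineConfig:
    """Single source of truth for a pipeline run."""

    seed: int = 0
    outdir: str = "teashuttle_run"
    stages: tuple[str, ...] = ALL_STAGES
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    # thresholds, study defaults
    score_cutoff: int = network.SCORE_CUTOFF
    min_degree_keep: int = network.MIN_DEGREE_KEEP
    top_k: int = network.TOP_K
    alpha: float = enrichment.ALPHA
    adj_p_cutoff: float = deg_mod.ADJ_P_CUTOFF
    fc_cutoff: float = deg_mod.FC_CUTOFF
    fc_scale: str = "linear"
    bioavailability_min: float = screen.BIOAVAILABILITY_MIN
    hia_max: float = screen.HIA_MAX
    es_amplification: float = electrochem.ES_AMPLIFICATION_THRESHOLD

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["sim"]["cv_scan_limits"] = list(self.sim.cv_scan_limits)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        sim_d = d.pop("sim", {})
        if "cv_scan_limits" in sim_d:
            sim_d["cv_scan_limits"] = tuple(sim_d["cv_scan_limits"])
        d["stages"] = tuple(d.get("stages", ALL_STAGES))
        return cls(sim=simulate.SimConfig(**sim_d), **d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _need(path: Path, producer: str) -> Path:
    if not path.exists():
        raise StageDependencyError(
            f"missing {path.name}; run the {producer!r} stage first")
    return path


def run(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order.

    Returns the manifest: per stage, the produced files with SHA-256
    content hashes.  The manifest is also written to ``manifest.json``
    in the run directory.
    """
    out = Path(config.outdir)
    inputs = out / "inputs"
    results = out / "results"
    inputs.mkdir(parents=True, exist_ok=True)
    results.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.sim, seed=config.seed)
    manifest: dict[str, dict[str, str]] = {}

    def record(stage: str, *paths: Path) -> None:
        manifest.setdefault(stage, {})
        for p in paths:
            manifest[stage][str(p.relative_to(out))] = _sha256(p)

    if "simulate" in config.stages:
        study, expr_truth = simulate.generate_expression(sim)
        io.write_expression(study, inputs / "expression.tsv",
                            inputs / "classes.csv")
        compounds, comp_truth = simulate.generate_compound_library(sim)
        compounds.to_csv(inputs / "compounds.csv", index=False)
        genes = list(study.matrix.index)
        preds = simulate.generate_target_predictions(
            sim, list(compounds["compound_id"]), genes)
        io.write_target_predictions(preds, inputs / "targets.csv")
        edges, ppi_truth = simulate.generate_ppi(sim, genes)
        io.write_edge_list(edges, inputs / "ppi_edges.tsv")
        db = enrichment.GeneSetDB(simulate.generate_annotation(sim, genes))
        io.write_gmt(db, inputs / "annotation.gmt")
        for assay_name in simulate.PLATE_ASSAYS:
            plate, _ = simulate.generate_plate(sim, assay_name)
            io.write_plate(plate, inputs / f"plate_{assay_name}.csv")
        series, mfc_truth = simulate.generate_mfc_series(sim)
        io.write_mfc(series, inputs / "mfc.csv", inputs / "mfc_meta.yaml")
        vgram = simulate.generate_voltammogram(sim, n_cycles=5, decay=0.95)
        io.write_voltammogram(vgram, inputs / "cv.csv")
        truth = {
            "spiked_genes": {s: {d: sorted(g) for d, g in dd.items()}
                             for s, dd in expr_truth.spiked_genes.items()},
            "es_positive_compound_ids":
                sorted(comp_truth.es_positive_compound_ids),
            "planted_clique_members":
                sorted(ppi_truth.planted_clique_members),
            "mfc_amplification": mfc_truth.mfc_amplification,
        }
        (inputs / "ground_truth.json").write_text(
            json.dumps(truth, indent=1, sort_keys=True))
        record("simulate", *sorted(inputs.iterdir()))

    if "screen" in config.stages:
        comp = pd.read_csv(_need(inputs / "compounds.csv", "simulate"))
        records = [screen.CompoundRecord(
            r.compound_id, r.smiles, gi_absorption=r.gi_absorption,
            bioavailability_score=r.bioavailability_score,
            hia_score=r.hia_score)
            for r in comp.itertuples(index=False)]
        table, attrition = screen.screen_library(
            records, bioavailability_min=config.bioavailability_min,
            hia_max=config.hia_max)
        table.to_csv(results / "screen.csv", index=False)
        attrition.to_csv(results / "screen_attrition.csv", index=False)
        record("screen", results / "screen.csv",
               results / "screen_attrition.csv")

    if "deg" in config.stages:
        study = io.read_expression(
            _need(inputs / "expression.tsv", "simulate"),
            _need(inputs / "classes.csv", "simulate"))
        study = deg_mod.normalize(study)
        present = set(study.sample_classes)
        for subtype in deg_mod.SUBTYPES:
            if subtype not in present:
                continue
            table = deg_mod.moderated_t(study, subtype)
            table = deg_mod.call_degs(table, config.adj_p_cutoff,
                                      config.fc_cutoff, config.fc_scale)
            table.to_csv(results / f"deg_{subtype}.csv", index=False)
            record("deg", results / f"deg_{subtype}.csv")

    if "overlap" in config.stages:
        preds = io.read_target_predictions(
            _need(inputs / "targets.csv", "simulate"))
        screened = pd.read_csv(_need(results / "screen.csv", "screen"))
        survivors = set(screened.loc[screened["survives"], "compound_id"])
        preds = preds[preds["compound_id"].isin(survivors)]
        _, pooled = deg_mod.qualify_targets(preds)
        for subtype in deg_mod.SUBTYPES:
            path = results / f"deg_{subtype}.csv"
            if not path.exists():
                continue
            calls = pd.read_csv(path)
            for direction in DIRECTIONS:
                genes = deg_mod.overlap(calls, pooled, direction)
                p = results / f"overlap_{subtype}_{direction}.txt"
                io.write_gene_list(genes, p)
                record("overlap", p)

    if "hub" in config.stages:
        edges = io.read_edge_list(_need(inputs / "ppi_edges.tsv",
                                        "simulate"))
        consensus_by_dir: dict[str, dict[str, list[str]]] = {
            d: {} for d in DIRECTIONS}
        for subtype in deg_mod.SUBTYPES:
            for direction in DIRECTIONS:
                p = results / f"overlap_{subtype}_{direction}.txt"
                if not p.exists():
                    continue
                genes = set(io.read_gene_list(p))
                sub = edges[edges["protein1"].isin(genes)
                            & edges["protein2"].isin(genes)]
                net = network.build_network(sub, config.score_cutoff,
                                            config.min_degree_keep)
                if net.number_of_nodes() == 0:
                    consensus = []
                else:
                    table = network.centrality_table(net)
                    table.to_csv(
                        results
                        / f"centrality_{subtype}_{direction}.csv")
                    record("hub", results
                           / f"centrality_{subtype}_{direction}.csv")
                    consensus = network.top_k_consensus(
                        table, config.top_k).consensus
                consensus_by_dir[direction][subtype] = consensus
                cp = results / f"hubs_{subtype}_{direction}.txt"
                io.write_gene_list(consensus, cp)
                record("hub", cp)
        for direction in DIRECTIONS:
            key = network.key_hub_intersection(consensus_by_dir[direction])
            kp = results / f"key_hubs_{direction}.txt"
            io.write_gene_list(key, kp)
            record("hub", kp)

    if "enrich" in config.stages:
        db = io.read_gmt(_need(inputs / "annotation.gmt", "simulate"))
        for subtype in deg_mod.SUBTYPES:
            for direction in DIRECTIONS:
                p = results / f"overlap_{subtype}_{direction}.txt"
                if not p.exists():
                    continue
                query = set(io.read_gene_list(p))
                rows = enrichment.enrich(query, db)
                top = enrichment.rank_terms(rows, config.alpha)
                ep = results / f"enrichment_{subtype}_{direction}.csv"
                top.to_csv(ep, index=False)
                record("enrich", ep)

    if "electro" in config.stages:
        series = io.read_mfc(_need(inputs / "mfc.csv", "simulate"),
                             _need(inputs / "mfc_meta.yaml", "simulate"))
        records = [electrochem.power_density(s) for s in series]
        records = electrochem.amplification(records)
        rows = [{"condition_id": r.condition_id, "pd_mean": r.pd_mean,
                 "pd_sd": r.pd_sd, "amplification": r.amplification,
                 "amplification_sd": r.amplification_sd,
                 "es_presence": electrochem.es_presence(
                     r, config.es_amplification)}
                for r in records]
        pd.DataFrame(rows).to_csv(results / "mfc_results.csv", index=False)
        vgram = io.read_voltammogram(_need(inputs / "cv.csv", "simulate"))
        prof = electrochem.area_profile(vgram)
        pd.DataFrame({"cycle": range(1, len(prof.areas) + 1),
                      "area_uA_V": prof.areas}).to_csv(
            results / "cv_areas.csv", index=False)
        record("electro", results / "mfc_results.csv",
               results / "cv_areas.csv")

    if "assay" in config.stages:
        rows = []
        for name in ("TPC", "TFC", "TCTC", "FRAP"):
            plate = io.read_plate(
                _need(inputs / f"plate_{name}.csv", "simulate"), name)
            curve = assay_mod.fit_calibration(plate)
            rows.append({"assay": name, "quantity": "slope",
                         "value": curve.slope})
            rows.append({"assay": name, "quantity": "intercept",
                         "value": curve.intercept})
            rows.append({"assay": name, "quantity": "r_squared",
                         "value": curve.r_squared})
            if name == "FRAP":
                eq = assay_mod.frap_equivalents(plate, curve)
                for sid, v in eq.items():
                    rows.append({"assay": name,
                                 "quantity": f"equivalents_{sid}",
                                 "value": v})
            else:
                for r in plate.by_role("sample").groupby(
                        "sample_id")["absorbance"].mean().items():
                    rows.append({"assay": name,
                                 "quantity": f"equivalents_{r[0]}",
                                 "value": assay_mod.to_equivalents(
                                     r[1], curve)})
        dpph = io.read_plate(_need(inputs / "plate_DPPH.csv", "simulate"),
                             "DPPH")
        res = assay_mod.dpph_analysis(dpph)
        rows.append({"assay": "DPPH", "quantity": "ic50",
                     "value": res.ic50.ic50})
        pd.DataFrame(rows).to_csv(results / "assay_results.csv",
                                  index=False)
        record("assay", results / "assay_results.csv")

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
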