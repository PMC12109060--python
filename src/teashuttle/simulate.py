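"""Synthetic data generators for every input class of the pipeline.

Each generator emulates one laboratory or web-service data source with a
known ground truth so downstream stages are testable end to end without
external downloads:

* expression matrices shaped like the GSE45827 breast-cancer design
  (29/30/30/41 tumor samples across four subtypes vs 11 normal), i.i.d.
  log2-normal per gene with a chosen number of genes spiked by a fixed
  log2 fold change in the tumor groups;
* compound libraries mixing unambiguous electron-shuttle-positive
  scaffolds (catechol-, hydroquinone- and pyrogallol-like) with negative
  scaffolds (meta-diols, mono-phenols, non-aromatics), plus plausible
  absorption predictor scores;
* target-prediction tables in the two predictor dialects;
* scale-free-ish PPI edge lists with one planted high-confidence clique;
* GO-style annotation term collections;
* plate-reader absorbance tables following linear calibration with
  Gaussian noise and two-fold standard dilution ladders;
* MFC voltage plateaus per dosing condition with known fold
  amplification, and multi-cycle voltammograms built from a Gaussian
  redox peak pair over a rectangular capacitive gap with optional
  per-cycle decay.

One global seed fans out to fixed per-generator child seeds, so adding a
generator never perturbs the output of another, and identical
configurations reproduce outputs bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assay import AbsorbancePlate, PLATE_COLUMNS
from .deg import ExpressionStudy
from .electrochem import (
    DEFAULT_ANODE_AREA_M2,
    DEFAULT_RESISTANCE_OHM,
    MFCSeries,
    Voltammogram,
)
from .errors import InvalidConfigError
from .reference import CALIBRATION_CURVES, GSE45827_GROUP_SIZES

# Fixed child-seed offsets, one per generator.
_SEED_OFFSETS = {
    "expression": 11, "compounds": 23, "targets": 29, "ppi": 37,
    "annotation": 41, "plate": 53, "mfc": 61, "cv": 71,
}

#: Electron-shuttle-positive scaffolds: every SMILES carries an aromatic
#: ortho- or para-dihydroxy pair (catechol, hydroquinone, pyrogallol
#: families and catechol-bearing flavonoids).
ES_POSITIVE_SMILES = (
    "Oc1ccccc1O",                        # catechol
    "Oc1ccc(O)cc1",                      # hydroquinone
    "Oc1cccc(O)c1O",                     # pyrogallol
    "Cc1ccc(O)c(O)c1",                   # 4-methylcatechol
    "Cc1cc(O)ccc1O",                     # methylhydroquinone
    "OC(=O)c1cc(O)c(O)c(O)c1",           # gallic acid
    "OC(=O)c1ccc(O)c(O)c1",              # protocatechuic acid
    "OC(=O)C=Cc1ccc(O)c(O)c1",           # caffeic acid
    "O=c1cc(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12",       # luteolin
    "O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12",    # quercetin
)

#: Negative scaffolds: meta-diols, single phenols, non-aromatics.
ES_NEGATIVE_SMILES = (
    "Oc1ccccc1",                         # phenol
    "Oc1cccc(O)c1",                      # resorcinol (meta)
    "Cc1cc(O)cc(O)c1",                   # orcinol (meta)
    "Cc1cccc(O)c1",                      # m-cresol
    "OC(=O)c1ccccc1",                    # benzoic acid
    "OC(=O)c1ccc(O)cc1",                 # 4-hydroxybenzoic acid
    "OC(=O)c1cc(O)cc(O)c1",              # 3,5-dihydroxybenzoic acid
    "COc1cc(C=O)ccc1O",                  # vanillin (OH + OMe)
    "OC1CCCCC1",                         # cyclohexanol
    "CC(C)CC(O)=O",                      # isovaleric acid
)

PLATE_ASSAYS = ("TPC", "TFC", "TCTC", "DPPH", "FRAP")

#: True calibration lines used by the plate generator (reported standard
#: curves for the content assays; a chosen Trolox line for FRAP).
TRUE_CALIBRATIONS = {
    **{a: (s, i) for a, (s, i, _, _) in CALIBRATION_CURVES.items()},
    "FRAP": (2.2, 0.05),
}

#: MFC dosing conditions and true fold amplification of the plateau power
#: density vs blank 1 (profile shaped like a water-extract dose ladder).
MFC_TRUE_AMPLIFICATION = {
    "blank1": 1.00, "250ppm": 1.65, "500ppm": 1.92, "750ppm": 2.04,
    "1000ppm": 2.16, "1500ppm": 2.24, "2000ppm": 2.47, "blank2": 1.22,
    "dopamine": 3.39,
}


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with GSE45827-shaped defaults."""

    seed: int = 0
    n_genes: int = 2000
    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(GSE45827_GROUP_SIZES))
    n_spiked: int = 100
    spike_log2fc: float = 2.0
    noise_sd: float = 0.3               # log2 units
    baseline_mean: float = 7.0          # log2 units
    baseline_mean_sd: float = 1.0
    n_compounds: int = 60
    frac_es_positive: float = 0.4
    ppi_nodes: int = 150
    ppi_edge_prob: float = 0.02
    planted_clique_size: int = 8
    plate_noise_sd: float = 0.0         # absorbance units
    dpph_true_ic50: float = 0.075       # mg/mL
    mfc_base_voltage: float = 0.05      # V
    mfc_voltage_noise_sd: float = 0.0   # V
    cv_peak_current: float = 150.0      # uA
    cv_capacitive_gap: float = 20.0     # uA
    cv_scan_limits: tuple[float, float] = (-1.5, 1.5)
    cv_step_v: float = 0.010            # V

    def validate(self) -> None:
        if self.n_spiked > self.n_genes:
            raise InvalidConfigError("n_spiked exceeds n_genes")
        for name in ("frac_es_positive", "ppi_edge_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name}={v} outside [0, 1]")
        if self.cv_scan_limits[0] >= self.cv_scan_limits[1]:
            raise InvalidConfigError("cv_scan_limits must be increasing")

    def rng(self, generator: str) -> np.random.Generator:
        return np.random.default_rng([_SEED_OFFSETS[generator],
                                      int(self.seed)])


@dataclass
class GroundTruth:
    """Everything the generators knew before noise was added."""

    spiked_genes: dict[str, dict[str, set[str]]] = field(
        default_factory=dict)          # subtype -> direction -> gene ids
    es_positive_compound_ids: set[str] = field(default_factory=set)
    planted_clique_members: set[str] = field(default_factory=set)
    calibration: dict[str, tuple[float, float]] = field(
        default_factory=dict)          # assay -> (slope, intercept)
    true_ic50: float | None = None
    sample_concentrations: dict[str, float] = field(default_factory=dict)
    mfc_amplification: dict[str, float] = field(default_factory=dict)


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i:05d}" for i in range(1, n + 1)]


def generate_expression(config: SimConfig
                        ) -> tuple[ExpressionStudy, GroundTruth]:
    """Log2-scale genes x samples matrix with spiked fold changes.

    Every gene draws a baseline mean once from N(baseline_mean,
    baseline_mean_sd^2); samples add i.i.d. N(0, noise_sd^2).  The first
    half of the spiked genes shift up and the second half down by
    spike_log2fc in every tumor group; normals stay at baseline.
    """
    config.validate()
    rng = config.rng("expression")
    genes = _gene_ids(config.n_genes)
    baselines = rng.normal(config.baseline_mean, config.baseline_mean_sd,
                           size=config.n_genes)
    spiked_idx = rng.choice(config.n_genes, size=config.n_spiked,
                            replace=False)
    n_up = config.n_spiked // 2 + config.n_spiked % 2
    up_idx = spiked_idx[:n_up]
    down_idx = spiked_idx[n_up:]
    shift = np.zeros(config.n_genes)
    shift[up_idx] = config.spike_log2fc
    shift[down_idx] = -config.spike_log2fc

    columns, classes, blocks = [], {}, []
    for cls, size in config.group_sizes.items():
        mean = baselines[:, None] + (shift[:, None] if cls != "normal"
                                     else 0.0)
        block = mean + rng.normal(0.0, config.noise_sd,
                                  size=(config.n_genes, size))
        names = [f"{cls}_{j:02d}" for j in range(1, size + 1)]
        columns.extend(names)
        classes.update({s: cls for s in names})
        blocks.append(block)
    matrix = pd.DataFrame(np.hstack(blocks), index=genes, columns=columns)
    study = ExpressionStudy(matrix, pd.Series(classes), already_logged=True)

    up = {genes[i] for i in up_idx}
    down = {genes[i] for i in down_idx}
    truth = GroundTruth(spiked_genes={
        cls: {"up": set(up), "down": set(down)}
        for cls in config.group_sizes if cls != "normal"})
    return study, truth


def generate_compound_library(config: SimConfig
                              ) -> tuple[pd.DataFrame, GroundTruth]:
    """Compound table with SMILES, absorption scores and known ES labels.

    Exactly round(n_compounds * frac_es_positive) compounds draw from the
    ES-positive scaffold pool; the rest from the negative pool.  Predictor
    scores are sampled so that all four screening rules see both passing
    and failing compounds.
    """
    config.validate()
    rng = config.rng("compounds")
    n_pos = int(round(config.n_compounds * config.frac_es_positive))
    smiles = [ES_POSITIVE_SMILES[rng.integers(len(ES_POSITIVE_SMILES))]
              for _ in range(n_pos)]
    smiles += [ES_NEGATIVE_SMILES[rng.integers(len(ES_NEGATIVE_SMILES))]
               for _ in range(config.n_compounds - n_pos)]
    ids = [f"C{i:04d}" for i in range(1, config.n_compounds + 1)]
    gi = rng.choice(["high", "low"], size=config.n_compounds,
                    p=[0.8, 0.2])
    bio = np.round(rng.uniform(0.30, 0.95, size=config.n_compounds), 2)
    hia = np.round(rng.uniform(0.0, 0.6, size=config.n_compounds), 3)
    table = pd.DataFrame({
        "compound_id": ids, "smiles": smiles, "gi_absorption": gi,
        "bioavailability_score": bio, "hia_score": hia,
    })
    truth = GroundTruth(
        es_positive_compound_ids=set(ids[:n_pos]))
    return table, truth


def generate_target_predictions(config: SimConfig, compound_ids: list[str],
                                genes: list[str]) -> pd.DataFrame:
    """Predictor-style target table mixing the two source dialects."""
    rng = config.rng("targets")
    rows = []
    for cid in compound_ids:
        n_hits = int(rng.integers(5, 15))
        hit_genes = rng.choice(genes, size=min(n_hits, len(genes)),
                               replace=False)
        for g in hit_genes:
            if rng.random() < 0.5:
                rows.append({"compound_id": cid, "gene": g,
                             "probability": float(rng.uniform(0.0, 1.0)),
                             "source": "swiss_like",
                             "model_accuracy": np.nan})
            else:
                rows.append({"compound_id": cid, "gene": g,
                             "probability": float(rng.uniform(0.0, 1.0)),
                             "source": "super_like",
                             "model_accuracy": float(
                                 rng.uniform(0.6, 1.0))})
    return pd.DataFrame(rows)


def generate_ppi(config: SimConfig, genes: list[str] | None = None
                 ) -> tuple[pd.DataFrame, GroundTruth]:
    """STRING-dialect edge list with one planted high-confidence clique.

    Background pairs appear with ppi_edge_prob and scores uniform on
    [0, 1000]; the planted clique's edges score on [800, 1000], above the
    70% confidence cutoff, so the clique always survives filtering.
    """
    config.validate()
    rng = config.rng("ppi")
    if genes is None:
        genes = _gene_ids(config.ppi_nodes)
    genes = list(genes)[:config.ppi_nodes]
    k = min(config.planted_clique_size, len(genes))
    clique = sorted(rng.choice(len(genes), size=k, replace=False))
    clique_names = {genes[i] for i in clique}
    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            in_clique = i in clique and j in clique
            if in_clique:
                score = float(rng.uniform(800.0, 1000.0))
            elif rng.random() < config.ppi_edge_prob:
                score = float(rng.uniform(0.0, 1000.0))
            else:
                continue
            rows.append({"protein1": genes[i], "protein2": genes[j],
                         "combined_score": round(score, 1)})
    edges = pd.DataFrame(rows,
                         columns=["protein1", "protein2", "combined_score"])
    return edges, GroundTruth(planted_clique_members=clique_names)


def generate_annotation(config: SimConfig, genes: list[str],
                        n_terms: int = 30,
                        term_size_range: tuple[int, int] = (5, 30)
                        ) -> dict[str, tuple[str, str, set[str]]]:
    """GO-style term collection over the supplied gene universe."""
    rng = config.rng("annotation")
    cats = ("BP", "CC", "MF")
    terms = {}
    for i in range(1, n_terms + 1):
        size = int(rng.integers(term_size_range[0],
                                term_size_range[1] + 1))
        members = set(rng.choice(genes, size=min(size, len(genes)),
                                 replace=False))
        terms[f"GO:{i:07d}"] = (f"synthetic term {i}",
                                cats[(i - 1) % 3], members)
    return terms


def _standard_ladder(top: float = 1.0, levels: int = 6) -> list[float]:
    """Two-fold serial dilution ladder starting at ``top`` mg/mL."""
    return [top / 2 ** k for k in range(levels)]


def generate_plate(config: SimConfig, assay: str,
                   sample_concentrations: dict[str, float] | None = None,
                   replicates: int = 3
                   ) -> tuple[AbsorbancePlate, GroundTruth]:
    """Plate-reader table for one assay with known calibration truth.

    Content assays (TPC/TFC/TCTC/FRAP) emit a six-level two-fold standard
    ladder following A = slope*c + intercept + N(0, plate_noise_sd) in
    triplicate, plus sample wells at the supplied true concentrations
    (standard-equivalent mg/mL) and, for FRAP, per-sample blanks.  DPPH
    plates emit control, blank and dosed sample wells with %RSA linear in
    concentration through the configured true IC50.
    """
    config.validate()
    if assay not in PLATE_ASSAYS:
        raise InvalidConfigError(f"unknown assay {assay!r}")
    rng = config.rng("plate")
    noise = lambda: float(rng.normal(0.0, config.plate_noise_sd)) \
        if config.plate_noise_sd > 0 else 0.0
    rows: list[dict] = []
    truth = GroundTruth()

    if assay == "DPPH":
        a_ctl, a_blk = 1.0, 0.05
        ic50 = config.dpph_true_ic50
        truth.true_ic50 = ic50
        for rep in range(1, replicates + 1):
            rows.append({"sample_id": "control", "role": "control",
                         "concentration": np.nan, "replicate": rep,
                         "absorbance": a_ctl + noise()})
            rows.append({"sample_id": "blank", "role": "blank",
                         "concentration": np.nan, "replicate": rep,
                         "absorbance": a_blk + noise()})
        for conc in _standard_ladder(0.125, 5):
            rsa = 50.0 * conc / ic50          # linear response, 50% at IC50
            a_spl = a_blk + (1.0 - rsa / 100.0) * (a_ctl - a_blk)
            for rep in range(1, replicates + 1):
                rows.append({"sample_id": "extract", "role": "sample",
                             "concentration": conc, "replicate": rep,
                             "absorbance": a_spl + noise()})
    else:
        slope, intercept = TRUE_CALIBRATIONS[assay]
        truth.calibration[assay] = (slope, intercept)
        for conc in _standard_ladder():
            for rep in range(1, replicates + 1):
                rows.append({"sample_id": "standard", "role": "standard",
                             "concentration": conc, "replicate": rep,
                             "absorbance": slope * conc + intercept
                             + noise()})
        samples = sample_concentrations or {"extract": 0.2}
        truth.sample_concentrations = dict(samples)
        for sid, conc in samples.items():
            for rep in range(1, replicates + 1):
                rows.append({"sample_id": sid, "role": "sample",
                             "concentration": np.nan, "replicate": rep,
                             "absorbance": slope * conc + intercept
                             + noise()})
            if assay == "FRAP":
                for rep in range(1, replicates + 1):
                    rows.append({"sample_id": sid, "role": "blank",
                                 "concentration": np.nan, "replicate": rep,
                                 "absorbance": intercept + noise()})
    plate = AbsorbancePlate(pd.DataFrame(rows, columns=PLATE_COLUMNS),
                            assay=assay)
    return plate, truth


def generate_mfc_series(config: SimConfig,
                        amplification: dict[str, float] | None = None,
                        duration_s: float = 1800.0, dt_s: float = 30.0
                        ) -> tuple[list[MFCSeries], GroundTruth]:
    """Voltage plateaus per dosing condition with known amplification.

    Power density scales with voltage squared, so a condition with true
    fold amplification a sits at plateau voltage V_blank * sqrt(a).
    """
    config.validate()
    rng = config.rng("mfc")
    amps = amplification or dict(MFC_TRUE_AMPLIFICATION)
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    series = []
    for cond, amp in amps.items():
        v = config.mfc_base_voltage * math.sqrt(amp) * np.ones_like(t)
        if config.mfc_voltage_noise_sd > 0:
            v = v + rng.normal(0.0, config.mfc_voltage_noise_sd,
                               size=t.shape)
        series.append(MFCSeries(cond, t, v,
                                DEFAULT_RESISTANCE_OHM,
                                DEFAULT_ANODE_AREA_M2))
    return series, GroundTruth(mfc_amplification=dict(amps))


def gaussian_pair_loop_area(peak: float, sigma: float, gap: float,
                            v_low: float, v_high: float,
                            mu_ox: float = 0.3, mu_red: float = 0.2
                            ) -> float:
    """Closed-form loop area of the generator's current model (uA*V).

    The forward-minus-reverse gap is the capacitive rectangle plus the
    two Gaussian peaks truncated to the scan window.
    """
    def _phi(x: float) -> float:
        return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))

    area = gap * (v_high - v_low)
    for mu in (mu_ox, mu_red):
        mass = _phi((v_high - mu) / sigma) - _phi((v_low - mu) / sigma)
        area += peak * sigma * math.sqrt(2.0 * math.pi) * mass
    return area


def generate_voltammogram(config: SimConfig, n_cycles: int = 10,
                          decay: float = 1.0, peak_sigma_v: float = 0.15,
                          current_noise_sd: float = 0.0) -> Voltammogram:
    """Multi-cycle CV trace from a reversible redox couple.

    Forward sweeps carry a Gaussian oxidation peak (center +0.3 V) above
    half the capacitive gap; reverse sweeps mirror it with a reduction
    peak at +0.2 V.  Peak and gap amplitudes shrink by ``decay`` each
    cycle, emulating serial-cycle attenuation; decay = 1 keeps all cycle
    areas identical.
    """
    config.validate()
    rng = config.rng("cv")
    v_low, v_high = config.cv_scan_limits
    n = int(round((v_high - v_low) / config.cv_step_v)) + 1
    grid = np.linspace(v_low, v_high, n)
    peak0, gap0 = config.cv_peak_current, config.cv_capacitive_gap
    cycles: dict[int, dict[str, np.ndarray]] = {}
    for c in range(1, n_cycles + 1):
        scale = decay ** (c - 1)
        peak, gap = peak0 * scale, gap0 * scale
        i_fwd = gap / 2.0 + peak * np.exp(
            -((grid - 0.3) ** 2) / (2.0 * peak_sigma_v ** 2))
        i_rev = -gap / 2.0 - peak * np.exp(
            -((grid - 0.2) ** 2) / (2.0 * peak_sigma_v ** 2))
        if current_noise_sd > 0:
            i_fwd = i_fwd + rng.normal(0, current_noise_sd, size=n)
            i_rev = i_rev + rng.normal(0, current_noise_sd, size=n)
        cycles[c] = {
            "forward": np.column_stack([grid, i_fwd]),
            "reverse": np.column_stack([grid[::-1], i_rev[::-1]]),
        }
    return Voltammogram(cycles, v_low, v_high)


def small_test_config(seed: int = 0, **overrides) -> SimConfig:
    """A fast, reduced-size configuration for tests and examples."""
    base = SimConfig(
        seed=seed, n_genes=200,
        group_sizes={"LaBC": 6, "LbBC": 6, "Her2BC": 6, "TNBC": 6,
                     "normal": 5},
        n_spiked=20, n_compounds=24, ppi_nodes=60,
        planted_clique_size=6)
    return replace(base, **overrides)
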