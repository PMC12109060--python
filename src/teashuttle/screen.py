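"""Drug-likeness and electron-shuttle structural screening of compounds.

The screen composes four rules, all strict inequalities as conventionally
stated except bioavailability:

* Lipinski: HBD < 5, HBA < 10, MW < 500 Da, logP < 5
* Veber: rotatable bonds < 10, TPSA < 140 A^2
* Absorption: high gastrointestinal absorption, bioavailability >= 0.55,
  human intestinal absorption score < 0.3 (scores are consumed from the
  input table, emulating ADMET web-predictor output; an RDKit-descriptor
  fallback exists but is not equivalent to those predictors)
* Electron shuttle (ES): the molecule carries an aromatic carbocyclic
  six-ring with hydroxyl substituents in ortho (1,2) or para (1,4)
  position -- the structural signature of a reversible redox mediator.
  Meta-diols, mono-phenols and non-aromatics do not qualify.

A compound survives iff all enabled rules pass; the screen also emits a
per-rule attrition table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .errors import IncompleteRecordError, SmilesParseError

ALL_RULES = ("lipinski", "veber", "absorption", "es")

LIPINSKI_LIMITS = {"hbd": 5, "hba": 10, "mw": 500.0, "logp": 5.0}
VEBER_LIMITS = {"rotb": 10, "tpsa": 140.0}
BIOAVAILABILITY_MIN = 0.55
HIA_MAX = 0.3

_ENEDIOL_SMARTS = Chem.MolFromSmarts("[OX2H][#6]=[#6][OX2H]")


@dataclass
class CompoundRecord:
    """One candidate molecule with descriptors, scores and verdicts."""

    compound_id: str
    smiles: str
    descriptors: dict[str, float] = field(default_factory=dict)
    gi_absorption: str | None = None          # "high" / "low"
    bioavailability_score: float | None = None
    hia_score: float | None = None
    flags: dict[str, bool] = field(default_factory=dict)
    es_motif: str | None = None


def parse_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


def compute_descriptors(smiles: str) -> dict[str, float]:
    """Physicochemical descriptors from the molecular graph via RDKit."""
    mol = parse_smiles(smiles)
    return {
        "mw": Descriptors.MolWt(mol),
        "hbd": Lipinski.NumHDonors(mol),
        "hba": Lipinski.NumHAcceptors(mol),
        "logp": Crippen.MolLogP(mol),
        "rotb": Lipinski.NumRotatableBonds(mol),
        "tpsa": rdMolDescriptors.CalcTPSA(mol),
    }


def _require(descriptors: dict[str, float], keys: tuple[str, ...]) -> None:
    missing = [k for k in keys if descriptors.get(k) is None]
    if missing:
        raise IncompleteRecordError(f"missing descriptors {missing}")


def lipinski(descriptors: dict[str, float]) -> bool:
    """Rule-of-five drug likeness (all strict)."""
    _require(descriptors, ("hbd", "hba", "mw", "logp"))
    return (descriptors["hbd"] < LIPINSKI_LIMITS["hbd"]
            and descriptors["hba"] < LIPINSKI_LIMITS["hba"]
            and descriptors["mw"] < LIPINSKI_LIMITS["mw"]
            and descriptors["logp"] < LIPINSKI_LIMITS["logp"])


def veber(descriptors: dict[str, float]) -> bool:
    """Oral bioavailability by rotatable-bond and polar-surface limits."""
    _require(descriptors, ("rotb", "tpsa"))
    return (descriptors["rotb"] < VEBER_LIMITS["rotb"]
            and descriptors["tpsa"] < VEBER_LIMITS["tpsa"])


def absorption_filter(record: CompoundRecord,
                      bioavailability_min: float = BIOAVAILABILITY_MIN,
                      hia_max: float = HIA_MAX) -> bool:
    """Absorption screen on externally supplied predictor scores."""
    if (record.gi_absorption is None or record.bioavailability_score is None
            or record.hia_score is None):
        raise IncompleteRecordError(
            f"{record.compound_id}: missing absorption scores")
    return (record.gi_absorption == "high"
            and record.bioavailability_score >= bioavailability_min
            and record.hia_score < hia_max)


def _hydroxyl_positions(mol: Chem.Mol, ring: tuple[int, ...]) -> list[int]:
    """Indices within ``ring`` whose atom bears a free -OH substituent."""
    positions = []
    for pos, idx in enumerate(ring):
        atom = mol.GetAtomWithIdx(idx)
        for nbr in atom.GetNeighbors():
            if (nbr.GetSymbol() == "O" and nbr.GetTotalNumHs() >= 1
                    and nbr.GetDegree() == 1):
                positions.append(pos)
                break
    return positions


def es_classify(smiles: str,
                allow_enediol: bool = False) -> tuple[bool, str | None]:
    """Electron-shuttle structural call with the motif that matched.

    Every aromatic carbocyclic six-ring is inspected independently (fused
    systems included).  The ring atoms are walked in ring order, so two
    hydroxyls one step apart are ortho and three steps apart are para,
    regardless of SMILES atom numbering or kekulization.  Pyrogallol-like
    1,2,3-triols match through their ortho pairs.  ``allow_enediol``
    additionally accepts non-aromatic enediol systems (e.g. ascorbic
    acid), an opt-in extension because such compounds lack the canonical
    aromatic motif.
    """
    mol = parse_smiles(smiles)
    for ring in mol.GetRingInfo().AtomRings():
        if len(ring) != 6:
            continue
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        if not all(a.GetIsAromatic() and a.GetSymbol() == "C"
                   for a in atoms):
            continue
        oh = _hydroxyl_positions(mol, ring)
        present = set(oh)
        for p in oh:
            if (p + 1) % 6 in present or (p - 1) % 6 in present:
                return True, "ortho"
        for p in oh:
            if (p + 3) % 6 in present:
                return True, "para"
    if allow_enediol and mol.HasSubstructMatch(_ENEDIOL_SMARTS):
        return True, "enediol"
    return False, None


def screen_library(records: list[CompoundRecord],
                   rules: tuple[str, ...] = ALL_RULES,
                   allow_enediol: bool = False,
                   bioavailability_min: float = BIOAVAILABILITY_MIN,
                   hia_max: float = HIA_MAX,
                   lipinski_limits: dict | None = None,
                   veber_limits: dict | None = None,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the enabled rules to a library.

    Returns the screened table (one row per compound with per-rule flags,
    the matched ES motif and the overall ``survives`` verdict) and an
    attrition summary counting, per rule, how many compounds fail it.
    Relaxing any threshold or disabling a rule can only enlarge the
    survivor set (the screen is a conjunction of monotone predicates).
    """
    lip = {**LIPINSKI_LIMITS, **(lipinski_limits or {})}
    veb = {**VEBER_LIMITS, **(veber_limits or {})}
    rows = []
    for rec in records:
        if not rec.descriptors:
            rec.descriptors = compute_descriptors(rec.smiles)
        d = rec.descriptors
        flags: dict[str, bool] = {}
        if "lipinski" in rules:
            flags["lipinski"] = (d["hbd"] < lip["hbd"] and d["hba"] < lip["hba"]
                                 and d["mw"] < lip["mw"]
                                 and d["logp"] < lip["logp"])
        if "veber" in rules:
            flags["veber"] = (d["rotb"] < veb["rotb"]
                              and d["tpsa"] < veb["tpsa"])
        if "absorption" in rules:
            flags["absorption"] = absorption_filter(
                rec, bioavailability_min, hia_max)
        motif = None
        if "es" in rules:
            es, motif = es_classify(rec.smiles, allow_enediol)
            flags["es"] = es
        rec.flags = flags
        rec.es_motif = motif
        rows.append({"compound_id": rec.compound_id, "smiles": rec.smiles,
                     **{k: d[k] for k in sorted(d)},
                     **{f"{r}_pass": flags.get(r) for r in rules},
                     "es_motif": motif,
                     "survives": all(flags.values())})
    table = pd.DataFrame(rows)
    attrition = pd.DataFrame({
        "rule": list(rules),
        "n_fail": [int((~table[f"{r}_pass"]).sum()) if len(table) else 0
                   for r in rules],
        "n_pass": [int(table[f"{r}_pass"].sum()) if len(table) else 0
                   for r in rules],
    })
    return table, attrition
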