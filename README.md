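# teashuttle

An offline, tested pipeline for analysing the bioactive compounds of
Oolong tea (*Camellia sinensis*): phytochemical and antioxidant assay
quantification, electrochemical profiling of electron-shuttle behaviour,
drug-likeness screening, and network pharmacology against breast-cancer
expression data.  It is aimed at researchers who want the computational
half of such a wet-lab + in-silico study to be reproducible from plain
text inputs, with every web-service step (ADMET predictors, target
prediction, STRING, DAVID) replaced by local computation on tables, and a
synthetic-data module that regenerates every input class with known
ground truth.

## What it computes

**Assays.** Total polyphenol / flavonoid / condensed-tannin contents via
OLS calibration lines (e.g. the gallic-acid curve `y = 3.8354x − 0.0132`,
`R² = 0.9998`) expressed as GAE/RE/CE equivalents; DPPH radical
scavenging `%RSA = 100·(A_ctl − A_spl)/(A_ctl − A_blk)` with IC50 from a
linear fit at 50%; FRAP Trolox equivalents with per-sample blanks.

**Electrochemistry.** Microbial-fuel-cell power density
`P = V·I/A_anode` with `I = V/R_ext`, blank-normalized fold
amplification (a fold > 2.00 flags electron-shuttle presence), and
cyclic-voltammetry closed-loop areas
`Area = ∫ (i_h − i_l) dV` over the scan window, with serial-cycle
attenuation profiling.

**Compound screening.** Lipinski (HBD < 5, HBA < 10, MW < 500, logP < 5),
Veber (RotB < 10, TPSA < 140 Å²), absorption scores (high GI,
bioavailability ≥ 0.55, HIA < 0.3), and a structural electron-shuttle
rule: an aromatic carbocyclic six-ring bearing *ortho*- or
*para*-dihydroxyl substituents (catechol / hydroquinone / pyrogallol
chemotypes), evaluated ring by ring on the RDKit molecular graph.

**Network pharmacology.** Moderated-t differential expression per tumor
subtype vs normal (empirical-Bayes variance shrinkage, BH-FDR,
calls at adj-p < 0.05 and signed fold change beyond ±1.5), target
qualification (≥ 10% probability in the Swiss-style dialect; ≥ 60% with
≥ 90% model accuracy in the SuperPred-style dialect), overlap sets, a
70%-confidence PPI network, and hub ranking by four centralities
implemented from scratch — degree, harmonic closeness,
MCC(v) = Σ_{maximal cliques C ∋ v} (|C|−1)! via Bron–Kerbosch with
pivoting, and MNC (largest neighbourhood component) — intersected over
top-15 lists and across subtypes.  GO over-representation uses the
upper-tail hypergeometric p with fold enrichment
`FE = (k/n)/(K/N)`.

## Worked example

Blank-normalized MFC amplification of the solvent-extracted water
fraction (OTL-W), from the packaged reference measurements:

```python
from teashuttle import electrochem, network, reference

table = reference.MFC_POWER_DENSITY["OTL-W"]
records = [electrochem.PDRecord(c, mean, sd)
           for c, (mean, sd) in table.items()]
for r in electrochem.amplification(records):
    flag = "ES" if electrochem.es_presence(r) else "--"
    print(f"{r.condition_id:>9}: {r.pd_mean:7.3f} mW/m2  "
          f"x{r.amplification:4.2f} +/- {r.amplification_sd:4.2f}  {flag}")

down = network.key_hub_intersection(
    {s: reference.HUB_GENES[s]["down"] for s in reference.SUBTYPES})
print("key down-regulated hubs:", ", ".join(down))
```

prints

```
   blank1:   9.882 mW/m2  x1.00 +/- 0.07  --
   250ppm:  16.349 mW/m2  x1.65 +/- 0.14  --
   500ppm:  18.946 mW/m2  x1.92 +/- 0.20  --
   750ppm:  20.129 mW/m2  x2.04 +/- 0.18  ES
  1000ppm:  21.369 mW/m2  x2.16 +/- 0.22  ES
  1500ppm:  22.166 mW/m2  x2.24 +/- 0.23  ES
  2000ppm:  24.374 mW/m2  x2.47 +/- 0.43  ES
   blank2:  12.070 mW/m2  x1.22 +/- 0.08  --
 dopamine:  33.531 mW/m2  x3.39 +/- 0.27  ES
key down-regulated hubs: HSP90AB1, MAPK1
```

Reading: power density rises monotonically with dosing, crossing the
2.00-fold electron-shuttle criterion at 750 ppm and peaking at 2.47-fold
at 2000 ppm (dopamine, the positive control, reaches 3.39-fold); and the
four subtypes' consensus hub lists reduce to *HSP90AB1* and *MAPK1* for
down-regulated genes.

The same operations are exposed on the command line
(`teashuttle simulate|screen|deg|hub|enrich|run`, plus `assay` and
`electro` groups); `teashuttle run config.yaml` executes the full
synthetic-study pipeline and writes a SHA-256 manifest of every artifact.

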