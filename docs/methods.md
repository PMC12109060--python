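# Methods

This note documents the models, defaults and numerical choices behind
`teashuttle`, and what the synthetic-data tests do and do not establish
about real data.

## Assay quantification

Calibration curves are ordinary least squares on replicate-averaged
(concentration, absorbance) pairs.  Replicates are averaged before the
regression — the standard plate-practice convention — so R² describes
level-to-level fit rather than well-to-well noise.  Requiring three
distinct standard levels makes the slope and the R² both identifiable;
a zero-variance design is rejected outright.

`%RSA` is computed exactly from the control/blank/sample absorbances and
is affine-invariant (adding a constant to all three readings cancels).
IC50 comes from a global linear fit of `%RSA` on **raw** concentration
(not log concentration — the choice is exposed to the caller by
restricting the point set), with the 50% crossing accepted within the
observed range extended by one two-fold dilution step; anything further
is flagged `extrapolated` rather than rejected, and a flat 50% response
returns the smallest observed concentration flagged `degenerate`.
Four-parameter logistic dose–response fitting is deliberately out of
scope: the linear estimator is the method being reproduced.

Equivalents are reported in mg of standard per g of lyophilized extract
only when the caller supplies the extract concentration of the assayed
solution; otherwise the raw mg/mL equivalent concentration is returned,
leaving mass bookkeeping (and any g/100 g conversion) to the caller.

## Electrochemistry

MFC power density is `V²/(R_ext·A_anode)` per time sample, averaged over
a plateau window (default: the whole series).  Defaults follow the
reference cell: `R_ext` = 1.0 kΩ, graphite anode contact area
1.649 cm².  Outputs are labelled **mW/m²**; at 0.05 V the formula gives
15.16 mW/m², matching the magnitude of the reference table, whose
printed unit (mV/m²) we take to be a typographical artifact and do not
reproduce.  Amplification is the ratio of plateau means against
**blank 1** (the pre-dosing blank; the blank-2 and dopamine folds in the
reference table are consistent with blank-1 normalization), with SD by
first-order Taylor propagation — the upstream aggregation method is not
otherwise specified.  The electron-shuttle call uses a strict
`fold > 2.00`.

CV loop areas interpolate both sweeps linearly onto a uniform 10 mV
voltage grid over their overlap before integrating `(i_h − i_l)` with
the trapezoid rule; this makes the integrand well defined when the two
sweeps sample different voltages, and sorting within a sweep makes the
result invariant to sample order.  The oxidation current is assigned to
the forward (increasing-V) sweep by convention, switchable via
`ih_direction`.  Scan rate is carried as metadata only.  Areas in µA·V
are reported interchangeably with µW (dimensionally identical); no
further conversion factor is applied.  The stabilization cycle is the
first cycle after which every successive relative area change is ≤ 2%
(tunable); attenuation is area(last)/area(first).

## Compound screening

Descriptor computation uses RDKit (MolWt, Lipinski H-bond donor/acceptor
counts, Crippen logP, rotatable bonds, TPSA).  All rule inequalities are
strict as conventionally stated, except bioavailability (≥ 0.55).  The
GI-absorption, bioavailability and HIA numbers are **inputs**, emulating
proprietary web-predictor output; the package does not re-implement
those models, and its descriptor fallback is labelled non-equivalent.

The electron-shuttle rule walks every aromatic carbocyclic six-ring in
ring order and looks for free hydroxyls one step apart (ortho) or three
steps apart (para).  Evaluating each ring of a fused system
independently means flavonoids with a catechol B-ring (luteolin,
quercetin) match while 5,7-dihydroxy A-rings (meta) alone do not.
Canonicalized graph matching makes the call invariant to SMILES atom
order and kekulization.  Enediol systems such as ascorbic acid do not
match the default rule — their aromatic-motif status is chemically
debatable — and are accepted only behind the opt-in `allow_enediol`
flag.  Because the screen is a conjunction of monotone predicates,
relaxing any threshold can only enlarge the survivor set; the tests
exercise this property directly.

## Differential expression

The contrast statistic is a moderated two-sample t: per-gene pooled
variances are shrunk toward a prior `s0²` with weight `d0` (prior
degrees of freedom), `s²_post = (d0·s0² + d·s²)/(d0 + d)`, and p-values
use Student's t with `d + d0` degrees of freedom.  The prior is fitted
across genes by the method of moments on log variances (digamma/
trigamma inversion); when the observed spread of log variances does not
exceed pure sampling noise the prior df is infinite and all genes share
`s0²`.  Setting the prior df to zero recovers the textbook pooled t
exactly, which the tests verify against SciPy.  This is a "limma-like"
scheme: the upstream precision-weight (voom-style) pipeline is *not*
re-implemented, since the object of interest here is the thresholding
pipeline around it.

Fold-change calls interpret the ±1.5 threshold on the **signed linear**
fold change `sign(log2FC)·2^|log2FC|` (a `fc_scale` switch applies it to
log2FC instead, since the convention is ambiguous in common reporting).
Benjamini–Hochberg adjustment uses the standard step-up
cumulative-minimum form (via statsmodels), and all thresholds are
strict.  Duplicate probes collapse to the probe with the smallest raw p
per gene before overlap — note this policy can hide the real
phenomenon of one gene appearing in both directions via different
probes.  Log-scale detection uses a max-value > 50 heuristic,
overridable; optional quantile normalization forces identical sorted
values across samples.

## Network hubs

Edges below combined score 700 (the 70% confidence convention on the
0–1000 STRING scale) are dropped, then nodes of degree ≤ 2 are removed
in a **single pass** — the pruning wording does not specify iteration,
so an iterated 3-core mode is available but not default.  Closeness is
the harmonic form (sum of reciprocal BFS distances), which stays well
defined on the disconnected graphs pruning can create; classic Freeman
closeness is available behind a flag.  MCC enumerates maximal cliques
with Bron–Kerbosch with pivoting, capped at 5000 nodes (clique
enumeration is exponential in the worst case).  Rank-k cuts are strict
with lexicographic tie-breaks, so rankings are deterministic; consensus
is the intersection over all **four** algorithms (one upstream
description says "three" after listing four; we do not guess which
three) and is invariant to algorithm order.

## Enrichment

Over-representation uses the exact upper-tail hypergeometric
probability; an optional EASE mode removes one overlap gene from the
tail, reproducing the more conservative modified-Fisher statistic of
the DAVID service.  No multiple-testing correction is applied by
default (matching the common `p < 0.05` reporting convention for GO
terms); BH is available behind a flag.  The universe defaults to all
genes in the annotation file and can be overridden with a platform gene
list; no claim is made that either equals any particular web service's
background.

## Synthetic data

The generators define the study conditions for all stochastic tests:

* **Expression** — per-gene baseline means drawn once from N(7, 1),
  i.i.d. Gaussian noise with sd 0.3 log2 units, group sizes defaulting
  to the 29/30/30/41-tumor vs 11-normal microarray design, 100 genes
  spiked by ±2.0 log2 units in all tumor groups (half up, half down).
  There is no probe-level structure, no correlation between genes, no
  batch effects and no mean–variance trend — so passing recovery tests
  shows the thresholding pipeline is correct, not that it is robust to
  microarray artifacts.
* **Compounds** — scaffolds chosen so motif labels are unambiguous by
  construction; classifier accuracy of 100% on them demonstrates rule
  fidelity, not performance on borderline chemistry (glycosylated or
  tautomeric hydroxyls).
* **PPI** — G(n, p) background (p = 0.02) with uniform scores plus one
  planted clique (default 8 nodes) scored 800–1000 so it survives
  filtering; planted-clique recovery by MCC is a sanity check of the
  ranking machinery, not a statement about STRING topology.
* **Plates** — exact linearity plus Gaussian well noise (default 0);
  the reported calibration slopes serve as the true generating lines.
  The DPPH response is linear through 50% at the configured IC50
  (default 0.075 mg/mL, within the reported extract range), with the
  sample ladder chosen (0.125 mg/mL, five two-fold steps) so %RSA stays
  in [0, 100].
* **MFC / CV** — plateau voltages set as `V_blank·√fold` with the
  reference water-extract fold profile as default truth; voltammograms
  are a rectangular capacitive gap (20 µA) plus Gaussian redox peaks
  (150 µA, σ = 0.15 V, centers +0.3/+0.2 V) on a 10 mV grid over
  −1.5…+1.5 V, with closed-form loop areas for oracle checks and a
  per-cycle decay factor for attenuation profiles.

One global seed fans out to fixed per-generator child seeds; every
generator is byte-for-byte reproducible, and the pipeline manifest
(SHA-256 per output file) makes whole-run idempotence testable.

## Problem sizes

The default test and acceptance runs use 2000 genes for the spiked
30-vs-11 contrast, 50 independent 200-gene null datasets for the
false-positive rate, 200 random ≤ 8-node graphs and 500 random
hypergeometric configurations for the oracle-agreement checks, and a
10⁶-point reference quadrature for CV areas — sizes chosen so the whole
suite completes in seconds while keeping binomial error bars tight
enough for the stated bounds.

## Known limitations

Counts that depend on proprietary predictor scores (e.g. how many of a
real compound library survive screening) are not reproducible from
structure alone; the package reproduces the **rule composition** and its
attrition bookkeeping.  Docking, molecular dynamics and their derived
observables are out of scope.  GO term identities on real data depend
on the annotation snapshot and background choice.  The moderated t here
is not limma and will differ slightly on real microarray data with a
mean–variance trend.
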