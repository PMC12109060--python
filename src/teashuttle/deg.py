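"""Differential expression calling and compound-target overlap.

Each tumor subtype is contrasted against normal tissue on log2 intensities
with a moderated two-sample t-statistic: per-gene pooled variances are
shrunk toward a common prior fitted across all genes by the method of
moments on log variances (an empirical-Bayes scheme in the limma spirit,
though not a reimplementation of limma's precision-weight pipeline), and
the residual degrees of freedom gain the prior degrees of freedom.
P-values are Benjamini-Hochberg adjusted per contrast.

A gene is called **up** when adj-p < 0.05 and signed linear fold change
FC > 1.5, **down** when adj-p < 0.05 and FC < -1.5 (both strict), where
FC = 2^log2FC carrying the sign of log2FC.  Qualified compound targets
(probability filters on two predictor dialects) are intersected with the
per-subtype calls to produce the overlap gene sets carried into network
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientReplicatesError

SUBTYPES = ("LaBC", "LbBC", "Her2BC", "TNBC")
NORMAL_CLASS = "normal"

ADJ_P_CUTOFF = 0.05
FC_CUTOFF = 1.5
SWISS_PROB_MIN = 0.10
SUPER_PROB_MIN = 0.60
SUPER_ACCURACY_MIN = 0.90

#: Values above this suggest the matrix is on the raw intensity scale.
LOG_DETECTION_MAX = 50.0


@dataclass
class ExpressionStudy:
    """Genes x samples intensity matrix with per-sample class labels."""

    matrix: pd.DataFrame                # genes x samples
    sample_classes: pd.Series           # sample -> subtype or "normal"
    already_logged: bool = True

    def __post_init__(self):
        missing = set(self.matrix.columns) - set(self.sample_classes.index)
        if missing:
            raise ValueError(f"samples without class labels: {missing}")

    def samples_of(self, cls: str) -> list[str]:
        labels = self.sample_classes
        return [s for s in self.matrix.columns if labels[s] == cls]


def normalize(study: ExpressionStudy, force_log: bool | None = None,
              quantile: bool = False) -> ExpressionStudy:
    """Log2-transform (auto-detected or forced) and optionally
    quantile-normalize columns so every sample shares one distribution."""
    mat = study.matrix
    needs_log = (force_log if force_log is not None
                 else not study.already_logged
                 and float(mat.to_numpy().max()) > LOG_DETECTION_MAX)
    if needs_log:
        mat = np.log2(mat.clip(lower=1.0))
    if quantile:
        vals = mat.to_numpy(float)
        ref = np.sort(vals, axis=0).mean(axis=1)
        ranks = vals.argsort(axis=0).argsort(axis=0)
        mat = pd.DataFrame(ref[ranks], index=mat.index, columns=mat.columns)
    return replace(study, matrix=mat, already_logged=True)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        step = (tri - y) / float(special.polygamma(2, x))
        x -= step
        if x <= 0:
            x = 1e-8
        if abs(step) < 1e-10 * x:
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-inverse-chi2 variance prior.

    Works on log variances: if s2 ~ s0^2 * F(df, d0), then
    log(s2) has mean log(s0^2) + [psi(df/2) - log(df/2)]
    - [psi(d0/2) - log(d0/2)] and excess variance trigamma(d0/2) beyond
    the trigamma(df/2) sampling term.  Returns (d0, s0^2); d0 = inf when
    the observed spread is no larger than sampling noise alone.
    """
    s2 = np.asarray(s2, float)
    ok = s2 > 0
    z = np.log(s2[ok])
    if z.size < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    ev = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    d0 = 2.0 * _trigamma_inverse(ev / 1.0) if ev > 0 else np.inf
    if np.isfinite(d0):
        log_s0 = float(e.mean()) + special.digamma(d0 / 2.0) \
            - np.log(d0 / 2.0)
    else:
        log_s0 = float(e.mean())
    return d0, float(np.exp(log_s0))


def moderated_t(study: ExpressionStudy, subtype: str,
                prior_df: float | None = None) -> pd.DataFrame:
    """Per-gene moderated t contrast of one tumor subtype vs normal.

    ``prior_df`` overrides the fitted prior degrees of freedom; 0 recovers
    the ordinary pooled-variance t-test exactly.  Returns a DataFrame with
    gene, log2fc, signed_fc, t_stat, p_value, adj_p and a ``call`` column
    initialized to ``ns``.
    """
    g1 = study.samples_of(subtype)
    g0 = study.samples_of(NORMAL_CLASS)
    n1, n0 = len(g1), len(g0)
    if n1 < 2 or n0 < 2:
        raise InsufficientReplicatesError(
            f"{subtype} vs {NORMAL_CLASS}: group sizes {n1}, {n0}")
    x1 = study.matrix[g1].to_numpy(float)
    x0 = study.matrix[g0].to_numpy(float)
    log2fc = x1.mean(axis=1) - x0.mean(axis=1)
    df = n1 + n0 - 2
    s2 = (x1.var(axis=1, ddof=1) * (n1 - 1)
          + x0.var(axis=1, ddof=1) * (n0 - 1)) / df
    if prior_df is None:
        d0, s0_sq = fit_variance_prior(s2, df)
    elif prior_df == 0:
        d0, s0_sq = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s0_sq = fit_variance_prior(s2, df)
    if np.isfinite(d0):
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = df + d0
    else:
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0),
                     np.where(log2fc == 0, 0.0,
                              np.sign(log2fc) * np.inf))
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)
    adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({
        "gene": study.matrix.index,
        "log2fc": log2fc,
        "signed_fc": signed_fold_change(log2fc),
        "t_stat": t,
        "p_value": p,
        "adj_p": adj,
        "call": "ns",
    }).reset_index(drop=True)


def signed_fold_change(log2fc: np.ndarray) -> np.ndarray:
    """Linear fold change carrying the direction sign: +2^|lfc| or
    -2^|lfc|."""
    log2fc = np.asarray(log2fc, float)
    return np.sign(log2fc) * 2.0 ** np.abs(log2fc) + (log2fc == 0) * 1.0


def call_degs(records: pd.DataFrame, adj_p_cutoff: float = ADJ_P_CUTOFF,
              fc_cutoff: float = FC_CUTOFF,
              fc_scale: str = "linear") -> pd.DataFrame:
    """Fill up/down/ns calls with strict thresholds on adj-p and FC.

    ``fc_scale`` selects whether the +-cutoff applies to the signed linear
    fold change (default) or directly to log2FC.
    """
    out = records.copy()
    fc = out["signed_fc"] if fc_scale == "linear" else out["log2fc"]
    sig = out["adj_p"] < adj_p_cutoff
    out["call"] = np.where(sig & (fc > fc_cutoff), "up",
                           np.where(sig & (fc < -fc_cutoff), "down", "ns"))
    return out


def collapse_probes(records: pd.DataFrame) -> pd.DataFrame:
    """Keep one row per gene: the probe with the smallest raw p-value."""
    idx = records.groupby("gene")["p_value"].idxmin()
    return records.loc[sorted(idx)].reset_index(drop=True)


def qualify_targets(predictions: pd.DataFrame
                    ) -> tuple[dict[str, set[str]], set[str]]:
    """Filter predicted targets by source-specific probability rules.

    Rows from the Swiss-style predictor need probability >= 0.10 ("at
    least 10%"); rows from the SuperPred-style predictor need probability
    >= 0.60 together with model accuracy >= 0.90.  Returns per-compound
    gene sets and their pooled union.
    """
    swiss = (predictions["source"] == "swiss_like") \
        & (predictions["probability"] >= SWISS_PROB_MIN)
    sup = (predictions["source"] == "super_like") \
        & (predictions["probability"] >= SUPER_PROB_MIN)
    if "model_accuracy" in predictions.columns:
        sup &= predictions["model_accuracy"].fillna(0.0) >= SUPER_ACCURACY_MIN
    kept = predictions[swiss | sup]
    per_compound = {str(cid): set(grp["gene"])
                    for cid, grp in kept.groupby("compound_id")}
    pooled = set(kept["gene"])
    return per_compound, pooled


def overlap(deg_calls: pd.DataFrame, qualified_targets: set[str],
            direction: str) -> list[str]:
    """Genes called in ``direction`` that are also qualified targets,
    sorted for deterministic output."""
    called = set(deg_calls.loc[deg_calls["call"] == direction, "gene"])
    return sorted(called & set(qualified_targets))
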