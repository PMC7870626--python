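"""Count-matrix differential expression for a targeted sequencing panel.

Implements the stated processing chain for per-condition DEG calling:
prefiltering (sample total >= 0.2 million reads, gene mean >= 1.5),
median-of-ratios size factors, a simplified negative-binomial Wald test per
treatment-vs-vehicle contrast with Benjamini-Hochberg FDR control, and the two
DEG decision rules (FDR-only; FDR plus a 1.5-fold / 0.59-log2 change cut).

The Wald test is a documented, transparent variant: no fold-change shrinkage,
no outlier or independent filtering.  Per-gene NB dispersions are estimated by
pooled within-group method of moments and moderated 50/50 (geometrically)
toward a log-linear mean-dispersion trend fitted across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    AllSamplesRemoved,
    InsufficientReplicates,
    NoReferenceGenes,
)

__all__ = [
    "CountMatrix",
    "SampleMeta",
    "DEGCall",
    "prefilter",
    "size_factors",
    "test_differential_expression",
    "benjamini_hochberg",
    "call_degs",
    "MIN_SAMPLE_TOTAL",
    "MIN_GENE_MEAN",
    "DEFAULT_LFC_CUT",
    "DEFAULT_ALPHA",
]

MIN_SAMPLE_TOTAL = 200_000  # reads; samples below are dropped
MIN_GENE_MEAN = 1.5  # mean raw count; genes below are dropped
DEFAULT_LFC_CUT = 0.59  # log2 of a 1.5-fold change
DEFAULT_ALPHA = 0.05

_DISPERSION_FLOOR = 1e-8
_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class CountMatrix:
    """Raw integer counts, genes x samples, with unique ids on both axes."""

    counts: pd.DataFrame

    def __post_init__(self):
        df = self.counts
        if df.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if df.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        vals = df.to_numpy()
        if (vals < 0).any():
            raise ValueError("negative counts")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")
        object.__setattr__(self, "counts", df.astype(np.int64))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample design table; vehicle controls carry concentration 0."""

    table: pd.DataFrame  # columns: sample_id, compound_id, concentration_M, replicate

    _REQUIRED = ("sample_id", "compound_id", "concentration_M", "replicate")

    def __post_init__(self):
        missing = [c for c in self._REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample metadata missing columns {missing}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in metadata")

    def control_samples(self) -> list[str]:
        t = self.table
        return list(t.loc[t["concentration_M"] == 0.0, "sample_id"])

    def treated_samples(self, compound_id: str, concentration: float) -> list[str]:
        t = self.table
        sel = (t["compound_id"] == compound_id) & np.isclose(
            t["concentration_M"], concentration
        )
        return list(t.loc[sel, "sample_id"])

    def subset(self, sample_ids) -> "SampleMeta":
        keep = self.table["sample_id"].isin(list(sample_ids))
        return SampleMeta(self.table.loc[keep].reset_index(drop=True))


def prefilter(counts: CountMatrix, meta: SampleMeta | None = None):
    """Drop low-coverage samples, then low-count genes.

    Samples with a raw column total below 0.2 million reads are removed first;
    genes whose mean raw count over the surviving samples is below 1.5 are
    removed second.  Returns the filtered matrix and a removal report.
    """
    df = counts.counts
    totals = df.sum(axis=0)
    bad_samples = list(totals.index[totals < MIN_SAMPLE_TOTAL])
    df = df.drop(columns=bad_samples)
    if df.shape[1] == 0:
        raise AllSamplesRemoved("every sample fell below the total-count threshold")
    gene_means = df.mean(axis=1)
    bad_genes = list(gene_means.index[gene_means < MIN_GENE_MEAN])
    df = df.drop(index=bad_genes)
    report = {
        "removed_samples": {
            s: f"total count {int(totals[s])} < {MIN_SAMPLE_TOTAL}" for s in bad_samples
        },
        "removed_genes": {
            g: f"mean count {gene_means[g]:.3g} < {MIN_GENE_MEAN}" for g in bad_genes
        },
    }
    filtered = CountMatrix(df)
    if meta is not None:
        return filtered, meta.subset(df.columns), report
    return filtered, report


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    Reference genes are those with strictly positive counts in every sample;
    each sample's factor is the median over reference genes of the ratio of its
    count to the gene's geometric mean across samples.
    """
    df = counts.counts
    positive = (df.to_numpy() > 0).all(axis=1)
    if not positive.any():
        raise NoReferenceGenes("every gene has a zero count in some sample")
    ref = df.loc[positive].to_numpy(dtype=float)
    log_geomean = np.log(ref).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(ref) - log_geomean)
    return pd.Series(np.median(ratios, axis=0), index=df.columns, name="size_factor")


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pooled_dispersion(norm_t: np.ndarray, norm_c: np.ndarray):
    """Per-gene NB dispersion by pooled within-group method of moments.

    Returns the *unfloored* estimate (var - mean) / mean**2, which may be
    negative for genes whose sample variance falls below the Poisson level,
    together with the pooled mean.  The sign information is kept because the
    mean-dispersion trend is fitted to bin averages, where negative estimates
    legitimately cancel the positive sampling noise.
    """
    n_t, n_c = norm_t.shape[1], norm_c.shape[1]
    ss = ((norm_t - norm_t.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss += ((norm_c - norm_c.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    var = ss / max(n_t + n_c - 2, 1)
    mean = (norm_t.sum(axis=1) + norm_c.sum(axis=1)) / (n_t + n_c)
    mean = np.maximum(mean, _PSEUDOCOUNT)
    return (var - mean) / mean**2, mean


def _fit_trend(alpha_unfloored: np.ndarray, mean: np.ndarray, n_bins: int = 20):
    """Log-linear mean-dispersion trend fitted to bin-averaged raw estimates.

    Averaging the raw (signed) method-of-moments estimates within quantile
    bins of log mean before taking logs avoids the strong downward bias a
    direct log-scale regression suffers from at few replicates.
    """
    log_m = np.log(mean)
    qs = np.quantile(log_m, np.linspace(0.0, 1.0, n_bins + 1))
    qs[-1] += 1e-9
    idx = np.clip(np.searchsorted(qs, log_m, side="right") - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() < 5:
            continue
        xs.append(log_m[sel].mean())
        ys.append(np.log(max(alpha_unfloored[sel].mean(), _DISPERSION_FLOOR)))
    if len(xs) < 2:
        level = max(float(np.mean(alpha_unfloored)), _DISPERSION_FLOOR)
        return np.full_like(log_m, level)
    slope, intercept = np.polyfit(xs, ys, 1)
    return np.exp(intercept + slope * log_m)


def _moderate_dispersion(alpha_unfloored: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Blend floored raw dispersions 50/50 with the fitted trend."""
    trend = _fit_trend(alpha_unfloored, mean)
    alpha = 0.5 * np.maximum(alpha_unfloored, _DISPERSION_FLOOR) + 0.5 * trend
    return np.maximum(alpha, _DISPERSION_FLOOR)


def test_differential_expression(
    counts: CountMatrix,
    meta: SampleMeta,
    condition: tuple[str, float],
) -> pd.DataFrame:
    """NB Wald test of one (compound, concentration) condition vs vehicle.

    Returns a per-gene table with columns ``log2fc``, ``p``, ``padj``,
    ``mean_control``, ``mean_treated`` and ``dispersion``.  Group means are
    size-factor normalized with a 0.5 pseudocount; the Wald statistic is
    z = (ln mu_t - ln mu_c) / sqrt(v_t + v_c) with v = (1/n)(1/mu + alpha),
    compared against a standard normal; BH adjustment spans all genes of the
    contrast.
    """
    compound_id, concentration = condition
    treated = meta.treated_samples(compound_id, concentration)
    control = meta.control_samples()
    if len(treated) < 2 or len(control) < 2:
        raise InsufficientReplicates(
            f"{compound_id} @ {concentration:g} M: {len(treated)} treated / "
            f"{len(control)} control samples (need >= 2 each)"
        )
    sf = size_factors(counts)
    norm = counts.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    cols = {s: i for i, s in enumerate(counts.sample_ids)}
    norm_t = norm[:, [cols[s] for s in treated]]
    norm_c = norm[:, [cols[s] for s in control]]

    mu_t = norm_t.mean(axis=1) + _PSEUDOCOUNT
    mu_c = norm_c.mean(axis=1) + _PSEUDOCOUNT
    alpha_raw, pooled_mean = _pooled_dispersion(norm_t, norm_c)
    alpha = _moderate_dispersion(alpha_raw, pooled_mean)

    v = (1.0 / norm_t.shape[1]) * (1.0 / mu_t + alpha) + (1.0 / norm_c.shape[1]) * (
        1.0 / mu_c + alpha
    )
    delta = np.log(mu_t) - np.log(mu_c)
    z = delta / np.sqrt(v)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "log2fc": delta / np.log(2.0),
            "p": p,
            "padj": benjamini_hochberg(p),
            "mean_control": mu_c,
            "mean_treated": mu_t,
            "dispersion": alpha,
        },
        index=counts.counts.index,
    )


@dataclass(frozen=True)
class DEGCall:
    """Differentially expressed gene set for one condition."""

    genes: tuple[str, ...]
    n_up: int
    n_down: int
    rule: str
    lfc_cut: float
    alpha: float

    @property
    def n_deg(self) -> int:
        return self.n_up + self.n_down


def call_degs(
    table: pd.DataFrame,
    lfc_cut: float = DEFAULT_LFC_CUT,
    alpha: float = DEFAULT_ALPHA,
    rule: str = "fdr_and_fc",
) -> DEGCall:
    """Apply a DEG decision rule to a differential-expression table.

    ``fdr_and_fc`` (default, used for concentration-response analysis): a gene
    is differentially expressed iff |log2fc| > lfc_cut and padj < alpha.
    ``fdr_only``: padj <= alpha with no fold-change requirement.
    """
    if rule == "fdr_and_fc":
        sel = (table["log2fc"].abs() > lfc_cut) & (table["padj"] < alpha)
    elif rule == "fdr_only":
        sel = table["padj"] <= alpha
    else:
        raise ValueError(f"unknown DEG rule {rule!r}")
    hits = table.loc[sel]
    return DEGCall(
        genes=tuple(hits.index),
        n_up=int((hits["log2fc"] > 0).sum()),
        n_down=int((hits["log2fc"] <= 0).sum()),
        rule=rule,
        lfc_cut=lfc_cut,
        alpha=alpha,
    )
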