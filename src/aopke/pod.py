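"""Transcriptomic point-of-departure statistics built on DEG counts.

Two complementary summaries of a compound's concentration-dependent
transcriptome response are provided:

* the normalized DEG response (per-condition DEG count expressed as a
  percentage of a positive-control DEG count, capped at 100%), an increasing
  curve whose 10% crossing is EC10(DEG);
* the degree of gene-expression homeostasis, DGH = 100 - n_deg floored at 0,
  a decreasing curve fed to the benchmark-concentration machinery to obtain
  BMC10(DGH).

The module also builds the two-concentration overlap gene signature, the
FDR-masked cross-compound regulation matrix, and a PCA overview of the most
variable genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import deg as _deg
from .dose_response import (
    BMCResult,
    DoseResponseDataset,
    ECEstimate,
    benchmark_concentration,
    effective_concentration,
    fit_hill,
)
from .errors import FlatCurve

__all__ = [
    "DEGResponsePoint",
    "SignatureSet",
    "RegulationMatrix",
    "deg_response",
    "dgh",
    "ec10_deg",
    "bmc10_dgh",
    "build_signature",
    "regulation_matrix",
    "pca_overview",
]


def deg_response(n_deg: int, positive_control_count: int) -> float:
    """DEG count as % of the positive-control count, capped at 100%."""
    if positive_control_count < 1:
        raise ValueError("positive-control DEG count must be >= 1")
    if n_deg < 0:
        raise ValueError("DEG count cannot be negative")
    return min(n_deg / positive_control_count, 1.0) * 100.0


def dgh(n_deg: int) -> float:
    """Degree of gene-expression homeostasis: 100 - n_deg, floored at 0."""
    if n_deg < 0:
        raise ValueError("DEG count cannot be negative")
    return max(0.0, 100.0 - n_deg)


@dataclass(frozen=True)
class DEGResponsePoint:
    """One concentration's DEG count with its derived response statistics."""

    concentration: float
    n_deg: int
    normalized_response: float
    dgh: float

    @classmethod
    def from_counts(
        cls, concentration: float, n_deg: int, positive_control_count: int
    ) -> "DEGResponsePoint":
        return cls(
            concentration=float(concentration),
            n_deg=int(n_deg),
            normalized_response=deg_response(n_deg, positive_control_count),
            dgh=dgh(n_deg),
        )


def _points_dataset(points, responses, compound_id, endpoint) -> DoseResponseDataset:
    pts = tuple(
        (p.concentration, (float(r),)) for p, r in zip(points, responses)
    )
    return DoseResponseDataset(compound_id, endpoint, "transcriptome", pts)


def ec10_deg(
    points: list[DEGResponsePoint], x: float = 10.0, compound_id: str = ""
) -> ECEstimate:
    """EC of an x% normalized DEG response (default 10%).

    The increasing Hill form (bottom 0, top 100) is fitted to the normalized
    responses by fitting the fixed-asymptote decreasing model to
    ``100 - response``; the x% crossing is solved analytically.  Raises
    :class:`FlatCurve` when the maximum response stays below x%.
    """
    responses = [p.normalized_response for p in points]
    if max(responses) < x:
        raise FlatCurve(
            f"maximum normalized DEG response {max(responses):.3g}% < {x:g}%"
        )
    ds = _points_dataset(points, [100.0 - r for r in responses], compound_id, "DEG")
    fit = fit_hill(ds, flat_effect_threshold=x)
    if fit.flat:
        raise FlatCurve("DEG response never reaches the requested level")
    return effective_concentration(fit, x)


def bmc10_dgh(
    points: list[DEGResponsePoint],
    n_bootstrap: int = 1000,
    seed: int = 0,
    benchmark_response: float = 10.0,
    compound_id: str = "",
) -> BMCResult:
    """Benchmark concentration of the DGH series (decreasing from 100)."""
    ds = _points_dataset(points, [p.dgh for p in points], compound_id, "DGH")
    return benchmark_concentration(
        ds,
        benchmark_response=benchmark_response,
        n_bootstrap=n_bootstrap,
        seed=seed,
        flat_effect_threshold=benchmark_response,
    )


@dataclass(frozen=True)
class SignatureSet:
    """Overlap of the DEG sets at an anchor concentration and a lower one.

    Genes regulated at both the anchor (e.g. the EC10 of viability) and a
    several-fold lower, definitely non-cytotoxic concentration are taken as a
    compound-characteristic signature free of cell-death confounders.
    """

    gene_ids: frozenset
    anchor_concentration: float
    low_concentration: float
    source_compound: str

    @property
    def empty(self) -> bool:
        return len(self.gene_ids) == 0


def build_signature(
    deg_anchor,
    deg_low,
    anchor_concentration: float,
    source_compound: str = "",
    dilution: float = 4.0,
) -> SignatureSet:
    """Intersect the anchor-concentration DEG set with the diluted one."""
    if dilution <= 1:
        raise ValueError("dilution factor must exceed 1")
    return SignatureSet(
        gene_ids=frozenset(deg_anchor) & frozenset(deg_low),
        anchor_concentration=float(anchor_concentration),
        low_concentration=float(anchor_concentration) / dilution,
        source_compound=source_compound,
    )


@dataclass(frozen=True)
class RegulationMatrix:
    """Signature-gene log2 fold changes across conditions with an FDR mask.

    ``values`` holds log2fc (NaN where masked or absent); ``state`` records per
    cell whether the value is shown, masked (padj above the mask threshold) or
    absent from the condition's table.
    """

    values: pd.DataFrame
    state: pd.DataFrame
    mask_alpha: float


def regulation_matrix(
    signature: SignatureSet,
    tables: dict[str, pd.DataFrame],
    mask_alpha: float = 0.1,
) -> RegulationMatrix:
    """Assemble the masked regulation matrix of signature genes x conditions."""
    genes = sorted(signature.gene_ids)
    values = pd.DataFrame(np.nan, index=genes, columns=list(tables))
    state = pd.DataFrame("absent", index=genes, columns=list(tables))
    for cond, table in tables.items():
        for g in genes:
            if g not in table.index:
                continue
            padj = table.at[g, "padj"]
            if padj > mask_alpha:
                state.at[g, cond] = "masked"
            else:
                state.at[g, cond] = "shown"
                values.at[g, cond] = table.at[g, "log2fc"]
    return RegulationMatrix(values=values, state=state, mask_alpha=mask_alpha)


def pca_overview(
    counts: _deg.CountMatrix,
    meta: _deg.SampleMeta | None = None,
    n_top: int = 100,
):
    """Per-sample coordinates on the two leading principal components.

    Genes are ranked by variance of log2(normalized count + 1) across samples;
    the ``n_top`` most variable genes are centered per gene and decomposed.
    Returns a coordinates DataFrame (sample_id, pc1, pc2) and the explained
    variance fractions of the two components.
    """
    if len(counts.gene_ids) < n_top:
        raise ValueError(
            f"need >= {n_top} genes for the PCA overview, got {len(counts.gene_ids)}"
        )
    sf = _deg.size_factors(counts)
    log_norm = np.log2(counts.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :] + 1.0)
    variances = log_norm.var(axis=1, ddof=1)
    top = np.argsort(variances)[::-1][:n_top]
    x = log_norm[top]
    x = x - x.mean(axis=1, keepdims=True)
    pca = PCA(n_components=2)
    coords = pca.fit_transform(x.T)
    out = pd.DataFrame(
        {"sample_id": counts.sample_ids, "pc1": coords[:, 0], "pc2": coords[:, 1]}
    )
    if meta is not None:
        out = out.merge(meta.table, on="sample_id", how="left")
    return out, tuple(float(f) for f in pca.explained_variance_ratio_)
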