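#!/usr/bin/env python
"""Differential expression and transcriptomic points of departure.

Reads the count matrix from 01_simulate_panel.py, runs the prefilter /
median-of-ratios / NB-Wald chain per concentration, converts DEG counts into
the normalized response (positive control = 325 DEGs = 100%) and the DGH
series, and derives EC10(DEG) and BMC10(DGH).  Also builds the
anchor-vs-4x-lower overlap signature, the FDR-masked regulation matrix and the
PCA overview.  Writes deg_summary.csv, pod.csv, signature.json,
regulation_matrix.csv (+ mask), pca.csv under results/.
"""

import json
from pathlib import Path

import pandas as pd

from aopke import (
    DEGResponsePoint,
    bmc10_dgh,
    build_signature,
    call_degs,
    ec10_deg,
    pca_overview,
    prefilter,
    regulation_matrix,
)
from aopke.deg import test_differential_expression
from aopke.errors import AopkeError
from aopke.io import read_counts_tsv, read_sample_meta, write_json

SEED = 1
NPOS = 325  # positive-control DEG count the responses are normalized to
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    counts = read_counts_tsv(ROOT / "data" / "counts.tsv")
    meta = read_sample_meta(ROOT / "data" / "samples.tsv")
    counts, meta, report = prefilter(counts, meta)
    write_json(report, ROOT / "prefilter_report.json")

    compound = meta.table.loc[meta.table["concentration_M"] > 0, "compound_id"].iloc[0]
    concs = sorted(set(meta.table.loc[meta.table["concentration_M"] > 0,
                                      "concentration_M"]))
    tables, points, summary = {}, [], []
    for c in concs:
        table = test_differential_expression(counts, meta, (compound, c))
        call = call_degs(table)
        tables[c] = table
        points.append(DEGResponsePoint.from_counts(c, call.n_deg, NPOS))
        summary.append({"compound_id": compound, "concentration_M": c,
                        "n_up": call.n_up, "n_down": call.n_down,
                        "n_deg": call.n_deg,
                        "response_pct": points[-1].normalized_response,
                        "dgh": points[-1].dgh})
        print(f"c = {c:.3e} M: {call.n_deg:4d} DEGs "
              f"({points[-1].normalized_response:5.1f}% of positive control, "
              f"DGH {points[-1].dgh:5.1f})")
    pd.DataFrame(summary).to_csv(ROOT / "deg_summary.csv", index=False)

    row = {"compound_id": compound, "npos": NPOS}
    try:
        est = ec10_deg(points, compound_id=compound)
        row["ec10_deg_M"] = est.concentration
        print(f"EC10(DEG) = {est.concentration:.3e} M"
              + (" (extrapolated)" if est.extrapolated else ""))
    except AopkeError as exc:
        row["ec10_deg_flag"] = str(exc)
        print(f"EC10(DEG): {exc}")
    try:
        bmc = bmc10_dgh(points, n_bootstrap=300, seed=SEED, compound_id=compound)
        row.update(bmc10_dgh_M=bmc.bmc, ci_lower=bmc.ci_lower, ci_upper=bmc.ci_upper)
        print(f"BMC10(DGH) = {bmc.bmc:.3e} M "
              f"[{bmc.ci_lower:.3e}, {bmc.ci_upper:.3e}]")
    except AopkeError as exc:
        row["bmc10_flag"] = str(exc)
        print(f"BMC10(DGH): {exc}")
    pd.DataFrame([row]).to_csv(ROOT / "pod.csv", index=False)

    # overlap signature: DEGs shared by the top concentration and its 4x dilution
    anchor_c, low_c = concs[-1], concs[-2]
    sig = build_signature(
        call_degs(tables[anchor_c]).genes, call_degs(tables[low_c]).genes,
        anchor_c, source_compound=compound, dilution=anchor_c / low_c,
    )
    write_json({"source_compound": compound,
                "anchor_concentration_M": sig.anchor_concentration,
                "low_concentration_M": sig.low_concentration,
                "genes": sorted(sig.gene_ids)}, ROOT / "signature.json")
    print(f"overlap signature: {len(sig.gene_ids)} genes shared by "
          f"{anchor_c:.2e} M and {low_c:.2e} M")

    reg = regulation_matrix(sig, {f"{compound}@{c:.3e}": t for c, t in tables.items()},
                            mask_alpha=0.1)
    reg.values.to_csv(ROOT / "regulation_matrix.csv", index_label="gene_id")
    reg.state.to_csv(ROOT / "regulation_mask.csv", index_label="gene_id")

    coords, explained = pca_overview(counts, meta)
    coords.to_csv(ROOT / "pca.csv", index=False)
    print(f"PCA on the 100 most variable genes: PC1 {explained[0]:.0%}, "
          f"PC2 {explained[1]:.0%} of variance")


if __name__ == "__main__":
    main()
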