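#!/usr/bin/env python
"""Specificity calls, the 50 uM virtual screen and the KE ratio matrix.

Reads results/fits.csv (from 02_fit_dose_response.py) and results/data/
(truth), classifies each compound's neurotoxic specificity from the
EC25(V)/EC25(NA) ratio, calls hits at a fixed 50 uM screen concentration,
builds the KE4-anchored sensitivity-ratio matrix with its category labels, and
reports how many categories match the generating truth.  Writes
specificity.csv, hit_calls.csv and ke_ratio_matrix.csv under results/.
"""

import json
import math
from pathlib import Path

import pandas as pd

from aopke import (
    concordance_table,
    hit_call,
    ke_ratio_matrix,
    ratio_category,
    specificity_call,
)
from aopke.errors import AopkeError
from aopke.io import read_assay_table, write_json

ROOT = Path(__file__).resolve().parent.parent / "results"
SCREEN_CONC = 50e-6


def _num(row, col):
    v = row.get(col)
    return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)


def main() -> None:
    # the endpoint label "NA" is data, not a missing value
    fits = pd.read_csv(ROOT / "fits.csv", keep_default_na=False, na_values=[""])
    truth = json.loads((ROOT / "data" / "truth.json").read_text())
    by_key = {(r["compound_id"], r["endpoint"]): r for r in fits.to_dict("records")}
    compounds = sorted({c for c, _ in by_key})

    spec_rows = []
    for cid in compounds:
        na, v = by_key.get((cid, "NA"), {}), by_key.get((cid, "V"), {})
        max_conc = truth["compounds"][cid]["max_test_conc"]
        call = specificity_call(cid, _num(v, "ec25_M"), _num(na, "ec25_M"), max_conc)
        spec_rows.append({"compound_id": cid, "ec25_v_M": call.ec25_v,
                          "ec25_na_M": call.ec25_na, "ratio": call.ratio,
                          "lower_bound": call.ratio_is_lower_bound,
                          "category": call.category})
        print(f"{cid:12s} specificity: {call.category}"
              + (f" (ratio {call.ratio:.1f})" if call.ratio else ""))
    pd.DataFrame(spec_rows).to_csv(ROOT / "specificity.csv", index=False)

    datasets = {(d.compound_id, d.endpoint): d
                for d in read_assay_table(ROOT / "data" / "assay.csv")}
    hit_rows, hit_map = [], {}
    for (cid, ep), ds in sorted(datasets.items()):
        if not ep.startswith("KE"):
            continue
        try:
            hc = hit_call(ds, screen_concentration=SCREEN_CONC)
        except AopkeError:
            continue
        hit_map.setdefault(cid, {})[ep] = hc
        hit_rows.append({"compound_id": cid, "assay": ep,
                         "effect_pct": round(hc.effect_at_conc, 1), "call": hc.call})
    pd.DataFrame(hit_rows).to_csv(ROOT / "hit_calls.csv", index=False)
    rows = concordance_table(hit_map)
    write_json(rows, ROOT / "concordance.json")
    n_conc = sum(r["concordant"] for r in rows)
    print(f"50 uM virtual screen: {n_conc}/{len(rows)} compounds fully "
          f"concordant with the KE4 call")

    ec25 = {}
    for (cid, ep), row in by_key.items():
        if ep.startswith("KE"):
            ec25.setdefault(cid, {})[ep] = _num(row, "ec25_M")
    cells = ke_ratio_matrix(ec25)
    out = []
    matches = total = 0
    for c in cells:
        truth_mult = truth["ke_offsets"][truth["compounds"][c.compound_id]["moa"]].get(
            c.denominator_ke
        )
        truth_cat = ratio_category(truth_mult) if truth_mult else "n.a."
        if c.category != "n.a.":
            total += 1
            matches += c.category == truth_cat
        out.append({"compound_id": c.compound_id, "ke": c.denominator_ke,
                    "ratio": c.ratio, "category": c.category,
                    "truth_category": truth_cat})
    pd.DataFrame(out).to_csv(ROOT / "ke_ratio_matrix.csv", index=False)
    print(f"KE ratio categories: {matches}/{total} match the generating truth")


if __name__ == "__main__":
    main()
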