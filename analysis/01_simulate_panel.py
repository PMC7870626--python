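#!/usr/bin/env python
"""Generate the synthetic compound panel all downstream analyses consume.

Writes, under results/data/:
  assay.csv    - replicate %-of-control responses for viability (V), neurite
                 area (NA) and the four key-event assays of every compound
  counts.tsv   - a ~3000-gene count matrix for the deguelin-like compound at
                 five concentrations (4-fold dilutions) plus vehicle controls
  samples.tsv  - the count matrix design table
  truth.json   - the generating potencies and KE offsets, for later recovery
"""

import json
from pathlib import Path

from aopke import generate_dose_response, generate_ke_panel, generate_counts
from aopke.io import write_assay_table, write_counts_tsv, write_sample_meta
from aopke.synthetic import CountSimConfig
from aopke.pipeline import default_ke_offsets, default_panel

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    panel = default_panel()
    offsets = default_ke_offsets()

    datasets = [
        generate_dose_response(spec, ep, noise_sd=5.0, n_replicates=3, seed=SEED)
        for spec in panel
        for ep in ("V", "NA")
    ]
    ke = generate_ke_panel(panel, offsets, seed=SEED, noise_sd=5.0,
                           n_replicates=3, n_points=10)
    datasets.extend(ke.datasets.values())
    write_assay_table(datasets, OUT / "assay.csv")

    tx = panel[1]  # the deguelin-like complex-I inhibitor
    anchor = tx.ec50["V"] * (10.0 / 90.0) ** (1.0 / tx.hill["V"])  # its EC10(V)
    concs = tuple(anchor * 2.0 / 4.0**i for i in range(4, -1, -1))
    counts, meta, _truth = generate_counts(
        CountSimConfig(concentrations=concs, de_fraction=0.04, seed=SEED), tx
    )
    write_counts_tsv(counts, OUT / "counts.tsv")
    write_sample_meta(meta, OUT / "samples.tsv")

    truth = {
        "seed": SEED,
        "compounds": {
            s.compound_id: {"moa": s.moa_class, "ec50": s.ec50, "hill": s.hill,
                            "max_test_conc": s.max_test_conc}
            for s in panel
        },
        "ke_offsets": offsets,
        "count_concentrations_M": list(concs),
    }
    (OUT / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")

    print(f"panel: {len(panel)} compounds, {len(datasets)} dose-response datasets")
    print(f"counts: {counts.counts.shape[0]} genes x {counts.counts.shape[1]} samples "
          f"at {len(concs)} concentrations")
    print(f"wrote {OUT}/assay.csv, counts.tsv, samples.tsv, truth.json")


if __name__ == "__main__":
    main()
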