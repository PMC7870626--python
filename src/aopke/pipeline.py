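"""End-to-end report: simulate -> fit -> DEG -> PoD -> concordance.

`run_report` chains every stage on simulated (or user-provided) inputs and
writes one directory of interchange tables plus a manifest recording seeds,
thresholds and per-file checksums, so a run is reproducible byte for byte.
"""

from __future__ import annotations

import logging
import math
import time
from pathlib import Path

import pandas as pd

from . import concordance as conc
from . import deg as degmod
from . import dose_response as dr
from . import pod as podmod
from . import synthetic as syn
from .errors import AopkeError, FlatCurve, SchemaError, UndefinedEC
from .io import (
    RunConfig,
    file_checksum,
    read_assay_table,
    read_counts_tsv,
    read_sample_meta,
    write_assay_table,
    write_counts_tsv,
    write_json,
    write_sample_meta,
)

logger = logging.getLogger("aopke")

__all__ = ["default_panel", "default_ke_offsets", "run_report"]

# Endpoints: V viability, NA neurite area, KE1..KE4 key-event assays,
# "tx" the latent transcriptome midpoint used by the count simulator.
_PANEL = [
    # (id, moa, V, NA, KE4, tx, hill, max_conc)
    ("cpdA_cI", "cI", 2.0e-6, 2.0e-7, 2.0e-7, 1.0e-6, 2.0, 1.0e-4),
    ("cpdB_cI", "cI", 2.0e-5, 4.0e-6, 4.0e-6, 3.0e-6, 1.5, 1.0e-4),
    ("cpdC_cII", "cII", 8.0e-5, 6.0e-5, 6.0e-5, 5.0e-5, 1.5, 1.0e-4),
    ("cpdD_cIII", "cIII", 1.0e-5, 2.0e-6, 2.0e-6, 2.0e-6, 2.0, 1.0e-4),
    ("cpdE_other", "other", 1.0e-2, 5.0e-5, 5.0e-5, 4.0e-5, 1.5, 1.0e-4),
]


def default_panel() -> list[syn.CompoundSpec]:
    """A small synthetic compound panel spanning the mode-of-action classes.

    Potencies are chosen so the panel exhibits the behaviors the pipeline must
    classify: a specific neurotoxicant (neurite potency ~10x viability), an
    unspecific cytotoxicant, a weak complex-II-like compound, and one compound
    whose viability curve stays flat within the tested range.
    """
    panel = []
    for cid, moa, v, na, ke4, tx, h, cmax in _PANEL:
        panel.append(
            syn.CompoundSpec(
                compound_id=cid,
                moa_class=moa,
                ec50={"V": v, "NA": na, "KE4": ke4, "tx": tx},
                hill={"V": h, "NA": h, "KE4": h, "tx": h},
                max_test_conc=cmax,
            )
        )
    return panel


def default_ke_offsets() -> dict[str, dict[str, float]]:
    """Per-MoA potency multipliers of upstream KEs relative to KE4.

    Complex-I inhibitors trigger the earliest key events at concentrations
    orders of magnitude below the adverse-outcome proxy; cIII inhibitors show
    ~10-fold offsets and cII inhibitors nearly none.
    """
    return {
        "cI": {"KE1": 300.0, "KE2": 30.0, "KE3": 1.0},
        "cIII": {"KE1": 10.0, "KE2": 10.0, "KE3": 1.0},
        "cII": {"KE1": 2.0, "KE2": 1.5, "KE3": 1.0},
        "other": {"KE1": 1.0, "KE2": 1.0, "KE3": 1.0},
    }


def _ec_or_none(fit, x):
    try:
        return dr.effective_concentration(fit, x).concentration
    except UndefinedEC:
        return None


def _stage(name):
    logger.info("stage %s", name)
    return time.perf_counter()


def run_report(config: RunConfig, outdir) -> dict:
    """Execute the full pipeline and return the manifest dictionary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "checksums": {}}

    # ---- stage 1: obtain inputs -------------------------------------------
    t0 = _stage("simulate/load")
    if config.simulate:
        panel = default_panel()
        offsets = default_ke_offsets()
        datasets = []
        for spec in panel:
            for ep in ("V", "NA"):
                datasets.append(
                    syn.generate_dose_response(
                        spec, ep, noise_sd=config.noise_sd,
                        n_replicates=config.n_replicates, seed=config.seed,
                    )
                )
        ke_panel = syn.generate_ke_panel(
            panel, offsets, seed=config.seed, noise_sd=config.noise_sd,
            n_replicates=config.n_replicates, n_points=10,
        )
        datasets.extend(ke_panel.datasets.values())
        write_assay_table(datasets, out / "assay.csv")

        tx_compound = panel[1]  # the deguelin-like cI compound
        anchor = tx_compound.ec50["V"] * (10.0 / 90.0) ** (1.0 / tx_compound.hill["V"])
        concs = tuple(anchor * 2.0 / config.dilution ** i for i in range(4, -1, -1))
        sim = syn.CountSimConfig(
            concentrations=concs, de_fraction=config.de_fraction,
            n_replicates=config.n_replicates, seed=config.seed,
        )
        counts, meta, _truth = syn.generate_counts(sim, tx_compound)
        write_counts_tsv(counts, out / "counts.tsv")
        write_sample_meta(meta, out / "samples.tsv")
        deg_compound = tx_compound.compound_id
    else:
        if not (config.assay_path and config.counts_path and config.meta_path):
            raise SchemaError(
                "simulate is disabled but assay_path/counts_path/meta_path "
                "are not all set"
            )
        datasets = read_assay_table(config.assay_path)
        counts = read_counts_tsv(config.counts_path)
        meta = read_sample_meta(config.meta_path)
        treated = meta.table[meta.table["concentration_M"] > 0]
        deg_compound = treated["compound_id"].iloc[0]
    manifest["stages"]["simulate"] = time.perf_counter() - t0

    # ---- stage 2: dose-response fits --------------------------------------
    t0 = _stage("fit-dr")
    fit_rows = []
    fits = {}
    for ds in datasets:
        try:
            fit = dr.fit_hill(ds)
        except AopkeError as exc:
            logger.warning("fit failed for %s/%s: %s", ds.compound_id, ds.endpoint, exc)
            continue
        fits[(ds.compound_id, ds.endpoint)] = (ds, fit)
        ec10 = _ec_or_none(fit, 10) if fit.converged else None
        ec25 = _ec_or_none(fit, 25) if fit.converged else None
        fit_rows.append(
            {
                "compound_id": ds.compound_id,
                "endpoint": ds.endpoint,
                "ec50_M": fit.ec50,
                "hill": fit.hill_coef,
                "rss": fit.rss,
                "converged": fit.converged,
                "flat": fit.flat,
                "ec10_M": ec10,
                "ec25_M": ec25,
                "pec25": -math.log10(ec25) if ec25 else None,
            }
        )
    pd.DataFrame(fit_rows).to_csv(out / "fits.csv", index=False)
    manifest["stages"]["fit_dr"] = time.perf_counter() - t0

    # ---- stage 3: differential expression ---------------------------------
    t0 = _stage("deg")
    counts_f, meta_f, removal = degmod.prefilter(counts, meta)
    write_json(removal, out / "prefilter_report.json")
    treated_concs = sorted(
        set(meta_f.table.loc[meta_f.table["concentration_M"] > 0, "concentration_M"])
    )
    deg_tables: dict[float, pd.DataFrame] = {}
    summary_rows = []
    for c in treated_concs:
        table = degmod.test_differential_expression(counts_f, meta_f, (deg_compound, c))
        call = degmod.call_degs(
            table, lfc_cut=config.lfc_cut, alpha=config.alpha, rule=config.deg_rule
        )
        deg_tables[c] = table
        table.to_csv(out / f"deg_{c:.6e}.csv", index_label="gene_id")
        summary_rows.append(
            {
                "compound_id": deg_compound,
                "concentration_M": c,
                "n_up": call.n_up,
                "n_down": call.n_down,
                "n_deg": call.n_deg,
            }
        )
    deg_summary = pd.DataFrame(summary_rows)
    deg_summary.to_csv(out / "deg_summary.csv", index=False)
    manifest["stages"]["deg"] = time.perf_counter() - t0

    # ---- stage 4: transcriptomic PoD --------------------------------------
    t0 = _stage("pod")
    points = [
        podmod.DEGResponsePoint.from_counts(r["concentration_M"], r["n_deg"], config.npos)
        for r in summary_rows
    ]
    pod_row: dict = {"compound_id": deg_compound, "npos": config.npos}
    try:
        est = podmod.ec10_deg(points, compound_id=deg_compound)
        pod_row.update(ec10_deg_M=est.concentration, ec10_deg_extrapolated=est.extrapolated)
    except (FlatCurve, AopkeError) as exc:
        pod_row.update(ec10_deg_M=None, ec10_deg_flag=str(exc))
    try:
        bmc = podmod.bmc10_dgh(
            points, n_bootstrap=config.n_bootstrap, seed=config.seed,
            benchmark_response=config.benchmark_response, compound_id=deg_compound,
        )
        pod_row.update(
            bmc10_dgh_M=bmc.bmc, bmc10_ci_lower=bmc.ci_lower, bmc10_ci_upper=bmc.ci_upper
        )
    except (FlatCurve, AopkeError) as exc:
        pod_row.update(bmc10_dgh_M=None, bmc10_flag=str(exc))
    pd.DataFrame([pod_row]).to_csv(out / "pod.csv", index=False)

    anchor_idx = len(points) - 1
    low_idx = next(
        (
            i
            for i, p in enumerate(points)
            if math.isclose(
                p.concentration, points[anchor_idx].concentration / config.dilution,
                rel_tol=1e-6,
            )
        ),
        None,
    )
    if low_idx is not None:
        anchor_c = points[anchor_idx].concentration
        anchor_call = degmod.call_degs(
            deg_tables[anchor_c], config.lfc_cut, config.alpha, config.deg_rule
        )
        low_call = degmod.call_degs(
            deg_tables[points[low_idx].concentration],
            config.lfc_cut, config.alpha, config.deg_rule,
        )
        sig = podmod.build_signature(
            anchor_call.genes, low_call.genes, anchor_c,
            source_compound=deg_compound, dilution=config.dilution,
        )
        write_json(
            {
                "source_compound": sig.source_compound,
                "anchor_concentration_M": sig.anchor_concentration,
                "low_concentration_M": sig.low_concentration,
                "genes": sorted(sig.gene_ids),
                "empty": sig.empty,
            },
            out / "signature.json",
        )
        reg = podmod.regulation_matrix(
            sig,
            {f"{deg_compound}@{c:.3e}": t for c, t in deg_tables.items()},
            mask_alpha=config.mask_alpha,
        )
        reg.values.to_csv(out / "regulation_matrix.csv", index_label="gene_id")
        reg.state.to_csv(out / "regulation_mask.csv", index_label="gene_id")
    coords, explained = podmod.pca_overview(counts_f, meta_f)
    coords.to_csv(out / "pca.csv", index=False)
    write_json({"explained_variance": list(explained)}, out / "pca_explained.json")
    manifest["stages"]["pod"] = time.perf_counter() - t0

    # ---- stage 5: concordance ---------------------------------------------
    t0 = _stage("concordance")
    compounds = sorted({c for c, _ in fits})
    spec_rows = []
    for cid in compounds:
        if (cid, "NA") not in fits:
            continue
        ds_na, fit_na = fits[(cid, "NA")]
        ec25_na = _ec_or_none(fit_na, 25) if fit_na.converged else None
        ec25_v = None
        if (cid, "V") in fits:
            _, fit_v = fits[(cid, "V")]
            ec25_v = _ec_or_none(fit_v, 25) if fit_v.converged else None
        call = conc.specificity_call(cid, ec25_v, ec25_na, max_tested_conc=fit_na.conc_max)
        spec_rows.append(
            {
                "compound_id": cid,
                "ec25_v_M": call.ec25_v,
                "ec25_na_M": call.ec25_na,
                "ratio": call.ratio,
                "lower_bound": call.ratio_is_lower_bound,
                "category": call.category,
            }
        )
    pd.DataFrame(spec_rows).to_csv(out / "specificity.csv", index=False)

    hit_rows, hit_map = [], {}
    ke_assays = ("KE1", "KE2", "KE3", "KE4")
    for cid in compounds:
        per_ke = {}
        for ke in ke_assays:
            if (cid, ke) not in fits:
                continue
            ds, _fit = fits[(cid, ke)]
            try:
                hc = conc.hit_call(ds, screen_concentration=config.screen_conc)
            except AopkeError:
                continue
            per_ke[ke] = hc
            hit_rows.append(
                {
                    "compound_id": cid,
                    "assay": ke,
                    "screen_conc_M": hc.screen_concentration,
                    "effect_pct": hc.effect_at_conc,
                    "call": hc.call,
                }
            )
        if per_ke:
            hit_map[cid] = per_ke
    pd.DataFrame(hit_rows).to_csv(out / "hit_calls.csv", index=False)
    if hit_map:
        write_json(conc.concordance_table(hit_map), out / "concordance.json")

    ec25_map: dict[str, dict[str, float | None]] = {}
    for cid in compounds:
        per = {}
        for ke in ke_assays:
            if (cid, ke) in fits:
                _, fit = fits[(cid, ke)]
                per[ke] = _ec_or_none(fit, 25) if fit.converged else None
        if per:
            ec25_map[cid] = per
    cells = conc.ke_ratio_matrix(ec25_map)
    pd.DataFrame(
        [
            {
                "compound_id": c.compound_id,
                "numerator_ke": c.numerator_ke,
                "denominator_ke": c.denominator_ke,
                "ratio": c.ratio,
                "category": c.category,
            }
            for c in cells
        ]
    ).to_csv(out / "ke_ratio_matrix.csv", index=False)
    manifest["stages"]["concordance"] = time.perf_counter() - t0

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["checksums"][f.name] = file_checksum(f)
    write_json(manifest, out / "manifest.json")
    return manifest
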