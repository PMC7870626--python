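"""Readers and writers for the pipeline's interchange formats.

Tables travel as CSV/TSV (counts optionally as MatrixMarket with a samples
sidecar), signatures and manifests as JSON, run configuration as YAML.
Concentrations are serialized in molar with scientific notation; the pEC
(-log10 M) convention appears only in report-layer columns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .deg import CountMatrix, SampleMeta
from .dose_response import DoseResponseDataset
from .errors import SchemaError

__all__ = [
    "ASSAY_COLUMNS",
    "RunConfig",
    "read_assay_table",
    "write_assay_table",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_counts_mtx",
    "read_sample_meta",
    "write_sample_meta",
    "file_checksum",
]

ASSAY_COLUMNS = [
    "compound_id",
    "endpoint",
    "cell_model",
    "concentration_M",
    "replicate",
    "response_pct",
]


def write_assay_table(datasets, path) -> None:
    """Write dose-response datasets to the long-format assay CSV."""
    rows = []
    for ds in datasets:
        for c, reps in ds.points:
            for i, r in enumerate(reps, start=1):
                rows.append((ds.compound_id, ds.endpoint, ds.cell_model, c, i, r))
    df = pd.DataFrame(rows, columns=ASSAY_COLUMNS)
    df["concentration_M"] = df["concentration_M"].map(lambda v: f"{v:.6e}")
    df.to_csv(path, index=False)


def read_assay_table(path) -> list[DoseResponseDataset]:
    """Read the assay CSV and group rows into datasets.

    Raises :class:`SchemaError` naming missing columns or unparseable values
    with their line numbers.
    """
    try:
        # keep_default_na: the endpoint label "NA" (neurite area) must not be
        # coerced to a missing value
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pass-through context
        raise SchemaError(f"cannot read assay table {path}: {exc}") from exc
    missing = [c for c in ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"assay table {path} missing columns {missing}")
    bad = []
    for col in ("concentration_M", "response_pct"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        for idx in df.index[parsed.isna()]:
            bad.append(f"line {idx + 2}: {col}={df.at[idx, col]!r}")
        df[col] = parsed
    if bad:
        raise SchemaError(f"assay table {path} has unparseable values: {bad}")

    datasets = []
    for (compound, endpoint, model), grp in df.groupby(
        ["compound_id", "endpoint", "cell_model"], sort=True
    ):
        points = tuple(
            (float(c), tuple(sub["response_pct"].astype(float)))
            for c, sub in grp.groupby("concentration_M", sort=True)
        )
        datasets.append(DoseResponseDataset(compound, endpoint, model, points))
    return datasets


def write_counts_tsv(matrix: CountMatrix, path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df)


def read_counts_mtx(mtx_path, genes_path, samples_path) -> CountMatrix:
    """Read a MatrixMarket counts file with gene/sample id sidecars."""
    from scipy.io import mmread

    m = mmread(mtx_path)
    mat = np.asarray(m.todense()) if hasattr(m, "todense") else np.asarray(m)
    genes = Path(genes_path).read_text().split()
    samples = Path(samples_path).read_text().split()
    return CountMatrix(pd.DataFrame(mat, index=genes, columns=samples))


def write_sample_meta(meta: SampleMeta, path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def read_sample_meta(path) -> SampleMeta:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SampleMeta._REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"sample metadata {path} missing columns {missing}")
    return SampleMeta(df)


@dataclasses.dataclass
class RunConfig:
    """All thresholds and toggles of one pipeline run.

    Every value is serialized into the run manifest so outputs are
    reproducible byte for byte given the config and seed.
    """

    seed: int = 0
    simulate: bool = True
    assay_path: str | None = None
    counts_path: str | None = None
    meta_path: str | None = None
    # DEG calling
    lfc_cut: float = 0.59
    alpha: float = 0.05
    deg_rule: str = "fdr_and_fc"
    # PoD
    npos: int = 325
    mask_alpha: float = 0.1
    dilution: float = 4.0
    benchmark_response: float = 10.0
    n_bootstrap: int = 200
    # classification
    specificity_cut: float = 4.0
    hit_cut: float = 25.0
    screen_conc: float = 50e-6
    # simulation conditions
    noise_sd: float = 5.0
    n_replicates: int = 3
    de_fraction: float = 0.04

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def file_checksum(path) -> str:
    """SHA-256 of a file's bytes, for the run manifest."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
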