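"""Synthetic data generation with retained ground truth.

Every downstream stage of the pipeline is exercised on data produced here:
Hill-shaped assay readouts with Gaussian replicate noise, negative-binomial
count matrices with a planted concentration-dependent differentially expressed
gene subset, and multi-endpoint key-event panels whose potency offsets between
endpoints are known exactly.  Each generated object carries its generating
parameters so recovery tests never need external data.

Randomness is organized as named substreams of one global seed (see
:mod:`aopke._rng`): adding a stream never perturbs draws of existing ones, and
identical seeds reproduce outputs bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .deg import CountMatrix, SampleMeta
from .dose_response import DoseResponseDataset, hill

__all__ = [
    "CompoundSpec",
    "CountSimConfig",
    "KEPanel",
    "concentration_grid",
    "generate_dose_response",
    "generate_counts",
    "generate_ke_panel",
]

MOA_CLASSES = ("cI", "cII", "cIII", "other")

_MEAN_CAP = 1e9  # overflow guard on NB means


@dataclass(frozen=True)
class CompoundSpec:
    """Ground-truth description of one test compound.

    ``ec50`` and ``hill`` map endpoint ids (e.g. "V", "NA", "KE1".."KE4",
    "tx" for the transcriptome response) to the true potency parameters used
    by the generators.
    """

    compound_id: str
    moa_class: str
    ec50: dict[str, float]
    hill: dict[str, float]
    max_test_conc: float

    def __post_init__(self):
        if self.moa_class not in MOA_CLASSES:
            raise ValueError(f"moa_class must be one of {MOA_CLASSES}")
        if self.max_test_conc <= 0:
            raise ValueError("max_test_conc must be positive")
        for ep, v in self.ec50.items():
            if v <= 0:
                raise ValueError(f"EC50 for {ep} must be positive")
        for ep, h in self.hill.items():
            if not 0.1 < h <= 10:
                raise ValueError(f"hill coefficient for {ep} must lie in (0.1, 10]")


def concentration_grid(
    top: float, dilution: float = 10.0**0.5, n_points: int = 8
) -> np.ndarray:
    """Strictly increasing log-spaced grid ending at ``top``.

    Half-log (default) or 2-fold serial dilutions mirror screening practice.
    """
    if top <= 0 or dilution <= 1 or n_points < 2:
        raise ValueError("need top > 0, dilution > 1 and >= 2 points")
    return top / dilution ** np.arange(n_points - 1, -1, -1, dtype=float)


def generate_dose_response(
    spec: CompoundSpec,
    endpoint: str,
    noise_sd: float = 5.0,
    n_replicates: int = 3,
    seed: int = 0,
    concentrations: np.ndarray | None = None,
) -> DoseResponseDataset:
    """Hill-shaped replicate responses with Gaussian noise on the % scale.

    Noise is truncated (clipped) to [-10, 110] to admit the slight overshoot
    seen with metabolic readouts while keeping responses physically plausible.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if concentrations is None:
        concentrations = concentration_grid(spec.max_test_conc)
    concentrations = np.asarray(concentrations, dtype=float)
    if (concentrations <= 0).any() or (concentrations > spec.max_test_conc).any():
        raise ValueError("concentrations must lie in (0, max_test_conc]")
    ec50, h = spec.ec50[endpoint], spec.hill[endpoint]
    rng = substream(seed, f"responses:{spec.compound_id}:{endpoint}")
    points = []
    for c in concentrations:
        mean = float(hill(c, ec50, h))
        reps = mean + rng.normal(0.0, noise_sd, size=n_replicates)
        reps = np.clip(reps, -10.0, 110.0)
        points.append((float(c), tuple(float(r) for r in reps)))
    return DoseResponseDataset(
        compound_id=spec.compound_id,
        endpoint=endpoint,
        cell_model="synthetic",
        points=tuple(points),
        truth={"ec50": ec50, "hill": h, "noise_sd": noise_sd},
    )


@dataclass(frozen=True)
class CountSimConfig:
    """Parameters of the targeted-panel count simulation.

    Defaults emulate a ~3000-gene panel profiled at five concentrations with
    three replicate differentiations plus vehicle controls.  ``dispersion`` is
    the NB overdispersion alpha (Var = mu + alpha mu^2); baseline means are
    log-normal(meanlog 4, sdlog 1.5) to span the panel's dynamic range, and
    per-sample size factors are log-normal(0, 0.15).
    """

    n_genes: int = 3000
    n_replicates: int = 3
    concentrations: tuple[float, ...] = ()
    de_fraction: float = 0.0
    max_log2fc: float = 3.0
    min_log2fc: float = 1.0
    dispersion: float = 0.05
    baseline_meanlog: float = 4.0
    baseline_sdlog: float = 1.5
    size_factor_sdlog: float = 0.15
    gene_ec50_spread_log10: float = 0.3
    gene_hill: float = 1.5
    seed: int = 0

    def __post_init__(self):
        concs = tuple(float(c) for c in self.concentrations)
        object.__setattr__(self, "concentrations", concs)
        if any(c <= 0 for c in concs):
            raise ValueError("concentrations must be positive")
        if list(concs) != sorted(set(concs)):
            raise ValueError("concentrations must be strictly increasing")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.de_fraction > 0 and self.de_fraction * self.n_genes < 1:
            raise ValueError("de_fraction * n_genes must be >= 1 when DE is requested")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Sample NB(mean, alpha) via the gamma-Poisson mixture."""
    mean = np.minimum(mean, _MEAN_CAP)
    if alpha < 1e-12:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=mean * alpha)
    return rng.poisson(lam)


def generate_counts(config: CountSimConfig, compound: CompoundSpec):
    """Simulate a count matrix with a planted concentration-dependent DE subset.

    For differentially expressed genes the true log2 fold change follows a
    rising Hill curve in concentration that saturates at the gene's planted
    magnitude (sign random); gene-level midpoints scatter log-normally around
    the compound's transcriptome EC50 (endpoint "tx").  Non-DE genes keep a
    log2FC of exactly 0 at every concentration.

    Returns ``(CountMatrix, SampleMeta, truth)``; ``truth`` holds a per-gene
    parameter table and the genes x concentrations matrix of true log2FC.
    """
    if not config.concentrations:
        raise ValueError("config must specify at least one concentration")
    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    concs = np.asarray(config.concentrations)

    rng_base = substream(config.seed, f"baselines:{compound.compound_id}")
    baseline = rng_base.lognormal(config.baseline_meanlog, config.baseline_sdlog,
                                  size=config.n_genes)

    rng_de = substream(config.seed, f"de_params:{compound.compound_id}")
    n_de = int(round(config.de_fraction * config.n_genes))
    de_idx = rng_de.choice(config.n_genes, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    sign = rng_de.choice([-1.0, 1.0], size=n_de)
    lfc_max = rng_de.uniform(config.min_log2fc, config.max_log2fc, size=n_de)
    tx_ec50 = compound.ec50.get("tx", float(np.median(concs)))
    gene_ec50 = tx_ec50 * 10.0 ** rng_de.normal(
        0.0, config.gene_ec50_spread_log10, size=n_de
    )

    # true log2FC per gene per concentration (rising Hill, saturating)
    lfc = np.zeros((config.n_genes, len(concs)))
    if n_de:
        ratio = (concs[None, :] / gene_ec50[:, None]) ** config.gene_hill
        lfc[de_idx, :] = (sign * lfc_max)[:, None] * ratio / (1.0 + ratio)

    sample_ids, meta_rows = [], []
    for r in range(config.n_replicates):
        sample_ids.append(f"{compound.compound_id}_veh_r{r + 1}")
        meta_rows.append((sample_ids[-1], compound.compound_id, 0.0, r + 1))
    for ci, c in enumerate(concs):
        for r in range(config.n_replicates):
            sample_ids.append(f"{compound.compound_id}_c{ci + 1}_r{r + 1}")
            meta_rows.append((sample_ids[-1], compound.compound_id, float(c), r + 1))

    rng_sf = substream(config.seed, f"size_factors:{compound.compound_id}")
    sf = rng_sf.lognormal(0.0, config.size_factor_sdlog, size=len(sample_ids))

    counts = np.empty((config.n_genes, len(sample_ids)), dtype=np.int64)
    for j, (sid, (_, _, conc, _)) in enumerate(zip(sample_ids, meta_rows)):
        if conc == 0.0:
            mu = baseline * sf[j]
        else:
            ci = int(np.argmin(np.abs(concs - conc)))
            mu = baseline * 2.0 ** lfc[:, ci] * sf[j]
        # one substream per sample: a column depends only on (seed, sample id,
        # its mean vector), so regenerating any sample is order-independent
        rng_counts = substream(config.seed, f"counts:{compound.compound_id}:{sid}")
        counts[:, j] = _nb_draw(rng_counts, mu, config.dispersion)

    matrix = CountMatrix(pd.DataFrame(counts, index=genes, columns=sample_ids))
    meta = SampleMeta(
        pd.DataFrame(
            meta_rows, columns=["sample_id", "compound_id", "concentration_M", "replicate"]
        )
    )
    params = pd.DataFrame(
        {"baseline_mean": baseline, "is_de": False, "lfc_max": 0.0, "gene_ec50": np.nan},
        index=genes,
    )
    if n_de:
        params.iloc[de_idx, params.columns.get_loc("is_de")] = True
        params.iloc[de_idx, params.columns.get_loc("lfc_max")] = sign * lfc_max
        params.iloc[de_idx, params.columns.get_loc("gene_ec50")] = gene_ec50
    truth = {
        "params": params,
        "lfc": pd.DataFrame(lfc, index=genes, columns=[float(c) for c in concs]),
        "size_factors": pd.Series(sf, index=sample_ids),
    }
    return matrix, meta, truth


@dataclass(frozen=True)
class KEPanel:
    """Multi-endpoint dose-response collection with known potency offsets."""

    datasets: dict = field(default_factory=dict)  # (compound_id, ke) -> dataset
    truth_ratios: dict = field(default_factory=dict)  # compound_id -> {ke: ratio}
    anchor_ke: str = "KE4"


def generate_ke_panel(
    compounds: list[CompoundSpec],
    ke_offset_map: dict[str, dict[str, float]],
    seed: int = 0,
    noise_sd: float = 5.0,
    n_replicates: int = 3,
    n_points: int = 8,
    dilution: float = 10.0**0.5,
    anchor_ke: str = "KE4",
) -> KEPanel:
    """Generate dose-response datasets across KE endpoints per compound.

    ``ke_offset_map`` maps a mode-of-action class to per-KE potency
    multipliers: a multiplier m for a KE means that KE's true EC50 is the
    anchor (KE4) EC50 divided by m, so the truth anchor/upstream EC25 ratio is
    exactly m (the Hill slope is shared across endpoints per compound).
    """
    datasets, truth_ratios = {}, {}
    for spec in compounds:
        offsets = ke_offset_map[spec.moa_class]
        if any(m <= 0 for m in offsets.values()):
            raise ValueError("KE potency multipliers must be positive")
        anchor_ec50 = spec.ec50[anchor_ke]
        anchor_h = spec.hill[anchor_ke]
        grid = concentration_grid(spec.max_test_conc, dilution, n_points)
        truth_ratios[spec.compound_id] = {}
        for ke in [anchor_ke, *offsets]:
            mult = 1.0 if ke == anchor_ke else offsets[ke]
            ke_spec = CompoundSpec(
                compound_id=spec.compound_id,
                moa_class=spec.moa_class,
                ec50={ke: anchor_ec50 / mult},
                hill={ke: anchor_h},
                max_test_conc=spec.max_test_conc,
            )
            datasets[(spec.compound_id, ke)] = generate_dose_response(
                ke_spec, ke, noise_sd=noise_sd, n_replicates=n_replicates,
                seed=seed, concentrations=grid,
            )
            if ke != anchor_ke:
                truth_ratios[spec.compound_id][ke] = mult
    return KEPanel(datasets=datasets, truth_ratios=truth_ratios, anchor_ke=anchor_ke)
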