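"""Constrained four-parameter Hill fitting and potency estimation.

The model is the decreasing Hill curve with asymptotes fixed at 100% (untreated
control) and 0%::

    f(c) = 100 / (1 + (c / EC50)**h)

Effective concentrations EC_x (the concentration producing an x% effect, i.e.
response = 100 - x) are solved analytically from the fitted parameters, and
benchmark concentrations (BMC) carry a case-resampling bootstrap confidence
interval.  Concentrations are molar throughout; the -log10(M) "pEC" convention
appears only in reporting columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateInput, FlatCurve, UndefinedEC

__all__ = [
    "DoseResponseDataset",
    "HillFit",
    "ECEstimate",
    "BMCResult",
    "hill",
    "fit_hill",
    "effective_concentration",
    "benchmark_concentration",
    "potency_shift",
]

_H_BOUNDS = (0.2, 10.0)  # plausible slope range for cell-based assays


def hill(conc, ec50: float, hill_coef: float):
    """Decreasing Hill response (% of control) with fixed 100/0 asymptotes."""
    conc = np.asarray(conc, dtype=float)
    with np.errstate(over="ignore"):
        return 100.0 / (1.0 + (conc / ec50) ** hill_coef)


@dataclass(frozen=True)
class DoseResponseDataset:
    """Replicate %-of-control responses across a concentration series.

    ``points`` maps one strictly positive molar concentration to >= 1 replicate
    responses.  At least four distinct concentrations are required for fitting.
    """

    compound_id: str
    endpoint: str
    cell_model: str
    points: tuple[tuple[float, tuple[float, ...]], ...]
    truth: dict | None = field(default=None, compare=False)

    def __post_init__(self):
        pts = tuple(
            (float(c), tuple(float(r) for r in reps)) for c, reps in self.points
        )
        object.__setattr__(self, "points", pts)
        for c, reps in pts:
            if c <= 0:
                raise DegenerateInput(f"non-positive concentration {c!r}")
            if len(reps) < 1:
                raise DegenerateInput(f"concentration {c} has no replicates")
        if len({c for c, _ in pts}) != len(pts):
            raise DegenerateInput("duplicate concentrations in dataset")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.points])

    @property
    def mean_responses(self) -> np.ndarray:
        return np.array([float(np.mean(r)) for _, r in self.points])

    def flat_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """All (concentration, response) pairs with replicates expanded."""
        cs, ys = [], []
        for c, reps in self.points:
            cs.extend([c] * len(reps))
            ys.extend(reps)
        return np.array(cs), np.array(ys)

    def replace_responses(self, responses: dict[float, tuple[float, ...]]):
        pts = tuple((c, responses[c]) for c, _ in self.points)
        return DoseResponseDataset(
            self.compound_id, self.endpoint, self.cell_model, pts, self.truth
        )


@dataclass(frozen=True)
class HillFit:
    """Result of a constrained Hill fit (top/bottom immutable at 100/0)."""

    ec50: float
    hill_coef: float
    rss: float
    converged: bool
    n_points: int
    conc_min: float
    conc_max: float
    flat: bool = False
    top: float = 100.0
    bottom: float = 0.0


@dataclass(frozen=True)
class ECEstimate:
    """Concentration producing an x% effect, solved from a converged fit."""

    x: float
    concentration: float
    extrapolated: bool

    @property
    def pec(self) -> float:
        """Potency as -log10 of the molar concentration."""
        return -math.log10(self.concentration)


@dataclass(frozen=True)
class BMCResult:
    benchmark_response: float
    bmc: float
    ci_lower: float
    ci_upper: float
    n_bootstrap: int
    seed: int
    failed_fraction: float = 0.0


def _residuals(params, logc, y):
    log_ec50, log_h = params
    h = math.exp(log_h)
    with np.errstate(over="ignore"):
        pred = 100.0 / (1.0 + 10.0 ** ((logc - log_ec50) * h))
    return pred - y


def fit_hill(dataset: DoseResponseDataset, flat_effect_threshold: float = 25.0) -> HillFit:
    """Least-squares Hill fit over (log10 EC50, log h).

    EC50 is bounded to [min tested conc / 100, max tested conc * 100] and h to
    [0.2, 10]; three starts at the geometric quartiles of the tested range are
    tried and the best residual sum of squares wins (ties -> smaller h).

    A series whose minimum mean response never drops below
    ``100 - flat_effect_threshold`` (default: no concentration reaches a 25%
    effect) is flagged flat: the fit is returned non-converged with EC50
    undefined rather than reporting an unconstrained extrapolation.
    """
    if len(dataset.points) < 4:
        raise DegenerateInput(
            f"need >= 4 distinct concentrations, got {len(dataset.points)}"
        )
    cs, ys = dataset.flat_arrays()
    n = len(ys)
    cmin, cmax = dataset.concentrations.min(), dataset.concentrations.max()

    if dataset.mean_responses.min() > 100.0 - flat_effect_threshold:
        return HillFit(
            ec50=math.nan, hill_coef=math.nan, rss=math.nan, converged=False,
            n_points=n, conc_min=cmin, conc_max=cmax, flat=True,
        )

    logc = np.log10(cs)
    lo = [math.log10(cmin / 100.0), math.log(_H_BOUNDS[0])]
    hi = [math.log10(cmax * 100.0), math.log(_H_BOUNDS[1])]
    lmin, lmax = math.log10(cmin), math.log10(cmax)
    starts = [lmin + f * (lmax - lmin) for f in (0.25, 0.5, 0.75)]

    best = None
    for s in starts:
        res = least_squares(
            _residuals, x0=[s, 0.0], bounds=(lo, hi), args=(logc, ys),
            xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=2000,
        )
        rss = float(2.0 * res.cost)
        h = math.exp(res.x[1])
        if best is None:
            best, best_rss, best_h, best_ok = res, rss, h, res.success
            continue
        tol = 1e-9 * (1.0 + best_rss)
        if rss < best_rss - tol or (abs(rss - best_rss) <= tol and h < best_h):
            best, best_rss, best_h, best_ok = res, rss, h, res.success

    # the solver can exhaust its iteration budget while sitting in a flat
    # valley of a numerically perfect fit; a near-zero gradient on the
    # 0-100% response scale counts as converged
    converged = bool(best_ok) or float(best.optimality) < 1e-6
    return HillFit(
        ec50=float(10.0 ** best.x[0]),
        hill_coef=float(math.exp(best.x[1])),
        rss=best_rss,
        converged=converged,
        n_points=n,
        conc_min=float(cmin),
        conc_max=float(cmax),
    )


def effective_concentration(fit: HillFit, x: float) -> ECEstimate:
    """Solve the fitted Hill equation for an x% effect.

    EC_x = EC50 * (x / (100 - x))**(1/h); ``extrapolated`` is set when the
    solution lies outside the tested concentration range.
    """
    if not fit.converged or not math.isfinite(fit.ec50):
        raise UndefinedEC("effective concentration requested from a non-converged fit")
    if not 0.0 < x < 100.0:
        raise ValueError(f"effect level must lie in (0, 100), got {x}")
    conc = fit.ec50 * (x / (100.0 - x)) ** (1.0 / fit.hill_coef)
    extrapolated = not (fit.conc_min <= conc <= fit.conc_max)
    return ECEstimate(x=float(x), concentration=float(conc), extrapolated=extrapolated)


def benchmark_concentration(
    dataset: DoseResponseDataset,
    benchmark_response: float = 10.0,
    n_bootstrap: int = 1000,
    seed: int = 0,
    flat_effect_threshold: float = 25.0,
) -> BMCResult:
    """Benchmark concentration with a case-resampling bootstrap CI.

    The point estimate is the EC at the benchmark response level from the fit
    on the full dataset (seed-independent).  Replicates are resampled with
    replacement within each concentration, the curve is refit per resample, and
    the 2.5/97.5 percentiles of the resampled BMCs form the interval.

    Resampling within a group of n replicates understates the group variance
    by a factor (n-1)/n, so the bootstrap deviations from the point estimate
    are inflated by sqrt(n/(n-1)) (on the log-concentration scale) before the
    percentiles are taken -- the usual finite-sample correction, material at
    the n = 3 typical of these assays.
    """
    fit = fit_hill(dataset, flat_effect_threshold=flat_effect_threshold)
    if fit.flat:
        raise FlatCurve(
            f"{dataset.compound_id}/{dataset.endpoint}: no concentration reaches "
            f"a {flat_effect_threshold:g}% effect; BMC undefined"
        )
    point = effective_concentration(fit, benchmark_response).concentration

    rng = np.random.default_rng(seed)
    start = [math.log10(fit.ec50), math.log(fit.hill_coef)]
    cmin, cmax = fit.conc_min, fit.conc_max
    lo = [math.log10(cmin / 100.0), math.log(_H_BOUNDS[0])]
    hi = [math.log10(cmax * 100.0), math.log(_H_BOUNDS[1])]
    start = [min(max(start[0], lo[0]), hi[0]), min(max(start[1], lo[1]), hi[1])]
    frac = (benchmark_response / (100.0 - benchmark_response))

    logc_rep, groups = [], []
    for c, reps in dataset.points:
        groups.append(np.asarray(reps, dtype=float))
        logc_rep.append(np.full(len(reps), math.log10(c)))
    logc_all = np.concatenate(logc_rep)

    bmcs, failed = [], 0
    for _ in range(int(n_bootstrap)):
        ys = np.concatenate(
            [g[rng.integers(0, len(g), size=len(g))] for g in groups]
        )
        res = least_squares(
            _residuals, x0=start, bounds=(lo, hi), args=(logc_all, ys),
        )
        if not res.success:
            failed += 1
            continue
        ec50_b = 10.0 ** res.x[0]
        h_b = math.exp(res.x[1])
        bmcs.append(ec50_b * frac ** (1.0 / h_b))

    if bmcs:
        n_bar = np.mean([len(g) for g in groups])
        inflate = math.sqrt(n_bar / (n_bar - 1.0)) if n_bar > 1 else 1.0
        log_dev = inflate * (np.log10(bmcs) - math.log10(point))
        ci_lo, ci_hi = 10.0 ** (math.log10(point) + np.percentile(log_dev, [2.5, 97.5]))
        ci_lo = float(min(ci_lo, point))
        ci_hi = float(max(ci_hi, point))
    else:  # degenerate: no resample converged
        ci_lo = ci_hi = point
    return BMCResult(
        benchmark_response=float(benchmark_response),
        bmc=float(point),
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        n_bootstrap=int(n_bootstrap),
        seed=int(seed),
        failed_fraction=failed / max(n_bootstrap, 1),
    )


def potency_shift(ec_a: ECEstimate, ec_b: ECEstimate) -> float:
    """Fold change between two effective concentrations on the linear scale."""
    if ec_a.x != ec_b.x:
        raise ValueError("potency shift requires matching effect levels")
    return ec_a.concentration / ec_b.concentration
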