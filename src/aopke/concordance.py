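"""Classification layers over fitted potencies along the adverse outcome pathway.

Three readouts are implemented:

* the specificity prediction model — a compound is a specific neurotoxicant
  when its cytotoxicity EC25 exceeds its neurite EC25 more than 4-fold;
* fixed-concentration hit calling (default 50 uM virtual screen, >= 25% effect);
* the synoptic key-event sensitivity-ratio matrix, with the anchor assay's
  EC25 divided by each upstream assay's EC25 and category boundaries at
  1/3, 3, 10 and 100 (strict inequalities; boundary values fall to the less
  extreme category).

All ratios are taken on the linear molar scale; rescaling every concentration
by a common factor leaves calls and categories unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dose_response import DoseResponseDataset, HillFit, fit_hill, hill
from .errors import UndefinedAtConcentration

__all__ = [
    "SpecificityCall",
    "KERatioCell",
    "HitCall",
    "specificity_call",
    "hit_call",
    "ke_ratio_matrix",
    "ratio_category",
    "concordance_table",
    "SPECIFICITY_CUT",
    "HIT_EFFECT_CUT",
    "DEFAULT_SCREEN_CONC",
]

SPECIFICITY_CUT = 4.0  # EC25(V)/EC25(NA) above which neurotoxicity is specific
LOWER_BOUND_CUT = 2.0  # censored ratio at least this -> potential specific call
HIT_EFFECT_CUT = 25.0  # % effect defining a hit
DEFAULT_SCREEN_CONC = 50e-6  # molar


@dataclass(frozen=True)
class SpecificityCall:
    compound_id: str
    ec25_v: float | None
    ec25_na: float | None
    ratio: float | None
    ratio_is_lower_bound: bool
    category: str  # specific | unspecific | potential_lower_bound | not_determinable


def specificity_call(
    compound_id: str,
    ec25_v: float | None,
    ec25_na: float | None,
    max_tested_conc: float,
) -> SpecificityCall:
    """Classify specific neurotoxicity from viability and neurite EC25 values.

    With both potencies defined the ratio EC25(V)/EC25(NA) decides: above 4 the
    compound is a specific neurotoxicant, otherwise unspecific (a ratio of
    exactly 4 is unspecific; the rule is a strict inequality).  When viability
    was never reduced by 25% within the tested range, the ratio is censored at
    max_tested_conc/EC25(NA): at least 2 yields a potential (lower-bound) call,
    anything else is not determinable.
    """
    if ec25_na is None or not math.isfinite(ec25_na):
        return SpecificityCall(compound_id, ec25_v, None, None, False, "not_determinable")
    if ec25_v is not None and math.isfinite(ec25_v):
        ratio = ec25_v / ec25_na
        cat = "specific" if ratio > SPECIFICITY_CUT else "unspecific"
        return SpecificityCall(compound_id, ec25_v, ec25_na, ratio, False, cat)
    bound = max_tested_conc / ec25_na
    if bound >= LOWER_BOUND_CUT:
        return SpecificityCall(
            compound_id, None, ec25_na, bound, True, "potential_lower_bound"
        )
    return SpecificityCall(compound_id, None, ec25_na, bound, True, "not_determinable")


@dataclass(frozen=True)
class HitCall:
    compound_id: str
    assay: str
    screen_concentration: float
    effect_at_conc: float
    call: str  # "+" or "O"
    extrapolated: bool = False


def hit_call(
    source: DoseResponseDataset | HillFit,
    screen_concentration: float = DEFAULT_SCREEN_CONC,
    compound_id: str = "",
    assay: str = "",
) -> HitCall:
    """Call a hit at a fixed screen concentration from the fitted curve.

    The effect is 100 minus the fitted response at the screen concentration; a
    compound is a hit ("+") when the effect is at least 25%, inactive ("O")
    otherwise.  A flat series (never reaching a 25% effect anywhere) is an
    immediate non-hit.  Calls outside the tested range are flagged extrapolated.
    """
    dataset = source if isinstance(source, DoseResponseDataset) else None
    if dataset is not None:
        compound_id = compound_id or dataset.compound_id
        assay = assay or dataset.endpoint
        fit = fit_hill(dataset)
    else:
        fit = source
    extrapolated = not (fit.conc_min <= screen_concentration <= fit.conc_max)
    if fit.flat:
        # no concentration produced a 25% effect; the screen call is negative
        # provided the screen concentration was actually covered
        if extrapolated:
            raise UndefinedAtConcentration(
                f"{compound_id}/{assay}: flat series does not cover "
                f"{screen_concentration:g} M"
            )
        effect = 0.0
        if dataset is not None:
            nearest = int(
                np.abs(np.log10(dataset.concentrations / screen_concentration)).argmin()
            )
            effect = 100.0 - float(dataset.mean_responses[nearest])
        return HitCall(compound_id, assay, screen_concentration, effect, "O")
    if not fit.converged:
        raise UndefinedAtConcentration(
            f"{compound_id}/{assay}: no converged fit at {screen_concentration:g} M"
        )
    effect = 100.0 - float(hill(screen_concentration, fit.ec50, fit.hill_coef))
    call = "+" if effect >= HIT_EFFECT_CUT else "O"
    return HitCall(compound_id, assay, screen_concentration, effect, call, extrapolated)


@dataclass(frozen=True)
class KERatioCell:
    compound_id: str
    numerator_ke: str
    denominator_ke: str
    ratio: float | None
    category: str  # strong | marked | moderate | neutral | inverse | n.a.


def ratio_category(ratio: float | None) -> str:
    """Map a KE sensitivity ratio to its synoptic category.

    strong > 100, marked > 10, moderate > 3, neutral in [1/3, 3], inverse
    < 1/3; boundaries resolve to the less extreme class (strict inequalities).
    Undefined ratios are "n.a.".
    """
    if ratio is None or not math.isfinite(ratio):
        return "n.a."
    if ratio > 100.0:
        return "strong"
    if ratio > 10.0:
        return "marked"
    if ratio > 3.0:
        return "moderate"
    if ratio >= 1.0 / 3.0:
        return "neutral"
    return "inverse"


def ke_ratio_matrix(
    ec25: dict[str, dict[str, float | None]], anchor_ke: str = "KE4"
) -> list[KERatioCell]:
    """Anchor-over-upstream EC25 ratios for every compound x KE assay.

    ``ec25`` maps compound -> {KE assay -> EC25 in molar, or None when the
    effect level was not reached}.  A compound without a defined anchor EC25
    yields an all-n.a. row.
    """
    cells: list[KERatioCell] = []
    for compound, per_ke in ec25.items():
        anchor = per_ke.get(anchor_ke)
        for ke, value in per_ke.items():
            if ke == anchor_ke:
                continue
            if anchor is None or value is None:
                cells.append(KERatioCell(compound, anchor_ke, ke, None, "n.a."))
                continue
            ratio = anchor / value
            cells.append(
                KERatioCell(compound, anchor_ke, ke, ratio, ratio_category(ratio))
            )
    return cells


def concordance_table(
    hit_calls: dict[str, dict[str, HitCall]], anchor_ke: str = "KE4"
) -> list[dict]:
    """Summarize +/O hit calls per compound against the anchor key event.

    Returns one row per compound with the per-KE call vector, whether every
    available upstream assay agrees with the anchor call, and a partial flag
    when some KE assay is missing.
    """
    all_kes = sorted({ke for per in hit_calls.values() for ke in per})
    rows = []
    for compound, per_ke in hit_calls.items():
        if anchor_ke not in per_ke or len(per_ke) < 2:
            raise ValueError(
                f"{compound}: need the anchor assay and >= 1 other KE assay"
            )
        anchor_call = per_ke[anchor_ke].call
        calls = {ke: (per_ke[ke].call if ke in per_ke else None) for ke in all_kes}
        available = [c for ke, c in calls.items() if c is not None and ke != anchor_ke]
        rows.append(
            {
                "compound_id": compound,
                "calls": calls,
                "anchor_call": anchor_call,
                "concordant": all(c == anchor_call for c in available),
                "partial": any(c is None for c in calls.values()),
            }
        )
    return rows
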