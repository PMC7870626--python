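"""Mitochondrial-respiration inhibition from oxygen-consumption-rate traces.

An extracellular-flux experiment yields a per-well OCR time series with three
annotated events: the end of equilibration, the test-compound injection, and a
final rotenone + antimycin A injection that abolishes mitochondrial respiration
and reveals the non-mitochondrial residual.  Inhibition is the drop from the
last pre-treatment measurement to the first post-treatment measurement, after
subtracting the non-mitochondrial OCR from both:

    inhibition% = 100 * (baseline - post) / (baseline - nm)

The statistic is a ratio, so it is invariant to per-well normalization and to
uniform rescaling of the trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NonPositiveMitoBaseline, TooFewControls, ZeroBaseline

__all__ = ["OCRTrace", "normalize_trace", "mito_inhibition", "noise_band"]

MIN_CONTROLS = 6


@dataclass(frozen=True)
class OCRTrace:
    """One well's OCR time series with its injection-event indices."""

    well_id: str
    ocr: tuple[float, ...]
    equilibration_end: int
    treatment: int
    rot_aa_injection: int

    def __post_init__(self):
        object.__setattr__(self, "ocr", tuple(float(v) for v in self.ocr))
        n = len(self.ocr)
        for name in ("equilibration_end", "treatment", "rot_aa_injection"):
            idx = getattr(self, name)
            if not 0 <= idx < n:
                raise ValueError(f"{name} index {idx} outside trace of length {n}")
        if not (self.equilibration_end <= self.treatment < self.rot_aa_injection):
            raise ValueError(
                "events must be ordered equilibration_end <= treatment < rot_aa_injection"
            )
        if not np.isfinite(self.ocr).all():
            raise ValueError("OCR values must be finite")


def normalize_trace(trace: OCRTrace) -> OCRTrace:
    """Divide every OCR value by the value at the end of equilibration."""
    ref = trace.ocr[trace.equilibration_end]
    if ref == 0:
        raise ZeroBaseline(f"well {trace.well_id}: OCR at equilibration end is zero")
    return OCRTrace(
        well_id=trace.well_id,
        ocr=tuple(v / ref for v in trace.ocr),
        equilibration_end=trace.equilibration_end,
        treatment=trace.treatment,
        rot_aa_injection=trace.rot_aa_injection,
    )


def mito_inhibition(trace: OCRTrace) -> float:
    """Percent inhibition of mitochondrial respiration by the treatment.

    baseline = last measurement at or before the treatment injection (the
    treatment index itself, being the last pre-treatment measurement); post =
    first measurement after treatment; nm = first measurement after the
    rotenone/antimycin injection.  Values below 0% (stimulation) or above 100%
    (post-treatment OCR below the non-mitochondrial residual) are reported
    as-is rather than clamped.
    """
    baseline = trace.ocr[trace.treatment]
    post = trace.ocr[trace.treatment + 1]
    nm_index = trace.rot_aa_injection + 1
    nm = trace.ocr[nm_index] if nm_index < len(trace.ocr) else trace.ocr[-1]
    mito_baseline = baseline - nm
    if mito_baseline <= 0:
        raise NonPositiveMitoBaseline(
            f"well {trace.well_id}: baseline OCR does not exceed the "
            "non-mitochondrial residual"
        )
    return 100.0 * (baseline - post) / mito_baseline


def noise_band(control_inhibitions) -> tuple[float, float]:
    """Negative-control noise band: mean +/- 2 SD of vehicle inhibition values.

    Compound inhibition inside the band is regarded as insignificant.
    """
    vals = np.asarray(list(control_inhibitions), dtype=float)
    if vals.size < MIN_CONTROLS:
        raise TooFewControls(
            f"need >= {MIN_CONTROLS} vehicle-control values, got {vals.size}"
        )
    mean, sd = vals.mean(), vals.std(ddof=1)
    return float(mean - 2.0 * sd), float(mean + 2.0 * sd)
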