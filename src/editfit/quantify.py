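"""Water-scaled quantification in institutional units (i.u.).

Metabolite model amplitudes are referenced to the unsuppressed-water
amplitude of the same acquisition: ``estimate = kappa * met / water``.
No relaxation or tissue-segmentation corrections are applied anywhere in
this path; ``kappa`` is a single arbitrary scale constant that makes the
numbers convenient to read and cancels from every scale-invariant
statistic downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["QuantResult", "water_scaled", "DEFAULT_KAPPA"]

DEFAULT_KAPPA = 1000.0


@dataclass
class QuantResult:
    """One water-scaled metabolite estimate."""

    metabolite: str
    estimate_iu: float
    method_tag: str  # PEAK | LCM
    sequence_tag: str
    subject_id: str
    scan_id: int
    flagged: bool = False


def water_scaled(
    met_amplitude: float, water_amplitude: float, kappa: float = DEFAULT_KAPPA
) -> float:
    """``kappa * met_amplitude / water_amplitude``; scale-invariant under
    common rescaling of both amplitudes."""
    if water_amplitude <= 0:
        raise ValueError("water amplitude must be positive")
    return kappa * met_amplitude / water_amplitude
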