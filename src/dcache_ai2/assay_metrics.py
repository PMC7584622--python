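"""Quantitative metrics for the phenotype assays.

* Plate-gradient chemotaxis: response index RI = D1/(D1+D2), where D1
  and D2 are the colony-edge distances toward and away from the
  attractant spot; RI > 0.52 (strictly) scores as chemotaxis.
* Capillary chemotaxis: CFU counts corrected by subtracting cells that
  swam into buffer-only capillaries, floored at zero.
* Reporter luminescence: fold induction over background, and the
  optimal dose of a dose-response series (argmax, ties toward the
  lower dose).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

RI_THRESHOLD = 0.52


@dataclass(frozen=True)
class GradientPlateMeasurement:
    """Colony-edge distances (mm) toward (D1) and away from (D2) the spot."""

    D1: float
    D2: float

    def __post_init__(self) -> None:
        if self.D1 < 0 or self.D2 < 0:
            raise ValueError("distances must be non-negative")
        if self.D1 + self.D2 == 0:
            raise ValueError("D1 + D2 must be positive")


def response_index(m: GradientPlateMeasurement) -> float:
    """RI = D1/(D1+D2), in [0, 1]."""
    return m.D1 / (m.D1 + m.D2)


def is_chemotactic(ri: float, threshold: float = RI_THRESHOLD) -> bool:
    """Strictly greater than the threshold scores as chemotaxis."""
    return ri > threshold


def capillary_net_count(treatment_cfu: float,
                        buffer_cfu: float) -> tuple[float, bool]:
    """Buffer-corrected capillary count; returns (count, flagged).

    Negative raw differences are floored at zero and flagged.
    """
    if treatment_cfu < 0 or buffer_cfu < 0:
        raise ValueError("CFU counts must be non-negative")
    diff = treatment_cfu - buffer_cfu
    if diff < 0:
        return 0.0, True
    return float(diff), False


def fold_induction(signal: float, background: float) -> float:
    """Signal over background; background must be positive."""
    if background <= 0:
        raise ValueError("background must be positive")
    return signal / background


def optimal_dose(series: Sequence[tuple[float, float]]) -> float:
    """Dose with the maximal response; ties broken toward the lower dose."""
    if not series:
        raise ValueError("empty dose-response series")
    best_dose, best_resp = None, None
    for dose, resp in series:
        if best_resp is None or resp > best_resp or \
                (resp == best_resp and dose < best_dose):
            best_dose, best_resp = dose, resp
    return best_dose
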