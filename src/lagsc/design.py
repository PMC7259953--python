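"""Cell-loading arithmetic for droplet runs.

A pooled culture (or mix of cultures) is diluted to a measured concentration
in cells/mL and loaded onto the droplet chip; the number of cells expected to
be recovered follows the kit's consistent concentration -> expected-cells
mapping, here a simple division by ``recovery_divisor`` (default 100, i.e.
2.15e5 cells/mL -> 2150 expected cells). For a mix, concentrations combine by
their mixing weights before division.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass
class LoadingPlan:
    """Post-dilution concentrations plus mixing weights for one chip lane.

    ``concentrations`` are cells/mL for each pooled culture; ``mix_weights``
    are the volume fractions of each culture in the loaded suspension and must
    sum to 1.
    """

    concentrations: list[float]
    mix_weights: list[float] = field(default=None)  # type: ignore[assignment]
    recovery_divisor: float = 100.0

    def __post_init__(self) -> None:
        self.concentrations = [float(c) for c in self.concentrations]
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be non-negative")
        if self.mix_weights is None:
            n = len(self.concentrations)
            self.mix_weights = [1.0 / n] * n
        self.mix_weights = [float(w) for w in self.mix_weights]
        if len(self.mix_weights) != len(self.concentrations):
            raise ValueError("mix_weights and concentrations length mismatch")
        if any(w < 0 for w in self.mix_weights):
            raise ValueError("mix_weights must be non-negative")
        if abs(sum(self.mix_weights) - 1.0) > 1e-9:
            raise ValueError("mix_weights must sum to 1")
        if self.recovery_divisor <= 0:
            raise ValueError("recovery_divisor must be positive")


def expected_cells(plan: LoadingPlan) -> float:
    """Expected number of recovered cells for a loading plan.

    Sum of weight x concentration over pooled cultures, divided by the
    recovery divisor.
    """
    return (
        sum(w * c for w, c in zip(plan.mix_weights, plan.concentrations))
        / plan.recovery_divisor
    )


def expected_cells_int(plan: LoadingPlan) -> int:
    """Integer report of :func:`expected_cells`, rounding half away from zero."""
    x = expected_cells(plan)
    return int(math.floor(x + 0.5))


def required_concentration(
    target_cells: float, recovery_divisor: float = 100.0
) -> float:
    """Planning inverse: concentration (cells/mL) needed for a target count."""
    if target_cells < 0:
        raise ValueError("target_cells must be non-negative")
    return target_cells * recovery_divisor


#: Post-dilution loading plans for the five samples of the study design
#: (single cultures for the four time points; a 50-50 mix of maltose
#: pre-growth and glucose-12h cultures for the control sample).
STUDY_LOADING_PLANS: dict[str, LoadingPlan] = {
    "glucose-6h": LoadingPlan([2.15e5]),
    "glucose-12h": LoadingPlan([2.07e5]),
    "lag-1h": LoadingPlan([1.62e5]),
    "lag-3h": LoadingPlan([2.09e5]),
    "mix-glucose-maltose": LoadingPlan([6.06e4, 1.32e5], [0.5, 0.5]),
}
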