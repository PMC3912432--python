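"""Attribution of anoxic nitrite consumption to anammox versus other sinks.

In an anoxic assay on mixed nitritation-anammox sludge, nitrite is
consumed both by the canonical anammox reaction (which removes a fixed
~1.32 mol of nitrite per mol of ammonium) and by other processes --
heterotrophic denitrification on residual organics, or anammox bacteria
running dissimilatory nitrate/nitrite reduction to ammonium.  Either
extra sink inflates the observed nitrite-to-ammonium consumption ratio
above the stoichiometric 1.32, so the excess partitions total nitrite
consumption:

    anammox_fraction = theoretical_ratio / observed_ratio   (capped at 1)

An observed ratio *below* the theoretical one indicates ammonium sinks
other than anammox instead; the fraction is then clamped to 1 and the
result flagged ``sub-stoichiometric`` rather than extrapolated.

The two non-anammox sinks cannot be separated from the ratio alone, so
they are reported as a single "other" bucket.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError

__all__ = ["THEORETICAL_ANAMMOX_RATIO", "PartitionResult", "partition_nitrite"]

#: Canonical anammox stoichiometry, mol nitrite consumed per mol ammonium.
THEORETICAL_ANAMMOX_RATIO = 1.32


@dataclass(frozen=True)
class PartitionResult:
    """Split of total nitrite consumption between anammox and other sinks."""

    observed_ratio: float
    theoretical_ratio: float
    anammox_fraction: float
    other_fraction: float
    sub_stoichiometric: bool = False

    @property
    def anammox_percent(self) -> float:
        """Raw anammox share in percent."""
        return 100.0 * self.anammox_fraction

    @property
    def anammox_percent_rounded(self) -> int:
        """Anammox share rounded to the nearest 5 percentage points.

        Exact halves round down (the anammox-conservative side): 82.5 -> 80.
        """
        return _round_nearest5_half_down(self.anammox_percent)

    @property
    def other_percent_rounded(self) -> int:
        return 100 - self.anammox_percent_rounded

    def to_dict(self) -> dict:
        return {
            "observed_ratio": self.observed_ratio,
            "theoretical_ratio": self.theoretical_ratio,
            "anammox_fraction": self.anammox_fraction,
            "other_fraction": self.other_fraction,
            "anammox_percent_rounded": self.anammox_percent_rounded,
            "other_percent_rounded": self.other_percent_rounded,
            "sub_stoichiometric": self.sub_stoichiometric,
        }


def _round_nearest5_half_down(pct: float) -> int:
    # ceil(x/5 - 1/2): nearest multiple of 5 with exact halves rounded down.
    return int(5 * math.ceil(pct / 5.0 - 0.5))


def partition_nitrite(
    observed_ratio: float,
    theoretical_ratio: float = THEORETICAL_ANAMMOX_RATIO,
) -> PartitionResult:
    """Partition nitrite consumption given the observed TNN/TAN molar ratio.

    Parameters
    ----------
    observed_ratio : float
        Measured mol nitrite consumed per mol ammonium consumed (> 0).
    theoretical_ratio : float
        Anammox stoichiometry to attribute (default 1.32); configurable
        to admit alternative stoichiometries.

    Returns
    -------
    PartitionResult
        Fractions always sum to 1.  When ``observed_ratio`` is below the
        theoretical value the anammox fraction is clamped to 1 and the
        ``sub_stoichiometric`` flag set.

    Examples
    --------
    >>> partition_nitrite(1.4).anammox_percent_rounded
    95
    >>> partition_nitrite(1.6).anammox_percent_rounded
    80
    """
    if observed_ratio <= 0:
        raise DomainError(f"observed_ratio must be > 0, got {observed_ratio}")
    if theoretical_ratio <= 0:
        raise DomainError(f"theoretical_ratio must be > 0, got {theoretical_ratio}")
    frac = min(1.0, theoretical_ratio / observed_ratio)
    return PartitionResult(
        observed_ratio=observed_ratio,
        theoretical_ratio=theoretical_ratio,
        anammox_fraction=frac,
        other_fraction=1.0 - frac,
        sub_stoichiometric=observed_ratio < theoretical_ratio,
    )
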