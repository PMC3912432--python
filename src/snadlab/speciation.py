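"""Ammonium acid-base speciation and unit conversions.

Total ammonium nitrogen (TAN) in solution is the sum of the ionized
(NH4+) and un-ionized (NH3, "free ammonia", FA) forms.  Only the
un-ionized fraction crosses cell membranes freely, so FA -- not TAN --
is the quantity that acts as substrate and inhibitor for ammonia
oxidizers and as inhibitor for nitrite oxidizers.  The equilibrium
fraction follows from the ammonium dissociation constant, whose
temperature dependence is captured by the classical van't Hoff form
``Kb/Kw = exp(6344 / (273 + T))``:

    FA = TAN / (1 + 10^-pH / exp(-6344 / (273 + T)))

with TAN and FA in mg N/L, pH dimensionless and T in degrees Celsius.

All concentrations in this package are carried as mg N per litre; the
millimolar scale appears only at the I/O boundary via :func:`mm_to_mgN`.
Nitrogen molar mass is fixed at 14.0 g/mol so that round millimolar
figures convert to the round mass figures used throughout reactor
practice (3 mM -> 42 mg N/L).

Free nitrous acid (FNA) speciation is deliberately not implemented:
nitrite protonation matters in acidic, nitrite-rich systems, but this
toolkit targets reactors operated near neutral pH with single-digit
nitrite levels.  ``free_ammonia`` is the natural template should an FNA
hook ever be needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError

__all__ = [
    "N_MOLAR_MASS",
    "AssayCondition",
    "Concentration",
    "free_ammonia",
    "mm_to_mgN",
    "specific_activity",
    "tss_activity",
]

#: Molar mass of nitrogen used for all mol <-> mass conversions (g/mol).
#: Fixed at 14.0 (not 14.0067) so that the conventional round-number
#: conversions of reactor engineering hold exactly (3 mM N = 42 mg N/L).
N_MOLAR_MASS = 14.0

#: Species labels for measured and derived nitrogen pools.
SPECIES = ("TAN", "TNN", "NO3N", "FA")


@dataclass(frozen=True)
class AssayCondition:
    """Physico-chemical state of one batch incubation.

    Parameters
    ----------
    pH : float
        Incubation pH, in (0, 14).
    temperature_C : float
        Incubation temperature in degrees Celsius. Default 23, the
        midpoint consistent with room-temperature assays (22 +/- 1 C).
    protein_conc : float or None
        Biomass protein concentration in mg protein per mL, used to
        express volumetric rates as protein-specific activities.
    tss : float or None
        Total suspended solids in g TSS per L, used for TSS-normalized
        activities.
    protein_fraction : float
        Protein content of the biomass, g protein per g dry weight
        (default 0.3, typical for nitritation-anammox sludge).
    """

    pH: float = 7.5
    temperature_C: float = 23.0
    protein_conc: float | None = None
    tss: float | None = None
    protein_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 < self.pH < 14.0:
            raise DomainError(f"pH must be in (0, 14), got {self.pH}")
        if not -10.0 < self.temperature_C < 60.0:
            raise DomainError(
                f"temperature_C must be in (-10, 60), got {self.temperature_C}"
            )
        if self.protein_conc is not None and self.protein_conc <= 0:
            raise DomainError(f"protein_conc must be > 0, got {self.protein_conc}")
        if self.tss is not None and self.tss <= 0:
            raise DomainError(f"tss must be > 0, got {self.tss}")
        if not 0.0 < self.protein_fraction < 1.0:
            raise DomainError(
                f"protein_fraction must be in (0, 1), got {self.protein_fraction}"
            )


@dataclass(frozen=True)
class Concentration:
    """A nitrogen concentration tagged with its chemical species.

    ``value`` is mg N per litre (the package-wide canonical unit);
    ``species`` is one of TAN, TNN, NO3N or FA.  FA is always derived
    from TAN by speciation, never measured directly.
    """

    value: float
    species: str

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise DomainError(f"unknown species {self.species!r}; expected one of {SPECIES}")
        if self.value < 0:
            raise DomainError(f"concentration must be >= 0, got {self.value}")

    @property
    def mM(self) -> float:
        """Concentration on the millimolar-N scale."""
        return self.value / N_MOLAR_MASS


def free_ammonia(tan: float, pH: float, temperature_C: float) -> float:
    """Un-ionized ammonia (NH3-N) concentration in equilibrium with TAN.

    Parameters
    ----------
    tan : float
        Total ammonium nitrogen, mg N/L. Must be >= 0.
    pH : float
        Solution pH, in (0, 14).
    temperature_C : float
        Temperature in degrees Celsius, in (-10, 60).

    Returns
    -------
    float
        Free ammonia concentration, mg NH3-N/L; always in ``[0, tan]``.

    Examples
    --------
    >>> round(free_ammonia(126.0, 8.0, 23.0), 1)
    5.9
    """
    if tan < 0:
        raise DomainError(f"tan must be >= 0, got {tan}")
    if not 0.0 < pH < 14.0:
        raise DomainError(f"pH must be in (0, 14), got {pH}")
    if not -10.0 < temperature_C < 60.0:
        raise DomainError(f"temperature_C must be in (-10, 60), got {temperature_C}")
    # Kb/Kw = exp(6344/(273+T)); FA fraction = 1 / (1 + [H+] * Kb/Kw)
    return tan / (1.0 + 10.0 ** (-pH) / math.exp(-6344.0 / (273.0 + temperature_C)))


def mm_to_mgN(conc_mM: float) -> float:
    """Convert a millimolar nitrogen concentration to mg N/L (x 14.0)."""
    if conc_mM < 0:
        raise DomainError(f"conc_mM must be >= 0, got {conc_mM}")
    return conc_mM * N_MOLAR_MASS


def specific_activity(volumetric_rate: float, protein_conc: float) -> float:
    """Protein-specific activity from a volumetric conversion rate.

    Converts mg N/L/h to nmol N per mg protein per minute:
    ``(rate * 1000 / 14.0 / 60) / protein_conc``.

    Parameters
    ----------
    volumetric_rate : float
        Volumetric rate, mg N/L/h (sign preserved).
    protein_conc : float
        Protein concentration of the assayed biomass, mg/mL (> 0).
    """
    if protein_conc <= 0:
        raise DomainError(f"protein_conc must be > 0, got {protein_conc}")
    # mg N/L/h -> umol N/L/h (x1000/14) -> nmol N/mL/min (/60) -> per mg protein
    return volumetric_rate * 1000.0 / N_MOLAR_MASS / 60.0 / protein_conc


def tss_activity(volumetric_rate: float, tss: float) -> float:
    """Biomass-specific activity on the dry-weight scale, mg N/gTSS/h.

    Simply ``volumetric_rate / tss`` with tss in g/L.  Note that with
    typical sludge at 10 gTSS/L this is numerically one tenth of the
    volumetric rate; published gTSS-scale figures sometimes coincide
    with the volumetric rate instead, so both scales are reported
    side by side downstream rather than reconciled.
    """
    if tss <= 0:
        raise DomainError(f"tss must be > 0, got {tss}")
    return volumetric_rate / tss
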