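"""Free-ammonia inhibition windows and SBR operating guards.

Un-ionized ammonia inhibits the two nitrifier guilds at very different
levels (Anthonisen-type windows): ammonia oxidizers (AOB) only above
roughly 10-150 mg NH3-N/L, nitrite oxidizers (NOB) already at
0.08-0.82 mg NH3-N/L.  A partial-nitritation reactor exploits the gap:
keeping free ammonia between the NOB onset and the AOB onset suppresses
nitrate formation while leaving ammonia oxidation unimpaired.

:func:`classify_state` places one reactor or assay state in those
windows; :func:`check_sbr_guards` evaluates the operating rules of a
sequencing batch reactor cycle that maintain this selective pressure:
low nitrite after aeration, no complete ammonium depletion at cycle
end, NOB-inhibiting free ammonia throughout, and nitrite below the
anammox-safe ceiling.

Window boundaries are treated as closed (a value exactly at a bound
counts as inside), and the NOB verdict uses the conservative 0.08
onset; whether the stronger 0.82 bound is also exceeded is reported
separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DomainError, IncompleteCycleError
from .speciation import free_ammonia

__all__ = [
    "InhibitionThresholds",
    "OperatingPoint",
    "StateClassification",
    "classify_state",
    "check_sbr_guards",
]


@dataclass(frozen=True)
class InhibitionThresholds:
    """Free-ammonia inhibition windows, mg NH3-N/L.

    ``aob_inhibit`` is the onset range for ammonia oxidizers,
    ``nob_inhibit`` the onset range for nitrite oxidizers; free ammonia
    at or above a range's lower bound counts as inhibiting for that
    guild.
    """

    aob_inhibit: tuple[float, float] = (10.0, 150.0)
    nob_inhibit: tuple[float, float] = (0.08, 0.82)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("aob_inhibit", self.aob_inhibit), ("nob_inhibit", self.nob_inhibit)):
            if not lo < hi:
                raise DomainError(f"{name} bounds must satisfy lower < upper, got ({lo}, {hi})")


@dataclass(frozen=True)
class OperatingPoint:
    """One reactor/assay state: bulk concentrations plus pH and temperature."""

    tan: float
    pH: float
    temperature_C: float
    tnn: float = 0.0
    phase_label: str = ""

    def __post_init__(self) -> None:
        if self.tan < 0 or self.tnn < 0:
            raise DomainError("concentrations must be >= 0")

    @property
    def free_ammonia(self) -> float:
        return free_ammonia(self.tan, self.pH, self.temperature_C)


@dataclass(frozen=True)
class StateClassification:
    """Inhibition verdict for one operating point."""

    fa: float
    aob_status: str  # below_window | inhibited
    nob_status: str  # uninhibited | inhibited
    nob_strongly_inhibited: bool
    thresholds: InhibitionThresholds = field(default_factory=InhibitionThresholds)

    def to_dict(self) -> dict:
        return {
            "free_ammonia_mgN_L": self.fa,
            "aob_status": self.aob_status,
            "nob_status": self.nob_status,
            "nob_strongly_inhibited": self.nob_strongly_inhibited,
        }


def classify_state(
    point: OperatingPoint,
    thresholds: InhibitionThresholds | None = None,
) -> StateClassification:
    """Classify one operating point against the AOB and NOB windows.

    Free ammonia is computed from the point's TAN, pH and temperature.
    AOB are flagged ``inhibited`` at FA >= the AOB onset (10 mg/L by
    default), NOB at FA >= the conservative NOB onset (0.08 mg/L);
    FA >= the upper NOB bound (0.82) is additionally reported as
    strong inhibition.

    Examples
    --------
    >>> c = classify_state(OperatingPoint(tan=126, pH=8.0, temperature_C=23))
    >>> (c.aob_status, c.nob_status)
    ('below_window', 'inhibited')
    """
    th = thresholds or InhibitionThresholds()
    fa = point.free_ammonia
    return StateClassification(
        fa=fa,
        aob_status="inhibited" if fa >= th.aob_inhibit[0] else "below_window",
        nob_status="inhibited" if fa >= th.nob_inhibit[0] else "uninhibited",
        nob_strongly_inhibited=fa >= th.nob_inhibit[1],
        thresholds=th,
    )


#: TNN ceiling after aeration that keeps NOB substrate-limited (mg N/L).
POST_AERATION_TNN_MAX = 8.0
#: TNN level above which short-term anammox inhibition risk begins (mg N/L).
ANAMMOX_TNN_SAFE_MAX = 42.0
#: Residual-ammonium band recommended at cycle end (mg N/L).
CYCLE_END_TAN_BAND = (10.0, 40.0)

REQUIRED_PHASES = ("cycle_start", "post_aeration", "cycle_end")


def check_sbr_guards(
    cycle: list[OperatingPoint],
    thresholds: InhibitionThresholds | None = None,
) -> dict:
    """Evaluate the four NOB-suppression / anammox-safety guards on a cycle.

    The cycle must contain at least one point for each phase label in
    ``cycle_start``, ``post_aeration`` and ``cycle_end``.  Guards:

    g1
        Nitrite at every post-aeration point <= 8 mg TNN/L.
    g2
        Ammonium at cycle end > 0 (never fully depleted); a warning is
        attached when the residual is outside the 10-40 mg/L band.
    g3
        Free ammonia at every point >= the NOB onset (0.08 mg/L), i.e.
        NOB stay inhibited throughout the cycle.
    g4
        Nitrite at every post-aeration point <= 42 mg TNN/L, the
        short-term anammox-safe ceiling.

    Returns a dict with one boolean per guard, per-guard detail, and
    ``all_pass``.  Evaluation is order-independent over the point list.
    """
    th = thresholds or InhibitionThresholds()
    by_phase: dict[str, list[OperatingPoint]] = {}
    for p in cycle:
        by_phase.setdefault(p.phase_label, []).append(p)
    missing = [ph for ph in REQUIRED_PHASES if ph not in by_phase]
    if missing:
        raise IncompleteCycleError(f"cycle is missing phase label(s): {missing}")

    post_tnn = [p.tnn for p in by_phase["post_aeration"]]
    end_tan = [p.tan for p in by_phase["cycle_end"]]
    fas = sorted((p.phase_label, p.free_ammonia) for p in cycle)

    g1 = max(post_tnn) <= POST_AERATION_TNN_MAX
    g2 = min(end_tan) > 0.0
    g2_warning = g2 and not all(
        CYCLE_END_TAN_BAND[0] <= tan <= CYCLE_END_TAN_BAND[1] for tan in end_tan
    )
    g3 = all(fa >= th.nob_inhibit[0] for _, fa in fas)
    g4 = max(post_tnn) <= ANAMMOX_TNN_SAFE_MAX

    return {
        "g1_post_aeration_tnn_le_8": g1,
        "g2_cycle_end_tan_positive": g2,
        "g2_tan_outside_10_40_warning": g2_warning,
        "g3_fa_nob_inhibiting_throughout": g3,
        "g4_post_aeration_tnn_le_42": g4,
        "all_pass": g1 and g2 and g3 and g4,
        "detail": {
            "post_aeration_tnn_max": max(post_tnn),
            "cycle_end_tan_min": min(end_tan),
            "free_ammonia_by_phase": [
                {"phase": ph, "fa": fa} for ph, fa in fas
            ],
        },
    }
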