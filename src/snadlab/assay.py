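"""Batch-assay rate estimation, specific activities and stoichiometric ratios.

Activities of the nitrogen-converting guilds (aerobic ammonia oxidizers,
anammox bacteria, heterotrophic denitrifiers) are measured in short batch
incubations: concentrated washed sludge is spiked with substrate and
sampled repeatedly (canonically 7 samples over 3 h at 30-min intervals).
Over such a short window substrate conversion is well approximated as
zero order, so the rate of each nitrogen species is the slope of an
ordinary least-squares line through concentration versus time.  Slopes
are converted to protein-specific (nmol N/mg protein/min) and TSS-
specific (mg N/gTSS/h) activities, and ratios of slopes give the molar
stoichiometry of the dominant process (e.g. nitrite-consumed over
ammonium-consumed for anammox).

The module exposes both a functional surface (:func:`fit_rate`,
:func:`stoichiometric_ratio`, :func:`ph_optimum`) and a model-object
surface (:class:`BatchAssayModel` / :class:`BatchAssayResults`) in the
style of statsmodels: build the model from data, call ``fit()``, read
estimates and uncertainties off the results object or print
``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateInputError,
    DomainError,
    InsufficientDataError,
    UndefinedRatioError,
)
from .speciation import AssayCondition, specific_activity, tss_activity

__all__ = [
    "ASSAY_TYPES",
    "AssaySeries",
    "RateEstimate",
    "StoichRatio",
    "BatchAssayModel",
    "BatchAssayResults",
    "fit_rate",
    "stoichiometric_ratio",
    "ph_optimum",
    "read_assay_csv",
]

ASSAY_TYPES = ("AOB_aerobic", "anammox_anoxic", "denitrification_NO3", "denitrification_NO2")

MEASURED_SPECIES = ("TAN", "TNN", "NO3N")

#: Detection rule: a slope within 3 standard errors of zero is reported
#: as "no detectable activity" and refused as a ratio denominator.
DETECTION_SIGMA = 3.0


@dataclass(frozen=True)
class AssaySeries:
    """Timed concentration measurements for one assay bottle.

    ``times`` are minutes from substrate addition, strictly increasing;
    ``concentrations`` maps each measured species (TAN, TNN, NO3N) to an
    array of mg N/L values aligned with ``times``.
    """

    times: np.ndarray
    concentrations: dict[str, np.ndarray]
    condition: AssayCondition = field(default_factory=AssayCondition)
    assay_type: str = "AOB_aerobic"
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1 or len(t) < 2:
            raise DomainError("times must be a 1-D array of at least 2 points")
        if not np.all(np.diff(t) > 0):
            raise DomainError("times must be strictly increasing")
        conc = {}
        for sp, values in self.concentrations.items():
            if sp not in MEASURED_SPECIES:
                raise DomainError(f"unknown species {sp!r}; measured species are {MEASURED_SPECIES}")
            v = np.asarray(values, dtype=float)
            if v.shape != t.shape:
                raise DomainError(f"series for {sp} has length {len(v)}, expected {len(t)}")
            if np.any(v < 0):
                raise DomainError(f"negative concentration in series for {sp}")
            conc[sp] = v
        object.__setattr__(self, "concentrations", conc)
        if self.assay_type not in ASSAY_TYPES:
            raise DomainError(f"unknown assay_type {self.assay_type!r}; expected one of {ASSAY_TYPES}")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.concentrations)

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame with a ``time_min`` column per species column."""
        data = {"time_min": self.times}
        data.update(self.concentrations)
        return pd.DataFrame(data)


@dataclass(frozen=True)
class RateEstimate:
    """OLS rate of one species in one bottle, with derived activities.

    ``slope`` is signed (negative = depletion) in mg N/L/h; ``specific_rate``
    (nmol N/mg protein/min) and ``tss_rate`` (mg N/gTSS/h) carry the
    magnitude of the slope on the biomass-normalized scales, when the
    assay condition provides the normalizers.
    """

    species: str
    slope: float
    stderr: float
    r_squared: float
    n_points: int
    window: tuple[float, float]
    specific_rate: float | None = None
    tss_rate: float | None = None

    @property
    def detectable(self) -> bool:
        """True when the slope differs from zero by more than 3 stderr."""
        return abs(self.slope) > DETECTION_SIGMA * self.stderr

    @property
    def activity(self) -> float:
        """Magnitude of the volumetric rate, mg N/L/h."""
        return abs(self.slope)


@dataclass(frozen=True)
class StoichRatio:
    """Molar ratio of two rates from the same bottle (mg N scales cancel)."""

    numerator_species: str
    denominator_species: str
    ratio: float
    stderr: float

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise DomainError("stoichiometric ratio must be >= 0")


def fit_rate(
    series: AssaySeries,
    species: str,
    window: tuple[float, float] | None = None,
    trim_lag: bool = False,
) -> RateEstimate:
    """Ordinary least-squares rate of one species over a time window.

    Parameters
    ----------
    series : AssaySeries
        The bottle's measurements.
    species : str
        One of the species present in ``series``.
    window : (float, float), optional
        Inclusive time window in minutes; default is the full series.
    trim_lag : bool
        If True, drop leading points one at a time while doing so
        improves r-squared by more than 0.02 (simple lag-phase
        trimming). Off by default: the short-assay design assumes
        linearity from t=0.

    Returns
    -------
    RateEstimate
        Slope in mg N/L/h with its standard error, r-squared and, when
        the assay condition carries protein/TSS normalizers, the
        protein- and TSS-specific activities of the slope magnitude.
    """
    if species not in series.concentrations:
        raise DomainError(f"species {species!r} not measured in this series")
    t = series.times
    c = series.concentrations[species]
    if window is not None:
        lo, hi = window
        mask = (t >= lo) & (t <= hi)
        t, c = t[mask], c[mask]
    if len(t) < 3:
        raise InsufficientDataError(
            f"need >= 3 points to fit a rate, got {len(t)} for {species}"
        )
    if np.ptp(t) == 0:
        raise DegenerateInputError("zero time variance in fitting window")

    if trim_lag:
        best = _ols(t, c)
        while len(t) > 3:
            cand = _ols(t[1:], c[1:])
            if cand[2] > best[2] + 0.02:
                t, c = t[1:], c[1:]
                best = cand
            else:
                break
        slope_min, stderr_min, r2 = best
    else:
        slope_min, stderr_min, r2 = _ols(t, c)

    slope = slope_min * 60.0  # mg N/L/min -> mg N/L/h
    stderr = stderr_min * 60.0
    cond = series.condition
    spec = (
        specific_activity(abs(slope), cond.protein_conc)
        if cond.protein_conc is not None
        else None
    )
    tss = tss_activity(abs(slope), cond.tss) if cond.tss is not None else None
    return RateEstimate(
        species=species,
        slope=slope,
        stderr=stderr,
        r_squared=r2,
        n_points=len(t),
        window=(float(t[0]), float(t[-1])),
        specific_rate=spec,
        tss_rate=tss,
    )


def _ols(t: np.ndarray, c: np.ndarray) -> tuple[float, float, float]:
    """Slope, slope stderr and r^2 of c ~ t (per-minute scale)."""
    res = stats.linregress(t, c)
    stderr = 0.0 if np.isnan(res.stderr) else float(res.stderr)
    r2 = float(res.rvalue) ** 2
    if np.isnan(r2):
        # constant series: SST = 0, r^2 undefined; the zero-slope line
        # fits exactly, so report 1 when residuals vanish, else 0
        resid = c - (res.intercept + res.slope * t)
        r2 = 1.0 if np.allclose(resid, 0.0) else 0.0
    return float(res.slope), stderr, r2


def stoichiometric_ratio(est_num: RateEstimate, est_den: RateEstimate) -> StoichRatio:
    """Molar ratio of two rate magnitudes with propagated uncertainty.

    Both estimates must come from the same bottle so that the mass->mol
    conversion cancels (both are mg N).  The denominator must be
    detectable (|slope| > 3 stderr); otherwise the ratio is undefined
    and an :class:`UndefinedRatioError` is raised rather than returning
    a spurious zero or infinity.
    """
    if not est_den.detectable:
        raise UndefinedRatioError(
            f"denominator rate for {est_den.species} "
            f"({est_den.slope:.3g} +/- {est_den.stderr:.3g} mg N/L/h) "
            "is indistinguishable from zero"
        )
    num, den = abs(est_num.slope), abs(est_den.slope)
    ratio = num / den
    # First-order (delta-method) propagation for a quotient of independent rates.
    rel_var = 0.0
    if num > 0:
        rel_var += (est_num.stderr / num) ** 2
    rel_var += (est_den.stderr / den) ** 2
    return StoichRatio(
        numerator_species=est_num.species,
        denominator_species=est_den.species,
        ratio=ratio,
        stderr=ratio * float(np.sqrt(rel_var)),
    )


def ph_optimum(profile: dict[float, float]) -> tuple[float, str]:
    """Optimal pH of an activity profile measured on a pH grid.

    Returns the pH of the maximum activity and a flag: ``"interior"``
    when the maximum lies strictly inside the measured grid, or
    ``"boundary"`` when it sits at an endpoint (the profile may be
    monotone and the true optimum outside the tested range).  Exact ties
    are broken toward the lowest pH, so a plateau such as 7.8-8.0
    reports its acidic edge.
    """
    if not profile:
        raise DomainError("empty pH profile")
    if len(profile) < 3:
        raise InsufficientDataError(f"need >= 3 pH points, got {len(profile)}")
    phs = sorted(profile)
    best_ph = min((ph for ph in phs if profile[ph] == max(profile.values())))
    flag = "interior" if phs[0] < best_ph < phs[-1] else "boundary"
    return best_ph, flag


# ---------------------------------------------------------------------------
# Model-object surface
# ---------------------------------------------------------------------------

#: Which ratio summarizes each assay type: (numerator, denominator, name).
_RATIO_FOR_ASSAY = {
    "AOB_aerobic": ("TNN", "TAN", "TNN_produced/TAN_removed"),
    "anammox_anoxic": ("TNN", "TAN", "TNN_consumed/TAN_consumed"),
}


class BatchAssayModel:
    """Linear initial-rate model for one batch-assay bottle.

    The model treats every measured nitrogen species as depleting or
    accumulating at constant rate over the assay window and estimates
    those rates jointly by per-species OLS.  Construct it from an
    :class:`AssaySeries` or from a tidy DataFrame, then call
    :meth:`fit`.

    Examples
    --------
    >>> import numpy as np
    >>> t = np.arange(0, 181, 30)
    >>> series = AssaySeries(t, {"TAN": 126 - 10 * t / 60, "TNN": 10 * t / 60})
    >>> res = BatchAssayModel(series).fit()
    >>> round(res.rates["TAN"].slope, 6)
    -10.0
    """

    def __init__(self, series: AssaySeries):
        self.series = series

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        condition: AssayCondition | None = None,
        assay_type: str = "AOB_aerobic",
        label: str = "",
    ) -> "BatchAssayModel":
        """Build from a DataFrame with ``time_min`` and species columns.

        Recognized species columns: ``TAN_mgN_L``/``TAN``, ``TNN_mgN_L``/
        ``TNN``, ``NO3_mgN_L``/``NO3N``.
        """
        if "time_min" not in df.columns:
            raise DomainError("DataFrame must have a 'time_min' column")
        aliases = {
            "TAN_mgN_L": "TAN",
            "TNN_mgN_L": "TNN",
            "NO3_mgN_L": "NO3N",
            "TAN": "TAN",
            "TNN": "TNN",
            "NO3N": "NO3N",
        }
        conc = {
            canon: df[col].to_numpy(dtype=float)
            for col, canon in aliases.items()
            if col in df.columns
        }
        if not conc:
            raise DomainError("no recognized species columns in DataFrame")
        series = AssaySeries(
            times=df["time_min"].to_numpy(dtype=float),
            concentrations=conc,
            condition=condition or AssayCondition(),
            assay_type=assay_type,
            label=label,
        )
        return cls(series)

    def fit(
        self,
        window: tuple[float, float] | None = None,
        trim_lag: bool = False,
    ) -> "BatchAssayResults":
        """Estimate all per-species rates; returns a results object."""
        rates = {
            sp: fit_rate(self.series, sp, window=window, trim_lag=trim_lag)
            for sp in self.series.species
        }
        return BatchAssayResults(self, rates)


class BatchAssayResults:
    """Fitted rates for one bottle, with the assay's headline stoichiometry.

    Attributes
    ----------
    rates : dict[str, RateEstimate]
        One estimate per measured species.
    """

    def __init__(self, model: BatchAssayModel, rates: dict[str, RateEstimate]):
        self.model = model
        self.rates = rates

    @property
    def series(self) -> AssaySeries:
        return self.model.series

    def ratio(self, numerator: str, denominator: str) -> StoichRatio:
        """Stoichiometric ratio of two fitted species rates."""
        return stoichiometric_ratio(self.rates[numerator], self.rates[denominator])

    @property
    def headline_ratio(self) -> StoichRatio | None:
        """The conventional ratio for the assay type (None if undefined)."""
        spec = _RATIO_FOR_ASSAY.get(self.series.assay_type)
        if spec is None:
            return None
        num, den, _ = spec
        if num not in self.rates or den not in self.rates:
            return None
        try:
            return self.ratio(num, den)
        except UndefinedRatioError:
            return None

    def to_dict(self) -> dict:
        """JSON-friendly report of rates, activities and the headline ratio."""
        out: dict = {
            "label": self.series.label,
            "assay_type": self.series.assay_type,
            "rates": {
                sp: {
                    "slope_mgN_L_h": est.slope,
                    "stderr_mgN_L_h": est.stderr,
                    "r_squared": est.r_squared,
                    "n_points": est.n_points,
                    "window_min": list(est.window),
                    "specific_rate_nmolN_mgprot_min": est.specific_rate,
                    "tss_rate_mgN_gTSS_h": est.tss_rate,
                    "detectable": est.detectable,
                }
                for sp, est in sorted(self.rates.items())
            },
        }
        hr = self.headline_ratio
        if hr is not None:
            out["ratio"] = {
                "name": _RATIO_FOR_ASSAY[self.series.assay_type][2],
                "value": hr.ratio,
                "stderr": hr.stderr,
            }
        return out

    def summary(self) -> str:
        """Plain-text summary table in the spirit of statsmodels results."""
        s = self.series
        lines = [
            "Batch assay rate estimates",
            "=" * 62,
            f"bottle: {s.label or '(unlabelled)'}   type: {s.assay_type}",
            f"pH {s.condition.pH}  T {s.condition.temperature_C} C  "
            f"n_times {len(s.times)}",
            "-" * 62,
            f"{'species':<8}{'rate mgN/L/h':>14}{'stderr':>10}{'r^2':>8}"
            f"{'nmolN/mgP/min':>16}",
        ]
        for sp, est in sorted(self.rates.items()):
            spec = f"{est.specific_rate:.3f}" if est.specific_rate is not None else "-"
            lines.append(
                f"{sp:<8}{est.slope:>14.3f}{est.stderr:>10.3f}"
                f"{est.r_squared:>8.3f}{spec:>16}"
            )
        hr = self.headline_ratio
        if hr is not None:
            name = _RATIO_FOR_ASSAY[s.assay_type][2]
            lines.append("-" * 62)
            lines.append(f"{name} = {hr.ratio:.3f} +/- {hr.stderr:.3f} (mol/mol)")
        lines.append("=" * 62)
        return "\n".join(lines)

    def plot(self, ax=None):
        """Measured points and fitted lines, one panel for all species."""
        from .plotting import plot_assay_fit

        return plot_assay_fit(self, ax=ax)


def read_assay_csv(
    path,
    condition: AssayCondition | None = None,
    assay_type: str = "AOB_aerobic",
    label: str = "",
) -> AssaySeries:
    """Read one bottle's time series from CSV.

    Expected header: ``time_min,TAN_mgN_L,TNN_mgN_L,NO3_mgN_L`` (any
    subset of the species columns; decimal point, comma separator,
    UTF-8).
    """
    df = pd.read_csv(path)
    model = BatchAssayModel.from_dataframe(
        df, condition=condition, assay_type=assay_type, label=label or str(path)
    )
    return model.series
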