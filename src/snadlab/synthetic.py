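"""Synthetic data with the statistical structure the analysis assumes.

Three generators, each deterministic for a fixed seed:

* :func:`simulate_assay` -- batch-assay time series from a multi-guild
  zero-order kinetic model with fixed stoichiometric coupling, substrate
  cut-off and Gaussian measurement noise.  Zero-order (initial-rate)
  kinetics is deliberate: short batch assays are analyzed as initial
  linear depletion, and half-saturation constants are not part of the
  model.
* :func:`sample_clone_library` -- a multinomial draw emulating random
  selection of clones from a library with known taxon proportions.
* :func:`evolve_sequences` -- sequences evolved along a known tree under
  the Jukes-Cantor substitution process, for exercising the distance
  and tree-building pipeline against a known truth.

Guild stoichiometries (per mol of the guild's primary substrate):

==============  ===========================  ==========================
guild           consumes                     produces
==============  ===========================  ==========================
AOB             1 TAN                        1 TNN
NOB             1 TNN                        1 NO3
anammox         1 TAN + R TNN (R = 1.32)     y NO3 (y = 0.26), rest N2
denit_NO3       1 NO3                        1 TNN
denit_NO2       1 TNN                        1 N2-N
==============  ===========================  ==========================

Nitrogen is conserved exactly in the noiseless model: TAN + TNN + NO3 +
cumulative N2-N is constant over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assay import AssaySeries
from .errors import DomainError
from .phylo import Alignment, PhyloTree, TreeNode
from .speciation import AssayCondition

__all__ = [
    "GuildConfig",
    "SimConfig",
    "SimulatedAssay",
    "simulate_assay",
    "sample_clone_library",
    "evolve_sequences",
    "ph_activity_factor",
]

GUILDS = ("AOB", "NOB", "anammox", "denit_NO3", "denit_NO2")

#: Default anammox nitrite/ammonium coupling (mol TNN per mol TAN).
ANAMMOX_R = 1.32
#: Default anammox nitrate yield (mol NO3-N per mol TAN); set 0 to disable.
ANAMMOX_NO3_YIELD = 0.26


@dataclass(frozen=True)
class GuildConfig:
    """One guild's volumetric rate and stoichiometric coupling.

    ``volumetric_rate`` is the conversion rate of the guild's primary
    substrate (TAN for AOB and anammox, TNN for NOB and denit_NO2, NO3
    for denit_NO3) in mg N/L/h.  ``anammox_R`` and ``anammox_no3_yield``
    apply to the anammox guild only.
    """

    guild: str
    volumetric_rate: float
    anammox_R: float = ANAMMOX_R
    anammox_no3_yield: float = ANAMMOX_NO3_YIELD

    def __post_init__(self) -> None:
        if self.guild not in GUILDS:
            raise DomainError(f"unknown guild {self.guild!r}; expected one of {GUILDS}")
        if self.volumetric_rate < 0:
            raise DomainError("volumetric_rate must be >= 0")
        if self.anammox_R <= 0:
            raise DomainError("anammox_R must be > 0")
        if self.anammox_no3_yield < 0:
            raise DomainError("anammox_no3_yield must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one simulated batch assay."""

    guilds: tuple[GuildConfig, ...]
    tan0: float = 0.0
    tnn0: float = 0.0
    no3_0: float = 0.0
    duration_min: float = 180.0
    sample_interval_min: float = 30.0
    noise_sd: float = 1.0
    seed: int | None = None
    condition: AssayCondition = field(default_factory=AssayCondition)
    assay_type: str = "AOB_aerobic"
    euler_step_min: float = 0.1

    def __post_init__(self) -> None:
        if self.duration_min <= 0 or self.sample_interval_min <= 0:
            raise DomainError("duration and sample interval must be > 0")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")
        if min(self.tan0, self.tnn0, self.no3_0) < 0:
            raise DomainError("initial concentrations must be >= 0")
        if not 0 < self.euler_step_min <= 0.1:
            raise DomainError("euler_step_min must be in (0, 0.1]")
        object.__setattr__(self, "guilds", tuple(self.guilds))


@dataclass(frozen=True)
class SimulatedAssay:
    """Noisy sampled series plus the retained noiseless truth."""

    series: AssaySeries
    truth: AssaySeries
    cumulative_n2: float  # mg N/L converted to N2 by the end of the run


def _guild_fluxes(g: GuildConfig, tan: float, tnn: float, no3: float):
    """(dTAN, dTNN, dNO3, dN2) in mg N/L/h, honouring substrate cut-off."""
    r = g.volumetric_rate
    if g.guild == "AOB":
        if tan <= 0:
            return 0.0, 0.0, 0.0, 0.0
        return -r, r, 0.0, 0.0
    if g.guild == "NOB":
        if tnn <= 0:
            return 0.0, 0.0, 0.0, 0.0
        return 0.0, -r, r, 0.0
    if g.guild == "anammox":
        if tan <= 0 or tnn <= 0:
            return 0.0, 0.0, 0.0, 0.0
        R, y = g.anammox_R, g.anammox_no3_yield
        return -r, -R * r, y * r, (1.0 + R - y) * r
    if g.guild == "denit_NO3":
        if no3 <= 0:
            return 0.0, 0.0, 0.0, 0.0
        return 0.0, r, -r, 0.0
    # denit_NO2
    if tnn <= 0:
        return 0.0, 0.0, 0.0, 0.0
    return 0.0, -r, 0.0, r


def simulate_assay(cfg: SimConfig) -> SimulatedAssay:
    """Forward-Euler integration of the multi-guild zero-order model.

    Integrates at steps of ``cfg.euler_step_min`` (<= 0.1 min); a
    guild's rate switches to zero whenever its substrate is exhausted,
    so concentrations never go negative.  Samples are taken every
    ``sample_interval_min``; noisy observations are truth +
    N(0, noise_sd^2), clipped at zero.  The noiseless truth is
    seed-independent and returned alongside.
    """
    times = np.arange(0.0, cfg.duration_min + 1e-9, cfg.sample_interval_min)
    n_steps = int(round(cfg.duration_min / cfg.euler_step_min))
    dt_h = cfg.euler_step_min / 60.0

    tan, tnn, no3, n2 = cfg.tan0, cfg.tnn0, cfg.no3_0, 0.0
    sample_idx = {round(t / cfg.euler_step_min): k for k, t in enumerate(times)}
    truth = np.zeros((len(times), 3))
    if 0 in sample_idx:
        truth[0] = (tan, tnn, no3)

    for step in range(1, n_steps + 1):
        remaining = dt_h
        # advance in sub-steps that stop exactly where a pool depletes,
        # so the substrate cut-off never drives a pool negative and
        # nitrogen stays conserved to rounding error
        for _ in range(4 * len(cfg.guilds) + 4):
            if remaining <= 0:
                break
            d_tan = d_tnn = d_no3 = d_n2 = 0.0
            for g in cfg.guilds:
                f = _guild_fluxes(g, tan, tnn, no3)
                d_tan += f[0]
                d_tnn += f[1]
                d_no3 += f[2]
                d_n2 += f[3]
            alpha = remaining
            for pool, flux in ((tan, d_tan), (tnn, d_tnn), (no3, d_no3)):
                if flux < 0 and pool + flux * alpha < 0:
                    alpha = pool / -flux
            tan += d_tan * alpha
            tnn += d_tnn * alpha
            no3 += d_no3 * alpha
            n2 += d_n2 * alpha
            tan, tnn, no3 = (max(0.0, x) for x in (tan, tnn, no3))
            remaining -= alpha
            if d_tan == d_tnn == d_no3 == d_n2 == 0.0:
                break  # nothing active; rest of the step is quiescent
        if not all(np.isfinite((tan, tnn, no3, n2))):
            raise FloatingPointError("non-finite concentration during integration")
        if step in sample_idx:
            truth[sample_idx[step]] = (tan, tnn, no3)

    rng = np.random.default_rng(cfg.seed)
    noisy = truth + rng.normal(0.0, cfg.noise_sd, size=truth.shape) if cfg.noise_sd > 0 else truth.copy()
    noisy = np.clip(noisy, 0.0, None)

    def mk(series_values: np.ndarray) -> AssaySeries:
        return AssaySeries(
            times=times,
            concentrations={
                "TAN": series_values[:, 0],
                "TNN": series_values[:, 1],
                "NO3N": series_values[:, 2],
            },
            condition=cfg.condition,
            assay_type=cfg.assay_type,
        )

    return SimulatedAssay(series=mk(noisy), truth=mk(truth), cumulative_n2=n2)


def ph_activity_factor(pH, optimum: float = 8.0, width: float = 1.5, floor: float = 0.0):
    """Piecewise-linear bell in pH for generating pH-profile fixtures.

    Activity multiplier: 1 at ``optimum``, falling linearly to ``floor``
    at ``optimum +/- width``.  A shape device for synthetic profiles,
    not a mechanistic pH model.
    """
    x = np.asarray(pH, dtype=float)
    f = np.maximum(floor, 1.0 - np.abs(x - optimum) / width * (1.0 - floor))
    return float(f) if np.isscalar(pH) else f


def sample_clone_library(proportions, n_clones: int, seed: int | None = None,
                         labels=None, marker: str = ""):
    """One multinomial clone-library draw with known taxon proportions.

    Returns a :class:`~snadlab.diversity.CloneCounts`; deterministic for
    a fixed seed.
    """
    from .diversity import CloneCounts

    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise DomainError("proportions must be non-negative and sum to 1")
    if n_clones < 1:
        raise DomainError("n_clones must be >= 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_clones, p / p.sum())
    if labels is None:
        labels = tuple(f"taxon_{i + 1}" for i in range(len(p)))
    return CloneCounts(labels=tuple(labels), counts=tuple(int(c) for c in counts), marker=marker)


def evolve_sequences(
    tree: PhyloTree,
    length: int,
    kind: str = "nt",
    seed: int | None = None,
) -> Alignment:
    """Evolve sequences along a tree under the Jukes-Cantor process.

    The root sequence is uniform over the alphabet; along each branch of
    length ``d`` (expected substitutions per site) every site is
    redrawn from the JC transition kernel for that duration, i.e. it
    differs from its parent with probability
    ``(K-1)/K * (1 - exp(-K d / (K-1)))`` for alphabet size K.
    Deterministic per seed.
    """
    if length < 1:
        raise DomainError("length must be >= 1")
    if kind not in ("nt", "aa"):
        raise DomainError("kind must be 'nt' or 'aa'")
    alphabet = "ACGT" if kind == "nt" else "ARNDCQEGHILKMFPSTWYV"
    k = len(alphabet)
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, k, size=length)

    out: dict[str, np.ndarray] = {}

    def walk(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            if child.length < 0:
                raise DomainError("branch lengths must be >= 0")
            # JC kernel: P(change) over branch d
            p_change = (k - 1) / k * (1.0 - np.exp(-k * child.length / (k - 1)))
            child_seq = seq.copy()
            mutate = rng.random(length) < p_change
            if mutate.any():
                # new state uniform over the other k-1 characters
                shift = rng.integers(1, k, size=int(mutate.sum()))
                child_seq[mutate] = (child_seq[mutate] + shift) % k
            if child.is_leaf:
                out[child.name] = child_seq
            else:
                walk(child, child_seq)

    walk(tree.root, root_seq)
    if not out:
        raise DomainError("tree has no leaves below the root")
    ids = tuple(sorted(out))
    rows = tuple("".join(alphabet[s] for s in out[i]) for i in ids)
    return Alignment(ids=ids, rows=rows, kind=kind)
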