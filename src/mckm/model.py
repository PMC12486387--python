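"""Core kinetic model of a GS-CHO fed-batch culture.

The model tracks eight state variables: viable cell concentration (``Xv``,
10^9 cells/L), product titre (``P``, g/L), glucose (``glc``, g/L), glutamine
(``gln``, mM), glutamate (``glu``, mM), ammonium (``amm``, mM), lactate
(``lac``, g/L) and an estimated specific growth rate (``mu_est``, 1/h) that
is carried as an additional state to constrain regression towards realistic
growth dynamics.

Growth follows Monod kinetics on glucose, the only growth-limiting
substrate in these glutamine-synthetase (GS) cultures; death follows a
Monod-type dependence on ammonium, the dominant cytotoxic by-product.
All other specific rates are growth-associated (Luedeking-Piret) with a
yield coefficient per metabolite, plus a glucose maintenance draw. Lactate
metabolism switches from overflow production to consumption when glucose
falls below a threshold ``alpha_glc``.

Units follow the bounds table (:data:`TABLE3`): glucose, lactate and titre
in gram units, amino species in mM, biomass in 10^9 cells/L, time in hours.
Conversion helpers for users with molar assay data are provided at the
bottom of the module.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "VARIABLE_NAMES",
    "N_PARAMS",
    "N_VARIABLES",
    "KineticParameters",
    "CultureState",
    "ModelConstants",
    "ParameterBounds",
    "RateVector",
    "TABLE3",
    "MCKMError",
    "InvalidParameterError",
    "SimulationError",
    "growth_rate",
    "death_rate",
    "specific_rates",
    "batch_rhs",
    "glucose_mm_to_g_per_l",
    "glucose_g_per_l_to_mm",
    "lactate_mm_to_g_per_l",
    "lactate_g_per_l_to_mm",
]


class MCKMError(Exception):
    """Base class for package errors."""


class InvalidParameterError(MCKMError, ValueError):
    """A kinetic-parameter vector violates its constraints."""


class SimulationError(MCKMError, RuntimeError):
    """ODE integration failed; carries the fed-batch interval index."""

    def __init__(self, message: str, interval: int | None = None):
        super().__init__(message)
        self.interval = interval


#: Canonical ordering of the 13 kinetic parameters.
PARAM_NAMES: tuple[str, ...] = (
    "mu_max",
    "k_d",
    "K_glc",
    "m_glc",
    "Y_X_glc",
    "Y_X_gln",
    "Y_X_glu",
    "Y_lac_glc",
    "Y_X_amm",
    "Y_gln_glu",
    "Y_X_lac",
    "Y_P_X",
    "KD_amm",
)
N_PARAMS = len(PARAM_NAMES)

#: Canonical ordering of the 8 model variables (7 measured + mu_est).
VARIABLE_NAMES: tuple[str, ...] = (
    "Xv",
    "P",
    "glc",
    "gln",
    "glu",
    "amm",
    "lac",
    "mu_est",
)
N_VARIABLES = len(VARIABLE_NAMES)

# Stoichiometric caps: at most 2 lactate per glucose (carbon balance of
# glycolysis) and at most 1 glutamine per glutamate (GS reaction).
_STOICH_CAPS = {"Y_lac_glc": 2.0, "Y_gln_glu": 1.0}


@dataclass(frozen=True)
class KineticParameters:
    """The 13-entry kinetic parameter vector theta.

    Attributes
    ----------
    mu_max : float
        Maximum specific growth rate [1/h].
    k_d : float
        Maximum specific death rate [1/h].
    K_glc : float
        Glucose half-saturation constant of growth [g/L].
    m_glc : float
        Glucose maintenance coefficient [g / (10^9 cells) / h].
    Y_X_glc, Y_X_gln, Y_X_glu, Y_X_amm, Y_X_lac : float
        Biomass yields on glucose [10^9 cells/g], glutamine
        [10^9 cells/mmol], glutamate [10^9 cells/mmol], ammonium
        [10^9 cells/mmol] and lactate [10^9 cells/g].
    Y_lac_glc : float
        Lactate yield on glucose [g/g], capped at 2 by stoichiometry.
    Y_gln_glu : float
        Glutamine yield on glutamate [mol/mol], capped at 1.
    Y_P_X : float
        Product yield on biomass [g / (10^9 cells)].
    KD_amm : float
        Ammonium half-saturation constant of death [mM].
    """

    mu_max: float
    k_d: float
    K_glc: float
    m_glc: float
    Y_X_glc: float
    Y_X_gln: float
    Y_X_glu: float
    Y_lac_glc: float
    Y_X_amm: float
    Y_gln_glu: float
    Y_X_lac: float
    Y_P_X: float
    KD_amm: float

    def __post_init__(self):
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise InvalidParameterError(f"{name} is not finite: {value!r}")
            if value < 0:
                raise InvalidParameterError(f"{name} must be non-negative, got {value}")
        for name, cap in _STOICH_CAPS.items():
            value = getattr(self, name)
            if value > cap * (1 + 1e-12):
                raise InvalidParameterError(
                    f"{name}={value} exceeds its stoichiometric cap of {cap}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta: Iterable[float]) -> "KineticParameters":
        values = np.asarray(list(theta), dtype=float)
        if values.shape != (N_PARAMS,):
            raise InvalidParameterError(
                f"expected {N_PARAMS} parameters, got shape {values.shape}"
            )
        return cls(**dict(zip(PARAM_NAMES, values)))

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "KineticParameters":
        return cls(**{n: float(mapping[n]) for n in PARAM_NAMES})

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}

    def replace(self, **kwargs) -> "KineticParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CultureState:
    """The 8 model variables at one instant (units as in module docstring)."""

    Xv: float
    P: float
    glc: float
    gln: float
    glu: float
    amm: float
    lac: float
    mu_est: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in VARIABLE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, state: Iterable[float]) -> "CultureState":
        values = np.asarray(list(state), dtype=float)
        if values.shape != (N_VARIABLES,):
            raise ValueError(f"expected {N_VARIABLES} states, got shape {values.shape}")
        return cls(**dict(zip(VARIABLE_NAMES, values)))

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in VARIABLE_NAMES}


@dataclass(frozen=True)
class ModelConstants:
    """Fixed model constants shared across culture runs.

    ``alpha_glc`` is the glucose concentration below which the culture
    switches from lactate production to lactate consumption. The shipped
    default of 0.5 g/L is a synthetic stand-in on the depletion scale set
    by typical K_glc estimates (0.5-1.05 g/L); fit it to your own data when
    the switch point matters.

    ``lactate_switch_as_printed`` flips the switch inequality so that the
    production branch is active below the threshold; it exists only for
    strict comparison against the originally printed piecewise form, which
    is inconsistent with the switch's biological direction.
    """

    alpha_glc: float = 0.5
    glc_F_in: float = 100.0
    glu_F_in: float = 70.0
    V0: float = 0.015
    lactate_switch_as_printed: bool = False

    def __post_init__(self):
        if self.alpha_glc <= 0:
            raise ValueError(f"alpha_glc must be positive, got {self.alpha_glc}")
        if self.V0 <= 0:
            raise ValueError(f"V0 must be positive, got {self.V0}")


#: Lower bound, default initial guess, upper bound per parameter.
#: mu_max and K_glc initial guesses are normally produced per run by the
#: Monod pre-regression; the entries here are the fallback midpoints.
TABLE3: dict[str, tuple[float, float, float]] = {
    "mu_max": (0.01, 0.055, 0.1),
    "k_d": (0.0001, 0.016, 0.1),
    "K_glc": (0.1, 5.05, 10.0),
    "m_glc": (0.0, 0.006192, 1.0),
    "Y_X_glc": (0.1, 1.0, 10.0),
    "Y_X_gln": (0.1, 0.974, 10.0),
    "Y_X_glu": (0.001, 1.0, 20.0),
    "Y_lac_glc": (0.1, 0.615, 2.0),
    "Y_X_amm": (0.1, 0.67, 20.0),
    "Y_gln_glu": (0.001, 0.7, 1.0),
    "Y_X_lac": (0.01, 2.7, 5.0),
    "Y_P_X": (0.0001, 0.2, 1.0),
    "KD_amm": (0.0, 5.0, 100.0),
}


@dataclass(frozen=True)
class ParameterBounds:
    """Box bounds and default initial guesses for the 13 parameters."""

    lb: np.ndarray
    ub: np.ndarray
    ig: np.ndarray

    def __post_init__(self):
        lb = np.asarray(self.lb, dtype=float)
        ub = np.asarray(self.ub, dtype=float)
        ig = np.asarray(self.ig, dtype=float)
        for name, arr in (("lb", lb), ("ub", ub), ("ig", ig)):
            if arr.shape != (N_PARAMS,):
                raise ValueError(f"{name} must have shape ({N_PARAMS},)")
        if np.any(lb > ig) or np.any(ig > ub):
            bad = [
                PARAM_NAMES[i]
                for i in range(N_PARAMS)
                if not (lb[i] <= ig[i] <= ub[i])
            ]
            raise ValueError(f"need lb <= ig <= ub elementwise; violated for {bad}")
        object.__setattr__(self, "lb", lb)
        object.__setattr__(self, "ub", ub)
        object.__setattr__(self, "ig", ig)

    @classmethod
    def default(cls) -> "ParameterBounds":
        lb, ig, ub = (np.array([TABLE3[n][k] for n in PARAM_NAMES]) for k in (0, 1, 2))
        return cls(lb=lb, ub=ub, ig=ig)

    def index(self, name: str) -> int:
        return PARAM_NAMES.index(name)

    def with_updates(
        self,
        lb: Mapping[str, float] | None = None,
        ub: Mapping[str, float] | None = None,
        ig: Mapping[str, float] | None = None,
    ) -> "ParameterBounds":
        """Return a copy with selected entries replaced by name."""
        new = {k: getattr(self, k).copy() for k in ("lb", "ub", "ig")}
        for key, updates in (("lb", lb), ("ub", ub), ("ig", ig)):
            for name, value in (updates or {}).items():
                new[key][PARAM_NAMES.index(name)] = value
        return ParameterBounds(**new)

    def clip(self, theta: np.ndarray) -> np.ndarray:
        return np.clip(np.asarray(theta, dtype=float), self.lb, self.ub)


@dataclass(frozen=True)
class RateVector:
    """Specific (per-cell) rates plus growth and death rates at one state."""

    q_P: float
    q_glc: float
    q_glu: float
    q_gln: float
    q_amm: float
    q_lac: float
    mu: float
    mu_d: float


def growth_rate(theta: KineticParameters, glc):
    """Monod growth rate on glucose, mu = mu_max * glc / (K_glc + glc) [1/h]."""
    glc = np.asarray(glc, dtype=float)
    if np.any(glc < 0):
        raise ValueError("glucose concentration must be non-negative")
    denom = theta.K_glc + glc
    with np.errstate(invalid="ignore"):
        mu = np.where(denom > 0, theta.mu_max * glc / np.where(denom > 0, denom, 1.0), 0.0)
    return float(mu) if mu.ndim == 0 else mu


def death_rate(theta: KineticParameters, amm):
    """Monod-type ammonium-driven death rate, mu_d = k_d*amm/(KD_amm+amm) [1/h]."""
    amm = np.asarray(amm, dtype=float)
    if np.any(amm < 0):
        raise ValueError("ammonium concentration must be non-negative")
    denom = theta.KD_amm + amm
    with np.errstate(invalid="ignore"):
        mu_d = np.where(denom > 0, theta.k_d * amm / np.where(denom > 0, denom, 1.0), 0.0)
    return float(mu_d) if mu_d.ndim == 0 else mu_d


def _check_yields(theta: KineticParameters) -> None:
    for name in ("Y_X_glc", "Y_X_gln", "Y_X_glu", "Y_X_amm", "Y_X_lac"):
        if getattr(theta, name) == 0:
            raise InvalidParameterError(f"{name} must be nonzero (appears in a quotient)")


def _lactate_production_active(glc: float, constants: ModelConstants) -> bool:
    # Overflow production while glucose is plentiful; consumption after
    # depletion. The printed-form flag flips the inequality.
    if constants.lactate_switch_as_printed:
        return glc < constants.alpha_glc
    return glc >= constants.alpha_glc


def specific_rates(
    theta: KineticParameters, state: CultureState, constants: ModelConstants
) -> RateVector:
    """Evaluate all specific rates at one state.

    All q's are per-cell rates (per 10^9 cells per hour); the ODE layer
    multiplies each by Xv exactly once.
    """
    _check_yields(theta)
    glc = max(state.glc, 0.0)
    amm = max(state.amm, 0.0)
    mu = growth_rate(theta, glc)
    mu_d = death_rate(theta, amm)
    q_P = mu * theta.Y_P_X
    # Maintenance draw vanishes once glucose is exhausted so that the clamp
    # at zero cannot source glucose from nothing.
    q_glc = mu / theta.Y_X_glc + (theta.m_glc if glc > 0 else 0.0)
    q_glu = mu / theta.Y_X_glu
    q_gln = mu / theta.Y_X_gln
    q_amm = mu / theta.Y_X_amm
    if _lactate_production_active(glc, constants):
        q_lac = theta.Y_lac_glc * q_glc
    else:
        q_lac = -mu / theta.Y_X_lac
    return RateVector(q_P, q_glc, q_glu, q_gln, q_amm, q_lac, mu, mu_d)


def _rhs_core(
    t: float,
    y: np.ndarray,
    p: np.ndarray,
    alpha_glc: float,
    switch_as_printed: bool,
) -> np.ndarray:
    """Scalar fast path of the batch right-hand side.

    ``p`` is the parameter vector in :data:`PARAM_NAMES` order. Negative
    state excursions are clamped to zero for rate evaluation; the
    maintenance glucose draw vanishes at glc = 0 so the clamp cannot
    source glucose from nothing.
    """
    (mu_max, k_d, K_glc, m_glc, Y_X_glc, Y_X_gln, Y_X_glu, Y_lac_glc,
     Y_X_amm, Y_gln_glu, Y_X_lac, Y_P_X, KD_amm) = p
    Xv = y[0] if y[0] > 0 else 0.0
    glc = y[2] if y[2] > 0 else 0.0
    amm = y[5] if y[5] > 0 else 0.0
    denom_g = K_glc + glc
    mu = mu_max * glc / denom_g if denom_g > 0 else 0.0
    denom_a = KD_amm + amm
    mu_d = k_d * amm / denom_a if denom_a > 0 else 0.0
    q_glc = mu / Y_X_glc + (m_glc if glc > 0 else 0.0)
    q_glu = mu / Y_X_glu
    production = (glc < alpha_glc) if switch_as_printed else (glc >= alpha_glc)
    q_lac = Y_lac_glc * q_glc if production else -mu / Y_X_lac
    dglc = -q_glc * Xv
    dmu_est = mu_max * dglc * K_glc / (denom_g * denom_g) if denom_g > 0 else 0.0
    return np.array(
        [
            (mu - mu_d) * Xv,
            mu * Y_P_X * Xv,
            dglc,
            (-mu / Y_X_gln + Y_gln_glu * q_glu) * Xv,
            -q_glu * Xv,
            (mu / Y_X_amm) * Xv,
            q_lac * Xv,
            dmu_est,
        ]
    )


def batch_rhs(
    t: float,
    y: np.ndarray,
    theta: KineticParameters,
    constants: ModelConstants,
) -> np.ndarray:
    """Right-hand side of the batch (feed-free) model, d(state)/dt.

    The state vector follows :data:`VARIABLE_NAMES`. Small negative
    excursions are clamped to zero for rate evaluation. The last equation
    propagates the estimated growth rate via the chain rule of the Monod
    law, d(mu_est)/dt = mu_max * (dglc/dt) * K_glc / (K_glc + glc)^2,
    which ties the mu_est state to the glucose balance during regression.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise SimulationError(f"non-finite state encountered at t={t}: {y}")
    _check_yields(theta)
    return _rhs_core(
        t,
        y,
        theta.as_array(),
        constants.alpha_glc,
        constants.lactate_switch_as_printed,
    )


# --- unit conversion helpers -------------------------------------------------

GLUCOSE_MW = 180.16  # g/mol
LACTATE_MW = 90.08  # g/mol


def glucose_mm_to_g_per_l(mm: float) -> float:
    return mm * GLUCOSE_MW / 1000.0


def glucose_g_per_l_to_mm(g_per_l: float) -> float:
    return g_per_l * 1000.0 / GLUCOSE_MW


def lactate_mm_to_g_per_l(mm: float) -> float:
    return mm * LACTATE_MW / 1000.0


def lactate_g_per_l_to_mm(g_per_l: float) -> float:
    return g_per_l * 1000.0 / LACTATE_MW
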