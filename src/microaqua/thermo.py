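"""Activity-coefficient models and the isoactivity liquid–liquid equilibrium.

The water solubility ("capacity") of an organic reaction medium and the water
activity a_W of its mixtures are computed from a symmetric multicomponent
Margules excess-Gibbs model

    G^E / (n RT) = Σ_{i<j} A_ij x_i x_j,     ln γ_k = Σ_j A_kj x_j − G^E/(nRT)

on a pure-liquid (Raoult) reference, so γ_i → 1 as x_i → 1.  The capacity is
the smallest mole fraction x on (0, 1] solving the isoactivity condition with
an (assumed nearly pure) aqueous phase,

    x · γ_water(x) = 1,

and a_W = x_water · γ_water for any mixture.  Pair parameters are calibrated
to solubility anchors (dissolved water in CPME ≈ 0.7 wt%); the model is
built to reproduce the signs and monotonicities of the system, not
quantum-chemistry-grade absolute predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import CalibrationError, ConvergenceError, DomainError, RegistryError
from .species import DEFAULT_SPECIES, WATER

__all__ = [
    "MixtureComposition",
    "ActivityModel",
    "PhaseSplit",
    "WaterState",
    "WaterCapacity",
    "activity_coefficients",
    "water_activity",
    "water_capacity",
    "lle_split",
    "calibrate_water_cpme",
    "default_model",
]


@dataclass(frozen=True)
class MixtureComposition:
    """Molar amounts of named species forming one liquid phase.

    Amounts are in mol; mole fractions are derived on demand.
    """

    amounts: Mapping[str, float]

    def __post_init__(self):
        amts = dict(self.amounts)
        if not amts:
            raise DomainError("empty composition")
        if any(v < 0 for v in amts.values()):
            raise DomainError("negative molar amount")
        if sum(amts.values()) <= 0:
            raise DomainError("at least one amount must be positive")
        object.__setattr__(self, "amounts", amts)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.amounts)

    @property
    def total(self) -> float:
        return sum(self.amounts.values())

    def mole_fractions(self) -> dict[str, float]:
        tot = self.total
        return {k: v / tot for k, v in self.amounts.items()}

    def x(self, name: str) -> float:
        return self.amounts.get(name, 0.0) / self.total

    def without(self, name: str) -> "MixtureComposition":
        rest = {k: v for k, v in self.amounts.items() if k != name and v > 0}
        return MixtureComposition(rest)

    def with_water(self, moles: float) -> "MixtureComposition":
        amts = dict(self.amounts)
        amts[WATER] = amts.get(WATER, 0.0) + moles
        return MixtureComposition(amts)


@dataclass(frozen=True)
class ActivityModel:
    """Parametrized γ-calculator on a pure-liquid (Raoult) reference.

    Parameters
    ----------
    kind : {"ideal", "margules"}
        ``ideal`` returns γ = 1 for every composition; ``margules`` uses the
        symmetric multicomponent form above.
    params : mapping
        Dimensionless pair interaction parameters A_ij keyed by frozenset
        pairs of species names; unspecified pairs default to 0, A_ii = 0.
    species : frozenset or None
        If given, the registry of species the model is defined for; unknown
        names are rejected.
    """

    kind: str = "ideal"
    params: Mapping[frozenset, float] = field(default_factory=dict)
    species: frozenset | None = None

    def __post_init__(self):
        if self.kind not in ("ideal", "margules"):
            raise DomainError(f"unknown model kind {self.kind!r}")
        for pair in self.params:
            if len(pair) != 2:
                raise DomainError(f"pair parameter key must name two species: {set(pair)}")

    @classmethod
    def ideal(cls) -> "ActivityModel":
        return cls(kind="ideal")

    @classmethod
    def margules(cls, pairs: Mapping, species=None) -> "ActivityModel":
        params = {frozenset(k): float(v) for k, v in pairs.items()}
        return cls(kind="margules", params=params,
                   species=frozenset(species) if species else None)

    def a(self, i: str, j: str) -> float:
        """Interaction parameter A_ij (= A_ji, A_ii = 0)."""
        if i == j:
            return 0.0
        return self.params.get(frozenset((i, j)), 0.0)

    def check_species(self, names: Sequence[str]) -> None:
        if self.species is not None:
            unknown = set(names) - self.species
            if unknown:
                raise RegistryError(f"species not in model registry: {sorted(unknown)}")

    def matrix(self, names: Sequence[str]) -> np.ndarray:
        n = len(names)
        A = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                A[i, j] = A[j, i] = self.a(names[i], names[j])
        return A

    def ln_gamma(self, names: Sequence[str], x: np.ndarray) -> np.ndarray:
        """ln γ for compositions ``x`` (shape (n,) or (n, m) column-wise)."""
        self.check_species(names)
        x = np.asarray(x, dtype=float)
        if self.kind == "ideal":
            return np.zeros_like(x)
        A = self.matrix(names)
        Ax = A @ x
        gE = np.sum(x * Ax, axis=0) / 2.0
        return Ax - gE


@dataclass(frozen=True)
class PhaseSplit:
    """Result of a two-phase liquid–liquid flash.

    ``split`` is False inside the single-phase region (then both phases,
    activities, and residual are None / nan).
    """

    split: bool
    phase_i: MixtureComposition | None = None
    phase_ii: MixtureComposition | None = None
    activities_i: dict | None = None
    activities_ii: dict | None = None
    residual: float = float("nan")
    beta: float = float("nan")  # mole fraction of the feed in phase II


@dataclass(frozen=True)
class WaterCapacity:
    """Saturation mole fraction of water in the organic phase."""

    x_sat: float
    miscible: bool = False  # True when no root < 1 exists (unbounded capacity)

    def __float__(self):
        return self.x_sat


@dataclass(frozen=True)
class WaterState:
    """Water capacity, inventory, and activity of one process state."""

    capacity: float          # saturation mole fraction of water
    available_water: float   # mol accessible to the organic phase
    a_w: float               # water activity in [0, 1]
    enzyme_inactive: bool = False  # flagged when no water is available


def activity_coefficients(comp: MixtureComposition, model: ActivityModel) -> dict[str, float]:
    """Per-species activity coefficients γ_i of a liquid mixture."""
    names = list(comp.species)
    x = np.array([comp.x(n) for n in names])
    ln_g = model.ln_gamma(names, x)
    return dict(zip(names, np.exp(ln_g)))


def water_activity(comp: MixtureComposition, model: ActivityModel, water: str = WATER) -> float:
    """Water activity a_W = x_water · γ_water (0 when water is absent)."""
    if model.species is not None and water not in model.species:
        raise RegistryError(f"{water!r} not in model registry")
    if comp.amounts.get(water, 0.0) == 0.0:
        return 0.0
    gam = activity_coefficients(comp, model)[water]
    return comp.x(water) * gam


def _ln_gamma_water_curve(z_names, z, model, xs, water=WATER):
    """ln γ_water over a grid of water mole fractions ``xs``.

    Solute mole fractions are rescaled to (1 − x)·z along the hydration path.
    """
    names = [water] + list(z_names)
    X = np.empty((len(names), len(xs)))
    X[0] = xs
    X[1:] = (1.0 - xs) * np.asarray(z)[:, None]
    return model.ln_gamma(names, X)[0]


def water_capacity(solute_mix: MixtureComposition, model: ActivityModel,
                   water: str = WATER, grid: int = 4096,
                   tol: float = 1e-10, max_iter: int = 200) -> WaterCapacity:
    """Saturation water mole fraction of a water-free solute mixture.

    Solves x · γ_water(x) = 1 for the smallest root on (0, 1], keeping the
    solutes in their given ratio; the coexisting aqueous phase is treated as
    pure water (activity 1).  Returns capacity 1 with ``miscible=True`` when
    no root below 1 exists.
    """
    if water in solute_mix.amounts and solute_mix.amounts[water] > 0:
        raise DomainError("solute mixture must be water-free")
    model.check_species([water, *solute_mix.species])
    z_names = list(solute_mix.species)
    z = np.array([solute_mix.x(n) for n in z_names])

    xs = np.linspace(1e-9, 1.0, grid)[:-1]  # exclude the trivial root at x = 1
    g = np.log(xs) + _ln_gamma_water_curve(z_names, z, model, xs, water)
    idx = np.flatnonzero(g >= 0.0)
    if idx.size == 0:
        return WaterCapacity(1.0, miscible=True)
    i = idx[0]
    if g[i] == 0.0:
        return WaterCapacity(float(xs[i]))

    def f(x):
        return float(np.log(x) + _ln_gamma_water_curve(z_names, z, model, np.array([x]), water)[0])

    lo = xs[i - 1] if i > 0 else 1e-12
    try:
        root = brentq(f, lo, xs[i], xtol=tol, maxiter=max_iter)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - defensive
        raise ConvergenceError(f"water-capacity root find failed: {exc}") from exc
    return WaterCapacity(float(root))


def _rachford_rice(z, K):
    """Phase-II fraction β solving Σ z_i (K_i − 1)/(1 + β(K_i − 1)) = 0."""
    def h(beta):
        return float(np.sum(z * (K - 1.0) / (1.0 + beta * (K - 1.0))))

    lo, hi = 1e-12, 1.0 - 1e-12
    h_lo, h_hi = h(lo), h(hi)
    if h_lo * h_hi > 0:
        return None
    return brentq(h, lo, hi, xtol=1e-14)


def lle_split(comp: MixtureComposition, model: ActivityModel,
              max_iter: int = 500, tol: float = 1e-12) -> PhaseSplit:
    """Two-phase isoactivity flash x_i^I γ_i^I = x_i^II γ_i^II.

    Successive substitution on activity-coefficient K-values with a
    Rachford–Rice inner solve, started from trial phases enriched in each
    component in turn.  A composition inside the single-phase region yields
    an explicit no-split result, never an exception.
    """
    names = list(comp.species)
    n = len(names)
    z = np.array([comp.x(m) for m in names])
    if model.kind == "ideal":
        return PhaseSplit(split=False)
    model.check_species(names)

    def lngam(x):
        return model.ln_gamma(names, x)

    for k in range(n):
        trial = 0.05 * z.copy()
        trial[k] += 0.95
        trial /= trial.sum()
        K = np.exp(lngam(z) - lngam(trial))
        converged = False
        for _ in range(max_iter):
            beta = _rachford_rice(z, K)
            if beta is None:
                break
            x1 = z / (1.0 + beta * (K - 1.0))
            x1 = np.clip(x1, 1e-300, None)
            x1 /= x1.sum()
            x2 = K * x1
            x2 = np.clip(x2, 1e-300, None)
            x2 /= x2.sum()
            K_new = np.exp(lngam(x1) - lngam(x2))
            if np.max(np.abs(np.log(K_new) - np.log(K))) < tol:
                K = K_new
                converged = True
                break
            K = K_new
        if not converged:
            continue
        if np.max(np.abs(x1 - x2)) < 1e-4:  # trivial (identical-phase) solution
            continue
        a1 = x1 * np.exp(lngam(x1))
        a2 = x2 * np.exp(lngam(x2))
        residual = float(np.max(np.abs(a1 - a2)))
        n_tot = comp.total
        phase_i = MixtureComposition(dict(zip(names, (1.0 - beta) * n_tot * x1)))
        phase_ii = MixtureComposition(dict(zip(names, beta * n_tot * x2)))
        return PhaseSplit(split=True, phase_i=phase_i, phase_ii=phase_ii,
                          activities_i=dict(zip(names, a1)),
                          activities_ii=dict(zip(names, a2)),
                          residual=residual, beta=float(beta))
    return PhaseSplit(split=False)


def calibrate_water_cpme(target_water_wt_fraction: float,
                         water: str = WATER, solvent: str = "CPME") -> float:
    """Margules A for the water–solvent pair from a saturation anchor.

    Converts the target dissolved-water mass fraction to a saturation mole
    fraction x and inverts the binary closed form x·e^{A(1−x)²} = 1, i.e.
    A = ln(1/x)/(1−x)².  Raises :class:`CalibrationError` when the target
    cannot be the smallest root of the isoactivity condition (full
    miscibility under the symmetric model).
    """
    w = target_water_wt_fraction
    if not 0.0 < w < 1.0:
        raise DomainError("mass fraction must lie in (0, 1)")
    m_w = DEFAULT_SPECIES[water].molar_mass
    m_s = DEFAULT_SPECIES[solvent].molar_mass
    x = (w / m_w) / (w / m_w + (1.0 - w) / m_s)
    A = np.log(1.0 / x) / (1.0 - x) ** 2
    if A <= 2.0:
        raise CalibrationError(
            f"target {w:.4g} implies full miscibility under the symmetric model (A = {A:.3g} ≤ 2)")
    # The target must sit on the rising branch below the local maximum of
    # x·e^{A(1−x)²}; otherwise the smallest root would not reproduce it.
    x_turn = 0.5 * (1.0 - np.sqrt(1.0 - 2.0 / A))
    if x > x_turn:
        raise CalibrationError(
            f"target saturation x = {x:.4g} is beyond the organic-branch turning point {x_turn:.4g}")
    model = ActivityModel.margules({(water, solvent): A})
    cap = water_capacity(MixtureComposition({solvent: 1.0}), model, water=water)
    if cap.miscible or abs(cap.x_sat - x) > 1e-6:
        raise CalibrationError("round-trip check failed")  # pragma: no cover - defensive
    return float(A)


#: Default water–solute pair parameters: water–CPME is calibrated at import
#: from the 0.7 wt% dissolved-water anchor; FA and 4VG values encode the
#: hydrophilicity ordering FA > 4VG > CPME (trend-level, config-overridable).
DEFAULT_PAIRS = {
    ("H2O", "FA"): 0.5,
    ("H2O", "4VG"): 2.0,
}


def default_model(water_wt_fraction_in_cpme: float = 0.007,
                  extra_pairs: Mapping | None = None) -> ActivityModel:
    """Margules model for the CPME/FA/4VG/water system with default anchors."""
    pairs = {("H2O", "CPME"): calibrate_water_cpme(water_wt_fraction_in_cpme)}
    pairs.update(DEFAULT_PAIRS)
    if extra_pairs:
        pairs.update(extra_pairs)
    return ActivityModel.margules(pairs, species=("H2O", "CPME", "FA", "4VG"))
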