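"""Mass-action reaction schemes and ODE simulation of aptamer-ligand binding.

A binding mechanism is written as a small set of elementary mass-action
reactions between named species (free receptor RNA, free ligand, intermediate
and final complexes, and optionally a binding-incompetent receptor state).
Five canonical one- and two-step mechanisms are shipped as presets
``model1`` .. ``model5``:

``model1``
    ``R + L <=> B`` — reversible one-step binding.
``model2``
    ``Ri <=> Ra``, ``Ra + L <=> B`` — conformational selection: only a
    preformed receptor state binds.
``model3``
    ``R + L -> I -> B`` — two consecutive irreversible steps.
``model4``
    ``R + L <=> I <=> B`` — reversible induced fit.
``model5``
    ``R + L <=> I -> B`` — induced fit with an irreversible final step.

Units are fixed package-wide: concentrations in uM, time in seconds,
unimolecular rates in 1/s and bimolecular rates in 1/(uM s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, SimulationError

logger = logging.getLogger(__name__)

#: Allowed species roles.
ROLES = frozenset(
    {"receptor", "ligand", "intermediate-complex", "final-complex", "inactive-receptor"}
)

#: Roles describing a 1:1 receptor-ligand complex.
COMPLEX_ROLES = frozenset({"intermediate-complex", "final-complex"})

#: Default integration tolerances.  The preset rate constants span roughly
#: 0.06/s to 23/s plus bimolecular terms up to ~200/s at 20 uM ligand, which
#: makes the systems mildly stiff; an implicit-capable integrator with tight
#: tolerances keeps conservation errors well below 1e-6 uM.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10

#: Negative concentrations larger (in magnitude) than this are a hard error;
#: smaller ones are integrator round-off and clamped to zero.
NEGATIVE_CLAMP = 1e-9


# ---------------------------------------------------------------------------
# Scheme data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Species:
    """A chemical species of a binding scheme."""

    name: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigurationError(
                f"unknown role {self.role!r} for species {self.name!r}; "
                f"expected one of {sorted(ROLES)}"
            )


@dataclass(frozen=True)
class Reaction:
    """An elementary mass-action reaction with unit stoichiometry.

    ``reverse_rate_symbol=None`` marks an irreversible step.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    forward_rate_symbol: str
    reverse_rate_symbol: str | None = None

    def __post_init__(self) -> None:
        for side, what in ((self.reactants, "reactants"), (self.products, "products")):
            if not 1 <= len(side) <= 2:
                raise ConfigurationError(
                    f"reaction must have 1 or 2 {what}, got {len(side)}"
                )


@dataclass(frozen=True)
class ReactionScheme:
    """A named set of species and elementary reactions."""

    id: str
    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"scheme {self.id!r}: species names not unique")
        ligands = [s for s in self.species if s.role == "ligand"]
        if len(ligands) != 1:
            raise ConfigurationError(
                f"scheme {self.id!r}: exactly one ligand species required, "
                f"found {len(ligands)}"
            )
        known = set(names)
        seen_symbols: set[str] = set()
        participating: set[str] = set()
        for rxn in self.reactions:
            for name in (*rxn.reactants, *rxn.products):
                if name not in known:
                    raise ConfigurationError(
                        f"scheme {self.id!r}: reaction references unknown "
                        f"species {name!r}"
                    )
                participating.add(name)
            for sym in filter(None, (rxn.forward_rate_symbol, rxn.reverse_rate_symbol)):
                if sym in seen_symbols:
                    raise ConfigurationError(
                        f"scheme {self.id!r}: rate symbol {sym!r} appears in more "
                        "than one reaction direction"
                    )
                seen_symbols.add(sym)
        orphans = known - participating
        if orphans:
            raise ConfigurationError(
                f"scheme {self.id!r}: species {sorted(orphans)} appear in no reaction"
            )

    # -- derived views ------------------------------------------------------

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    @property
    def ligand_name(self) -> str:
        return next(s.name for s in self.species if s.role == "ligand")

    @property
    def complex_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species if s.role in COMPLEX_ROLES)

    @property
    def rate_symbols(self) -> tuple[str, ...]:
        syms: list[str] = []
        for rxn in self.reactions:
            syms.append(rxn.forward_rate_symbol)
            if rxn.reverse_rate_symbol is not None:
                syms.append(rxn.reverse_rate_symbol)
        return tuple(syms)

    def composition(self, name: str) -> dict[str, int]:
        """Receptor/ligand content of one species (for conservation checks)."""
        role = next(s.role for s in self.species if s.name == name)
        if role == "ligand":
            return {"L": 1}
        if role in COMPLEX_ROLES:
            return {"R": 1, "L": 1}
        return {"R": 1}

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "species": [{"name": s.name, "role": s.role} for s in self.species],
            "reactions": [
                {
                    "reactants": list(r.reactants),
                    "products": list(r.products),
                    "forward_rate_symbol": r.forward_rate_symbol,
                    "reverse_rate_symbol": r.reverse_rate_symbol,
                }
                for r in self.reactions
            ],
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ReactionScheme":
        try:
            species = tuple(Species(s["name"], s["role"]) for s in payload["species"])
            reactions = tuple(
                Reaction(
                    tuple(r["reactants"]),
                    tuple(r["products"]),
                    r["forward_rate_symbol"],
                    r.get("reverse_rate_symbol"),
                )
                for r in payload["reactions"]
            )
            return cls(payload["id"], species, reactions)
        except KeyError as exc:  # pragma: no cover - defensive
            raise ConfigurationError(f"scheme config missing key {exc}") from exc


# Rate values are plain mappings from rate symbol to value; ``validate_rates``
# enforces completeness and non-negativity.
RateSet = Mapping[str, float]
ConcentrationState = Mapping[str, float]


def validate_rates(scheme: ReactionScheme, rates: RateSet) -> None:
    for sym in scheme.rate_symbols:
        if sym not in rates:
            raise ConfigurationError(
                f"scheme {scheme.id!r}: missing rate constant {sym!r}"
            )
        if rates[sym] < 0:
            raise ConfigurationError(
                f"scheme {scheme.id!r}: rate constant {sym!r} is negative "
                f"({rates[sym]})"
            )


# ---------------------------------------------------------------------------
# Built-in schemes
# ---------------------------------------------------------------------------

def _build_presets() -> dict[str, ReactionScheme]:
    R = Species("R", "receptor")
    L = Species("L", "ligand")
    I = Species("I", "intermediate-complex")
    B = Species("B", "final-complex")
    Ri = Species("Ri", "inactive-receptor")
    Ra = Species("Ra", "receptor")
    return {
        "model1": ReactionScheme(
            "model1", (R, L, B), (Reaction(("R", "L"), ("B",), "k1", "km1"),)
        ),
        "model2": ReactionScheme(
            "model2",
            (Ri, Ra, L, B),
            (
                Reaction(("Ri",), ("Ra",), "k_pre", "k_unpre"),
                Reaction(("Ra", "L"), ("B",), "k_on", "k_off"),
            ),
        ),
        "model3": ReactionScheme(
            "model3",
            (R, L, I, B),
            (
                Reaction(("R", "L"), ("I",), "k1"),
                Reaction(("I",), ("B",), "k2"),
            ),
        ),
        "model4": ReactionScheme(
            "model4",
            (R, L, I, B),
            (
                Reaction(("R", "L"), ("I",), "k1", "km1"),
                Reaction(("I",), ("B",), "k2", "km2"),
            ),
        ),
        "model5": ReactionScheme(
            "model5",
            (R, L, I, B),
            (
                Reaction(("R", "L"), ("I",), "k1", "km1"),
                Reaction(("I",), ("B",), "k2"),
            ),
        ),
    }


_PRESETS = _build_presets()

#: Mapping from internal rate symbols to conventional report labels.
#: Model 2 uses namespaced symbols internally because its preformation step
#: and binding step are conventionally both labelled k1/k-1, k2/k-2.
PAPER_SYMBOLS: dict[str, dict[str, str]] = {
    "model2": {"k_pre": "k1", "k_unpre": "k-1", "k_on": "k2", "k_off": "k-2"},
    "default": {"k1": "k1", "km1": "k-1", "k2": "k2", "km2": "k-2"},
}

SCHEME_IDS = tuple(sorted(_PRESETS))


def get_scheme(scheme_id: str) -> ReactionScheme:
    """Return a built-in scheme preset (``model1`` .. ``model5``)."""
    try:
        return _PRESETS[scheme_id]
    except KeyError:
        raise ConfigurationError(
            f"unknown scheme {scheme_id!r}; built-ins are {', '.join(SCHEME_IDS)}"
        ) from None


def _as_scheme(scheme: ReactionScheme | str) -> ReactionScheme:
    return get_scheme(scheme) if isinstance(scheme, str) else scheme


def paper_symbol(scheme: ReactionScheme | str, symbol: str) -> str:
    """Conventional label (k1, k-1, k2, k-2) for an internal rate symbol."""
    scheme = _as_scheme(scheme)
    table = PAPER_SYMBOLS.get(scheme.id, PAPER_SYMBOLS["default"])
    return table.get(symbol, symbol)


def initial_state(
    scheme: ReactionScheme | str,
    receptor_uM: float,
    ligand_uM: float,
    rates: RateSet | None = None,
) -> dict[str, float]:
    """Mixing-time initial condition: free receptor + free ligand, no complex.

    For the conformational-selection scheme (two receptor states) the total
    receptor is split according to the preformation equilibrium, which
    requires the rate set.
    """
    scheme = _as_scheme(scheme)
    state = {name: 0.0 for name in scheme.species_names}
    state[scheme.ligand_name] = float(ligand_uM)
    receptor_names = [
        s.name for s in scheme.species if s.role in ("receptor", "inactive-receptor")
    ]
    if len(receptor_names) == 1:
        state[receptor_names[0]] = float(receptor_uM)
        return state
    # Two receptor states: pre-equilibrate the (ligand-free) isomerization.
    if rates is None:
        raise ConfigurationError(
            f"scheme {scheme.id!r} has two receptor states; rates are required "
            "to split the initial receptor pool at the preformation equilibrium"
        )
    validate_rates(scheme, rates)
    iso = next(
        rxn
        for rxn in scheme.reactions
        if len(rxn.reactants) == 1 and len(rxn.products) == 1
    )
    k_f = rates[iso.forward_rate_symbol]
    k_r = rates[iso.reverse_rate_symbol] if iso.reverse_rate_symbol else 0.0
    total = k_f + k_r
    frac_product = 1.0 if total == 0 else k_f / total
    state[iso.products[0]] = float(receptor_uM) * frac_product
    state[iso.reactants[0]] = float(receptor_uM) * (1.0 - frac_product)
    return state


# ---------------------------------------------------------------------------
# ODE construction and simulation
# ---------------------------------------------------------------------------

def _compile_terms(
    scheme: ReactionScheme, rates: RateSet
) -> list[tuple[float, tuple[int, ...], np.ndarray]]:
    """Flatten the scheme into (rate, reactant indices, stoichiometry) terms."""
    index = {name: i for i, name in enumerate(scheme.species_names)}
    n = len(index)
    terms = []
    for rxn in scheme.reactions:
        delta = np.zeros(n)
        for name in rxn.reactants:
            delta[index[name]] -= 1.0
        for name in rxn.products:
            delta[index[name]] += 1.0
        terms.append(
            (float(rates[rxn.forward_rate_symbol]), tuple(index[r] for r in rxn.reactants), delta)
        )
        if rxn.reverse_rate_symbol is not None:
            terms.append(
                (
                    float(rates[rxn.reverse_rate_symbol]),
                    tuple(index[p] for p in rxn.products),
                    -delta,
                )
            )
    return terms


def _vector_rhs(
    scheme: ReactionScheme, rates: RateSet
) -> Callable[[float, np.ndarray], np.ndarray]:
    """RHS on arrays of shape (..., n_species); mass action with unit stoichiometry."""
    terms = _compile_terms(scheme, rates)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        for k, ridx, delta in terms:
            flux = k
            for i in ridx:
                flux = flux * y[..., i]
            dy += np.multiply.outer(flux, delta) if np.ndim(flux) else flux * delta
        return dy

    return rhs


def build_ode(
    scheme: ReactionScheme | str, rates: RateSet
) -> Callable[[float, ConcentrationState], dict[str, float]]:
    """Right-hand side of the mass-action ODE system as a state-dict function.

    Each reaction contributes ``±k · prod(reactant concentrations)`` to the
    derivative of every participating species.
    """
    scheme = _as_scheme(scheme)
    validate_rates(scheme, rates)
    names = scheme.species_names
    rhs = _vector_rhs(scheme, rates)

    def ode(t: float, state: ConcentrationState) -> dict[str, float]:
        y = np.array([state[name] for name in names], dtype=float)
        dy = rhs(t, y)
        return dict(zip(names, dy.tolist()))

    return ode


@dataclass
class SimulatedTrajectory:
    """Concentration time courses from one deterministic simulation."""

    time_s: np.ndarray
    concentrations: np.ndarray  # shape (n_times, n_species), uM
    species_names: tuple[str, ...]
    scheme_id: str
    rates: dict[str, float]
    initial: dict[str, float]

    def __getitem__(self, species: str) -> np.ndarray:
        return self.concentrations[:, self.species_names.index(species)]

    def state_at(self, i: int) -> dict[str, float]:
        return dict(zip(self.species_names, self.concentrations[i]))

    def to_dataframe(self):
        import pandas as pd

        data = {"time_s": self.time_s}
        for j, name in enumerate(self.species_names):
            data[name] = self.concentrations[:, j]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        """Write time_s plus one concentration column (uM) per species."""
        self.to_dataframe().to_csv(path, index=False)

    def conserved_totals(self) -> dict[str, np.ndarray]:
        """Total ligand and total receptor along the trajectory."""
        scheme = get_scheme(self.scheme_id) if self.scheme_id in _PRESETS else None
        if scheme is None:
            raise ConfigurationError(
                "conserved_totals requires a built-in scheme id on the trajectory"
            )
        totals = {"L": np.zeros_like(self.time_s), "R": np.zeros_like(self.time_s)}
        for j, name in enumerate(self.species_names):
            for elem, mult in scheme.composition(name).items():
                totals[elem] = totals[elem] + mult * self.concentrations[:, j]
        return totals


def _check_grid(time_grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(time_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ConfigurationError("time grid must be 1-D with at least two points")
    if grid[0] != 0:
        raise ConfigurationError("time grid must start at 0")
    if np.any(np.diff(grid) <= 0):
        raise ConfigurationError("time grid must be strictly increasing")
    return grid


def _clamp_negatives(y: np.ndarray, context: str) -> np.ndarray:
    worst = y.min()
    if worst < -NEGATIVE_CLAMP:
        raise SimulationError(
            f"{context}: integrator produced concentration {worst:.3e} uM "
            f"below -{NEGATIVE_CLAMP:g}"
        )
    if worst < 0:
        logger.debug("%s: clamping round-off negatives (min %.3e uM) to zero",
                     context, worst)
        y = np.where(y < 0, 0.0, y)
    return y


def simulate(
    scheme: ReactionScheme | str,
    rates: RateSet,
    initial: ConcentrationState,
    time_grid: Sequence[float],
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> SimulatedTrajectory:
    """Integrate the mass-action system on the given time grid."""
    scheme = _as_scheme(scheme)
    validate_rates(scheme, rates)
    grid = _check_grid(time_grid)
    names = scheme.species_names
    y0 = np.array([float(initial.get(name, 0.0)) for name in names])
    if np.any(y0 < 0):
        raise ConfigurationError("initial concentrations must be non-negative")
    rhs = _vector_rhs(scheme, rates)
    sol = solve_ivp(
        rhs, (grid[0], grid[-1]), y0, t_eval=grid, method="LSODA",
        rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise SimulationError(
            f"integration failed for scheme {scheme.id!r} with rates {dict(rates)}: "
            f"{sol.message}"
        )
    y = _clamp_negatives(sol.y.T, f"simulate({scheme.id})")
    return SimulatedTrajectory(
        time_s=grid,
        concentrations=y,
        species_names=names,
        scheme_id=scheme.id,
        rates={k: float(rates[k]) for k in scheme.rate_symbols},
        initial={name: float(initial.get(name, 0.0)) for name in names},
    )


def simulate_batch(
    scheme: ReactionScheme | str,
    rates: RateSet,
    initials: Sequence[ConcentrationState],
    time_grid: Sequence[float],
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> np.ndarray:
    """Integrate several initial conditions in one stacked system.

    The replicate systems are independent, so stacking them trades a single
    larger ODE solve for many small ones — the dominant cost in global fits.
    Returns an array of shape ``(n_times, n_batch, n_species)``.
    """
    scheme = _as_scheme(scheme)
    validate_rates(scheme, rates)
    grid = _check_grid(time_grid)
    names = scheme.species_names
    nb, ns = len(initials), len(names)
    y0 = np.array(
        [[float(init.get(name, 0.0)) for name in names] for init in initials]
    )
    if np.any(y0 < 0):
        raise ConfigurationError("initial concentrations must be non-negative")
    rhs = _vector_rhs(scheme, rates)

    def flat_rhs(t: float, y: np.ndarray) -> np.ndarray:
        return rhs(t, y.reshape(nb, ns)).ravel()

    sol = solve_ivp(
        flat_rhs, (grid[0], grid[-1]), y0.ravel(), t_eval=grid, method="LSODA",
        rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise SimulationError(
            f"batch integration failed for scheme {scheme.id!r} with rates "
            f"{dict(rates)}: {sol.message}"
        )
    y = sol.y.T.reshape(len(grid), nb, ns)
    return _clamp_negatives(y, f"simulate_batch({scheme.id})")


# ---------------------------------------------------------------------------
# Closed-form oracles and equilibrium algebra
# ---------------------------------------------------------------------------

def pfo_kobs(k1: float, k_minus1: float, L0: float) -> float:
    """Pseudo-first-order observed rate ``k_obs = k1*L0 + k_minus1`` (1/s)."""
    return k1 * L0 + k_minus1


def closed_form_model1_pfo(
    k1: float,
    k_minus1: float,
    L0: float,
    R0: float,
    time_grid: Sequence[float],
) -> np.ndarray:
    """Bound-complex time course of one-step binding under ligand excess.

    ``B(t) = B_eq (1 - exp(-k_obs t))`` with ``k_obs = k1 L0 + k_minus1`` and
    ``B_eq = R0 L0 / (L0 + k_minus1/k1)``.  Valid when the ligand stays
    effectively constant (L0 >> R0); enforced at L0 >= 2 R0 with a warning
    below 5 R0.
    """
    if k1 <= 0:
        raise ConfigurationError(f"k1 must be positive, got {k1}")
    if k_minus1 < 0:
        raise ConfigurationError(f"k_minus1 must be non-negative, got {k_minus1}")
    if L0 < 2 * R0:
        raise ConfigurationError(
            f"pseudo-first-order closed form requires L0 >= 2*R0 (got L0={L0}, R0={R0})"
        )
    if L0 < 5 * R0:
        logger.warning(
            "closed_form_model1_pfo: L0=%g is below 5*R0=%g; pseudo-first-order "
            "approximation is marginal", L0, 5 * R0,
        )
    grid = np.asarray(time_grid, dtype=float)
    k_obs = pfo_kobs(k1, k_minus1, L0)
    b_eq = R0 * L0 / (L0 + k_minus1 / k1)
    return b_eq * (1.0 - np.exp(-k_obs * grid))


def apparent_kd(scheme: ReactionScheme | str, rates: RateSet) -> float:
    """Overall equilibrium dissociation constant of a scheme (uM).

    One-step binding gives ``km1/k1``; the reversible two-step mechanism gives
    ``(km1/k1) * (km2/(k2+km2))`` (the second step pulls the equilibrium
    toward the final complex).  Mechanisms with an irreversible sink have a
    vanishing equilibrium dissociation constant and return 0.
    """
    scheme = _as_scheme(scheme)
    validate_rates(scheme, rates)
    if scheme.id == "model1":
        return rates["km1"] / rates["k1"]
    if scheme.id == "model4":
        return (rates["km1"] / rates["k1"]) * (
            rates["km2"] / (rates["k2"] + rates["km2"])
        )
    if scheme.id in ("model3", "model5"):
        return 0.0
    if scheme.id == "model2":
        raise ConfigurationError(
            "apparent_kd is unsupported for the conformational-selection scheme: "
            "the overall dissociation constant depends on the inactive receptor "
            "fraction (k_pre/k_unpre), not on the binding step alone"
        )
    raise ConfigurationError(
        f"apparent_kd has no closed form for user-defined scheme {scheme.id!r}"
    )
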