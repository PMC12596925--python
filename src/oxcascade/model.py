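"""Reaction networks for the sequential side-chain oxidation cascade.

The cascade oxidizes a 5-hydroxymethyl pyrimidine (``5hm``) to the 5-formyl
derivative (``5f``) and onward to the 5-carboxyl end product (``5ca``) using a
biomimetic iron(IV)-oxido oxidant (``TM1``, reduced form ``TM2``).  The formyl
species sits in a hydration equilibrium with its geminal diol (``5dhm``),
which opens two routes for the second oxidation step:

* ``DIRECT``        – the aldehyde itself is oxidized (rate constant ``k_f``);
* ``HYDRATE_ROUTE`` – only the hydrate is oxidized (``k_dhm``), fed through a
  fast hydration equilibrium ``5f + H2O <-> 5dhm``;
* ``DUAL``          – both channels are active (poorly conditioned; kept for
  completeness).

All oxidation steps are elementary second-order reactions consuming one TM1
and releasing one TM2 per event, and TM1 additionally self-deactivates by a
slow first-order path (``k_TM``).  Water is treated as a constant reservoir
(55.5 mol/L) and never enters the dynamic state.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

#: Molar concentration of neat water, mol/L.
WATER_CONC = 55.5

#: Default fast hydration forward rate constant, L mol^-1 s^-1.
DEFAULT_K_FOR = 1000.0


class Variant(str, enum.Enum):
    """Topology of the second oxidation step."""

    DIRECT = "direct"
    HYDRATE_ROUTE = "hydrate_route"
    DUAL = "dual"

    @property
    def uses_hydrate(self) -> bool:
        return self is not Variant.DIRECT


class SimulationError(RuntimeError):
    """Raised when the ODE integrator fails or produces unphysical output."""


@dataclass(frozen=True)
class SpeciesRole:
    """A chemical species and the role it plays in the cascade."""

    name: str
    role: str

    _ROLES = frozenset(
        {
            "substrate_5hm",
            "aldehyde_5f",
            "hydrate_5dhm",
            "acid_5ca",
            "oxidant_TM1",
            "reduced_TM2",
            "water",
        }
    )

    def __post_init__(self) -> None:
        if self.role not in self._ROLES:
            raise ValueError(f"unknown species role {self.role!r}")


@dataclass(frozen=True)
class RateParameters:
    """Rate-constant vector of the cascade.

    Units: ``k_TM`` and ``k_rev`` are first order (1/s); all other constants
    are second order (L mol^-1 s^-1).
    """

    k_TM: float = 0.0
    k_hm: float = 0.0
    k_f: float = 0.0
    k_dhm: float = 0.0
    k_for: float = 0.0
    k_rev: float = 0.0

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if value < 0 or not np.isfinite(value):
                raise ValueError(f"rate constant {name} must be finite and >= 0, got {value}")

    def as_dict(self) -> dict[str, float]:
        return {
            "k_TM": self.k_TM,
            "k_hm": self.k_hm,
            "k_f": self.k_f,
            "k_dhm": self.k_dhm,
            "k_for": self.k_for,
            "k_rev": self.k_rev,
        }

    def replace(self, **kwargs: float) -> "RateParameters":
        return replace(self, **kwargs)


#: Canonical species names, indexed by role.
SPECIES_BY_ROLE = {
    "substrate_5hm": "5hm",
    "aldehyde_5f": "5f",
    "hydrate_5dhm": "5dhm",
    "acid_5ca": "5ca",
    "oxidant_TM1": "TM1",
    "reduced_TM2": "TM2",
}

NUCLEOBASE_SPECIES = ("5hm", "5f", "5dhm", "5ca")
OXIDANT_SPECIES = ("TM1", "TM2")


@dataclass(frozen=True)
class KineticModel:
    """A fully parameterized oxidation-cascade network.

    ``reduced=True`` marks the rapid-pre-equilibrium form in which the
    aldehyde/hydrate pair is replaced by a single pool state partitioned
    algebraically by the equilibrium hydrate fraction.
    """

    variant: Variant
    params: RateParameters
    K: float | None = None
    water_conc: float = WATER_CONC
    oxidant_clamped: bool = False
    reduced: bool = False

    def __post_init__(self) -> None:
        if self.variant.uses_hydrate:
            if self.K is None:
                raise ValueError(f"{self.variant.value} variant requires a hydration constant K")
            if self.K < 0:
                raise ValueError("K must be >= 0")
            if self.params.k_rev > 0:
                ratio = self.params.k_for / self.params.k_rev
                if abs(ratio - self.K) > 1e-12 * max(self.K, 1e-300):
                    raise ValueError(
                        f"k_for/k_rev = {ratio} does not reproduce K = {self.K}"
                    )
            if self.variant is Variant.HYDRATE_ROUTE and self.params.k_f != 0.0:
                raise ValueError("HYDRATE_ROUTE sets k_f = 0; use DUAL for both channels")
        if self.water_conc <= 0:
            raise ValueError("water_conc must be > 0")

    # -- species bookkeeping -------------------------------------------------

    @property
    def state_species(self) -> tuple[str, ...]:
        """Names of the dynamic states, in integration order."""
        if self.reduced:
            return ("5hm", "5f_pool", "5ca", "TM1", "TM2")
        if self.variant.uses_hydrate:
            return ("5hm", "5f", "5dhm", "5ca", "TM1", "TM2")
        return ("5hm", "5f", "5ca", "TM1", "TM2")

    @property
    def output_species(self) -> tuple[str, ...]:
        """Names of the reported concentration columns (pool expanded)."""
        if self.variant.uses_hydrate:
            return ("5hm", "5f", "5dhm", "5ca", "TM1", "TM2")
        return ("5hm", "5f", "5ca", "TM1", "TM2")

    @property
    def species(self) -> tuple[SpeciesRole, ...]:
        roles = {v: k for k, v in SPECIES_BY_ROLE.items()}
        return tuple(SpeciesRole(n, roles[n]) for n in self.output_species)

    @property
    def hydrate_fraction(self) -> float:
        """Equilibrium fraction of the formyl pool present as hydrate."""
        if not self.variant.uses_hydrate or self.K is None:
            return 0.0
        kw = self.K * self.water_conc
        return kw / (1.0 + kw)

    # -- right-hand side -----------------------------------------------------

    def derivatives(self, state: np.ndarray) -> np.ndarray:
        """d[X]/dt for every dynamic state, mol L^-1 s^-1."""
        state = np.asarray(state, dtype=float)
        if state.shape != (len(self.state_species),):
            raise ValueError(
                f"state must have length {len(self.state_species)}, got {state.shape}"
            )
        p = self.params
        if self.reduced:
            hm, pool, ca, tm1, tm2 = state
            f_hyd = self.hydrate_fraction
            k_pool = p.k_dhm * f_hyd + p.k_f * (1.0 - f_hyd)
            r0 = p.k_TM * tm1
            r1 = p.k_hm * tm1 * hm
            r2 = k_pool * tm1 * pool
            d_tm1 = 0.0 if self.oxidant_clamped else -(r0 + r1 + r2)
            d_tm2 = 0.0 if self.oxidant_clamped else (r0 + r1 + r2)
            return np.array([-r1, r1 - r2, r2, d_tm1, d_tm2])
        if self.variant.uses_hydrate:
            hm, f, dhm, ca, tm1, tm2 = state
            r0 = p.k_TM * tm1
            r1 = p.k_hm * tm1 * hm
            r_hyd = p.k_for * f * self.water_conc - p.k_rev * dhm
            r2f = p.k_f * tm1 * f
            r2d = p.k_dhm * tm1 * dhm
            d_tm1 = 0.0 if self.oxidant_clamped else -(r0 + r1 + r2f + r2d)
            d_tm2 = 0.0 if self.oxidant_clamped else (r0 + r1 + r2f + r2d)
            return np.array(
                [-r1, r1 - r_hyd - r2f, r_hyd - r2d, r2f + r2d, d_tm1, d_tm2]
            )
        hm, f, ca, tm1, tm2 = state
        r0 = p.k_TM * tm1
        r1 = p.k_hm * tm1 * hm
        r2 = p.k_f * tm1 * f
        d_tm1 = 0.0 if self.oxidant_clamped else -(r0 + r1 + r2)
        d_tm2 = 0.0 if self.oxidant_clamped else (r0 + r1 + r2)
        return np.array([-r1, r1 - r2, r2, d_tm1, d_tm2])


@dataclass
class TimeCourse:
    """Sampled species concentrations versus time.

    ``frame`` holds a ``time_s`` column plus one mol/L column per species.
    """

    frame: pd.DataFrame
    provenance: str = "simulated"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "time_s" not in self.frame.columns:
            raise ValueError("TimeCourse frame requires a 'time_s' column")
        t = self.times
        if len(t) < 2:
            raise ValueError("TimeCourse requires at least two time points")
        if t[0] < 0:
            raise ValueError("times must be >= 0")
        if not np.all(np.diff(t) > 0):
            bad = np.where(np.diff(t) <= 0)[0] + 1
            raise ValueError(f"times must be strictly increasing; offending rows: {bad.tolist()}")
        if self.provenance not in ("measured", "simulated"):
            raise ValueError("provenance must be 'measured' or 'simulated'")

    @property
    def times(self) -> np.ndarray:
        return self.frame["time_s"].to_numpy(dtype=float)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(c for c in self.frame.columns if c != "time_s")

    def conc(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy(dtype=float)

    def subset(self, species: Sequence[str]) -> "TimeCourse":
        cols = ["time_s"] + [s for s in species if s in self.frame.columns]
        return TimeCourse(self.frame[cols].copy(), self.provenance, dict(self.meta))


def build_cascade(
    variant: Variant | str,
    params: RateParameters,
    K: float | None = None,
    *,
    water_conc: float = WATER_CONC,
    oxidant_clamped: bool = False,
) -> KineticModel:
    """Assemble a cascade network, deriving ``k_rev`` from ``k_for`` and K.

    The hydration equilibrium constant follows the ``K = k_for / k_rev``
    convention with the forward rate law first order in water, so
    ``k_rev = k_for / K``.  ``k_rev`` is always derived, never set directly.
    """
    variant = Variant(variant)
    if variant.uses_hydrate:
        if K is None:
            raise ValueError(f"variant {variant.value} requires a hydration constant K")
        if K < 0:
            raise ValueError("K must be >= 0")
        if K > 0:
            params = params.replace(k_rev=params.k_for / K)
        else:
            # K = 0: no hydrate ever forms; drop the hydration channel.
            params = params.replace(k_for=0.0, k_rev=0.0)
        if variant is Variant.HYDRATE_ROUTE:
            params = params.replace(k_f=0.0)
    else:
        params = params.replace(k_for=0.0, k_rev=0.0, k_dhm=0.0)
        K = None
    return KineticModel(
        variant=variant,
        params=params,
        K=K,
        water_conc=water_conc,
        oxidant_clamped=oxidant_clamped,
    )


def derivatives(model: KineticModel, state: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`KineticModel.derivatives`."""
    return model.derivatives(state)


def reduce_rapid_equilibrium(model: KineticModel) -> KineticModel:
    """Collapse the fast hydration equilibrium into a single formyl pool.

    The aldehyde and its hydrate are replaced by one state whose oxidation
    rate constant is the equilibrium-weighted average
    ``k_dhm * f + k_f * (1 - f)`` with hydrate fraction
    ``f = K*[H2O] / (1 + K*[H2O])``.  Valid whenever hydration equilibrates
    much faster than oxidation (k_for >~ 1000 L mol^-1 s^-1 here).
    """
    if not model.variant.uses_hydrate:
        raise ValueError("rapid-equilibrium reduction applies only to hydrate-aware variants")
    return replace(model, reduced=True)


def _initial_state(model: KineticModel, init: Mapping[str, float]) -> np.ndarray:
    known = set(model.output_species) | {"5f_pool"}
    for name in init:
        if name not in known:
            raise ValueError(f"unknown species {name!r} in initial state")
    y0 = []
    for name in model.state_species:
        if name == "5f_pool":
            v = init.get("5f_pool", init.get("5f", 0.0) + init.get("5dhm", 0.0))
        else:
            v = init.get(name, 0.0)
        if v < 0:
            raise ValueError(f"negative initial concentration for {name}")
        y0.append(float(v))
    return np.array(y0)


def simulate(
    model: KineticModel,
    init: Mapping[str, float],
    times: Sequence[float],
    *,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
    provenance: str = "simulated",
) -> TimeCourse:
    """Integrate the cascade ODEs and sample the trajectory at ``times``.

    A stiff-capable solver is required: with the explicit hydration
    equilibrium the reverse rate constant reaches ~1e7 1/s while the
    oxidation evolves over a day.  Small negative excursions (|x| < atol)
    are clipped to zero; anything larger is treated as an integration
    failure rather than silently truncated.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 2:
        raise ValueError("times must be a 1-D grid with at least two points")
    if times[0] < 0 or not np.all(np.diff(times) > 0):
        raise ValueError("times must be non-negative and strictly increasing")
    y0 = _initial_state(model, init)
    sol = solve_ivp(
        lambda t, y: model.derivatives(y),
        (0.0, float(times[-1])),
        y0,
        t_eval=times,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SimulationError(f"ODE integration failed: {sol.message}")
    y = sol.y
    negative = y < 0
    if negative.any():
        worst = y[negative].min()
        if -worst >= 100 * atol:
            raise SimulationError(
                f"integration produced a negative concentration {worst:.3e} mol/L "
                f"beyond the clipping threshold {100 * atol:.1e}"
            )
        y = np.where(negative, 0.0, y)

    data = {"time_s": times}
    if model.reduced:
        f_hyd = model.hydrate_fraction
        idx = {s: i for i, s in enumerate(model.state_species)}
        data["5hm"] = y[idx["5hm"]]
        data["5f"] = y[idx["5f_pool"]] * (1.0 - f_hyd)
        data["5dhm"] = y[idx["5f_pool"]] * f_hyd
        data["5ca"] = y[idx["5ca"]]
        data["TM1"] = y[idx["TM1"]]
        data["TM2"] = y[idx["TM2"]]
    else:
        for i, s in enumerate(model.state_species):
            data[s] = y[i]
    meta = {
        "init": {k: float(v) for k, v in init.items()},
        "variant": model.variant.value,
        "params": model.params.as_dict(),
        "K": model.K,
        "water_conc": model.water_conc,
        "reduced": model.reduced,
        "rtol": rtol,
        "atol": atol,
    }
    return TimeCourse(pd.DataFrame(data), provenance=provenance, meta=meta)
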