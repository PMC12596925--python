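"""Aldehyde-hydration equilibrium arithmetic.

The geminal-diol (hydrate) content of a formyl nucleobase is governed by the
equilibrium ``5f + H2O <-> 5dhm`` with constant ``K = [5dhm]/([5f][H2O])`` in
L/mol.  With water effectively constant at 55.5 mol/L the hydrate fraction of
the formyl pool is ``f = K*[H2O] / (1 + K*[H2O])``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import WATER_CONC

#: Default ratio by which uracil derivatives hydrate more readily than their
#: cytosine analogues.
URACIL_HYDRATION_FACTOR = 20.0


def hydrate_fraction(K: float, water_conc: float = WATER_CONC) -> float:
    """Equilibrium fraction of the formyl pool present as hydrate.

    Parameters
    ----------
    K : hydration equilibrium constant, L/mol (>= 0).
    water_conc : water concentration, mol/L (> 0).
    """
    if K < 0:
        raise ValueError("K must be >= 0")
    if water_conc <= 0:
        raise ValueError("water_conc must be > 0")
    kw = K * water_conc
    return kw / (1.0 + kw)


def ratio_from_fraction(fraction: float) -> float:
    """Hydrate:aldehyde concentration ratio from the hydrate fraction."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    return fraction / (1.0 - fraction)


def K_from_ratio(ratio_hydrate_to_aldehyde: float, water_conc: float = WATER_CONC) -> float:
    """Equilibrium constant from an observed hydrate:aldehyde ratio.

    Inverse of :func:`hydrate_fraction` composed with ``ratio = f/(1-f)``:
    ``K = ratio / [H2O]``.
    """
    if ratio_hydrate_to_aldehyde < 0:
        raise ValueError("ratio must be >= 0")
    if water_conc <= 0:
        raise ValueError("water_conc must be > 0")
    return ratio_hydrate_to_aldehyde / water_conc


def extrapolate_uracil_K(K_cytosine: float, factor: float = URACIL_HYDRATION_FACTOR) -> float:
    """Extrapolate a uracil-family K from the cytosine analogue's value.

    Uracil derivatives hydrate roughly ``factor``-fold (default 20) more
    readily than the corresponding cytosines.
    """
    if K_cytosine <= 0 or factor <= 0:
        raise ValueError("K_cytosine and factor must be > 0")
    return K_cytosine * factor


def average_K_from_detection_limits(K_lod: float, K_loq: float) -> float:
    """Arithmetic mean of K estimates from NMR detection and quantification limits.

    Used when the hydrate signal never rises above the quantification
    threshold, so only bracketing estimates of K exist.
    """
    if K_lod <= 0 or K_loq <= 0:
        raise ValueError("both K estimates must be > 0")
    return 0.5 * (K_lod + K_loq)


@dataclass(frozen=True)
class HydrationEquilibrium:
    """A hydration equilibrium and its derived hydrate fraction."""

    K: float
    water_conc: float = WATER_CONC

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError("K must be >= 0")
        if self.water_conc <= 0:
            raise ValueError("water_conc must be > 0")

    @property
    def fraction_hydrate(self) -> float:
        return hydrate_fraction(self.K, self.water_conc)

    @property
    def ratio_hydrate_to_aldehyde(self) -> float:
        return ratio_from_fraction(self.fraction_hydrate)

    @property
    def percent_hydrate(self) -> int:
        """Hydrate content rounded to the nearest integer percent."""
        return round(self.fraction_hydrate * 100.0)

    @classmethod
    def from_ratio(cls, ratio: float, water_conc: float = WATER_CONC) -> "HydrationEquilibrium":
        return cls(K_from_ratio(ratio, water_conc), water_conc)

    @classmethod
    def from_fraction(cls, fraction: float, water_conc: float = WATER_CONC) -> "HydrationEquilibrium":
        return cls(K_from_ratio(ratio_from_fraction(fraction), water_conc), water_conc)
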