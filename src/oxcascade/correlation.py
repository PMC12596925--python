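"""Linear free-energy analysis: ln k versus C-H bond dissociation energy.

If hydrogen-atom transfer is rate-limiting, the logarithm of the second-order
oxidation rate constant should correlate inversely with the homolytic
BDE(C-H) of the abstracted bond.  This module regresses ln k on BDE within
user-defined series (hydroxymethyl, formyl, hydrate, previous-study methyl
records) by ordinary least squares.

``ln_k`` is always recomputed from ``k`` at full precision; rounded
literature ln k columns are only used as a transcription cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

SERIES_TAGS = ("hm", "f", "dhm", "methyl_prev")


@dataclass(frozen=True)
class BDERecord:
    """One (nucleobase, BDE, rate constant) record.

    ``inferred`` marks rate constants that were not directly measured but
    back-calculated through a hydration equilibrium (reported in parentheses
    in the source tables).
    """

    base: str
    bde: float  # kJ/mol
    k: float  # L mol^-1 s^-1
    series: str
    inferred: bool = False

    def __post_init__(self) -> None:
        if self.series not in SERIES_TAGS:
            raise ValueError(f"unknown series tag {self.series!r}")
        if self.k <= 0:
            raise ValueError(f"rate constant must be > 0 to take ln k (base {self.base})")

    @property
    def ln_k(self) -> float:
        return math.log(self.k)


@dataclass(frozen=True)
class CorrelationResult:
    """OLS line of ln k on BDE: slope (per kJ/mol), intercept, R^2."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")


def lnk_bde_regression(records: Sequence[BDERecord]) -> CorrelationResult:
    """Ordinary least-squares regression of ln k on BDE(C-H).

    R^2 is the squared Pearson correlation of the (BDE, ln k) pairs.  An
    inverse (negative-slope) relationship is expected for HAT-limited
    oxidations but not enforced.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("regression requires at least two records")
    bde = np.array([r.bde for r in records])
    lnk = np.array([r.ln_k for r in records])
    if np.unique(bde).size < 2:
        raise ValueError("regression requires at least two distinct BDE values")
    fit = stats.linregress(bde, lnk)
    return CorrelationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(records),
        members=tuple(r.base for r in records),
    )


def predict_lnk(corr: CorrelationResult, bde: float) -> float:
    """Evaluate the fitted free-energy line at a BDE value."""
    return corr.slope * bde + corr.intercept


def select_series(records: Iterable[BDERecord], *series: str) -> list[BDERecord]:
    """Filter records by series tag, preserving order."""
    for tag in series:
        if tag not in SERIES_TAGS:
            raise ValueError(f"unknown series tag {tag!r}")
    wanted = set(series)
    return [r for r in records if r.series in wanted]
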