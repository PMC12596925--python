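"""Rate-constant estimation from oxidation time courses.

The estimation protocol mirrors how the cascade data are analysed in
practice:

* **step 1** fits the first oxidation constant (``k_hm``) and a free initial
  substrate concentration against the substrate decay alone;
* **step 2** fixes the step-1 constant and fits the second-step constant
  (``k_f`` on the direct route, ``k_dhm`` on the hydrate route) against all
  tracked species except the final acid, whose quantification is unreliable;
* the two steps are iterated to a fixed point because the substrate decay is
  coupled to the second step through oxidant consumption;
* samples at very long reaction times (t >= 86,400 s by default) are dropped
  from every objective.

Fits are bound-constrained nonlinear least squares with multiple log-spaced
starts; parameter standard deviations come from the linearized (Gauss-Newton)
covariance scaled by the residual variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .model import (
    KineticModel,
    RateParameters,
    SimulationError,
    TimeCourse,
    Variant,
    build_cascade,
    reduce_rapid_equilibrium,
    simulate,
    DEFAULT_K_FOR,
    NUCLEOBASE_SPECIES,
)

#: Default cutoff: samples with t >= t_cut are excluded from objectives, s.
DEFAULT_T_CUT = 86_400.0

#: Rate-constant search bounds, L mol^-1 s^-1 (or 1/s).
RATE_BOUNDS = (0.0, 1.0e4)

#: Log-spaced multi-start guesses for a fitted rate constant.
MULTISTART_GUESSES = (1.0e-2, 1.0, 1.0e2)


class FitError(RuntimeError):
    """Raised when a fit cannot be set up or fails outright."""


@dataclass(frozen=True)
class FittedParameter:
    value: float
    sd: float  # NaN when the linearized covariance is unavailable

    def as_tuple(self) -> tuple[float, float]:
        return (self.value, self.sd)


@dataclass
class FitResult:
    """Outcome of one rate-constant fit."""

    variant: Variant
    fitted: dict[str, FittedParameter]
    fitted_init: float | None
    rmsd_tot: float
    included_species: list[str]
    excluded_times: list[float]
    converged: bool
    measurement: str = "indirect"
    message: str = ""
    n_points: int = 0
    cost: float = math.inf

    def __post_init__(self) -> None:
        if self.rmsd_tot < 0:
            raise ValueError("rmsd_tot must be >= 0")
        for name, p in self.fitted.items():
            if not math.isnan(p.sd) and p.sd < 0:
                raise ValueError(f"sd for {name} must be >= 0")

    def value(self, name: str) -> float:
        return self.fitted[name].value

    def to_dict(self) -> dict:
        return {
            "variant": self.variant.value,
            "measurement": self.measurement,
            "fitted": {
                k: {"value": p.value, "sd": None if math.isnan(p.sd) else p.sd}
                for k, p in sorted(self.fitted.items())
            },
            "fitted_init": self.fitted_init,
            "rmsd_tot": self.rmsd_tot,
            "included_species": list(self.included_species),
            "excluded_times": [float(t) for t in self.excluded_times],
            "converged": self.converged,
            "n_points": self.n_points,
            "message": self.message,
        }


# ---------------------------------------------------------------------------
# internals


def _build_model(
    variant: Variant,
    params: RateParameters,
    K: float | None,
    use_reduced: bool,
) -> KineticModel:
    model = build_cascade(variant, params, K)
    if use_reduced and variant.uses_hydrate:
        model = reduce_rapid_equilibrium(model)
    return model


def _predict(
    variant: Variant,
    params: RateParameters,
    K: float | None,
    init: Mapping[str, float],
    times: np.ndarray,
    use_reduced: bool,
    rtol: float,
    atol: float,
) -> TimeCourse:
    model = _build_model(variant, params, K, use_reduced)
    return simulate(model, init, times, rtol=rtol, atol=atol)


def estimate_parameter_sd(jacobian: np.ndarray, residuals: np.ndarray) -> np.ndarray:
    """Linearized (Gauss-Newton) parameter standard deviations.

    ``cov = s^2 (J^T J)^{-1}`` with ``s^2 = SSR / (m - n)``.  Returns NaN for
    every parameter when the Jacobian is singular (unidentifiable fit) or
    there are no residual degrees of freedom.
    """
    jacobian = np.atleast_2d(np.asarray(jacobian, dtype=float))
    residuals = np.asarray(residuals, dtype=float)
    m, n = jacobian.shape
    if m <= n:
        return np.full(n, np.nan)
    jtj = jacobian.T @ jacobian
    sv = np.linalg.svd(jacobian, compute_uv=False)
    if sv[0] == 0 or sv[-1] / sv[0] < 1e-12:
        return np.full(n, np.nan)
    s2 = float(residuals @ residuals) / (m - n)
    cov = np.linalg.inv(jtj) * s2
    return np.sqrt(np.diag(cov))


def _mask_times(times: np.ndarray, t_cut: float | None) -> np.ndarray:
    if t_cut is None:
        return np.ones_like(times, dtype=bool)
    return times < t_cut


def _observed_matrix(tc: TimeCourse, species: Sequence[str], mask: np.ndarray) -> np.ndarray:
    return np.column_stack([tc.conc(s)[mask] for s in species])


def _predicted_matrix(
    pred: TimeCourse, species: Sequence[str], pool_formyl: bool = False
) -> np.ndarray:
    """Model predictions per included species.

    Species the model does not produce (e.g. hydrate under the DIRECT
    variant) predict zero.  With ``pool_formyl`` the observed formyl signal
    is compared against the total formyl pool (aldehyde + hydrate): used when
    the data never resolve a hydrate peak, where the aldehyde/pool
    distinction is below experimental error by construction.
    """
    zeros = np.zeros(len(pred.times))

    def col(s: str) -> np.ndarray:
        if s == "5f" and pool_formyl and "5dhm" in pred.species:
            return pred.conc("5f") + pred.conc("5dhm")
        return pred.conc(s) if s in pred.species else zeros

    return np.column_stack([col(s) for s in species])


def _resolve_oxidant_init(tc: TimeCourse, oxidant_init: float | None) -> float:
    if oxidant_init is not None:
        return oxidant_init
    meta_init = tc.meta.get("init", {})
    if "TM1" in meta_init:
        return float(meta_init["TM1"])
    raise FitError("oxidant_init not given and not recoverable from TimeCourse metadata")


def _core_fit(
    tc: TimeCourse,
    variant: Variant,
    *,
    rate_name: str,
    fixed: Mapping[str, float],
    K: float | None,
    start_species: str,
    oxidant_init: float,
    included_species: Sequence[str],
    fit_init: bool,
    init_conc: float | None,
    t_cut: float | None,
    use_reduced: bool,
    n_starts: int,
    rtol: float,
    atol: float,
    measurement: str,
) -> FitResult:
    variant = Variant(variant)
    times = tc.times
    mask = _mask_times(times, t_cut)
    fit_times = times[mask]
    if len(fit_times) < 4:
        raise FitError(f"only {len(fit_times)} usable time points after exclusion; need >= 4")
    included = [s for s in included_species if s in tc.species]
    if not included:
        raise FitError("no included species present in the time course")
    obs = _observed_matrix(tc, included, mask)
    scale = float(np.abs(obs).max())
    if scale == 0:
        scale = 1.0
    # data with no resolved hydrate peak: match the formyl signal to the pool
    pool_formyl = "5dhm" not in tc.species

    if init_conc is None:
        init_conc = float(tc.conc(start_species)[0]) if not fit_init else None
    c0_guess = init_conc if init_conc is not None else max(float(tc.conc(start_species)[0]), atol)
    if c0_guess <= 0:
        c0_guess = 2.0e-4

    base = dict(fixed)

    def make_params(k_value: float) -> RateParameters:
        d = dict(base)
        d[rate_name] = k_value
        if variant.uses_hydrate:
            d.setdefault("k_for", DEFAULT_K_FOR)
        return RateParameters(**{k: v for k, v in d.items() if k != "k_rev"})

    def residual(theta: np.ndarray) -> np.ndarray:
        k_value = theta[0]
        c0 = theta[1] if fit_init else init_conc
        init = {start_species: c0, "TM1": oxidant_init}
        try:
            pred = _predict(variant, make_params(k_value), K, init, fit_times, use_reduced, rtol, atol)
        except SimulationError as exc:  # pragma: no cover - solver hiccup path
            raise FitError(f"simulation failed during fitting: {exc}") from exc
        pred_mat = _predicted_matrix(pred, included, pool_formyl)
        return ((pred_mat - obs) / scale).ravel()

    # the free initial concentration is a small correction to the first
    # observed value, not an unconstrained degree of freedom: bounding it
    # also excludes a degenerate oxidant-titration branch on flat data
    lo = [RATE_BOUNDS[0]] + ([0.5 * c0_guess] if fit_init else [])
    hi = [RATE_BOUNDS[1]] + ([2.0 * c0_guess] if fit_init else [])
    x_scale = [1.0] + ([c0_guess] if fit_init else [])

    starts = list(MULTISTART_GUESSES[:n_starts]) if n_starts > 1 else [1.0]
    best = None
    for guess in starts:
        x0 = [min(max(guess, lo[0] + 1e-12), hi[0])] + ([c0_guess] if fit_init else [])
        try:
            res = least_squares(
                residual,
                x0,
                bounds=(lo, hi),
                method="trf",
                x_scale=x_scale,
                ftol=1e-14,
                xtol=1e-14,
                gtol=1e-14,
            )
        except FitError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("all optimization starts failed")

    sds = estimate_parameter_sd(best.jac, best.fun)
    # identifiability: a numerically rank-deficient Jacobian means the fitted
    # constant leaves no signature in the observed species
    sv = np.linalg.svd(best.jac, compute_uv=False)
    identifiable = bool(sv[0] > 0 and sv[-1] / sv[0] > 1e-9)
    converged = bool(best.success) and identifiable

    k_hat = float(best.x[0])
    c0_hat = float(best.x[1]) if fit_init else (float(init_conc) if init_conc is not None else None)
    fitted = {rate_name: FittedParameter(k_hat, float(sds[0]))}
    if fit_init:
        fitted["init_" + start_species] = FittedParameter(c0_hat, float(sds[1]))

    resid = best.fun * scale
    rmsd = float(np.sqrt(np.mean(resid**2)))
    return FitResult(
        variant=variant,
        fitted=fitted,
        fitted_init=c0_hat,
        rmsd_tot=rmsd,
        included_species=included,
        excluded_times=[float(t) for t in times[~mask]],
        converged=converged,
        measurement=measurement,
        message="" if converged else "fit flagged: " + ("optimizer failure" if not best.success else "parameter unidentifiable"),
        n_points=int(mask.sum()),
        cost=float(best.cost),
    )


# ---------------------------------------------------------------------------
# public protocol


def fit_step1(
    tc: TimeCourse,
    variant: Variant | str = Variant.DIRECT,
    k_TM: float = 0.0,
    *,
    K: float | None = None,
    downstream_k: float = 0.0,
    oxidant_init: float | None = None,
    fit_init: bool = True,
    t_cut: float | None = DEFAULT_T_CUT,
    use_reduced: bool = True,
    n_starts: int = 3,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> FitResult:
    """Fit the first-step constant ``k_hm`` to the substrate decay alone.

    ``k_TM`` is fixed from independent oxidant-decay experiments.  Because
    the second oxidation step also consumes oxidant, its constant enters as
    ``downstream_k`` (held fixed); iterate with :func:`fit_step2` via
    :func:`fit_staged` for an unbiased pair.
    """
    variant = Variant(variant)
    if "5hm" not in tc.species:
        raise FitError("time course lacks the substrate column '5hm'")
    fixed = {"k_TM": k_TM}
    if variant is Variant.DIRECT:
        fixed["k_f"] = downstream_k
    else:
        fixed["k_dhm"] = downstream_k
        if variant is Variant.DUAL:
            fixed["k_f"] = 0.0
    return _core_fit(
        tc,
        variant,
        rate_name="k_hm",
        fixed=fixed,
        K=K,
        start_species="5hm",
        oxidant_init=_resolve_oxidant_init(tc, oxidant_init),
        included_species=["5hm"],
        fit_init=fit_init,
        init_conc=None if fit_init else float(tc.conc("5hm")[0]),
        t_cut=t_cut,
        use_reduced=use_reduced,
        n_starts=n_starts,
        rtol=rtol,
        atol=atol,
        measurement="direct",
    )


def _step2_rate_name(variant: Variant) -> str:
    return "k_f" if variant is Variant.DIRECT else "k_dhm"


def fit_step2(
    tc: TimeCourse,
    variant: Variant | str,
    k_hm_fixed: float,
    k_TM: float,
    K: float | None = None,
    *,
    init_substrate: float | None = None,
    oxidant_init: float | None = None,
    exclude_acid: bool = True,
    t_cut: float | None = DEFAULT_T_CUT,
    use_reduced: bool = True,
    n_starts: int = 3,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> FitResult:
    """Fit the second-step constant with the step-1 constant held fixed.

    The objective pools every tracked nucleobase species except (by default)
    the final acid, whose work-up losses make it unreliable.
    """
    variant = Variant(variant)
    if variant.uses_hydrate and K is None:
        raise FitError("hydrate-aware variants require the equilibrium constant K")
    included = [s for s in NUCLEOBASE_SPECIES if s in tc.species]
    if exclude_acid and "5ca" in included:
        included.remove("5ca")
    if init_substrate is None:
        init_substrate = float(tc.conc("5hm")[0]) if "5hm" in tc.species else None
    if init_substrate is None:
        raise FitError("init_substrate not given and substrate column absent")
    return _core_fit(
        tc,
        variant,
        rate_name=_step2_rate_name(variant),
        fixed={"k_TM": k_TM, "k_hm": k_hm_fixed},
        K=K,
        start_species="5hm",
        oxidant_init=_resolve_oxidant_init(tc, oxidant_init),
        included_species=included,
        fit_init=False,
        init_conc=init_substrate,
        t_cut=t_cut,
        use_reduced=use_reduced,
        n_starts=n_starts,
        rtol=rtol,
        atol=atol,
        measurement="indirect",
    )


def fit_staged(
    tc: TimeCourse,
    variant: Variant | str,
    k_TM: float,
    K: float | None = None,
    *,
    oxidant_init: float | None = None,
    exclude_acid: bool = True,
    t_cut: float | None = DEFAULT_T_CUT,
    use_reduced: bool = True,
    n_starts: int = 3,
    max_iter: int = 10,
    k_rel_tol: float = 1e-6,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> tuple[FitResult, FitResult]:
    """Iterate step-1 and step-2 fits to their joint fixed point.

    Returns the (step1, step2) results of the final round.
    """
    variant = Variant(variant)
    oxidant_init = _resolve_oxidant_init(tc, oxidant_init)
    downstream = 0.0
    prev = None
    fit1 = fit2 = None
    for _ in range(max_iter):
        fit1 = fit_step1(
            tc, variant, k_TM, K=K, downstream_k=downstream, oxidant_init=oxidant_init,
            t_cut=t_cut, use_reduced=use_reduced, n_starts=n_starts, rtol=rtol, atol=atol,
        )
        fit2 = fit_step2(
            tc, variant, fit1.value("k_hm"), k_TM, K,
            init_substrate=fit1.fitted_init, oxidant_init=oxidant_init,
            exclude_acid=exclude_acid, t_cut=t_cut, use_reduced=use_reduced,
            n_starts=n_starts, rtol=rtol, atol=atol,
        )
        pair = (fit1.value("k_hm"), fit2.value(_step2_rate_name(variant)))
        if prev is not None:
            dk = max(
                abs(pair[0] - prev[0]) / max(abs(prev[0]), 1e-12),
                abs(pair[1] - prev[1]) / max(abs(prev[1]), 1e-12),
            )
            if dk < k_rel_tol:
                break
        prev = pair
        downstream = pair[1]
    return fit1, fit2


def fit_direct_start(
    tc: TimeCourse,
    variant: Variant | str,
    k_TM: float,
    K: float | None = None,
    *,
    oxidant_init: float | None = None,
    exclude_acid: bool = True,
    fit_init: bool = True,
    t_cut: float | None = DEFAULT_T_CUT,
    use_reduced: bool = True,
    n_starts: int = 3,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> FitResult:
    """Single-step fit for experiments started from the formyl species.

    Fits ``k_f`` (direct route) or ``k_dhm`` (hydrate route) together with a
    free initial formyl-pool concentration; labelled measurement "direct".
    """
    variant = Variant(variant)
    if variant.uses_hydrate and K is None:
        raise FitError("hydrate-aware variants require the equilibrium constant K")
    included = [s for s in NUCLEOBASE_SPECIES if s in tc.species and s != "5hm"]
    if exclude_acid and "5ca" in included:
        included.remove("5ca")
    if not included:
        raise FitError("no formyl-pool species tracked in the time course")
    return _core_fit(
        tc,
        variant,
        rate_name=_step2_rate_name(variant),
        fixed={"k_TM": k_TM, "k_hm": 0.0},
        K=K,
        start_species="5f",
        oxidant_init=_resolve_oxidant_init(tc, oxidant_init),
        included_species=included,
        fit_init=fit_init,
        init_conc=None,
        t_cut=t_cut,
        use_reduced=use_reduced,
        n_starts=n_starts,
        rtol=rtol,
        atol=atol,
        measurement="direct",
    )


def rmsd_tot(
    model: KineticModel,
    tc: TimeCourse,
    included_species: Sequence[str],
    init: Mapping[str, float],
    *,
    t_cut: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> float:
    """Pooled per-point concentration RMSD between a model and observations.

    ``sqrt(mean((sim - obs)^2))`` over every included species and every
    non-excluded time point; all species share the mol/L scale so no
    per-species normalization is applied.
    """
    included = [s for s in included_species if s in tc.species]
    if not included:
        raise ValueError("included_species is empty or absent from the time course")
    times = tc.times
    mask = _mask_times(times, t_cut)
    pred = simulate(model, init, times[mask], rtol=rtol, atol=atol)
    obs = _observed_matrix(tc, included, mask)
    pred_mat = _predicted_matrix(pred, included, pool_formyl="5dhm" not in tc.species)
    return float(np.sqrt(np.mean((pred_mat - obs) ** 2)))


def compare_pathways(
    tc: TimeCourse,
    k_hm_fixed: float,
    k_TM: float,
    K: float,
    *,
    init_substrate: float | None = None,
    oxidant_init: float | None = None,
    include_dual: bool = False,
    exclude_acid: bool = True,
    t_cut: float | None = DEFAULT_T_CUT,
    use_reduced: bool = True,
    n_starts: int = 3,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> list[FitResult]:
    """Fit the direct and hydrate routes independently and rank by RMSD_tot.

    Returns results sorted by ascending RMSD_tot; when the two RMSDs agree to
    six significant figures the variant with fewer species states (DIRECT)
    ranks first.  Per-variant failures are reported in the result list rather
    than aborting the comparison.  The DUAL variant (both channels fitted
    jointly from one trace) is ill-conditioned and only attempted on request.
    """
    if not any(s in tc.species for s in NUCLEOBASE_SPECIES):
        raise ValueError("time course tracks no nucleobase species")
    variants = [Variant.DIRECT, Variant.HYDRATE_ROUTE]
    if include_dual:
        variants.append(Variant.DUAL)
    results: list[FitResult] = []
    for variant in variants:
        try:
            fit = fit_step2(
                tc, variant, k_hm_fixed, k_TM, K if variant.uses_hydrate else None,
                init_substrate=init_substrate, oxidant_init=oxidant_init,
                exclude_acid=exclude_acid, t_cut=t_cut, use_reduced=use_reduced,
                n_starts=n_starts, rtol=rtol, atol=atol,
            )
            if variant is Variant.DUAL:
                fit.message = (fit.message + " DUAL variant is ill-conditioned; "
                               "k_f and k_dhm are not jointly identifiable from one trace").strip()
        except (FitError, ValueError) as exc:
            fit = FitResult(
                variant=variant, fitted={}, fitted_init=None, rmsd_tot=0.0,
                included_species=[], excluded_times=[], converged=False,
                message=f"fit failed: {exc}", cost=math.inf,
            )
            fit.rmsd_tot = math.inf
        results.append(fit)

    def _sig6(x: float) -> float:
        if not math.isfinite(x) or x == 0:
            return x
        return float(f"{x:.6g}")

    order = {Variant.DIRECT: 0, Variant.HYDRATE_ROUTE: 1, Variant.DUAL: 2}
    results.sort(key=lambda r: (_sig6(r.rmsd_tot), order[r.variant]))
    return results
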