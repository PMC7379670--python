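"""Maximum-likelihood fitting, standard errors, bootstrap and AIC ranking.

Optimisation is quasi-Newton (L-BFGS) on unconstrained scales — logit for
probabilities, log for the never-removed count ``n0`` — with random
restarts, because near-redundant models can have flat, multimodal
likelihood surfaces.  Standard errors come from the numerically
differentiated observed information (delta method back to the natural
scale); when an estimate sits on a boundary of the parameter space the
Hessian is unreliable and the nonparametric bootstrap is the supported
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .likelihood import RemovalData, _as_datasets, log_likelihood
from .model_spec import (
    ModelSpec,
    count_free_parameters,
    expand_parameters,
    free_parameter_names,
)

__all__ = [
    "FitResult",
    "BootstrapResult",
    "fit_model",
    "hessian_se",
    "bootstrap",
    "rank_models",
]

_BOUNDARY_LOGIT = 9.2103  # |logit| beyond this puts a probability within 1e-4 of {0,1}
_BOUNDARY_N0 = 1e-4


def _natural_value(name: str, x: float) -> float:
    if name == "v":
        return 2.0 * float(expit(x))
    if name.startswith(("alpha", "beta", "gamma")):
        return float(x)
    if name.startswith("n0"):
        return float(np.exp(x))
    return float(expit(x))  # pi, phi12, phi21, p, p_i_j


def _natural_derivative(name: str, x: float) -> float:
    if name == "v":
        e = float(expit(x))
        return 2.0 * e * (1.0 - e)
    if name.startswith(("alpha", "beta", "gamma")):
        return 1.0
    if name.startswith("n0"):
        return float(np.exp(x))
    e = float(expit(x))
    return e * (1.0 - e)


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    spec: ModelSpec
    theta_free: np.ndarray
    params: tuple  # PopulationParameters per population
    loglik: float
    h: int
    aic: float
    converged: bool
    boundary_flags: tuple
    n_restarts: int
    message: str = ""
    se: Optional[dict] = None
    se_reason: Optional[str] = None
    data: object = field(default=None, repr=False)

    @property
    def D(self) -> tuple:
        datasets = [self.data] if isinstance(self.data, RemovalData) else list(self.data)
        return tuple(ds.D for ds in datasets)

    @property
    def N_hat(self) -> tuple:
        """Per-population abundance estimate ``n0_hat + D``."""
        return tuple(par.n0 + d for par, d in zip(self.params, self.D))

    def estimates(self) -> dict:
        """Natural-scale values of every free parameter."""
        names = free_parameter_names(self.spec)
        return {n: _natural_value(n, x) for n, x in zip(names, self.theta_free)}


@dataclass
class BootstrapResult:
    """Nonparametric bootstrap replicates, SEs and percentile intervals."""

    replicates: pd.DataFrame
    se: pd.Series
    ci: pd.DataFrame
    level: float
    n_failed: int
    scheme: str


def _objective(spec: ModelSpec, datasets):
    data = datasets[0] if spec.n_populations == 1 else datasets

    def nll(theta):
        try:
            ll = log_likelihood(theta, spec, data)
        except (ValueError, FloatingPointError):
            return 1e10
        if not np.isfinite(ll):
            return 1e10
        return -ll

    return nll


def _default_start(spec: ModelSpec, datasets) -> np.ndarray:
    """Moment-flavoured starting values.

    The within-primary depletion ratio of the first primary period with two
    positive counts gives a crude capture probability; availability and
    transition parameters start at 0.5 (logit 0); ``n0`` starts at half the
    removals.
    """
    p0 = 0.3
    counts = datasets[0].counts
    design = spec.design
    m = 0
    for i in range(design.T):
        ki = design.k[i]
        if ki >= 2 and counts[m] > 0 and counts[m + 1] > 0:
            p0 = float(np.clip(1.0 - counts[m + 1] / counts[m], 0.05, 0.9))
            break
        m += ki
    logit_p0 = float(np.log(p0 / (1.0 - p0)))
    start = []
    for name in free_parameter_names(spec):
        if name == "alpha":
            start.append(logit_p0)
        elif name == "p" or name.startswith("p_"):
            start.append(logit_p0)
        elif name.startswith("n0"):
            w = 0 if spec.n_populations == 1 else spec.population_labels.index(
                name.split("_", 1)[1])
            start.append(float(np.log(max(datasets[w].D / 2.0, 1.0))))
        else:
            start.append(0.0)  # pi/phi at 0.5, beta/gamma/v-offset at 0
    return np.asarray(start)


def fit_model(
    data: Union[RemovalData, Sequence[RemovalData]],
    spec: ModelSpec,
    starts: Optional[np.ndarray] = None,
    n_restarts: int = 10,
    seed: int = 0,
    compute_se: bool = True,
) -> FitResult:
    """Fit a removal model by maximum likelihood.

    ``starts`` optionally fixes the first starting vector (free scale);
    ``n_restarts`` additional starts are drawn by perturbing it.  The best
    local optimum over all starts is returned; the result is deterministic
    given ``data``, ``starts`` and ``seed``.
    """
    datasets = _as_datasets(data, spec)
    if sum(ds.D for ds in datasets) < 1:
        raise ValueError("no removals recorded: the likelihood carries no information")
    nll = _objective(spec, datasets)
    x0 = _default_start(spec, datasets) if starts is None else np.asarray(starts, float)
    rng = np.random.default_rng(seed)
    start_points = [x0] + [x0 + rng.normal(0.0, 1.0, size=x0.size)
                           for _ in range(int(n_restarts))]
    best = None
    for x in start_points:
        res = minimize(nll, x, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    theta = np.asarray(best.x, dtype=float)
    loglik = -float(best.fun)
    converged = bool(best.success) and loglik > -1e9
    names = free_parameter_names(spec)
    flags = []
    for name, x in zip(names, theta):
        if name.startswith(("alpha", "beta", "gamma")):
            continue
        if name.startswith("n0"):
            if np.exp(x) < _BOUNDARY_N0:
                flags.append(name)
        elif abs(x) > _BOUNDARY_LOGIT:
            flags.append(name)
    covariates = next((ds.covariates for ds in datasets if ds.covariates is not None), None)
    params = expand_parameters(theta, spec,
                               covariates=covariates if spec.constraints.p_model == "covariate" else None)
    h = count_free_parameters(spec, include_abundance=True)
    fit = FitResult(
        spec=spec,
        theta_free=theta,
        params=params,
        loglik=loglik,
        h=h,
        aic=-2.0 * loglik + 2.0 * h,
        converged=converged,
        boundary_flags=tuple(flags),
        n_restarts=int(n_restarts),
        message=str(best.message),
        data=datasets[0] if spec.n_populations == 1 else list(datasets),
    )
    if compute_se:
        se, reason = _hessian_se_impl(fit)
        fit.se, fit.se_reason = se, reason
    return fit


def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = x.size
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _hessian_se_impl(fit: FitResult):
    if not fit.converged:
        return None, "fit did not converge"
    if fit.boundary_flags:
        return None, (
            "estimates on the boundary (" + ", ".join(fit.boundary_flags)
            + "); use the nonparametric bootstrap"
        )
    datasets = _as_datasets(fit.data, fit.spec)
    nll = _objective(fit.spec, datasets)
    H = _numeric_hessian(nll, fit.theta_free)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None, "observed information is singular"
    diag = np.diag(cov)
    if np.any(diag <= 0) or not np.all(np.isfinite(diag)):
        return None, "observed information is not positive definite"
    names = free_parameter_names(fit.spec)
    se = {}
    for name, x, var in zip(names, fit.theta_free, diag):
        se[name] = abs(_natural_derivative(name, x)) * float(np.sqrt(var))
        if name.startswith("n0"):
            # N = n0 + D with D fixed, so the SE transfers unchanged
            se["N_hat" + name[2:]] = se[name]
    return se, None


def hessian_se(fit: FitResult) -> Optional[dict]:
    """Delta-method standard errors on the natural scale, or ``None``.

    Returns ``None`` (with the reason recorded on the fit) for boundary
    optima or a singular observed information matrix.
    """
    se, reason = _hessian_se_impl(fit)
    fit.se, fit.se_reason = se, reason
    return se


def bootstrap(
    data,
    spec: ModelSpec,
    B: int,
    seed: int = 0,
    scheme: str = "records",
    fit: Optional[FitResult] = None,
    level: float = 0.95,
    n_restarts: int = 1,
) -> BootstrapResult:
    """Nonparametric bootstrap standard errors and percentile intervals.

    ``scheme="records"`` resamples, within each population, the ``D``
    observed removal records over the occasion cells (D held fixed) and
    refits.  ``scheme="parametric"`` instead redraws full datasets from the
    fitted cell probabilities with the estimated abundance as the
    multinomial index.  Non-converging resamples are dropped and counted.
    """
    if scheme not in ("records", "parametric"):
        raise ValueError("scheme must be 'records' or 'parametric'")
    datasets = _as_datasets(data, spec)
    if fit is None:
        fit = fit_model(data, spec, seed=seed, compute_se=False)
    if not fit.converged:
        raise ValueError("bootstrap requires a converged original fit")
    rng = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    from .likelihood import cell_probabilities  # local to keep imports tidy

    for _ in range(int(B)):
        resampled = []
        for w, ds in enumerate(datasets):
            if scheme == "records":
                probs = ds.counts / ds.D
                counts = rng.multinomial(ds.D, probs)
            else:
                cells = cell_probabilities(fit.params[w], spec.design).as_vector()
                n_total = int(np.round(fit.N_hat[w]))
                counts = rng.multinomial(n_total, cells / cells.sum())[:-1]
            resampled.append(RemovalData(spec.design, counts, covariates=ds.covariates))
        boot_data = resampled[0] if spec.n_populations == 1 else resampled
        try:
            refit = fit_model(boot_data, spec, starts=fit.theta_free,
                              n_restarts=n_restarts, seed=int(rng.integers(2**31 - 1)),
                              compute_se=False)
        except ValueError:
            n_failed += 1
            continue
        if not refit.converged:
            n_failed += 1
            continue
        row = refit.estimates()
        labels = spec.population_labels
        for w, lab in enumerate(labels):
            suffix = "" if len(labels) == 1 else f"_{lab}"
            row[f"N_hat{suffix}"] = refit.N_hat[w]
        rows.append(row)
    reps = pd.DataFrame(rows)
    if len(reps):
        se = reps.std(ddof=1)
        alpha = (1.0 - level) / 2.0
        ci = pd.DataFrame({
            "lower": reps.quantile(alpha),
            "upper": reps.quantile(1.0 - alpha),
        })
    else:
        se = pd.Series(dtype=float)
        ci = pd.DataFrame(columns=["lower", "upper"])
    return BootstrapResult(replicates=reps, se=se, ci=ci, level=level,
                           n_failed=n_failed, scheme=scheme)


def rank_models(data, specs: Sequence, **fit_kwargs) -> pd.DataFrame:
    """Fit several models to the same data and rank them by AIC.

    Entries of ``specs`` may be :class:`ModelSpec` objects or already
    computed :class:`FitResult` objects (useful for mixing in baselines
    fitted elsewhere).  Returns rows sorted by AIC with the difference
    ``dAIC`` to the best model.
    """
    rows = []
    for s in specs:
        fit = s if isinstance(s, FitResult) else fit_model(data, s, **fit_kwargs)
        code = fit.spec.model_code if isinstance(fit.spec, ModelSpec) else str(fit.spec)
        rows.append({
            "model_code": code,
            "h": fit.h,
            "loglik": fit.loglik,
            "AIC": fit.aic,
            "converged": fit.converged,
        })
    table = pd.DataFrame(rows).sort_values("AIC", kind="stable").reset_index(drop=True)
    table["dAIC"] = table["AIC"] - table["AIC"].min()
    return table
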