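"""Numeric parameter-redundancy and near-redundancy diagnostics.

A model is parameter redundant when it can be rewritten with fewer
parameters; then no amount of data identifies the full parameter set.  The
diagnostic works on the *exhaustive summary* ``kappa(theta)`` — here the
vector of multinomial cell probabilities ``(L_{1,1}, ..., L_{T,k_T}, L_0)``
per population, which fully determines the sampling distribution up to the
multinomial index.  The deficiency is

    d = h - rank(d kappa / d theta),

with ``h`` the number of free parameters *excluding* ``n0`` (the summary
does not involve abundance).  The rank is computed numerically: central
finite-difference Jacobians at several random interior parameter points,
singular-value decomposition, and a relative threshold on the singular
values; the rank is the maximum over evaluation points, since the rank of
an analytic matrix function attains its generic value almost everywhere.

A full-rank model can still behave badly when it is *near redundant*: the
expected (multinomial Fisher) information ``N J' diag(1/kappa) J`` has an
eigenvalue close to zero at relevant parameter values, so some parameter
combination is almost flat.  :func:`near_redundancy` flags this via the
smallest-to-largest eigenvalue ratio.

For parameter-redundant models, invariance of the summary along prescribed
*estimable combinations* can be verified numerically: two parameter sets
agreeing on the combinations must produce identical cell probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .likelihood import cell_probabilities
from .model_spec import (
    ModelSpec,
    RobustDesign,
    count_free_parameters,
    expand_parameters,
    free_parameter_names,
    parse_model_code,
)

__all__ = [
    "RedundancyReport",
    "exhaustive_summary",
    "deficiency",
    "near_redundancy",
    "estimable_combinations_check",
    "reference_covariate",
    "representative_truth",
    "table_report",
    "TABLE_CONSTANT_MODELS",
    "TABLE_TIME_VARYING_MODELS",
    "ESTIMABLE_COMBINATIONS",
]

SV_RTOL = 1e-8  # relative singular-value threshold for numeric rank
NR_EIGENVALUE_RATIO = 1e-6  # min/max information eigenvalue ratio flagging near redundancy


@dataclass
class RedundancyReport:
    """Rank/deficiency diagnostics for one model."""

    model_code: str
    h: int
    rank: int
    deficiency: int
    status: str  # "FR" | "PR" | "NR"
    min_eigenvalue: Optional[float] = None
    eigenvalue_ratio: Optional[float] = None
    null_directions: Optional[np.ndarray] = None
    n_points: int = 0


def reference_covariate(K: int) -> np.ndarray:
    """Fixed, standardised, non-constant covariate series of length K.

    Covariate-link models have ranks that depend on the covariate varying
    over occasions; this deterministic synthetic series stands in wherever a
    covariate is needed but none is supplied.
    """
    rng = np.random.default_rng(73_2018)
    z = rng.normal(size=K)
    return (z - z.mean()) / z.std()


def exhaustive_summary(spec: ModelSpec, covariates=None) -> Callable:
    """Map ``theta`` (natural scale, abundance excluded) to ``kappa(theta)``.

    ``kappa`` stacks, population by population, the ``K`` removal cell
    probabilities followed by the never-removed probability, giving length
    ``n_populations * (K + 1)``.
    """
    if spec.constraints.p_model == "covariate" and covariates is None:
        covariates = reference_covariate(spec.design.K)

    def kappa(theta: np.ndarray) -> np.ndarray:
        pops = expand_parameters(
            theta, spec, covariates=covariates, include_abundance=False, scale="natural"
        )
        return np.concatenate(
            [cell_probabilities(par, spec.design).as_vector() for par in pops]
        )

    return kappa


def _jacobian(fun: Callable, x: np.ndarray, step: float) -> np.ndarray:
    cols = []
    for i in range(x.size):
        e = np.zeros(x.size)
        e[i] = step
        cols.append((fun(x + e) - fun(x - e)) / (2.0 * step))
    return np.column_stack(cols)


def _random_interior_point(spec: ModelSpec, rng: np.random.Generator) -> np.ndarray:
    theta = []
    for name in free_parameter_names(spec, include_abundance=False):
        if name == "v":
            theta.append(rng.uniform(0.7, 1.3))
        elif name.startswith(("alpha",)):
            theta.append(rng.uniform(-1.0, 0.0))
        elif name.startswith(("beta", "gamma")):
            theta.append(rng.uniform(0.3, 1.0) * rng.choice([-1.0, 1.0]))
        else:
            theta.append(rng.uniform(0.15, 0.85))
    return np.asarray(theta)


def _numeric_rank(J: np.ndarray, rtol: float = SV_RTOL):
    s = np.linalg.svd(J, compute_uv=False)
    if s.size == 0 or s[0] == 0.0:
        return 0, s
    return int(np.sum(s > rtol * s[0])), s


def deficiency(
    spec: ModelSpec,
    n_points: int = 5,
    seed: int = 0,
    covariates=None,
    step: float = 1e-5,
    truth: Optional[np.ndarray] = None,
    N: float = 500.0,
) -> RedundancyReport:
    """Numeric rank/deficiency report for ``spec``.

    The Jacobian of the exhaustive summary is evaluated at ``n_points``
    random interior parameter draws; the reported rank is the maximum over
    draws.  When the model is full rank (``d = 0``) a near-redundancy check
    is run at ``truth`` (default: :func:`representative_truth`) and the
    status is ``NR`` or ``FR`` accordingly; otherwise the status is ``PR``
    and the numeric null-space basis at the best draw is attached.
    """
    kappa = exhaustive_summary(spec, covariates=covariates)
    h = count_free_parameters(spec, include_abundance=False)
    rng = np.random.default_rng(seed)
    best_rank, best_sv, best_J = -1, None, None
    used = 0
    for _ in range(int(n_points)):
        theta = _random_interior_point(spec, rng)
        try:
            J = _jacobian(kappa, theta, step)
        except ValueError:
            continue
        used += 1
        r, s = _numeric_rank(J)
        if r > best_rank:
            best_rank, best_sv, best_J = r, s, J
    if used == 0:
        raise ValueError("no valid evaluation points for the Jacobian")
    if used < n_points:
        warnings.warn(f"only {used}/{n_points} evaluation points were valid")
    d = h - best_rank
    null_dirs = None
    if d > 0:
        _, _, vt = np.linalg.svd(best_J)
        null_dirs = vt[best_rank:].T
        status = "PR"
        min_eig = ratio = None
    else:
        if truth is None:
            truth = representative_truth(spec)
        min_eig, ratio, flagged = near_redundancy(
            spec, truth, N=N, covariates=covariates, step=step
        )
        status = "NR" if flagged else "FR"
    return RedundancyReport(
        model_code=spec.model_code,
        h=h,
        rank=best_rank,
        deficiency=d,
        status=status,
        min_eigenvalue=min_eig,
        eigenvalue_ratio=ratio,
        null_directions=null_dirs,
        n_points=used,
    )


def near_redundancy(
    spec: ModelSpec,
    truth: np.ndarray,
    N: float = 500.0,
    covariates=None,
    threshold: float = NR_EIGENVALUE_RATIO,
    step: float = 1e-5,
):
    """Smallest information eigenvalue at ``truth`` and a near-redundancy flag.

    ``truth`` is the free-parameter vector on the natural scale (abundance
    excluded).  The expected information of the multinomial model is
    ``N * J' diag(1/kappa) J`` over all cells including never-removed; cells
    with zero probability are excluded with a warning.  The flag is raised
    when the smallest-to-largest eigenvalue ratio falls below ``threshold``.
    """
    kappa_fun = exhaustive_summary(spec, covariates=covariates)
    truth = np.asarray(truth, dtype=float)
    kap = kappa_fun(truth)
    J = _jacobian(kappa_fun, truth, step)
    keep = kap > 0.0
    if not np.all(keep):
        warnings.warn(f"{int((~keep).sum())} zero-probability cells excluded "
                      "from the information matrix")
    info = N * (J[keep].T / kap[keep]) @ J[keep]
    eigs = np.linalg.eigvalsh(info)
    min_eig = float(eigs[0])
    ratio = float(eigs[0] / eigs[-1]) if eigs[-1] > 0 else 0.0
    return min_eig, ratio, bool(ratio < threshold)


def representative_truth(spec: ModelSpec, variant: str = "s1") -> np.ndarray:
    """Scenario-style parameter values on the natural scale for ``spec``.

    Capture probability 0.3; transitions follow the off-site-leaning ("s1")
    or on-site-leaning ("s2") scenario values, adjusted to respect the
    model's own constraint (even-flow models get symmetric transitions);
    free ``pi`` sits at the matching stationary value.
    """
    from .scenarios import CONST_PHI12, CONST_PHI21, TV_PHI12

    c = spec.constraints
    phi12_c, phi21_c = CONST_PHI12[variant], CONST_PHI21[variant]
    if c.phi == "even_flow":
        phi21_c = phi12_c
    pi_val = phi21_c / (phi12_c + phi21_c)
    T = spec.design.T
    key = (variant, 2 * (T - 1) + 2)
    tv = TV_PHI12.get(key)
    theta = []
    names = free_parameter_names(spec, include_abundance=False)
    n_tv = sum(1 for n in names if n.startswith("phi12_"))
    for idx, name in enumerate(names):
        if name.startswith("pi"):
            theta.append(pi_val)
        elif name.startswith("phi12_"):
            k = int(name.split("_")[-1]) - 1
            if tv is not None and len(tv) >= n_tv:
                theta.append(tv[k])
            else:
                theta.append(0.3 + 0.4 * ((k % 3) / 2.0))  # generic non-constant series
        elif name == "phi12":
            theta.append(phi12_c)
        elif name.startswith("phi21_"):
            k = int(name.split("_")[-1]) - 1
            base = tv[k] if (tv is not None and len(tv) >= n_tv) else 0.3 + 0.4 * ((k % 3) / 2.0)
            theta.append(base if c.phi == "even_flow" else 1.0 - base)
        elif name == "phi21":
            theta.append(phi21_c)
        elif name == "v":
            theta.append(1.0)
        elif name.startswith("gamma"):
            theta.append(-0.5)
        elif name == "alpha":
            theta.append(float(np.log(0.3 / 0.7)))
        elif name == "beta":
            theta.append(0.5)
        else:  # p, p_i_j
            theta.append(0.3)
    return np.asarray(theta)


# --------------------------------------------------------------------------
# estimable combinations


def _project_to_combinations(
    combos: Callable, target: np.ndarray, x0: np.ndarray, step: float = 1e-6,
    tol: float = 1e-12, max_iter: int = 50,
) -> Optional[np.ndarray]:
    """Gauss-Newton projection of ``x0`` onto the level set ``combos(x) = target``."""
    x = x0.copy()
    for _ in range(max_iter):
        resid = combos(x) - target
        if np.max(np.abs(resid)) < tol:
            return x
        J = _jacobian(combos, x, step)
        dx, *_ = np.linalg.lstsq(J, resid, rcond=None)
        x = x - dx
        if np.any(x < 1e-3) or np.any(x > 1 - 1e-3):
            return None  # wandered out of the interior
    return None


def estimable_combinations_check(
    spec: ModelSpec,
    combos: Callable,
    n_pairs: int = 20,
    seed: int = 0,
    tol: float = 1e-8,
    step_size: float = 0.05,
) -> bool:
    """Verify that ``combos`` captures exactly what the model can estimate.

    ``combos`` maps the natural-scale free vector to the claimed estimable
    combinations.  For each of ``n_pairs`` random interior points a second
    point is constructed on the same combination level set (step along the
    combination null space, then Gauss-Newton projection back); the two must
    give identical summaries to ``tol``.  Additionally, points with
    *different* combination values must give different summaries.  Returns
    ``True`` only when both hold for every pair tested.
    """
    kappa = exhaustive_summary(spec)
    rng = np.random.default_rng(seed)
    tested = 0
    attempts = 0
    while tested < n_pairs and attempts < 20 * n_pairs:
        attempts += 1
        x1 = _random_interior_point_clipped(spec, rng)
        Jc = _jacobian(combos, x1, 1e-6)
        _, s, vt = np.linalg.svd(Jc)
        null = vt[np.sum(s > 1e-10 * max(s[0], 1e-300)):]
        if null.shape[0] == 0:
            return False  # combos leave no freedom: nothing to be invariant along
        direction = null.T @ rng.normal(size=null.shape[0])
        norm = np.linalg.norm(direction)
        if norm < 1e-12:
            continue
        x2 = _project_to_combinations(combos, combos(x1),
                                      x1 + step_size * direction / norm)
        if x2 is None or np.linalg.norm(x2 - x1) < 1e-6:
            continue
        tested += 1
        if np.max(np.abs(kappa(x1) - kappa(x2))) > tol:
            return False
        # negative direction: different combination values must move kappa
        x3 = np.clip(x1 + rng.normal(0.0, 0.05, size=x1.size), 0.05, 0.95)
        if np.max(np.abs(combos(x3) - combos(x1))) > 1e-6:
            if np.max(np.abs(kappa(x3) - kappa(x1))) < 1e-10:
                return False
    if tested < n_pairs:
        raise RuntimeError("could not construct enough matched parameter pairs")
    return True


def _random_interior_point_clipped(spec, rng):
    x = _random_interior_point(spec, rng)
    return np.clip(x, 0.2, 0.8)


# estimable combinations for the single-secondary (MER) constant models;
# theta orderings follow free_parameter_names.  The third NNC combination is
# trace(M) - 2 of the between-occasion update matrix M; note pi*p and
# phi21*p are invariant while phi12*p is not (level-set tracing confirms).
ESTIMABLE_COMBINATIONS = {
    # theta = (pi, phi12, phi21, p)
    "NNC": lambda th: np.array([
        th[0] * th[3],
        th[2] * th[3],
        (th[1] - 1.0) * th[3] - th[1] - th[2],
    ]),
    # theta = (pi, phi12, p)
    "NRC": lambda th: np.array([th[0] * th[2], (th[1] - 1.0) * th[2]]),
    # theta = (phi12, p)
    "SRC": lambda th: np.array([(th[0] - 1.0) * th[1]]),
}


# --------------------------------------------------------------------------
# table presets

# constant-transition models: code suffix -> printed h (n0 excluded)
TABLE_CONSTANT_MODELS = (
    ("NNC", 4), ("NNZ", 5), ("SNC", 3), ("NRC", 3), ("NEC", 3), ("SNZ", 4),
    ("NRZ", 4), ("NEZ", 4), ("SRC", 2), ("SEC", 2), ("SRZ", 3), ("SEZ", 3),
)

# time-varying models: (code, h(K), d(K), minimum K for the formula)
TABLE_TIME_VARYING_MODELS = (
    ("R-NNtC", lambda K: K, lambda K: K // 2 - 1, 4),
    ("R-NNtZ", lambda K: K + 1, lambda K: K // 2 - 1, 4),
    ("R-SNtC", lambda K: K - 1, lambda K: K // 2 - 2, 4),
    ("R-NRtC", lambda K: K // 2 + 1, lambda K: 0, 4),
    ("R-NEtC", lambda K: K // 2 + 1, lambda K: 0, 4),
    ("R-N2tC", lambda K: K - 2, lambda K: K // 2 - 3, 6),
    ("R-SNtZ", lambda K: K, lambda K: K // 2 - 2, 4),
    ("R-NRtZ", lambda K: K // 2 + 2, lambda K: 0, 4),
    ("R-NEtZ", lambda K: K // 2 + 2, lambda K: 0, 4),
    ("R-N2tZ", lambda K: K - 1, lambda K: K // 2 - 3, 6),
    ("R-SRtC", lambda K: K // 2, lambda K: 0, 4),
    ("R-SEtC", lambda K: K // 2, lambda K: 0, 4),
    ("R-S2tC", lambda K: K - 3, lambda K: K // 2 - 4, 8),
    ("R-NR2tC", lambda K: K // 2, lambda K: 0, 6),
    ("R-NE2tC", lambda K: K // 2, lambda K: 0, 6),
    ("R-SRtZ", lambda K: K // 2 + 1, lambda K: 0, 4),
    ("R-SEtZ", lambda K: K // 2 + 1, lambda K: 0, 4),
    ("R-S2tZ", lambda K: K - 2, lambda K: K // 2 - 4, 8),
    ("R-NR2tZ", lambda K: K // 2 + 1, lambda K: 0, 6),
    ("R-NE2tZ", lambda K: K // 2 + 1, lambda K: 0, 6),
    ("R-SR2tC", lambda K: K // 2 - 1, lambda K: 0, 6),
    ("R-SR2tZ", lambda K: K // 2, lambda K: 0, 6),
    ("IR-NRtC", lambda K: K // 2 + 2, lambda K: 0, 4),
    ("IR-S1,2RtC", lambda K: K // 2, lambda K: 0, 4),
    ("IR-S1,2RatC", lambda K: K // 2 + 1, lambda K: 0, 4),
    ("IR-S1RatC", lambda K: K // 2 + 2, lambda K: 0, 4),
)


def table_report(which: str = "constant", K: int = 10, seed: int = 0) -> pd.DataFrame:
    """Redundancy report tables for the standard model lattices.

    ``which="constant"`` covers the constant-transition models in both the
    robust (two secondaries per primary) and single-secondary layouts;
    ``which="time_varying"`` covers the time-varying-transition robust and
    integrated models.  ``K`` is the total number of occasions (even).
    """
    rows = []
    if which == "constant":
        for code, h in TABLE_CONSTANT_MODELS:
            for layout, k in (("RMER", (2,) * (K // 2)), ("MER", (1,) * K)):
                full_code = ("R-" + code) if layout == "RMER" else code
                spec = parse_model_code(full_code, k)
                rep = deficiency(spec, seed=seed)
                rows.append({"layout": layout, "model_code": full_code, "h": rep.h,
                             "d": rep.deficiency, "status": rep.status})
    elif which == "time_varying":
        for code, h_fun, d_fun, min_K in TABLE_TIME_VARYING_MODELS:
            if K < min_K:
                continue
            spec = parse_model_code(code, (2,) * (K // 2))
            rep = deficiency(spec, seed=seed)
            rows.append({"model_code": code, "h": rep.h, "d": rep.deficiency,
                         "status": rep.status})
    else:
        raise ValueError("which must be 'constant' or 'time_varying'")
    return pd.DataFrame(rows)
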