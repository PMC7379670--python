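"""Multievent cell probabilities and the product-multinomial likelihood.

Each of the ``N`` animals falls into exactly one of ``K + 1`` multinomial
cells: "removed at occasion ``(i, j)``" for each of the ``K`` occasions, or
"never removed".  The cell probabilities follow from the hidden two-state
Markov chain by a forward recursion over the row vector
``v = (P(state 1, not yet removed), P(state 2, not yet removed))``:

* start at ``(pi, 1 - pi)``;
* a secondary occasion with capture probability ``p`` contributes removal
  probability ``v_1 p`` and updates ``v_1 <- v_1 (1 - p)``;
* between primaries ``v`` is multiplied by the transition matrix
  ``Phi_i = [[1-phi12, phi12], [phi21, 1-phi21]]``.

The likelihood is multinomial with index ``N = n0 + D`` where ``D`` is the
number of animals removed and ``n0`` the unknown number never removed.
``n0`` is treated as a continuous parameter through the gamma-function
relaxation of the factorials, so it can be profiled or optimised smoothly.
The multinomial coefficient is included, making maximised log-likelihoods
comparable across models fitted to the same data.

For several independently removed populations the joint log-likelihood is
the sum of the per-population terms, with shared parameters entering each.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .model_spec import ModelSpec, PopulationParameters, RobustDesign, expand_parameters

__all__ = [
    "RemovalData",
    "CellProbabilities",
    "cell_probabilities",
    "log_likelihood",
    "integrated_log_likelihood",
]


@dataclass
class RemovalData:
    """Removal counts aligned with a robust design.

    ``counts[m]`` is the number of animals removed at the ``m``-th occasion
    in flattened order (primary-major).  Counts at missing occasions must be
    zero.  ``covariates`` optionally carries a per-occasion value ``z_{i,j}``
    for logit-linear capture models.
    """

    design: RobustDesign
    counts: np.ndarray
    covariates: Optional[np.ndarray] = None

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.shape != (self.design.K,):
            raise ValueError(
                f"counts has shape {counts.shape}, expected ({self.design.K},)"
            )
        if np.any(counts < 0):
            raise ValueError("negative removal count")
        if not np.all(counts == np.round(counts)):
            raise ValueError("removal counts must be integers")
        self.counts = counts.astype(np.int64)
        mask = self.design.missing_mask()
        if np.any(self.counts[mask] != 0):
            raise ValueError("non-zero count at a missing occasion")
        if self.covariates is not None:
            z = np.asarray(self.covariates, dtype=float)
            if z.shape != (self.design.K,):
                raise ValueError("covariates must have one value per occasion")
            self.covariates = z

    @property
    def D(self) -> int:
        """Total number of animals removed."""
        return int(self.counts.sum())

    def count(self, i: int, j: int) -> int:
        return int(self.counts[self.design.occasion_index(i, j)])


@dataclass
class CellProbabilities:
    """Multinomial cell probabilities: one per occasion plus never-removed."""

    removal: np.ndarray  # L_{i,j}, flattened occasion order
    never: float  # L_0

    def as_vector(self) -> np.ndarray:
        """Full probability vector ``(L_{1,1}, ..., L_{T,k_T}, L_0)``."""
        return np.append(self.removal, self.never)


def cell_probabilities(
    params: PopulationParameters, design: RobustDesign
) -> CellProbabilities:
    """Forward-recursion cell probabilities for one population.

    The recursion keeps the joint probability of being not-yet-removed and in
    each latent state; closure within a primary period means no transition is
    applied between secondaries.  The probabilities sum to one exactly (up to
    rounding), which the test suite asserts to 1e-10.
    """
    if len(params.phi12) != design.T - 1 or len(params.phi21) != design.T - 1:
        raise ValueError("transition vectors must have length T-1")
    if len(params.p) != design.K:
        raise ValueError("p must have one entry per occasion")
    v1 = float(params.pi)
    v2 = 1.0 - v1
    L = np.empty(design.K)
    m = 0
    for i in range(design.T):
        for _ in range(design.k[i]):
            p = float(params.p[m])
            if not (0.0 <= p <= 1.0):
                raise ValueError("capture probability outside [0, 1]")
            L[m] = v1 * p
            v1 *= 1.0 - p
            m += 1
        if i < design.T - 1:
            f12 = float(params.phi12[i])
            f21 = float(params.phi21[i])
            v1, v2 = v1 * (1.0 - f12) + v2 * f21, v1 * f12 + v2 * (1.0 - f21)
    return CellProbabilities(removal=L, never=v1 + v2)


def _population_log_likelihood(
    params: PopulationParameters, data: RemovalData
) -> float:
    """Multinomial log-likelihood contribution of one population."""
    if params.n0 is None:
        raise ValueError("expanded parameters must include n0 for the likelihood")
    cells = cell_probabilities(params, data.design)
    counts = data.counts
    n0 = params.n0
    D = data.D
    N = n0 + D
    ll = gammaln(N + 1.0) - gammaln(n0 + 1.0) - float(gammaln(counts + 1.0).sum())
    observed = counts > 0
    probs = cells.removal[observed]
    if np.any(probs <= 0.0):
        # removals recorded in a zero-probability cell (e.g. p forced to 0)
        return -np.inf
    ll += float(counts[observed] @ np.log(probs))
    if cells.never > 0.0:
        ll += n0 * np.log(cells.never)
    elif n0 > 0.0:
        return -np.inf
    return ll


def _as_datasets(data, spec: ModelSpec) -> Sequence[RemovalData]:
    if isinstance(data, RemovalData):
        datasets = [data]
    else:
        datasets = list(data)
    if len(datasets) != spec.n_populations:
        raise ValueError(
            f"{len(datasets)} dataset(s) supplied for {spec.n_populations} population(s)"
        )
    for ds in datasets:
        if ds.design != spec.design:
            raise ValueError("dataset design does not match the model design")
    return datasets


def log_likelihood(theta_free, spec: ModelSpec, data, scale: str = "free") -> float:
    """Product-multinomial log-likelihood at a free-parameter vector.

    ``data`` is a single :class:`RemovalData` or, for integrated models, a
    sequence with one dataset per population.  Covariates (when the model
    requires them) are taken from the first dataset carrying them.
    Returns ``-inf`` for parameter values assigning zero probability to an
    observed removal.
    """
    datasets = _as_datasets(data, spec)
    covariates = None
    if spec.constraints.p_model == "covariate":
        for ds in datasets:
            if ds.covariates is not None:
                covariates = ds.covariates
                break
        if covariates is None:
            raise ValueError("covariate capture model but no dataset carries covariates")
    pops = expand_parameters(
        theta_free, spec, covariates=covariates, include_abundance=True, scale=scale
    )
    return float(sum(_population_log_likelihood(par, ds)
                     for par, ds in zip(pops, datasets)))


def integrated_log_likelihood(
    theta_free, spec: ModelSpec, datasets: Sequence[RemovalData], scale: str = "free"
) -> float:
    """Joint log-likelihood over populations sharing free parameters.

    Identical to :func:`log_likelihood` with a sequence of datasets; provided
    under its own name because the integrated product over populations is a
    model feature, not a convenience.
    """
    return log_likelihood(theta_free, spec, datasets, scale=scale)
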