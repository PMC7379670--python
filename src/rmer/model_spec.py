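"""Declarative specification of removal models with temporary emigration.

A removal study follows a robust design: ``T`` primary periods, the *i*-th
containing ``k_i`` secondary sampling occasions.  Each animal occupies one of
two latent states — present on site and available for capture (state 1) or
temporarily off site and unavailable (state 2).  The population is closed
within a primary period; between consecutive primaries individuals move
between states according to a first-order Markov chain with transition
probabilities ``phi12_i`` (on-site → off-site) and ``phi21_i``
(off-site → on-site), ``i = 1..T-1``.  A captured animal is permanently
removed.  The design with a single secondary occasion per primary is the
non-robust special case (MER); several populations sharing a design and some
parameters form the integrated model (IRMER).

A :class:`ModelSpec` bundles the design, the constraint choices and the
number of populations, and fixes a deterministic mapping from an ordered
free-parameter vector to the full parameter set
``(pi, phi12_i, phi21_i, p_{i,j}, n0)`` per population.

Constraint letters follow the field's conventions:

========  =======================================================
``S``     initial availability ``pi`` fixed at the mean of the
          stationary distributions of the transition matrices
``N``     no constraint (parameter free)
``R``     random emigration, ``phi12 + phi21 = 1``
``E``     even flow, ``phi12 = phi21``
``V``     generalised random emigration, ``phi12 + phi21 = v``
``t``     time-varying transition probabilities
``a``     additive logit offset on ``phi12`` for populations 2..W
``2``     last two transitions constrained equal
``C``     constant capture probability
``Z``     capture probability on a logit-linear covariate
``T``     fully time-dependent capture probability
========  =======================================================

Model codes concatenate these as ``[R-|IR-]<pi><phi><p>``, e.g. ``R-SRtC``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "RobustDesign",
    "ConstraintSet",
    "ModelSpec",
    "PopulationParameters",
    "free_parameter_names",
    "count_free_parameters",
    "expand_parameters",
    "model_code",
    "parse_model_code",
]

PI_CHOICES = ("free", "stationary")
PHI_CHOICES = ("free", "random", "even_flow", "general_v")
PHI_TIME_CHOICES = ("constant", "time_varying")
P_CHOICES = ("constant", "covariate", "time_varying")

_PHI_BASE_CODE = {"free": "N", "random": "R", "even_flow": "E", "general_v": "V"}
_PHI_BASE_FROM_CODE = {v: k for k, v in _PHI_BASE_CODE.items()}
_P_CODE = {"constant": "C", "covariate": "Z", "time_varying": "T"}
_P_FROM_CODE = {v: k for k, v in _P_CODE.items()}


@dataclass(frozen=True)
class RobustDesign:
    """Robust-design layout: primary periods and nested secondary occasions.

    Parameters
    ----------
    k
        Per-primary secondary occasion counts ``(k_1, ..., k_T)``.
    missing
        Set of 1-based ``(primary, secondary)`` occasions with no sampling
        effort.  Capture probability is forced to zero there.
    """

    k: tuple
    missing: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "k", tuple(int(x) for x in self.k))
        object.__setattr__(
            self, "missing", frozenset((int(i), int(j)) for i, j in self.missing)
        )
        if self.T < 1:
            raise ValueError("need at least one primary period")
        if any(ki < 1 for ki in self.k):
            raise ValueError("every primary period needs at least one secondary")
        for i, j in self.missing:
            if not (1 <= i <= self.T and 1 <= j <= self.k[i - 1]):
                raise ValueError(f"missing occasion ({i},{j}) outside the design")

    @property
    def T(self) -> int:
        return len(self.k)

    @property
    def K(self) -> int:
        return int(sum(self.k))

    def occasions(self):
        """All occasions as 1-based ``(primary, secondary)`` pairs, in order."""
        return [(i + 1, j + 1) for i in range(self.T) for j in range(self.k[i])]

    def occasion_index(self, i: int, j: int) -> int:
        """Flat 0-based index of 1-based occasion ``(i, j)``."""
        if not (1 <= i <= self.T and 1 <= j <= self.k[i - 1]):
            raise ValueError(f"occasion ({i},{j}) outside the design")
        return int(sum(self.k[: i - 1]) + j - 1)

    def missing_mask(self) -> np.ndarray:
        mask = np.zeros(self.K, dtype=bool)
        for i, j in self.missing:
            mask[self.occasion_index(i, j)] = True
        return mask

    @property
    def is_robust(self) -> bool:
        """True when at least one primary has repeated secondaries."""
        return any(ki > 1 for ki in self.k)


@dataclass(frozen=True)
class ConstraintSet:
    """Constraint choices binding the full parameter set.

    ``pi`` may be a single string (applied to every population) or a tuple
    with one entry per population, allowing e.g. a stationary initial state
    for one group and a free one for another.
    """

    pi: Union[str, tuple] = "free"
    phi: str = "free"
    phi_time: str = "constant"
    last_two_equal: bool = False
    p_model: str = "constant"
    group_effect: bool = False

    def __post_init__(self):
        pi = self.pi
        if isinstance(pi, str):
            pi = (pi,)
        object.__setattr__(self, "pi", tuple(pi))
        for c in self.pi:
            if c not in PI_CHOICES:
                raise ValueError(f"unknown pi constraint {c!r}")
        if self.phi not in PHI_CHOICES:
            raise ValueError(f"unknown phi constraint {self.phi!r}")
        if self.phi_time not in PHI_TIME_CHOICES:
            raise ValueError(f"unknown phi_time {self.phi_time!r}")
        if self.p_model not in P_CHOICES:
            raise ValueError(f"unknown p_model {self.p_model!r}")
        if self.last_two_equal and self.phi_time != "time_varying":
            raise ValueError('constraint "2" requires time-varying transitions')

    def pi_for(self, w: int, n_populations: int) -> str:
        if len(self.pi) == 1:
            return self.pi[0]
        if len(self.pi) != n_populations:
            raise ValueError("pi constraint tuple does not match population count")
        return self.pi[w]


@dataclass(frozen=True)
class ModelSpec:
    """A fully specified removal model: design + constraints + populations."""

    design: RobustDesign
    constraints: ConstraintSet = field(default_factory=ConstraintSet)
    n_populations: int = 1
    population_labels: Optional[tuple] = None

    def __post_init__(self):
        if self.n_populations < 1:
            raise ValueError("need at least one population")
        labels = self.population_labels
        if labels is None:
            labels = tuple(str(w + 1) for w in range(self.n_populations))
        labels = tuple(str(x) for x in labels)
        if len(labels) != self.n_populations:
            raise ValueError("population_labels length mismatch")
        for lab in labels:
            if not re.fullmatch(r"[a-z0-9]+", lab):
                raise ValueError(f"population label {lab!r} must be lowercase alphanumeric")
        object.__setattr__(self, "population_labels", labels)
        c = self.constraints
        if len(c.pi) not in (1, self.n_populations):
            raise ValueError("pi constraint tuple does not match population count")
        if c.group_effect:
            if self.n_populations < 2:
                raise ValueError("group_effect needs at least two populations")
            if c.phi == "free":
                raise ValueError("group_effect requires a phi constraint (R/E/V)")
        if c.last_two_equal and self.design.T < 3:
            raise ValueError('constraint "2" needs at least three primary periods')
        if any(c.pi_for(w, self.n_populations) == "stationary" for w in range(self.n_populations)):
            if self.design.T < 2:
                raise ValueError("stationary pi needs at least two primary periods")

    @property
    def model_code(self) -> str:
        return model_code(self)


@dataclass
class PopulationParameters:
    """Expanded parameters for one population.

    ``phi12``/``phi21`` have length ``T-1`` (transition *i* acts between
    primary *i* and *i+1*); ``p`` has one entry per occasion in flattened
    order, forced to zero at missing occasions; ``n0`` is the (continuous)
    number of animals never removed, ``None`` when abundance is excluded.
    """

    pi: float
    phi12: np.ndarray
    phi21: np.ndarray
    p: np.ndarray
    n0: Optional[float] = None

    def validate(self):
        for name, val in (("pi", np.atleast_1d(self.pi)),
                          ("phi12", self.phi12), ("phi21", self.phi21),
                          ("p", self.p)):
            if np.any(val < -1e-12) or np.any(val > 1 + 1e-12):
                raise ValueError(f"{name} outside [0, 1]")
        if self.n0 is not None and self.n0 < 0:
            raise ValueError("n0 must be non-negative")


# --------------------------------------------------------------------------
# free-parameter layout


def _n_phi_values(spec: ModelSpec) -> int:
    """Number of distinct time indices in one transition-parameter block."""
    T = spec.design.T
    if T == 1:
        return 0
    if spec.constraints.phi_time == "constant":
        return 1
    n = T - 1
    if spec.constraints.last_two_equal:
        n -= 1
    return n


def _free_p_occasions(spec: ModelSpec):
    """Occasions carrying a free capture parameter under p_model='time_varying'."""
    mask = spec.design.missing_mask()
    return [occ for occ, m in zip(spec.design.occasions(), mask) if not m]


def free_parameter_names(spec: ModelSpec, include_abundance: bool = True):
    """Ordered names of the free parameters of ``spec``.

    The order is: free initial-state parameters (one per unconstrained
    population), the ``phi12`` block, the ``phi21`` block (unconstrained
    transitions only), ``v`` (generalised random emigration), additive group
    offsets ``gamma``, the capture-probability block, and finally one ``n0``
    per population when ``include_abundance``.
    """
    c = spec.constraints
    labels = spec.population_labels
    single = spec.n_populations == 1
    names = []
    for w in range(spec.n_populations):
        if c.pi_for(w, spec.n_populations) == "free":
            names.append("pi" if single else f"pi_{labels[w]}")
    n_phi = _n_phi_values(spec)
    if n_phi == 1:
        names.append("phi12")
    else:
        names.extend(f"phi12_{i + 1}" for i in range(n_phi))
    if c.phi == "free":
        if n_phi == 1:
            names.append("phi21")
        else:
            names.extend(f"phi21_{i + 1}" for i in range(n_phi))
    if c.phi == "general_v":
        names.append("v")
    if c.group_effect:
        names.extend(f"gamma_{labels[w]}" for w in range(1, spec.n_populations))
    if c.p_model == "constant":
        names.append("p")
    elif c.p_model == "covariate":
        names.extend(["alpha", "beta"])
    else:
        names.extend(f"p_{i}_{j}" for i, j in _free_p_occasions(spec))
    if include_abundance:
        for w in range(spec.n_populations):
            names.append("n0" if single else f"n0_{labels[w]}")
    return names


def count_free_parameters(spec: ModelSpec, include_abundance: bool = True) -> int:
    """Number of free parameters *h*.

    ``include_abundance=True`` counts one ``n0`` per population (the AIC
    convention); ``False`` excludes abundance (the convention used by the
    redundancy diagnostics, whose exhaustive summary does not involve
    ``n0``).
    """
    return len(free_parameter_names(spec, include_abundance))


# --------------------------------------------------------------------------
# expansion


def _transition_series(values: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Map the free phi block to the T-1 per-transition values."""
    T = spec.design.T
    if T == 1:
        return np.zeros(0)
    if spec.constraints.phi_time == "constant":
        return np.full(T - 1, values[0])
    out = np.asarray(values, dtype=float)
    if spec.constraints.last_two_equal:
        out = np.append(out, out[-1])
    return out


def expand_parameters(
    theta,
    spec: ModelSpec,
    covariates=None,
    include_abundance: bool = True,
    scale: str = "free",
):
    """Expand a free-parameter vector to per-population parameter sets.

    Parameters
    ----------
    theta
        Free parameters, ordered as :func:`free_parameter_names`.  With
        ``scale="free"`` probabilities are on the logit scale, ``n0`` on the
        log scale and ``v`` on a ``logit(v/2)`` scale; regression
        coefficients (``alpha``, ``beta``, ``gamma``) are untransformed on
        either scale.  With ``scale="natural"`` probabilities, ``v`` and
        ``n0`` are given directly.
    covariates
        Per-occasion covariate values ``z_{i,j}`` (flattened, length K);
        required iff ``p_model == "covariate"``.

    Returns
    -------
    tuple of :class:`PopulationParameters`, one entry per population.
    """
    if scale not in ("free", "natural"):
        raise ValueError("scale must be 'free' or 'natural'")
    c = spec.constraints
    design = spec.design
    names = free_parameter_names(spec, include_abundance)
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (len(names),):
        raise ValueError(
            f"theta has length {theta.size}, expected {len(names)} for model "
            f"{spec.model_code}"
        )
    if (covariates is None) != (c.p_model != "covariate"):
        raise ValueError("covariates must be supplied iff p_model='covariate'")
    vals = dict(zip(names, theta))

    def prob(x):
        if scale == "free":
            return float(expit(x))
        if not (0.0 <= x <= 1.0):
            raise ValueError(f"probability {x} outside [0, 1]")
        return float(x)

    # phi12 baseline block
    n_phi = _n_phi_values(spec)
    if n_phi == 1:
        phi12_vals = np.array([prob(vals["phi12"])])
    else:
        phi12_vals = np.array([prob(vals[f"phi12_{i + 1}"]) for i in range(n_phi)])
    phi12_base = _transition_series(phi12_vals, spec)

    if c.phi == "general_v":
        v = 2.0 * expit(vals["v"]) if scale == "free" else float(vals["v"])
        if not (0.0 < v < 2.0):
            raise ValueError(f"v = {v} outside (0, 2)")

    def phi21_from(phi12):
        if c.phi == "free":
            if n_phi == 1:
                p21 = np.array([prob(vals["phi21"])])
            else:
                p21 = np.array([prob(vals[f"phi21_{i + 1}"]) for i in range(n_phi)])
            return _transition_series(p21, spec)
        if c.phi == "random":
            return 1.0 - phi12
        if c.phi == "even_flow":
            return phi12.copy()
        phi21 = v - phi12
        if np.any(phi21 < 0) or np.any(phi21 > 1):
            raise ValueError("phi21 = v - phi12 leaves [0, 1]")
        return phi21

    # shared capture probabilities
    mask = design.missing_mask()
    if c.p_model == "constant":
        p = np.full(design.K, prob(vals["p"]))
    elif c.p_model == "covariate":
        z = np.asarray(covariates, dtype=float)
        if z.shape != (design.K,):
            raise ValueError(f"covariates must have length K={design.K}")
        if np.any(~np.isfinite(z[~mask])):
            raise ValueError("covariate missing for a sampled occasion")
        p = expit(vals["alpha"] + vals["beta"] * np.where(mask, 0.0, z))
    else:
        p = np.zeros(design.K)
        for i, j in _free_p_occasions(spec):
            p[design.occasion_index(i, j)] = prob(vals[f"p_{i}_{j}"])
    p = np.where(mask, 0.0, p)

    labels = spec.population_labels
    single = spec.n_populations == 1
    pops = []
    for w in range(spec.n_populations):
        if c.group_effect and w > 0:
            gamma = float(vals[f"gamma_{labels[w]}"])
            with np.errstate(divide="ignore"):
                phi12 = expit(logit(phi12_base) + gamma)
            # a boundary baseline stays on the boundary under a finite offset
            phi12 = np.where(phi12_base <= 0.0, 0.0, np.where(phi12_base >= 1.0, 1.0, phi12))
        else:
            phi12 = phi12_base.copy()
        phi21 = phi21_from(phi12)
        pi_kind = c.pi_for(w, spec.n_populations)
        if pi_kind == "free":
            pi_w = prob(vals["pi" if single else f"pi_{labels[w]}"])
        else:
            denom = phi12 + phi21
            if np.any(denom <= 0):
                raise ValueError("stationary pi undefined: phi12 + phi21 = 0")
            pi_w = float(np.mean(phi21 / denom))
        n0_w = None
        if include_abundance:
            raw = vals["n0" if single else f"n0_{labels[w]}"]
            n0_w = float(np.exp(raw)) if scale == "free" else float(raw)
            if n0_w < 0:
                raise ValueError("n0 must be non-negative")
        pop = PopulationParameters(pi=pi_w, phi12=phi12, phi21=phi21, p=p.copy(), n0=n0_w)
        pop.validate()
        pops.append(pop)
    return tuple(pops)


# --------------------------------------------------------------------------
# model codes


def model_code(spec: ModelSpec) -> str:
    """Deterministic label of the form ``[R-|IR-]<pi><phi><p>``."""
    c = spec.constraints
    if spec.n_populations > 1:
        prefix = "IR-"
    elif spec.design.is_robust:
        prefix = "R-"
    else:
        prefix = ""
    stat = [spec.population_labels[w]
            for w in range(spec.n_populations)
            if c.pi_for(w, spec.n_populations) == "stationary"]
    if not stat:
        pi_part = "N"
    elif spec.n_populations == 1:
        pi_part = "S"
    else:
        pi_part = "S" + ",".join(stat)
    base = _PHI_BASE_CODE[c.phi]
    if c.phi == "free" and c.last_two_equal:
        base = ""  # the bare-"2" convention: constraint 2 on otherwise free transitions
    phi_part = base
    if c.group_effect:
        phi_part += "a"
    if c.last_two_equal:
        phi_part += "2"
    if c.phi_time == "time_varying":
        phi_part += "t"
    p_part = _P_CODE[c.p_model]
    return prefix + pi_part + phi_part + p_part


# population subscripts after "S" (e.g. S1,2 / Sju,ad) only occur in integrated
# codes; outside IR- a digit after S is the last-two-equal constraint "2"
_CODE_RE_IR = re.compile(
    r"^(?P<prefix>IR-)"
    r"(?P<pi>N|S(?P<subs>[a-z0-9]+(?:,[a-z0-9]+)*)?)"
    r"(?P<base>[NREV])?(?P<add>a)?(?P<two>2)?(?P<tv>t)?"
    r"(?P<p>[CZT])$"
)
_CODE_RE_SINGLE = re.compile(
    r"^(?P<prefix>R-)?"
    r"(?P<pi>[NS])"
    r"(?P<base>[NREV])?(?P<add>a)?(?P<two>2)?(?P<tv>t)?"
    r"(?P<p>[CZT])$"
)


def parse_model_code(
    code: str,
    k,
    missing=frozenset(),
    population_labels=None,
) -> ModelSpec:
    """Build a :class:`ModelSpec` from a model code and a design layout.

    Examples: ``"NNC"`` (single-secondary design, everything free, constant
    p), ``"R-SRtC"``, ``"IR-S1,2RatZ"``.  The design is supplied through
    ``k`` (and optional ``missing``) because the code alone does not carry
    the layout.
    """
    code = code.strip()
    m = _CODE_RE_IR.match(code) if code.startswith("IR-") else _CODE_RE_SINGLE.match(code)
    if m is None:
        raise ValueError(f"cannot parse model code {code!r}")
    design = RobustDesign(tuple(k), frozenset(missing))
    prefix = m.group("prefix") or ""
    base = m.group("base")
    if base is None:
        if not m.group("two"):
            raise ValueError(f"cannot parse model code {code!r}: missing phi constraint")
        phi = "free"
    else:
        phi = _PHI_BASE_FROM_CODE[base]
    phi_time = "time_varying" if m.group("tv") else "constant"
    constraints_kw = dict(
        phi=phi,
        phi_time=phi_time,
        last_two_equal=bool(m.group("two")),
        p_model=_P_FROM_CODE[m.group("p")],
        group_effect=bool(m.group("add")),
    )
    subs = m.groupdict().get("subs")
    if prefix == "IR-":
        if population_labels is None:
            if subs:
                labels = tuple(subs.split(","))
                if len(labels) == 1:
                    labels = labels + ("2",) if labels[0] != "2" else ("1", "2")
            else:
                labels = ("1", "2")
        else:
            labels = tuple(str(x) for x in population_labels)
        n_pop = len(labels)
        if m.group("pi") == "N":
            pi = ("free",) * n_pop
        else:
            stat = set(subs.split(",")) if subs else set(labels)
            unknown = stat - set(labels)
            if unknown:
                raise ValueError(f"unknown population labels {sorted(unknown)} in {code!r}")
            pi = tuple("stationary" if lab in stat else "free" for lab in labels)
        spec = ModelSpec(design, ConstraintSet(pi=pi, **constraints_kw),
                         n_populations=n_pop, population_labels=labels)
    else:
        if subs:
            raise ValueError(f"population subscripts need an IR- prefix: {code!r}")
        pi = "stationary" if m.group("pi") == "S" else "free"
        spec = ModelSpec(design, ConstraintSet(pi=pi, **constraints_kw))
        if prefix == "R-" and not design.is_robust:
            raise ValueError("code has an R- prefix but the design has no repeated secondaries")
        if prefix == "" and design.is_robust:
            raise ValueError("robust design requires an R- prefix in the model code")
    return spec
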