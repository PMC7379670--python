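"""Named simulation scenarios used throughout the package.

The presets emulate the study conditions of the simulation experiments that
motivated these models: a closed population of ``N`` animals surveyed under
a robust design with two secondaries per primary, constant capture
probability 0.3, and random-emigration transitions (``phi21 = 1 - phi12``).
"s1" variants have animals tending to stay off site (high ``phi12``), "s2"
variants tending to stay on site.  The initial availability ``pi`` is always
the mean of the first elements of the stationary distributions of the
transition matrices — under random emigration simply ``mean(1 - phi12)``.

========== =========================================================
Preset      Conditions
========== =========================================================
const-s1    N=500, constant phi12=0.8 (phi21=0.2)
const-s2    N=500, constant phi12=0.4 (phi21=0.6)
tv-s1       N=500, time-varying phi12, off-site-leaning series
tv-s2       N=500, time-varying phi12, on-site-leaning series
int-s1      two populations N=300/M=200, tv series of s1, additive
            logit offset gamma2 = -0.5 on phi12 for population 2
int-s2      as int-s1 with the s2 series
========== =========================================================
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit, logit

from .model_spec import PopulationParameters, RobustDesign

__all__ = ["SimulationScenario", "scenario", "SCENARIO_NAMES", "TV_PHI12"]

CONST_PHI12 = {"s1": 0.8, "s2": 0.4}
CONST_PHI21 = {"s1": 0.2, "s2": 0.6}
CAPTURE_P = 0.3
GAMMA2 = -0.5

# time-varying phi12 truth series, keyed by (variant, K); two secondaries per
# primary, so K occasions mean K/2 primaries and K/2 - 1 transitions
TV_PHI12 = {
    ("s1", 20): (0.8, 0.7, 0.8, 0.3, 0.6, 0.7, 0.8, 0.6, 0.6),
    ("s2", 20): (0.4, 0.4, 0.8, 0.4, 0.4, 0.8, 0.4, 0.4, 0.4),
    ("s1", 10): (0.7, 0.2, 0.7, 0.7),
    ("s2", 10): (0.3, 0.8, 0.3, 0.3),
}

SCENARIO_NAMES = ("const-s1", "const-s2", "tv-s1", "tv-s2", "int-s1", "int-s2")


@dataclass(frozen=True)
class SimulationScenario:
    """Truth for a simulation study: design, per-population truths and sizes."""

    name: str
    design: RobustDesign
    truths: tuple  # PopulationParameters per population (n0 unset)
    N: tuple  # true abundance per population
    n_replicates: int = 500
    seed: Optional[int] = None

    @property
    def n_populations(self) -> int:
        return len(self.N)


def _random_emigration_truth(phi12, design: RobustDesign) -> PopulationParameters:
    phi12 = np.asarray(phi12, dtype=float)
    phi21 = 1.0 - phi12
    pi = float(np.mean(phi21 / (phi12 + phi21)))
    return PopulationParameters(
        pi=pi,
        phi12=phi12,
        phi21=phi21,
        p=np.full(design.K, CAPTURE_P),
        n0=None,
    )


def scenario(name: str, K: int = 20, n_replicates: int = 500,
             seed: Optional[int] = None) -> SimulationScenario:
    """Build a named scenario at ``K`` total occasions (two per primary)."""
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    if K % 2 != 0 or K < 4:
        raise ValueError("scenario designs use two secondaries per primary; K must be even >= 4")
    kind, variant = name.split("-")
    T = K // 2
    design = RobustDesign((2,) * T)
    if kind == "const":
        phi12 = np.full(T - 1, CONST_PHI12[variant])
        truths = (_random_emigration_truth(phi12, design),)
        sizes = (500,)
    else:
        if (variant, K) not in TV_PHI12:
            raise ValueError(f"no time-varying truth series for K={K}")
        phi12 = np.asarray(TV_PHI12[(variant, K)], dtype=float)
        pop1 = _random_emigration_truth(phi12, design)
        if kind == "tv":
            truths = (pop1,)
            sizes = (500,)
        else:
            phi12_2 = expit(logit(phi12) + GAMMA2)
            pop2 = _random_emigration_truth(phi12_2, design)
            truths = (pop1, pop2)
            sizes = (300, 200)
    return SimulationScenario(
        name=name, design=design, truths=truths, N=sizes,
        n_replicates=n_replicates, seed=seed,
    )
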