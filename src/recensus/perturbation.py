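"""Forward model of the table-publication privacy mechanism.

Census tabulation platforms protect respondents by perturbing every
published cell: bounded symmetric integer noise is added, negative results
are floored at zero, and small results are suppressed (published as zero).
Community diabetes-register maps apply a different rule: counts below 20 are
censored and the rest rounded to the nearest ten.

Both mechanisms live here, together with the *exact* observation likelihood
P(published | true) that the reconstruction sampler uses as its data term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PerturbConfig",
    "perturb_count",
    "perturbation_loglik",
    "loglik_support",
    "ndss_censor_round",
    "SUPPRESSED",
]

#: Sentinel for a censored register report.
SUPPRESSED = "suppressed"

_NEG_INF = float("-inf")


@dataclass
class PerturbConfig:
    """Noise-injection and low-count-suppression settings.

    d
        Maximum noise magnitude; noise support is {-d..+d}.
    noise_pmf
        Probabilities over {-d..+d}; must sum to 1 and be symmetric about 0.
    tau
        Suppression threshold: noisy values <= tau publish as 0.
    zero_fixed
        True cell counts of zero publish as zero deterministically.

    Defaults give bounded +/-2 noise with a peaked symmetric pmf and
    suppression of noisy values below 3 — small true counts frequently
    publish as zero while large counts are published near-exactly.
    """

    d: int = 2
    noise_pmf: tuple[float, ...] = (0.1, 0.2, 0.4, 0.2, 0.1)
    tau: int = 2
    zero_fixed: bool = True

    def __post_init__(self) -> None:
        pmf = np.asarray(self.noise_pmf, dtype=float)
        if self.d < 0 or self.tau < 0:
            raise ValueError("d and tau must be nonnegative")
        if pmf.size != 2 * self.d + 1:
            raise ValueError("noise_pmf must have 2d+1 entries")
        if not math.isclose(pmf.sum(), 1.0, abs_tol=1e-12):
            raise ValueError("noise_pmf must sum to 1")
        if not np.allclose(pmf, pmf[::-1]):
            raise ValueError("noise_pmf must be symmetric about 0")
        if (pmf < 0).any():
            raise ValueError("noise_pmf entries must be nonnegative")

    @property
    def pmf(self) -> np.ndarray:
        return np.asarray(self.noise_pmf, dtype=float)

    @property
    def cdf(self) -> np.ndarray:
        """Cumulative pmf over noise values -d..+d."""
        return np.cumsum(self.pmf)


def perturb_count(y: int, pcfg: PerturbConfig, rng: np.random.Generator) -> int:
    """Publish one cell: add noise, floor at zero, suppress small results."""
    if y < 0:
        raise ValueError("true count must be nonnegative")
    if pcfg.zero_fixed and y == 0:
        return 0
    eps = int(rng.choice(2 * pcfg.d + 1, p=pcfg.pmf)) - pcfg.d
    noisy = max(0, y + eps)
    return 0 if noisy <= pcfg.tau else noisy


def perturbation_loglik(o: int, y: int, pcfg: PerturbConfig) -> float:
    """Exact log P(o | y) under :func:`perturb_count`.

    The published value o = 0 aggregates the suppression and zero-floor
    events; 0 < o <= tau is unreachable; o > tau requires |o - y| <= d.
    Returns -inf for impossible pairs.
    """
    if o < 0 or y < 0:
        raise ValueError("counts must be nonnegative")
    if pcfg.zero_fixed and y == 0:
        return 0.0 if o == 0 else _NEG_INF
    if o == 0:
        # noisy <= tau  <=>  eps <= tau - y  (tau >= 0 so flooring folds in)
        k = pcfg.tau - y
        if k < -pcfg.d:
            return _NEG_INF
        k = min(k, pcfg.d)
        p = float(pcfg.cdf[k + pcfg.d])
        return math.log(p) if p > 0 else _NEG_INF
    if o <= pcfg.tau:
        return _NEG_INF
    eps = o - y
    if abs(eps) > pcfg.d:
        return _NEG_INF
    p = float(pcfg.pmf[eps + pcfg.d])
    return math.log(p) if p > 0 else _NEG_INF


def loglik_support(o: int, pcfg: PerturbConfig, y_max: int) -> list[int]:
    """True counts y <= y_max with positive likelihood for published o."""
    return [
        y
        for y in range(y_max + 1)
        if perturbation_loglik(o, y, pcfg) > _NEG_INF
    ]


def ndss_censor_round(c: int):
    """Register-map disclosure rule: censor below 20, round to nearest ten.

    Ties round half-up (25 -> 30). Returns :data:`SUPPRESSED` for censored
    counts, else the rounded integer.
    """
    if c < 0:
        raise ValueError("count must be nonnegative")
    if c < 20:
        return SUPPRESSED
    return 10 * int(math.floor(c / 10 + 0.5))
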