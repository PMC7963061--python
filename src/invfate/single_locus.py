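"""Single-locus overdominant Wright-Fisher model (the inversion's control).

A biallelic locus with genotype fitnesses 1 : 1+s_het : 1, started from a
single allele copy, gives the no-allelic-content benchmark for the
inversion's short-term fate: the same population size and heterozygote
advantage, but no mutational load, no recombination suppression, no gene
flux. Selection is applied deterministically to the expected frequency and
then 2N allele copies are binomially resampled each generation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SingleLocusSummary",
    "simulate_overdominant_locus",
    "max_loss_time",
    "selection_recursion",
    "equilibrium_recursion",
]


@dataclass
class SingleLocusSummary:
    reps: int
    horizon: int
    loss_times: np.ndarray  # generations, one per replicate that lost the allele
    fixation_times: np.ndarray
    n_polymorphic: int

    @property
    def p_polymorphic_at_horizon(self) -> float:
        return self.n_polymorphic / self.reps

    @property
    def n_lost(self) -> int:
        return int(self.loss_times.size)

    @property
    def n_fixed(self) -> int:
        return int(self.fixation_times.size)


def _expected_next_frequency(p: np.ndarray, w_hom_derived, w_het, w_hom_anc) -> np.ndarray:
    """Deterministic selection update for genotype fitnesses (pp, pq, qq)."""
    q = 1.0 - p
    wbar = p * p * w_hom_derived + 2 * p * q * w_het + q * q * w_hom_anc
    return (p * p * w_hom_derived + p * q * w_het) / wbar


def simulate_overdominant_locus(
    N: int,
    s_het: float,
    reps: int,
    horizon: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> SingleLocusSummary:
    """Follow ``reps`` single-copy overdominant alleles to loss/fixation/horizon.

    Genotype fitnesses are 1 : 1 + s_het : 1 and the allele starts at
    frequency 1/(2N). Returns the aggregate fate summary. All replicates are
    advanced in lockstep with vectorized binomial sampling.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    p = np.full(reps, 1.0 / (2 * N))
    loss_times: list[int] = []
    fixation_times: list[int] = []
    active = np.ones(reps, dtype=bool)
    for t in range(1, horizon + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        pe = _expected_next_frequency(p[idx], 1.0, 1.0 + s_het, 1.0)
        pa = rng.binomial(2 * N, pe) / (2.0 * N)
        p[idx] = pa
        lost = pa == 0.0
        fixed = pa == 1.0
        loss_times.extend([t] * int(lost.sum()))
        fixation_times.extend([t] * int(fixed.sum()))
        active[idx[lost | fixed]] = False
    return SingleLocusSummary(
        reps=reps,
        horizon=horizon,
        loss_times=np.asarray(loss_times, dtype=np.int64),
        fixation_times=np.asarray(fixation_times, dtype=np.int64),
        n_polymorphic=int(active.sum()),
    )


def max_loss_time(summary: SingleLocusSummary, allowed_overshoot: float = 0.0) -> int:
    """Largest loss generation, optionally discarding a Monte-Carlo tail.

    ``allowed_overshoot`` is the fraction of losses permitted to exceed the
    returned bound (e.g. 0.01 returns the smallest generation that covers at
    least 99% of losses). With the default 0.0 this is the plain maximum.
    """
    if summary.loss_times.size == 0:
        raise ValueError("no losses observed; the loss-time bound is undefined")
    if allowed_overshoot <= 0:
        return int(summary.loss_times.max())
    return int(np.quantile(summary.loss_times, 1.0 - allowed_overshoot, method="higher"))


def selection_recursion(
    p0: float,
    w_hom_derived: float,
    w_het: float,
    w_hom_anc: float,
    n_gens: int,
) -> float:
    """Iterate the deterministic (infinite-N) genotype-frequency recursion."""
    p = float(p0)
    for _ in range(n_gens):
        p = float(_expected_next_frequency(np.asarray(p), w_hom_derived, w_het, w_hom_anc))
    return p


def equilibrium_recursion(
    w_hom_derived: float,
    w_het: float,
    w_hom_anc: float,
    p0: float = 0.1,
    tol: float = 1e-13,
    max_iter: int = 10_000_000,
) -> float:
    """Deterministic equilibrium frequency by fixed-point iteration."""
    p = float(p0)
    for _ in range(max_iter):
        nxt = float(_expected_next_frequency(np.asarray(p), w_hom_derived, w_het, w_hom_anc))
        if abs(nxt - p) < tol:
            return nxt
        p = nxt
    return p
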