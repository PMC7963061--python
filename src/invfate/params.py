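"""Model constants, genome layout, the deleterious DFE, and parameter rescaling.

The simulated system is a single isolated diploid population with three
chromosomes. Only coding positions carry allelic state; non-coding sequence
contributes recombination distance only. All mutations are deleterious and
fully recessive, with selection-coefficient magnitudes drawn from a gamma
distribution. A chromosomal inversion may span part of chromosome 1; its only
direct fitness effect is a heterokaryotype advantage ``s_het``.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "DFEParams",
    "RecombinationParams",
    "GenomeLayout",
    "SimulationParameters",
    "ConfigurationError",
    "build_genome_layout",
    "default_inversion_span",
    "rescale",
    "sample_selection_coefficient",
    "is_effectively_neutral",
]


class ConfigurationError(ValueError):
    """Raised when parameters are inconsistent or cannot be represented."""


@dataclass(frozen=True)
class DFEParams:
    """Gamma distribution of deleterious-effect magnitudes |s|.

    ``mean_s`` is the mean magnitude alpha/beta (beta acting as a rate), so the
    default gamma(shape=0.5) with mean 0.005 corresponds to beta = 100.
    Rescaling multiplies ``mean_s`` and never touches ``shape``.
    """

    shape: float = 0.5
    mean_s: float = 0.005

    def __post_init__(self) -> None:
        if not self.shape > 0:
            raise ConfigurationError(f"DFE shape must be > 0, got {self.shape}")
        if not self.mean_s > 0:
            raise ConfigurationError(f"DFE mean_s must be > 0, got {self.mean_s}")

    @property
    def scale(self) -> float:
        """Scale parameter of the gamma distribution (mean / shape)."""
        return self.mean_s / self.shape


@dataclass(frozen=True)
class RecombinationParams:
    """Crossover and gene-conversion initiation rates, per bp per meiosis.

    ``sex_halving`` folds female-limited recombination into a halved overall
    initiation rate r = (rho + gamma) / 2. Initiations are uniform along the
    genome; each one is a crossover with probability rho/(rho+gamma), else a
    gene-conversion tract of Poisson(``gc_tract_mean``) length extending
    rightward from the initiation point.
    """

    crossover_rate: float = 3.0e-8
    gc_init_rate: float = 1.8e-8
    gc_tract_mean: float = 500.0
    sex_halving: bool = True

    def __post_init__(self) -> None:
        if self.crossover_rate < 0:
            raise ConfigurationError("crossover_rate must be >= 0")
        if self.gc_init_rate < 0:
            raise ConfigurationError("gc_init_rate must be >= 0")
        if not self.gc_tract_mean > 0:
            raise ConfigurationError("gc_tract_mean must be > 0")

    @property
    def total_initiation_rate(self) -> float:
        """Overall per-bp initiation rate r."""
        r = self.crossover_rate + self.gc_init_rate
        return r / 2.0 if self.sex_halving else r

    @property
    def p_crossover(self) -> float:
        """Probability that an initiation resolves as a crossover."""
        tot = self.crossover_rate + self.gc_init_rate
        return self.crossover_rate / tot if tot > 0 else 0.0


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome lengths, coding segments, and the optional inversion span.

    ``coding_segments[c]`` is a tuple of half-open (start, end) bp intervals on
    chromosome ``c``. ``inversion_span`` is a half-open interval on chromosome
    0 (the first chromosome) or None.
    """

    chromosomes: tuple[int, ...]
    coding_segments: tuple[tuple[tuple[int, int], ...], ...]
    inversion_span: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if len(self.chromosomes) != len(self.coding_segments):
            raise ConfigurationError("one coding-segment list required per chromosome")
        for c, (length, segs) in enumerate(zip(self.chromosomes, self.coding_segments)):
            prev_end = 0
            for lo, hi in segs:
                if not (0 <= lo < hi <= length):
                    raise ConfigurationError(
                        f"coding segment ({lo}, {hi}) outside chromosome {c} [0, {length})"
                    )
                if lo < prev_end:
                    raise ConfigurationError(f"overlapping coding segments on chromosome {c}")
                prev_end = hi
        if self.inversion_span is not None:
            lo, hi = self.inversion_span
            if not (0 <= lo < hi <= self.chromosomes[0]):
                raise ConfigurationError("inversion span must lie on chromosome 1")

    # -- derived geometry ---------------------------------------------------

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def total_bp(self) -> int:
        return int(sum(self.chromosomes))

    @property
    def coding_bp(self) -> int:
        return int(
            sum(hi - lo for segs in self.coding_segments for lo, hi in segs)
        )

    @property
    def chrom_offsets(self) -> np.ndarray:
        """Concatenated-coordinate start of each chromosome, plus total length."""
        return np.concatenate([[0], np.cumsum(self.chromosomes)]).astype(np.int64)

    def global_position(self, chrom: int, pos: int) -> int:
        """Map (chrom, pos) to a single concatenated genome coordinate."""
        return int(self.chrom_offsets[chrom] + pos)

    def local_position(self, gpos: int) -> tuple[int, int]:
        """Inverse of :meth:`global_position`."""
        offsets = self.chrom_offsets
        chrom = int(np.searchsorted(offsets, gpos, side="right") - 1)
        return chrom, int(gpos - offsets[chrom])

    def coding_intervals_global(self) -> tuple[np.ndarray, np.ndarray]:
        """All coding segments as (starts, ends) in concatenated coordinates."""
        starts, ends = [], []
        for c, segs in enumerate(self.coding_segments):
            off = int(self.chrom_offsets[c])
            for lo, hi in segs:
                starts.append(off + lo)
                ends.append(off + hi)
        return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)

    def is_coding(self, chrom: int, pos: int) -> bool:
        """O(log k) membership query against the coding segments."""
        segs = self.coding_segments[chrom]
        i = bisect.bisect_right([s[0] for s in segs], pos) - 1
        return i >= 0 and segs[i][0] <= pos < segs[i][1]

    @property
    def inversion_span_global(self) -> Optional[tuple[int, int]]:
        if self.inversion_span is None:
            return None
        lo, hi = self.inversion_span
        return self.global_position(0, lo), self.global_position(0, hi)

    def region_class(self, chrom: int, pos: int) -> str:
        """Classify a position: ``inverted`` | ``linked`` | ``collinear``.

        Linked positions share chromosome 1 with the inversion but fall outside
        its span; positions on other chromosomes are collinear. Without an
        inversion everything is collinear.
        """
        if self.inversion_span is not None and chrom == 0:
            lo, hi = self.inversion_span
            return "inverted" if lo <= pos < hi else "linked"
        return "collinear"

    def with_inversion(self, span: tuple[int, int]) -> "GenomeLayout":
        return replace(self, inversion_span=(int(span[0]), int(span[1])))


def build_genome_layout(
    coding_fraction: float = 0.3,
    segment_len: int = 50_000,
    gap_len: int = 100_000,
    chrom_len: int = 1_000_000,
    n_chrom: int = 3,
) -> GenomeLayout:
    """Build the alternating coding/non-coding chromosome layout.

    Each chromosome starts with a coding segment at bp 0 and alternates
    ``segment_len`` coding with ``gap_len`` non-coding; leftover non-coding
    sequence sits at the chromosome end. The defaults give 6 x 50 kb coding
    segments (300 kb) per 1 Mb chromosome.
    """
    target = coding_fraction * chrom_len
    k = round(target / segment_len)
    if k < 1 or abs(k * segment_len - target) > 1e-6:
        raise ConfigurationError(
            f"coding_fraction {coding_fraction} of {chrom_len} bp is not an integer "
            f"number of {segment_len} bp segments"
        )
    needed = k * segment_len + (k - 1) * gap_len
    if needed > chrom_len:
        raise ConfigurationError(
            f"{k} segments of {segment_len} bp with {gap_len} bp gaps need "
            f"{needed} bp but the chromosome is {chrom_len} bp"
        )
    segs = tuple(
        (i * (segment_len + gap_len), i * (segment_len + gap_len) + segment_len)
        for i in range(k)
    )
    return GenomeLayout(
        chromosomes=tuple(int(chrom_len) for _ in range(n_chrom)),
        coding_segments=tuple(segs for _ in range(n_chrom)),
    )


def default_inversion_span(layout: GenomeLayout, chrom_fraction: float = 0.3) -> tuple[int, int]:
    """Centered span on chromosome 1 covering ``chrom_fraction`` of its length.

    The default 30% of chromosome 1 equals 10% of the three-chromosome genome.
    """
    L = layout.chromosomes[0]
    lo = round(L * (0.5 - chrom_fraction / 2))
    hi = lo + round(L * chrom_fraction)
    return int(lo), int(hi)


@dataclass(frozen=True)
class SimulationParameters:
    """Everything a run needs; the single source of model constants."""

    N: int = 25_000
    mu: float = 8.4e-9
    dfe: DFEParams = field(default_factory=DFEParams)
    recomb: RecombinationParams = field(default_factory=RecombinationParams)
    s_het: float = 0.003
    layout: GenomeLayout = field(default_factory=build_genome_layout)
    rescaling_q: float = 1.0
    burn_in_gens: int = 500_000
    max_gens: int = 500_000
    record_interval: int = 200
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ConfigurationError(f"N must be >= 2, got {self.N}")
        if self.mu < 0:
            raise ConfigurationError("mu must be >= 0")
        if self.s_het < 0:
            raise ConfigurationError("s_het must be >= 0")
        if self.rescaling_q < 1:
            raise ConfigurationError("rescaling factor must be >= 1")
        for name in ("burn_in_gens", "max_gens", "record_interval"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    # Rescaling-invariant products (diagnostics; see :func:`rescale`).
    @property
    def theta_total(self) -> float:
        """2 N mu L over coding sequence."""
        return 2.0 * self.N * self.mu * self.layout.coding_bp

    @property
    def rho_total(self) -> float:
        """2 N r L with r the overall initiation rate."""
        return 2.0 * self.N * self.recomb.total_initiation_rate * self.layout.total_bp

    @property
    def two_n_s(self) -> float:
        return 2.0 * self.N * self.dfe.mean_s

    @property
    def tract_fraction(self) -> float:
        """lambda / L — mean gene-conversion tract relative to genome length."""
        return self.recomb.gc_tract_mean / self.layout.total_bp


def _scaled_int(value: int, q: float, what: str) -> int:
    scaled = value / q
    if abs(scaled - round(scaled)) > 1e-9:
        raise ConfigurationError(f"{what} = {value} is not divisible by Q = {q}")
    return int(round(scaled))


def rescale(params: SimulationParameters, q: float) -> SimulationParameters:
    """Rescale to a smaller, faster population with the same dynamics.

    Population size and all genomic lengths shrink by ``q``; mutation and
    recombination initiation rates grow by ``q**2``; selection coefficients
    (the DFE mean and ``s_het``) grow by ``q``; the mean gene-conversion tract
    shrinks by ``q``. The products 2NmuL, 2Ns, 2NrL and lambda/L are invariant,
    so drift, selection, mutation and recombination keep their relative
    strengths while wall-clock cost drops by roughly q^3.

    Generation counts (burn-in, horizon, record interval) are left untouched:
    they are a run-profile choice, not part of the scaling group.
    """
    if q == 1:
        return params
    if q < 1:
        raise ConfigurationError("rescaling factor must be >= 1")
    layout = params.layout
    new_layout = GenomeLayout(
        chromosomes=tuple(
            _scaled_int(L, q, f"chromosome {c} length") for c, L in enumerate(layout.chromosomes)
        ),
        coding_segments=tuple(
            tuple(
                (_scaled_int(lo, q, "coding segment start"), _scaled_int(hi, q, "coding segment end"))
                for lo, hi in segs
            )
            for segs in layout.coding_segments
        ),
        inversion_span=None
        if layout.inversion_span is None
        else (
            _scaled_int(layout.inversion_span[0], q, "inversion start"),
            _scaled_int(layout.inversion_span[1], q, "inversion end"),
        ),
    )
    return replace(
        params,
        N=_scaled_int(params.N, q, "N"),
        mu=params.mu * q * q,
        dfe=replace(params.dfe, mean_s=params.dfe.mean_s * q),
        recomb=replace(
            params.recomb,
            crossover_rate=params.recomb.crossover_rate * q * q,
            gc_init_rate=params.recomb.gc_init_rate * q * q,
            gc_tract_mean=params.recomb.gc_tract_mean / q,
        ),
        s_het=params.s_het * q,
        layout=new_layout,
        rescaling_q=params.rescaling_q * q,
    )


def sample_selection_coefficient(
    rng: np.random.Generator, dfe: DFEParams, size: Optional[int] = None
):
    """Draw negative selection coefficients with |s| ~ Gamma(shape, scale)."""
    return -rng.gamma(dfe.shape, dfe.scale, size=size)


def is_effectively_neutral(s, n_total: int):
    """True iff |s| < 1/(2N) for the *total* population size, strictly."""
    return np.abs(s) < 1.0 / (2.0 * n_total)
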