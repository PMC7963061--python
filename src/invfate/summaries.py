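"""Descriptive statistics of arrangement divergence.

Everything here consumes an :class:`ArrangementSnapshot` — a binary
haplotype-by-site matrix sampled from a population, with per-site metadata —
or the fixation logs produced by a run: arrangement-private fixed
differences, cumulative fixation curves by genomic region, per-SNP F_ST
between arrangements, and the effectively-neutral share of fixed mutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .params import GenomeLayout, is_effectively_neutral
from .population import Haplotype, Population

__all__ = [
    "ArrangementSnapshot",
    "build_snapshot",
    "haplotype_matrix",
    "fixed_difference_count",
    "cumulative_fixation_curves",
    "per_site_fst",
    "neutral_fraction_of_fixed",
]

SITE_COLUMNS = ["uid", "chrom", "pos", "s", "origin_gen", "region_class"]


@dataclass
class ArrangementSnapshot:
    """Sampled haplotype-by-site binary matrix with site metadata.

    ``matrix`` has one row per sampled haplotype (entries 0/1, 1 = derived
    allele present), ``arrangements`` one 'I'/'S' label per row, and ``sites``
    one metadata row per column (uid, chrom, pos, s, origin_gen,
    region_class).
    """

    matrix: np.ndarray
    arrangements: np.ndarray
    sites: pd.DataFrame
    generation: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        self.arrangements = np.asarray(self.arrangements, dtype=object)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (haplotypes x sites)")
        if self.matrix.shape[0] != self.arrangements.shape[0]:
            raise ValueError("one arrangement label required per haplotype row")
        if self.matrix.shape[1] != len(self.sites):
            raise ValueError("one site-metadata row required per matrix column")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def rows_of(self, arrangement: str) -> np.ndarray:
        return np.flatnonzero(self.arrangements == arrangement)

    def restrict(self, mask: np.ndarray) -> "ArrangementSnapshot":
        """New snapshot keeping only the site columns selected by ``mask``."""
        return ArrangementSnapshot(
            matrix=self.matrix[:, mask],
            arrangements=self.arrangements,
            sites=self.sites.loc[np.asarray(mask)].reset_index(drop=True),
            generation=self.generation,
        )


def build_snapshot(
    haplotypes: Sequence[Haplotype],
    layout: GenomeLayout,
    generation: int = 0,
    span_only: bool = False,
) -> ArrangementSnapshot:
    """Build a snapshot from haplotype objects.

    Columns are the union of mutations carried by the sample (segregating or
    sample-fixed), ordered by (chrom, pos, id). ``span_only`` restricts to
    the inversion span.
    """
    muts = {}
    for h in haplotypes:
        for m in h.mutations:
            muts[m.id] = m
    ordered = sorted(muts.values(), key=lambda m: m.sort_key)
    if span_only:
        if layout.inversion_span is None:
            raise ValueError("layout has no inversion span to restrict to")
        lo, hi = layout.inversion_span
        ordered = [m for m in ordered if m.chrom == 0 and lo <= m.pos < hi]
    col = {m.id: j for j, m in enumerate(ordered)}
    matrix = np.zeros((len(haplotypes), len(ordered)), dtype=np.uint8)
    for i, h in enumerate(haplotypes):
        for m in h.mutations:
            j = col.get(m.id)
            if j is not None:
                matrix[i, j] = 1
    sites = pd.DataFrame(
        {
            "uid": [m.id for m in ordered],
            "chrom": [m.chrom for m in ordered],
            "pos": [m.pos for m in ordered],
            "s": [m.s for m in ordered],
            "origin_gen": [m.origin_gen for m in ordered],
            "region_class": [m.region_class(layout) for m in ordered],
        }
    )
    return ArrangementSnapshot(
        matrix=matrix,
        arrangements=np.array([h.arrangement for h in haplotypes], dtype=object),
        sites=sites,
        generation=generation,
    )


def haplotype_matrix(
    pop: Population,
    layout: GenomeLayout,
    arrangement: str,
    n: int,
    rng: np.random.Generator,
) -> ArrangementSnapshot:
    """Sample ``n`` haplotypes of one arrangement, restricted to the span."""
    haps = [h for h in pop.haplotypes() if h.arrangement == arrangement]
    if not haps:
        raise ValueError(f"arrangement {arrangement!r} absent from the population")
    if n > len(haps):
        raise ValueError(f"requested {n} haplotypes but only {len(haps)} carry {arrangement!r}")
    chosen = [haps[i] for i in rng.choice(len(haps), size=n, replace=False)]
    return build_snapshot(chosen, layout, generation=pop.generation, span_only=True)


def _arrangement_frequencies(snap: ArrangementSnapshot) -> tuple[np.ndarray, np.ndarray, int, int]:
    rows_i = snap.rows_of("I")
    rows_s = snap.rows_of("S")
    if rows_i.size == 0 or rows_s.size == 0:
        raise ValueError("both arrangements must be present in the snapshot")
    p_i = snap.matrix[rows_i].mean(axis=0)
    p_s = snap.matrix[rows_s].mean(axis=0)
    return p_i, p_s, rows_i.size, rows_s.size


def fixed_difference_count(
    snap: ArrangementSnapshot, span_bp: Optional[int] = None
) -> dict[str, float]:
    """Sites at frequency 1 in one arrangement and 0 in the other.

    Returns ``{"count": ..., "per_kb": ...}``; per_kb is NaN unless
    ``span_bp`` (the inversion span length) is given.
    """
    p_i, p_s, _, _ = _arrangement_frequencies(snap)
    fixed = ((p_i == 1.0) & (p_s == 0.0)) | ((p_i == 0.0) & (p_s == 1.0))
    count = int(fixed.sum())
    per_kb = count / (span_bp / 1000.0) if span_bp else float("nan")
    return {"count": count, "per_kb": per_kb}


def cumulative_fixation_curves(
    fixations: pd.DataFrame,
    extents_kb: Mapping[str, float],
) -> dict[str, pd.DataFrame]:
    """Cumulative fixed mutations per kb, by origin generation and class.

    ``fixations`` needs columns ``origin_gen`` and ``class`` (e.g. the
    arrangement or genomic region a mutation fixed in); ``extents_kb`` maps
    each class to the kb extent used for normalization. Each returned frame
    has columns ``origin_gen`` and ``cum_per_kb`` and is a non-decreasing
    step function of origin generation.
    """
    out: dict[str, pd.DataFrame] = {}
    for cls, kb in extents_kb.items():
        sub = fixations[fixations["class"] == cls]
        if sub.empty:
            out[cls] = pd.DataFrame({"origin_gen": [], "cum_per_kb": []})
            continue
        gens = np.sort(sub["origin_gen"].to_numpy())
        uniq, counts = np.unique(gens, return_counts=True)
        out[cls] = pd.DataFrame(
            {"origin_gen": uniq, "cum_per_kb": np.cumsum(counts) / kb}
        )
    return out


def per_site_fst(snap: ArrangementSnapshot, n_total: Optional[int] = None) -> pd.DataFrame:
    """Hudson-style per-site F_ST between the two arrangements.

    F_ST = 1 - H_w / H_b with H_w the mean within-arrangement heterozygosity
    (2 p q averaged over the two arrangements) and H_b the between-arrangement
    heterozygosity (p1 q2 + p2 q1), both from sample allele frequencies
    without small-sample correction. Sites monomorphic in the pooled sample
    are skipped. If ``n_total`` is given, an effectively-neutral flag
    (|s| < 1/(2 n_total)) is attached.
    """
    p_i, p_s, n_i, n_s = _arrangement_frequencies(snap)
    if n_i < 2 or n_s < 2:
        raise ValueError("need at least 2 haplotypes per arrangement")
    pooled = snap.matrix.mean(axis=0)
    keep = (pooled > 0.0) & (pooled < 1.0)
    h_w = 0.5 * (2 * p_i * (1 - p_i) + 2 * p_s * (1 - p_s))
    h_b = p_i * (1 - p_s) + p_s * (1 - p_i)
    keep &= h_b > 0.0
    fst = 1.0 - h_w[keep] / h_b[keep]
    out = snap.sites.loc[keep, ["uid", "chrom", "pos", "s", "origin_gen", "region_class"]].copy()
    out["fst"] = fst
    out["p_I"] = p_i[keep]
    out["p_S"] = p_s[keep]
    if n_total is not None:
        out["effectively_neutral"] = is_effectively_neutral(out["s"].to_numpy(), n_total)
    return out.reset_index(drop=True)


def neutral_fraction_of_fixed(s_values: np.ndarray, n_total: int) -> float:
    """Share of fixed mutations that are effectively neutral (|s| < 1/(2N))."""
    s_values = np.asarray(s_values, dtype=float)
    if s_values.size == 0:
        raise ValueError("neutral fraction undefined for an empty fixation set")
    return float(np.mean(is_effectively_neutral(s_values, n_total)))
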