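"""Per-run fate classification and long-term outcome detection.

A finished run is classified by the terminal state of the inversion (lost,
fixed, or still polymorphic), by the viability of the two homokaryotypes
(average relative fitness below 0.001 means inviable), by whether the run has
become a balanced lethal system (both homokaryotypes inviable while the
polymorphism persists, so only heterokaryotypes reproduce), and by whether an
arrangement has undergone haplotype structuring — the splitting of one
arrangement into complementary high-load haplotype clusters, recognizable as
a bimodal homokaryotype fitness distribution together with discrete cluster
structure in the haplotype matrix.

Analytic anchors: when only the minority homokaryotype is inviable and the
heterokaryotype advantage is the imposed s_het, the minority arrangement
equilibrates at s_het / (1 + 2 s_het); in the balanced lethal case the
expected equilibrium frequency is 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "StructuringReport",
    "OutcomeReport",
    "classify_fate",
    "inviability",
    "detect_balanced_lethal",
    "detect_haplotype_structuring",
    "predicted_equilibrium_frequency",
    "INVIABILITY_THRESHOLD",
]

INVIABILITY_THRESHOLD = 0.001  # mean relative fitness below this = inviable


@dataclass
class StructuringReport:
    status: str  # 'structured' | 'not-structured' | 'undetermined'
    n_clusters: int
    fitness_bimodal: bool
    cluster_ratio: float  # mean between-cluster / mean within-cluster distance
    low_mode_fraction: float
    high_mode_fraction: float

    @property
    def detected(self) -> bool:
        return self.status == "structured"


@dataclass
class OutcomeReport:
    fate: str  # 'lost' | 'fixed' | 'polymorphic'
    fate_gen: Optional[int]
    short_term_polymorphic: bool
    inviable_II: Optional[bool] = None
    inviable_SS: Optional[bool] = None
    balanced_lethal: Optional[bool] = None
    structuring: dict = field(default_factory=dict)
    predicted_equilibrium_p: Optional[float] = None


def classify_fate(
    series, n_hap: int, short_term_gen: int = 10_000
) -> tuple[str, Optional[int], bool]:
    """Fate from a recorded inversion-count series.

    ``series`` is a DataFrame with columns ``gen_since_intro`` and
    ``inv_count``; ``n_hap`` = 2N. Returns (fate, fate_gen, short_term_flag):
    the short-term flag is True iff the count is strictly inside (0, 2N) at
    the short-term window (``short_term_gen`` generations after introduction,
    clipped to the recorded horizon for runs shorter than the window).
    """
    if len(series) == 0:
        raise ValueError("empty series: cannot classify fate")
    gens = series["gen_since_intro"].to_numpy()
    counts = series["inv_count"].to_numpy()
    if (np.diff(gens) <= 0).any():
        raise ValueError("series generations must be strictly increasing")
    final = int(counts[-1])
    if final == 0:
        fate, fate_gen = "lost", int(gens[-1])
    elif final == n_hap:
        fate, fate_gen = "fixed", int(gens[-1])
    else:
        fate, fate_gen = "polymorphic", None
    # count at the last record no later than the window (absorptions stick)
    window = min(short_term_gen, int(gens[-1]))
    i = int(np.searchsorted(gens, window, side="right") - 1)
    short_term = 0 < int(counts[i]) < n_hap
    return fate, fate_gen, short_term


def inviability(relative_fitness_sample: np.ndarray) -> bool:
    """True iff the mean relative fitness is strictly below 0.001.

    Fitness values must be relative to the contemporaneous population mean.
    """
    sample = np.asarray(relative_fitness_sample, dtype=float)
    if sample.size == 0:
        raise ValueError("empty fitness sample; use virtual homokaryotypes instead")
    return bool(sample.mean() < INVIABILITY_THRESHOLD)


def detect_balanced_lethal(
    inviable_II: bool, inviable_SS: bool, fate: str
) -> bool:
    """Both homokaryotypes inviable while the polymorphism persists."""
    return bool(inviable_II and inviable_SS and fate == "polymorphic")


def _cluster_structure(
    matrix: np.ndarray, max_clusters: int = 8, ratio_threshold: float = 2.0
) -> tuple[int, float]:
    """Average-linkage clustering on pairwise Hamming distances.

    Returns (n_clusters, between/within ratio) for the best-supported cut: the
    number of clusters maximizing the ratio of mean between-cluster to mean
    within-cluster Hamming distance, among cuts meeting the threshold.
    Returns (1, 0.0) when no cut qualifies.
    """
    n = matrix.shape[0]
    d = pdist(matrix, metric="hamming")
    if not (d > 0).any():
        return 1, 0.0
    dm = squareform(d)
    link = linkage(d, method="average")
    best_k, best_ratio = 1, 0.0
    for k in range(2, min(max_clusters, n - 1) + 1):
        labels = fcluster(link, t=k, criterion="maxclust")
        if len(np.unique(labels)) != k:
            continue
        same = labels[:, None] == labels[None, :]
        iu = np.triu_indices(n, k=1)
        within = dm[iu][same[iu]]
        between = dm[iu][~same[iu]]
        if between.size == 0:
            continue
        w = within.mean() if within.size else 0.0
        b = between.mean()
        ratio = np.inf if w == 0 else b / w
        if ratio >= ratio_threshold and ratio >= best_ratio:
            best_k, best_ratio = k, float(ratio)
    return best_k, best_ratio


def detect_haplotype_structuring(
    matrix: np.ndarray,
    homokaryotype_relative_fitness: np.ndarray,
    min_haplotypes: int = 20,
    low_mode_threshold: float = INVIABILITY_THRESHOLD,
    gap_orders: float = 1.0,
    min_mode_fraction: float = 0.10,
    ratio_threshold: float = 2.0,
) -> StructuringReport:
    """Dual-criterion haplotype-structuring test for one arrangement.

    (a) Fitness bimodality: the (possibly virtual) homokaryotype relative
    fitness sample has a near-zero mode (< ``low_mode_threshold``) and a
    viable mode, each holding at least ``min_mode_fraction`` of the sample,
    separated by an empty gap of at least ``gap_orders`` orders of magnitude.
    (b) Cluster structure: average-linkage clustering of within-span
    haplotypes by Hamming distance yields >= 2 clusters whose mean
    between-cluster distance is >= ``ratio_threshold`` times the mean
    within-cluster distance. Structuring is called iff (a) AND (b); the
    cluster count comes from (b).

    Detection is invariant to row/column permutations of ``matrix``. With
    fewer than ``min_haplotypes`` rows the status is 'undetermined'.
    """
    matrix = np.asarray(matrix)
    w = np.asarray(homokaryotype_relative_fitness, dtype=float)
    if matrix.shape[0] < min_haplotypes:
        return StructuringReport("undetermined", 0, False, 0.0, 0.0, 0.0)

    high_threshold = low_mode_threshold * 10.0**gap_orders
    low_frac = float((w < low_mode_threshold).mean()) if w.size else 0.0
    high_frac = float((w >= high_threshold).mean()) if w.size else 0.0
    gap_empty = bool(
        ~((w >= low_mode_threshold) & (w < high_threshold)).any()
    ) if w.size else False
    bimodal = (
        low_frac >= min_mode_fraction and high_frac >= min_mode_fraction and gap_empty
    )

    n_clusters, ratio = _cluster_structure(matrix, ratio_threshold=ratio_threshold)
    clustered = n_clusters >= 2

    status = "structured" if (bimodal and clustered) else "not-structured"
    return StructuringReport(
        status=status,
        n_clusters=n_clusters if clustered else 1,
        fitness_bimodal=bimodal,
        cluster_ratio=ratio,
        low_mode_fraction=low_frac,
        high_mode_fraction=high_frac,
    )


def predicted_equilibrium_frequency(case: str, s_het: float = 0.0) -> float:
    """Analytic equilibrium frequency of the minority/inverted arrangement.

    ``minority-lethal``: one homokaryotype inviable, heterokaryotype advantage
    s_het only -> s_het / (1 + 2 s_het). ``balanced-lethal``: both
    homokaryotypes inviable -> 0.5.
    """
    if case == "minority-lethal":
        return s_het / (1.0 + 2.0 * s_het)
    if case == "balanced-lethal":
        return 0.5
    raise ValueError(f"unknown case {case!r}")
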