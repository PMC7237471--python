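"""Cluster census statistics, GO-term similarity, and correlation summaries.

Also carries, as plain input data, the published whole-proteome prediction
counts for the 15-species angiosperm panel (sequence counts and predicted
chloroplast-targeted counts per species) and the per-species counts of
nascent plastid-targeted protein (NPTP) families found by each clustering
method, so the proteome-size correlations can be recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import Cluster

__all__ = [
    "ClusterCensus",
    "census",
    "go_similarity",
    "r_squared",
    "PROTEOME_TABLE",
    "NPTP_COUNTS",
    "nptp_size_correlation",
    "plastid_size_correlation",
    "plot_census_histogram",
]


@dataclass(frozen=True)
class ClusterCensus:
    total: int
    singletons: int
    single_species: int
    by_species_count: Mapping[int, int]   # number of species -> cluster count
    per_species_totals: Mapping[str, int]  # species -> clusters containing it

    def __post_init__(self) -> None:
        if sum(self.by_species_count.values()) != self.total:
            raise ValueError("species-count histogram does not sum to total")
        if self.singletons > self.single_species:
            raise ValueError("singletons must be a subset of single-species clusters")

    @property
    def single_species_fraction(self) -> float:
        return self.single_species / self.total if self.total else 0.0

    @property
    def multi_species(self) -> int:
        return self.total - self.single_species


def census(
    clusters: Sequence[Cluster],
    species_of: Mapping[str, str],
) -> ClusterCensus:
    """Exact cluster census: totals, singletons, species-count histogram."""
    histogram: dict[int, int] = {}
    per_species: dict[str, int] = {}
    singletons = single_species = 0
    for cluster in clusters:
        species = {species_of[m] for m in cluster.members}
        histogram[len(species)] = histogram.get(len(species), 0) + 1
        for sp in species:
            per_species[sp] = per_species.get(sp, 0) + 1
        if len(species) == 1:
            single_species += 1
            if len(cluster) == 1:
                singletons += 1
    return ClusterCensus(
        total=len(clusters),
        singletons=singletons,
        single_species=single_species,
        by_species_count=dict(sorted(histogram.items())),
        per_species_totals=dict(sorted(per_species.items())),
    )


def go_similarity(
    cluster: Cluster,
    annotations: Mapping[str, Iterable[str]],
) -> float | None:
    """Mean pairwise Jaccard index of members' GO term sets.

    Members without annotations are excluded; with fewer than two annotated
    members the score is undefined and ``None`` is returned.  Identical
    term sets across all pairs score 1.0, disjoint sets 0.0.
    """
    term_sets = [
        frozenset(annotations[m])
        for m in cluster.members
        if m in annotations and annotations[m]
    ]
    if len(term_sets) < 2:
        return None
    total = 0.0
    n_pairs = 0
    for i in range(len(term_sets)):
        for j in range(i + 1, len(term_sets)):
            union = term_sets[i] | term_sets[j]
            total += len(term_sets[i] & term_sets[j]) / len(union)
            n_pairs += 1
    return total / n_pairs


def r_squared(x: Sequence[float], y: Sequence[float]) -> float:
    """Coefficient of determination: squared Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input")
    r, _ = sps.pearsonr(x, y)
    return float(r**2)


# ---------------------------------------------------------------------------
# Published per-species input data (15-species angiosperm panel).
#
# n_sequences / n_plastid are the proteome size and consensus-predicted
# chloroplast-targeted count per species; n_sequences_expanded differs only
# for Malus x domestica, whose proteome was expanded with de-novo
# transcriptome ORFs (74,249 total entries).  nptp_* are the per-species
# NPTP family counts from the two clustering methods.

PROTEOME_TABLE = pd.DataFrame(
    [
        # species, n_sequences, n_sequences_expanded, n_plastid, nptp_rbh, nptp_uclust
        ("Atr", 26846, 26846, 1833, 82, 195),
        ("Aam", 27959, 27959, 1324, 52, 97),
        ("Ath", 35386, 35386, 2826, 74, 166),
        ("Bdi", 52972, 52972, 4240, 229, 398),
        ("Fve", 32831, 32831, 2051, 140, 379),
        ("Gma", 73320, 73320, 5125, 191, 341),
        ("Mdo", 57386, 74249, 4665, 328, 728),
        ("Osa", 49061, 49061, 3417, 184, 329),
        ("Pvi", 133775, 133775, 10262, 682, 1458),
        ("Ptr", 73013, 73013, 5741, 167, 240),
        ("Ppe", 47089, 47089, 3615, 112, 193),
        ("Sit", 43001, 43001, 3461, 268, 382),
        ("Sly", 47205, 47205, 1875, 71, 166),
        ("Sbi", 34727, 34727, 3918, 250, 363),
        ("Vvi", 55564, 55564, 3932, 113, 197),
    ],
    columns=[
        "species", "n_sequences", "n_sequences_expanded", "n_plastid",
        "nptp_rbh", "nptp_uclust",
    ],
).set_index("species")

NPTP_COUNTS = {
    "rbh": PROTEOME_TABLE["nptp_rbh"],
    "uclust": PROTEOME_TABLE["nptp_uclust"],
}


def nptp_size_correlation(method: str = "rbh", expanded_malus: bool = True) -> float:
    """R² of per-species NPTP counts against total proteome size."""
    if method not in NPTP_COUNTS:
        raise ValueError(f"method must be one of {sorted(NPTP_COUNTS)}")
    col = "n_sequences_expanded" if expanded_malus else "n_sequences"
    return r_squared(PROTEOME_TABLE[col], NPTP_COUNTS[method])


def plastid_size_correlation(expanded_malus: bool = False) -> float:
    """R² of predicted plastid-targeted counts against proteome size."""
    col = "n_sequences_expanded" if expanded_malus else "n_sequences"
    return r_squared(PROTEOME_TABLE[col], PROTEOME_TABLE["n_plastid"])


def plot_census_histogram(cluster_census: ClusterCensus, path: str) -> None:
    """Bar chart of clusters by number of species (optional side output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    keys = sorted(cluster_census.by_species_count)
    values = [cluster_census.by_species_count[k] for k in keys]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(keys, values, color="#3a7d44")
    ax.set_xlabel("species per cluster")
    ax.set_ylabel("clusters")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
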