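"""Proteome preprocessing, consensus targeting, and cluster classification.

Proteomes are filtered to sequences of >= 100 residues starting with
methionine.  A protein counts as plastid-targeted when both TargetP and
Localizer call a chloroplast transit peptide (the 2-of-2 consensus).
Clusters are then classified from their per-species plastid profile:

* ``conserved`` — >= 13 of the 15 species present and every present
  species has >= 1 plastid-predicted member or >= 4 non-plastid members
  (the false-negative exemption: with a ~39% false-negative rate, four
  homologous non-plastid calls make a missed true positive likely).
* ``semi_conserved`` — plastid targeting confined to the smallest lineage
  group (family, then subclade, then clade) containing >= 2 targeted
  species, with no targeted species outside it and no outgroup evidence
  (neither a plastid call nor the >= 4-member exemption in the outgroup).
  Outgroup-only targeting with >= 2 sequences also counts (one-species
  clade).
* ``nptp`` — nascent plastid-targeted protein family: >= 3 species present
  but exactly one species with plastid-predicted members.
* single-species clusters and singletons are discarded; everything else is
  ``unclassified``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .targeting import WorkflowSpec, apply_workflow
from .types import Cluster, ProteinRecord, Taxonomy, LINEAGE_LEVELS

__all__ = [
    "PreprocessReport",
    "preprocess_proteome",
    "consensus_targeting",
    "SpeciesProfile",
    "build_profile",
    "ClassificationParams",
    "ClusterClassification",
    "classify_cluster",
    "classify_all",
    "CATEGORIES",
]

CATEGORIES = (
    "conserved",
    "semi_conserved",
    "nptp",
    "unclassified",
    "discarded_single_species",
)


@dataclass(frozen=True)
class PreprocessReport:
    kept: int
    removed_short: int
    removed_bad_start: int

    @property
    def removed(self) -> int:
        return self.removed_short + self.removed_bad_start


def preprocess_proteome(
    records: Sequence[ProteinRecord],
    min_length: int = 100,
) -> tuple[list[ProteinRecord], PreprocessReport]:
    """Keep sequences >= ``min_length`` residues that begin with methionine.

    Returns the filtered list plus a removal report.  A sequence failing
    both rules is counted under the length rule (checked first).
    """
    kept: list[ProteinRecord] = []
    short = bad_start = 0
    for rec in records:
        if rec.length < min_length:
            short += 1
        elif not rec.sequence.startswith("M"):
            bad_start += 1
        else:
            kept.append(rec)
    return kept, PreprocessReport(
        kept=len(kept), removed_short=short, removed_bad_start=bad_start
    )


def consensus_targeting(
    calls: pd.DataFrame,
    predictors: Sequence[str] = ("TargetP", "Localizer"),
) -> pd.Series:
    """2-of-2 consensus: plastid iff every listed predictor calls plastid.

    Equivalent to ``apply_workflow`` with the full subset and
    ``threshold=len(predictors)``.
    """
    spec = WorkflowSpec(tuple(predictors), threshold=len(predictors))
    return apply_workflow(spec, calls).rename("plastid")


@dataclass(frozen=True)
class SpeciesProfile:
    """Per-species counts of plastid- and non-plastid-predicted members."""

    counts: Mapping[str, tuple[int, int]]  # species -> (n_plastid, n_other)

    def __post_init__(self) -> None:
        for sp, (p, n) in self.counts.items():
            if p < 0 or n < 0 or p + n == 0:
                raise ValueError(f"invalid counts for species {sp!r}: {(p, n)}")

    @property
    def species_present(self) -> frozenset[str]:
        return frozenset(self.counts)

    @property
    def plastid_species(self) -> frozenset[str]:
        return frozenset(sp for sp, (p, _) in self.counts.items() if p > 0)

    def plastid_count(self, species: str) -> int:
        return self.counts.get(species, (0, 0))[0]

    def non_plastid_count(self, species: str) -> int:
        return self.counts.get(species, (0, 0))[1]

    @property
    def total(self) -> int:
        return sum(p + n for p, n in self.counts.values())


def build_profile(
    cluster: Cluster,
    species_of: Mapping[str, str],
    plastid_set: Iterable[str],
) -> SpeciesProfile:
    """Tally plastid / non-plastid members per species for one cluster."""
    plastid = set(plastid_set)
    counts: dict[str, list[int]] = {}
    for member in cluster.members:
        if member not in species_of:
            raise KeyError(f"no species for cluster member {member!r}")
        slot = counts.setdefault(species_of[member], [0, 0])
        slot[0 if member in plastid else 1] += 1
    return SpeciesProfile(counts={sp: (p, n) for sp, (p, n) in counts.items()})


@dataclass(frozen=True)
class ClassificationParams:
    """Tunable thresholds of the conservation rules.

    ``fn_exemption`` is the count of non-plastid members that lets a
    species pass as "likely plastid" despite predictor false negatives.
    """

    min_species_conserved: int = 13
    fn_exemption: int = 4
    min_clade_species: int = 2
    min_species_nptp: int = 3

    def __post_init__(self) -> None:
        for name in (
            "min_species_conserved", "fn_exemption",
            "min_clade_species", "min_species_nptp",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


@dataclass(frozen=True)
class ClusterClassification:
    category: str
    clade: str | None = None      # set for semi_conserved
    species: str | None = None    # set for nptp

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "semi_conserved" and not self.clade:
            raise ValueError("semi_conserved requires a clade label")
        if self.category == "nptp" and not self.species:
            raise ValueError("nptp requires a species label")


def _outgroup_blocked(
    profile: SpeciesProfile, taxonomy: Taxonomy, params: ClassificationParams
) -> bool:
    """Outgroup evidence that vetoes clade-specific calls."""
    og = taxonomy.outgroup
    return (
        profile.plastid_count(og) > 0
        or profile.non_plastid_count(og) >= params.fn_exemption
    )


def classify_cluster(
    profile: SpeciesProfile,
    taxonomy: Taxonomy,
    params: ClassificationParams = ClassificationParams(),
) -> ClusterClassification:
    """Classify one cluster's species profile (rules in module docstring)."""
    present = profile.species_present
    if not present:
        raise ValueError("empty profile")
    for sp in present:
        if sp not in taxonomy:
            raise KeyError(f"species {sp!r} not in taxonomy")
    if len(present) <= 1:
        return ClusterClassification("discarded_single_species")

    plastid_sp = profile.plastid_species
    likely = {
        sp
        for sp in present
        if profile.plastid_count(sp) > 0
        or profile.non_plastid_count(sp) >= params.fn_exemption
    }

    if (
        len(present) >= params.min_species_conserved
        and likely == present
        and plastid_sp
    ):
        return ClusterClassification("conserved")

    if plastid_sp:
        og = taxonomy.outgroup
        if plastid_sp == {og}:
            # outgroup-specific targeting: one-species clade; require >= 2
            # plastid sequences to mirror the two-species rule elsewhere
            if profile.plastid_count(og) >= params.min_clade_species:
                return ClusterClassification(
                    "semi_conserved", clade=taxonomy.clade_of(og)
                )
        elif len(plastid_sp) >= params.min_clade_species and not _outgroup_blocked(
            profile, taxonomy, params
        ):
            # smallest lineage group containing every targeted species
            for level in reversed(LINEAGE_LEVELS):  # family, subclade, clade
                labels = {taxonomy.label(sp, level) for sp in plastid_sp}
                if len(labels) == 1:
                    label = labels.pop()
                    if og not in taxonomy.members(level, label):
                        return ClusterClassification("semi_conserved", clade=label)

    if len(present) >= params.min_species_nptp and len(plastid_sp) == 1:
        return ClusterClassification("nptp", species=next(iter(plastid_sp)))

    return ClusterClassification("unclassified")


def classify_all(
    clusters: Sequence[Cluster],
    species_of: Mapping[str, str],
    plastid_set: Iterable[str],
    taxonomy: Taxonomy,
    params: ClassificationParams = ClassificationParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every cluster and build the per-species summary table.

    Returns ``(classifications, census)``.  ``classifications`` has one row
    per cluster (category, clade/species labels, member and species
    counts).  ``census`` has one row per species in the taxonomy: total
    clusters containing it, clusters with a plastid member of that species,
    clusters where it is the only targeted species, single-species
    clusters, and its NPTP count — the layout of the per-species clustering
    summaries.
    """
    plastid = set(plastid_set)
    rows = []
    per_species: dict[str, dict[str, int]] = {
        sp: {
            "total_clusters": 0,
            "plastid_clusters": 0,
            "unique_plastid_clusters": 0,
            "single_species_clusters": 0,
            "nptps": 0,
        }
        for sp in sorted(taxonomy.species)
    }
    for cluster in clusters:
        profile = build_profile(cluster, species_of, plastid)
        cls = classify_cluster(profile, taxonomy, params)
        plastid_sp = profile.plastid_species
        rows.append(
            {
                "cluster_id": cluster.id,
                "category": cls.category,
                "clade": cls.clade,
                "species": cls.species,
                "n_members": len(cluster),
                "n_species": len(profile.species_present),
                "n_plastid_members": sum(
                    profile.plastid_count(sp) for sp in plastid_sp
                ),
            }
        )
        for sp in profile.species_present:
            stats = per_species[sp]
            stats["total_clusters"] += 1
            if sp in plastid_sp:
                stats["plastid_clusters"] += 1
                if plastid_sp == {sp}:
                    stats["unique_plastid_clusters"] += 1
            if len(profile.species_present) == 1:
                stats["single_species_clusters"] += 1
        if cls.category == "nptp":
            per_species[cls.species]["nptps"] += 1

    classifications = pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "category", "clade", "species",
            "n_members", "n_species", "n_plastid_members",
        ],
    )
    census = pd.DataFrame.from_dict(per_species, orient="index")
    census.index.name = "species"
    return classifications, census.reset_index()
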