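"""Core domain types shared across the pipeline.

The unit of analysis is a protein sequence tagged with its species of
origin.  Pairwise similarity hits (BLAST-style) are the edge material for
clustering; clusters are plain member sets whose species composition and
predicted plastid targeting drive the downstream conservation calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "ProteinRecord",
    "SimilarityHit",
    "HomologyEdge",
    "Cluster",
    "Taxonomy",
    "LINEAGE_LEVELS",
    "default_taxonomy",
]

#: Lineage levels from coarsest to finest.  ``clade`` separates monocots,
#: eudicots and the Amborella outgroup; ``subclade`` and ``family`` refine it.
LINEAGE_LEVELS = ("clade", "subclade", "family")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its species of origin."""

    id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise similarity hit (identity/coverage on a 0-100 scale).

    ``rank`` is 1-based within the query's hit list, in hit-file order
    (BLAST emits hits best-first).  Self-hits are retained but flagged so
    intra-species operations can exclude them.
    """

    query: str
    target: str
    identity: float
    query_cov: float
    target_cov: float
    bitscore: float
    rank: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError(f"identity out of [0, 100]: {self.identity}")
        for cov in (self.query_cov, self.target_cov):
            if not (0.0 <= cov <= 100.0):
                raise ValueError(f"coverage out of [0, 100]: {cov}")
        if self.rank < 1:
            raise ValueError(f"rank must be >= 1, got {self.rank}")

    @property
    def is_self(self) -> bool:
        return self.query == self.target


@dataclass(frozen=True)
class HomologyEdge:
    """An undirected homology edge, stored with canonically ordered ends.

    ``kind`` records how the edge was derived: ``inter_species_rbh`` for
    reciprocal best hits between species, ``intra_species_better`` for the
    90/90 top-10 reciprocal paralog expansion.
    """

    a: str
    b: str
    kind: str = "inter_species_rbh"

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"self-edge not allowed: {self.a!r}")
        if self.a > self.b:
            lo, hi = self.b, self.a
            object.__setattr__(self, "a", lo)
            object.__setattr__(self, "b", hi)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a, self.b)


@dataclass(frozen=True)
class Cluster:
    """A protein family: a cluster id plus its member protein ids."""

    id: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"cluster {self.id!r} has no members")
        object.__setattr__(self, "members", tuple(sorted(set(self.members))))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.members

    def species_set(self, species_of: Mapping[str, str]) -> frozenset[str]:
        return frozenset(species_of[m] for m in self.members)

    def plastid_members(self, plastid_set: Iterable[str]) -> frozenset[str]:
        plastid = set(plastid_set)
        return frozenset(m for m in self.members if m in plastid)


def clusters_from_sets(member_sets: Iterable[Iterable[str]], prefix: str = "C") -> list[Cluster]:
    """Assign deterministic ids (sorted by smallest member) to member sets."""
    sets = [tuple(sorted(set(s))) for s in member_sets]
    sets.sort(key=lambda s: s[0])
    width = max(4, len(str(len(sets))))
    return [Cluster(f"{prefix}{i:0{width}d}", s) for i, s in enumerate(sets, start=1)]


@dataclass(frozen=True)
class Taxonomy:
    """Species → ordered lineage labels (clade, subclade, family).

    One species is distinguished as the outgroup (the Amborella role): the
    early-diverging lineage against which clade-specific plastid targeting
    is screened.
    """

    lineages: Mapping[str, tuple[str, str, str]]
    outgroup: str

    def __post_init__(self) -> None:
        if not self.lineages:
            raise ValueError("taxonomy has no species")
        for sp, lineage in self.lineages.items():
            if len(lineage) != len(LINEAGE_LEVELS) or not lineage[0]:
                raise ValueError(f"species {sp!r} has no complete lineage")
        if self.outgroup not in self.lineages:
            raise ValueError(f"outgroup {self.outgroup!r} is not a known species")
        # lineage levels must form a tree: one parent label per child label
        parent: dict[tuple[str, str], str] = {}
        for lineage in self.lineages.values():
            for lvl in range(1, len(LINEAGE_LEVELS)):
                key = (LINEAGE_LEVELS[lvl], lineage[lvl])
                if parent.setdefault(key, lineage[lvl - 1]) != lineage[lvl - 1]:
                    raise ValueError(
                        f"{LINEAGE_LEVELS[lvl]} {lineage[lvl]!r} appears under "
                        f"two different parents"
                    )

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self.lineages)

    def __contains__(self, species: str) -> bool:
        return species in self.lineages

    def _check(self, species: str) -> None:
        if species not in self.lineages:
            raise KeyError(f"species {species!r} not in taxonomy")

    def label(self, species: str, level: str) -> str:
        self._check(species)
        return self.lineages[species][LINEAGE_LEVELS.index(level)]

    def clade_of(self, species: str) -> str:
        return self.label(species, "clade")

    def members(self, level: str, label: str) -> frozenset[str]:
        idx = LINEAGE_LEVELS.index(level)
        return frozenset(
            sp for sp, lineage in self.lineages.items() if lineage[idx] == label
        )

    def groups(self, level: str) -> dict[str, frozenset[str]]:
        idx = LINEAGE_LEVELS.index(level)
        labels = {lineage[idx] for lineage in self.lineages.values()}
        return {lab: self.members(level, lab) for lab in sorted(labels)}


def default_taxonomy() -> Taxonomy:
    """The 15-species angiosperm panel: 6 monocots, 8 eudicots, Amborella.

    Species codes are three-letter abbreviations of the binomial names.
    Amborella trichopoda (Atr) is the outgroup, having diverged before the
    monocot/eudicot split.
    """
    lineages = {
        # monocots
        "Aam": ("monocot", "alismatid", "Araceae"),       # Anthurium amnicola
        "Bdi": ("monocot", "commelinid", "Poaceae"),      # Brachypodium distachyon
        "Osa": ("monocot", "commelinid", "Poaceae"),      # Oryza sativa
        "Pvi": ("monocot", "commelinid", "Poaceae"),      # Panicum virgatum
        "Sit": ("monocot", "commelinid", "Poaceae"),      # Setaria italica
        "Sbi": ("monocot", "commelinid", "Poaceae"),      # Sorghum bicolor
        # eudicots
        "Ath": ("eudicot", "rosid", "Brassicaceae"),      # Arabidopsis thaliana
        "Fve": ("eudicot", "rosid", "Rosaceae"),          # Fragaria vesca
        "Gma": ("eudicot", "rosid", "Fabaceae"),          # Glycine max
        "Mdo": ("eudicot", "rosid", "Rosaceae"),          # Malus x domestica
        "Ptr": ("eudicot", "rosid", "Salicaceae"),        # Populus trichocarpa
        "Ppe": ("eudicot", "rosid", "Rosaceae"),          # Prunus persica
        "Sly": ("eudicot", "asterid", "Solanaceae"),      # Solanum lycopersicum
        "Vvi": ("eudicot", "rosid", "Vitaceae"),          # Vitis vinifera
        # outgroup
        "Atr": ("amborella", "amborella", "Amborellaceae"),  # Amborella trichopoda
    }
    return Taxonomy(lineages=lineages, outgroup="Atr")
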