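"""Synthetic protein families, targeting truth, predictor calls, hit tables.

The generator emulates the statistical structure the pipeline assumes so
every stage is testable without external proteomes: homologous families
with controlled pairwise identity and paralog counts, per-species plastid
targeting truth under conserved / clade-specific / species-unique
scenarios, predictor calls with specified sensitivity and false-positive
rate, and all-vs-all hit tables consistent with the family structure.

Families are substitution-only descendants of a random ancestral sequence
(length ~ U(150, 800), always starting with methionine): each species'
ortholog diverges from the ancestor at half the target divergence, so
pairwise within-family identity lands on the target; paralogs are further,
milder mutations of the ortholog.  Because no indels are introduced all
family members share the ancestral length, making true pairwise identity
exactly computable (Hamming) for hit-table generation.  Transit peptides
exist only as truth flags — the pipeline consumes predictor calls, not
transit-peptide sequence features.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import ProteinRecord, SimilarityHit, Taxonomy

__all__ = [
    "AMINO_ACIDS",
    "FamilySpec",
    "SyntheticCorpus",
    "random_protein",
    "mutate_to_identity",
    "simulate_corpus",
    "simulate_calls",
    "precision_to_fpr",
    "simulate_hit_table",
    "hamming_identity",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

SCENARIOS = ("conserved", "clade_specific", "species_unique", "non_plastid")


@dataclass(frozen=True)
class FamilySpec:
    """Ground-truth description of one synthetic protein family."""

    family_id: str
    identity: float                      # target within-family pairwise identity
    paralog_mean: float                  # Poisson mean of extra copies per species
    species_present: tuple[str, ...]
    scenario: str                        # one of SCENARIOS
    scenario_label: str | None = None    # clade or species for the *_specific kinds

    def __post_init__(self) -> None:
        if not (0 < self.identity <= 1):
            raise ValueError("identity must be in (0, 1]")
        if not self.species_present:
            raise ValueError("family must be present in at least one species")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")


@dataclass(frozen=True)
class SyntheticCorpus:
    """Generated proteomes plus the truth table and family specs."""

    proteomes: Mapping[str, tuple[ProteinRecord, ...]]
    truth: pd.DataFrame  # index protein_id; columns family_id, species, plastid
    specs: tuple[FamilySpec, ...]

    @property
    def records(self) -> list[ProteinRecord]:
        return [r for recs in self.proteomes.values() for r in recs]

    @property
    def plastid_set(self) -> set[str]:
        return set(self.truth.index[self.truth["plastid"]])

    @property
    def species_of(self) -> dict[str, str]:
        return dict(self.truth["species"])

    def family_partition(self) -> dict[str, set[str]]:
        return {
            fam: set(group.index)
            for fam, group in self.truth.groupby("family_id")
        }


def random_protein(length: int, rng: np.random.Generator) -> str:
    """Random amino-acid sequence of ``length`` starting with methionine."""
    if length < 1:
        raise ValueError("length must be >= 1")
    body = rng.choice(list(AMINO_ACIDS), size=length - 1)
    return "M" + "".join(body)


def mutate_to_identity(
    seq: str, identity: float, rng: np.random.Generator
) -> str:
    """Substitute random positions so Hamming identity to ``seq`` hits target.

    Exactly ``round((1 - identity) * len)`` distinct positions are replaced
    with a *different* residue, so the realised identity equals the target
    up to the rounding granularity 1/len.  Position 0 is never touched (the
    start methionine is preserved) and length is unchanged.
    """
    if not (0 < identity <= 1):
        raise ValueError("identity must be in (0, 1]")
    n = len(seq)
    k = min(round((1 - identity) * n), n - 1)
    if k == 0:
        return seq
    positions = rng.choice(np.arange(1, n), size=k, replace=False)
    chars = list(seq)
    for pos in positions:
        current = chars[pos]
        alternatives = [a for a in AMINO_ACIDS if a != current]
        chars[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(chars)


def _truth_flag(scenario: str, label: str | None, species: str, taxonomy: Taxonomy) -> bool:
    if scenario == "conserved":
        return True
    if scenario == "clade_specific":
        return taxonomy.clade_of(species) == label
    if scenario == "species_unique":
        return species == label
    return False


def simulate_corpus(
    n_families: int,
    taxonomy: Taxonomy,
    scenario_mix: Mapping[str, float] | None = None,
    rng_seed: int = 0,
    within_identity: float = 0.7,
    paralog_mean: float = 0.5,
    length_range: tuple[int, int] = (150, 800),
    presence_prob: float = 1.0,
    allow_outgroup_unique: bool = False,
    scenario_sequence: Sequence[str] | None = None,
) -> SyntheticCorpus:
    """Generate a corpus of homologous families across the taxonomy.

    ``scenario_mix`` maps scenario names to fractions summing to 1 (default:
    uniform over the four scenarios).  Clade-specific families draw a
    non-outgroup clade; species-unique families draw a species (outgroup
    excluded by default so scenario and classification category map 1:1 —
    outgroup-unique targeting classifies as a one-species semi-conserved
    clade, not as an NPTP).  ``scenario_sequence`` fixes the scenario of
    each family explicitly (overriding the mix) for exact-count corpora.
    Deterministic under ``rng_seed``.
    """
    if scenario_sequence is not None and len(scenario_sequence) != n_families:
        raise ValueError("scenario_sequence length must equal n_families")
    mix = dict(scenario_mix or {s: 0.25 for s in SCENARIOS})
    unknown = set(mix) - set(SCENARIOS)
    if unknown:
        raise ValueError(f"unknown scenarios in mix: {sorted(unknown)}")
    fractions = np.array([mix.get(s, 0.0) for s in SCENARIOS], dtype=float)
    if fractions.sum() <= 0 or abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("scenario mix fractions must sum to 1")

    rng = np.random.default_rng(rng_seed)
    species_list = sorted(taxonomy.species)
    clades = sorted(
        {taxonomy.clade_of(sp) for sp in species_list}
        - {taxonomy.clade_of(taxonomy.outgroup)}
    )
    unique_pool = [
        sp for sp in species_list
        if allow_outgroup_unique or sp != taxonomy.outgroup
    ]

    specs: list[FamilySpec] = []
    proteomes: dict[str, list[ProteinRecord]] = {sp: [] for sp in species_list}
    truth_rows: list[dict] = []

    # divergence from the ancestor is half the pairwise target
    ortholog_identity = 1 - (1 - within_identity) / 2
    paralog_identity = 1 - (1 - within_identity) / 4

    for fam_idx in range(n_families):
        fam_id = f"F{fam_idx + 1:04d}"
        if scenario_sequence is not None:
            scenario = scenario_sequence[fam_idx]
            if scenario not in SCENARIOS:
                raise ValueError(f"unknown scenario {scenario!r}")
        else:
            scenario = SCENARIOS[int(rng.choice(len(SCENARIOS), p=fractions))]
        label: str | None = None
        if scenario == "clade_specific":
            if not clades:
                raise ValueError("taxonomy has no non-outgroup clade")
            label = clades[int(rng.integers(len(clades)))]
        elif scenario == "species_unique":
            label = unique_pool[int(rng.integers(len(unique_pool)))]

        present = tuple(
            sp for sp in species_list if rng.random() < presence_prob
        ) or (species_list[int(rng.integers(len(species_list)))],)
        if scenario == "clade_specific" and not any(
            taxonomy.clade_of(sp) == label for sp in present
        ):
            extra = tuple(sorted(taxonomy.members("clade", label)))[:2]
            present = tuple(dict.fromkeys(present + extra))
        if scenario == "species_unique" and label not in present:
            present = present + (label,)

        length = int(rng.integers(length_range[0], length_range[1] + 1))
        ancestor = random_protein(length, rng)
        spec = FamilySpec(
            family_id=fam_id, identity=within_identity,
            paralog_mean=paralog_mean, species_present=present,
            scenario=scenario, scenario_label=label,
        )
        specs.append(spec)

        for sp in present:
            flag = _truth_flag(scenario, label, sp, taxonomy)
            ortholog_seq = mutate_to_identity(ancestor, ortholog_identity, rng)
            n_copies = 1 + int(rng.poisson(paralog_mean))
            if scenario == "clade_specific" and sp == taxonomy.outgroup:
                # keep the outgroup below the four-member false-negative
                # exemption so clade-specific truth stays classifiable
                n_copies = min(n_copies, 3)
            for copy in range(n_copies):
                seq = (
                    ortholog_seq
                    if copy == 0
                    else mutate_to_identity(ortholog_seq, paralog_identity, rng)
                )
                pid = f"{sp}|{fam_id}.{copy + 1}"
                proteomes[sp].append(ProteinRecord(id=pid, species=sp, sequence=seq))
                truth_rows.append(
                    {
                        "protein_id": pid, "family_id": fam_id,
                        "species": sp, "plastid": flag,
                    }
                )

    truth = pd.DataFrame(truth_rows).set_index("protein_id")
    return SyntheticCorpus(
        proteomes={sp: tuple(recs) for sp, recs in proteomes.items()},
        truth=truth,
        specs=tuple(specs),
    )


def simulate_calls(
    truth: pd.DataFrame,
    predictors: Sequence[tuple[str, float, float]],
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Bernoulli predictor calls from (name, sensitivity, false-positive rate).

    True plastid proteins are called plastid with probability SE; true
    non-plastid proteins with probability FPR; draws are independent across
    proteins and predictors and deterministic under ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    flags = truth["plastid"].to_numpy(dtype=bool)
    data = {}
    for name, se, fpr in predictors:
        if not (0 <= se <= 1 and 0 <= fpr <= 1):
            raise ValueError(f"rates for {name!r} must be in [0, 1]")
        p = np.where(flags, se, fpr)
        data[name] = rng.random(len(flags)) < p
    return pd.DataFrame(data, index=truth.index)


def precision_to_fpr(se: float, precision: float, n_pos: int, n_neg: int) -> float:
    """Convert precision-style specificity to a false-positive rate.

    Published benchmarks report SP = tp/(tp+fp); simulation needs the
    generative FPR = fp/n_neg.  Given prevalence: tp = SE*n_pos, fp =
    tp*(1-SP)/SP.
    """
    if not (0 < precision <= 1):
        raise ValueError("precision must be in (0, 1]")
    tp = se * n_pos
    fp = tp * (1 - precision) / precision
    return fp / n_neg


def hamming_identity(a: str, b: str) -> float:
    """Fraction of equal positions between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def simulate_hit_table(
    corpus: SyntheticCorpus,
    spurious_rate: float = 0.0,
    identity_noise: float = 0.0,
    rng_seed: int = 0,
) -> dict[tuple[str, str], list[SimilarityHit]]:
    """All-vs-all hit tables consistent with the corpus family structure.

    Keyed by ordered species pair (a, b) including the self pair; each
    table holds a's members queried against b's.  Within-family pairs get
    their true Hamming identity (± optional Gaussian noise) at full
    coverage, with a bit score monotone in identity × length and ranks
    sorted by score.  Self-vs-self tables include the trivial self-hit at
    rank 1.  ``spurious_rate`` adds, per query, one low-identity (~25%)
    cross-family hit with that probability.
    """
    rng = np.random.default_rng(rng_seed)
    species = sorted(corpus.proteomes)
    by_family: dict[str, dict[str, list[ProteinRecord]]] = {}
    for sp in species:
        for rec in corpus.proteomes[sp]:
            fam = corpus.truth.loc[rec.id, "family_id"]
            by_family.setdefault(fam, {}).setdefault(sp, []).append(rec)

    tables: dict[tuple[str, str], list[SimilarityHit]] = {}
    for sp_a, sp_b in itertools.product(species, repeat=2):
        raw: list[tuple[str, str, float, float, float, float]] = []
        for fam, members in by_family.items():
            for qa in members.get(sp_a, ()):
                for tb in members.get(sp_b, ()):
                    if qa.id == tb.id:
                        ident = 100.0
                    else:
                        ident = 100.0 * hamming_identity(qa.sequence, tb.sequence)
                        if identity_noise:
                            ident += rng.normal(0.0, identity_noise)
                        ident = float(np.clip(ident, 0.0, 100.0))
                    score = ident / 100.0 * qa.length / 2.0
                    raw.append((qa.id, tb.id, ident, 100.0, 100.0, score))
        if spurious_rate > 0:
            targets = corpus.proteomes[sp_b]
            for qa in corpus.proteomes[sp_a]:
                if rng.random() >= spurious_rate:
                    continue
                fam_a = corpus.truth.loc[qa.id, "family_id"]
                others = [
                    t for t in targets
                    if corpus.truth.loc[t.id, "family_id"] != fam_a
                ]
                if not others:
                    continue
                tb = others[int(rng.integers(len(others)))]
                ident = float(rng.uniform(20.0, 28.0))
                cov = float(rng.uniform(50.0, 100.0))
                raw.append(
                    (qa.id, tb.id, ident, cov, cov, ident / 100.0 * qa.length / 4.0)
                )
        # ranks: per query, by descending bit score (ties by target id)
        raw.sort(key=lambda r: (r[0], -r[5], r[1]))
        hits: list[SimilarityHit] = []
        rank = 0
        prev_query = None
        for q, t, ident, qc, tc, score in raw:
            rank = rank + 1 if q == prev_query else 1
            prev_query = q
            hits.append(
                SimilarityHit(
                    query=q, target=t, identity=ident,
                    query_cov=qc, target_cov=tc, bitscore=score, rank=rank,
                )
            )
        tables[(sp_a, sp_b)] = hits
    return tables
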