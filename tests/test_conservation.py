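import numpy as np
import pandas as pd
import pytest

from oracles import classify_oracle
from plastidome.conservation import (
    ClassificationParams,
    build_profile,
    classify_all,
    classify_cluster,
    consensus_targeting,
    preprocess_proteome,
    SpeciesProfile,
)
from plastidome.simulate import random_protein, simulate_calls, simulate_corpus
from plastidome.targeting import WorkflowSpec, apply_workflow
from plastidome.types import Cluster, ProteinRecord, clusters_from_sets


def _profile(counts):
    return SpeciesProfile(counts=counts)


# ---------------------------------------------------------------------------
# Preprocessing

def test_preprocess_enforces_length_and_start_met():
    records = [
        ProteinRecord("short", "Ath", "M" + "A" * 98),     # 99 residues
        ProteinRecord("nomet", "Ath", "K" + "A" * 149),
        ProteinRecord("good", "Ath", "M" + "A" * 120),
    ]
    kept, report = preprocess_proteome(records)
    assert [r.id for r in kept] == ["good"]
    assert (report.removed_short, report.removed_bad_start) == (1, 1)


def test_preprocess_matches_known_violation_fraction():
    rng = np.random.default_rng(11)
    records = []
    n_bad = 0
    for i in range(500):
        if rng.random() < 0.12:
            n_bad += 1
            seq = (
                "M" + "A" * int(rng.integers(10, 98))
                if rng.random() < 0.5
                else "K" + "A" * 150
            )
        else:
            seq = random_protein(int(rng.integers(100, 300)), rng)
        records.append(ProteinRecord(f"p{i}", "Ath", seq))
    kept, report = preprocess_proteome(records)
    assert report.kept == 500 - n_bad
    assert report.removed == n_bad


# ---------------------------------------------------------------------------
# Consensus targeting

def test_two_of_two_consensus_rules():
    calls = pd.DataFrame(
        {"TargetP": [True, True, False], "Localizer": [True, False, True]},
        index=["both", "tp_only", "loc_only"],
    )
    flags = consensus_targeting(calls)
    assert flags.tolist() == [True, False, False]
    with pytest.raises(KeyError):
        consensus_targeting(calls[["TargetP"]])


def test_consensus_equals_two_of_two_workflow():
    rng = np.random.default_rng(3)
    calls = pd.DataFrame(
        {"TargetP": rng.random(200) < 0.4, "Localizer": rng.random(200) < 0.4},
        index=[f"p{i}" for i in range(200)],
    )
    spec = WorkflowSpec(("Localizer", "TargetP"), 2)
    assert consensus_targeting(calls).equals(
        apply_workflow(spec, calls).rename("plastid")
    )


# ---------------------------------------------------------------------------
# Profiles

def test_profile_tallies_by_species():
    cluster = Cluster("C1", ("a1", "a2", "b1"))
    species_of = {"a1": "Ath", "a2": "Ath", "b1": "Osa"}
    profile = build_profile(cluster, species_of, plastid_set={"a1"})
    assert profile.counts == {"Ath": (1, 1), "Osa": (0, 1)}
    assert profile.total == 3
    with pytest.raises(KeyError):
        build_profile(Cluster("C2", ("zz",)), species_of, set())


def test_profile_matches_brute_force_tally():
    rng = np.random.default_rng(8)
    species = [f"S{i}" for i in range(6)]
    members = [f"m{i}" for i in range(50)]
    species_of = {m: species[int(rng.integers(6))] for m in members}
    plastid = {m for m in members if rng.random() < 0.4}
    profile = build_profile(Cluster("C", tuple(members)), species_of, plastid)
    for sp in set(species_of.values()):
        want_p = sum(1 for m in members if species_of[m] == sp and m in plastid)
        want_n = sum(1 for m in members if species_of[m] == sp and m not in plastid)
        assert profile.counts[sp] == (want_p, want_n)


# ---------------------------------------------------------------------------
# Classification rules

def test_all_species_targeted_is_conserved(taxonomy):
    counts = {sp: (2, 1) for sp in taxonomy.species}
    assert classify_cluster(_profile(counts), taxonomy).category == "conserved"


def test_fn_exemption_rescues_one_untargeted_species(taxonomy):
    counts = {sp: (1, 0) for sp in taxonomy.species if sp != "Sly"}
    counts["Sly"] = (0, 5)  # >= 4 non-plastid members: likely false negatives
    assert classify_cluster(_profile(counts), taxonomy).category == "conserved"
    # with only 3 non-plastid members the exemption does not apply
    counts["Sly"] = (0, 3)
    assert classify_cluster(_profile(counts), taxonomy).category != "conserved"


def test_single_targeted_species_in_multispecies_cluster_is_nptp(taxonomy):
    counts = {"Osa": (1, 1), "Ath": (0, 2), "Vvi": (0, 1), "Sly": (0, 1)}
    cls = classify_cluster(_profile(counts), taxonomy)
    assert (cls.category, cls.species) == ("nptp", "Osa")


def test_clade_confined_targeting_is_semi_conserved(taxonomy):
    # three monocots across families -> clade-level label
    counts = {
        "Aam": (1, 0), "Osa": (2, 0), "Bdi": (1, 1),
        "Ath": (0, 1), "Vvi": (0, 1),
    }
    cls = classify_cluster(_profile(counts), taxonomy)
    assert (cls.category, cls.clade) == ("semi_conserved", "monocot")


def test_semi_conserved_assigns_smallest_lineage_group(taxonomy):
    counts = {"Osa": (1, 0), "Bdi": (1, 0), "Ath": (0, 1)}
    cls = classify_cluster(_profile(counts), taxonomy)
    assert (cls.category, cls.clade) == ("semi_conserved", "Poaceae")


def test_outgroup_evidence_blocks_semi_conserved(taxonomy):
    base = {"Osa": (1, 0), "Bdi": (1, 0), "Ath": (0, 1)}
    # plastid call in the outgroup
    blocked = dict(base, Atr=(1, 0))
    assert classify_cluster(_profile(blocked), taxonomy).category != "semi_conserved"
    # >= 4 non-plastid outgroup members also block
    blocked = dict(base, Atr=(0, 4))
    assert classify_cluster(_profile(blocked), taxonomy).category != "semi_conserved"
    # fewer outgroup members do not
    ok = dict(base, Atr=(0, 2))
    assert classify_cluster(_profile(ok), taxonomy).category == "semi_conserved"


def test_outgroup_specific_targeting_needs_two_sequences(taxonomy):
    counts = {"Atr": (2, 0), "Osa": (0, 1), "Ath": (0, 1)}
    cls = classify_cluster(_profile(counts), taxonomy)
    assert (cls.category, cls.clade) == ("semi_conserved", "amborella")
    counts["Atr"] = (1, 0)
    cls = classify_cluster(_profile(counts), taxonomy)
    assert (cls.category, cls.species) == ("nptp", "Atr")


def test_single_species_clusters_are_discarded(taxonomy):
    assert (
        classify_cluster(_profile({"Osa": (3, 2)}), taxonomy).category
        == "discarded_single_species"
    )


def test_classification_matches_rule_oracle_on_random_profiles(taxonomy):
    """Independent literal rule evaluator agrees on 10,000 random profiles."""
    rng = np.random.default_rng(19)
    species = sorted(taxonomy.species)
    for _ in range(10_000):
        n_sp = int(rng.integers(1, 16))
        chosen = rng.choice(species, size=n_sp, replace=False)
        counts = {}
        for sp in chosen:
            p = int(rng.integers(0, 4))
            n = int(rng.integers(0, 6))
            if p + n == 0:
                p = 1
            counts[sp] = (p, n)
        got = classify_cluster(_profile(counts), taxonomy)
        want_cat, want_label = classify_oracle(counts, taxonomy)
        assert got.category == want_cat
        if want_cat == "semi_conserved":
            assert got.clade == want_label
        if want_cat == "nptp":
            assert got.species == want_label


def test_raising_fn_exemption_never_increases_conserved_count(taxonomy):
    rng = np.random.default_rng(23)
    profiles = []
    species = sorted(taxonomy.species)
    for _ in range(300):
        counts = {
            sp: (int(rng.integers(0, 3)), int(rng.integers(1, 7)))
            for sp in species
        }
        profiles.append(_profile(counts))
    counts_by_exemption = []
    for exemption in (2, 3, 4, 5, 6):
        params = ClassificationParams(fn_exemption=exemption)
        n = sum(
            classify_cluster(p, taxonomy, params).category == "conserved"
            for p in profiles
        )
        counts_by_exemption.append(n)
    assert counts_by_exemption == sorted(counts_by_exemption, reverse=True)


# ---------------------------------------------------------------------------
# Whole-corpus classification

def _truth_clusters(corpus):
    return clusters_from_sets(corpus.family_partition().values())


def test_perfect_calls_recover_scenario_categories_exactly(taxonomy):
    scenario_sequence = (
        ["conserved"] * 8 + ["clade_specific"] * 12
        + ["species_unique"] * 12 + ["non_plastid"] * 8
    )
    corpus = simulate_corpus(
        n_families=40, taxonomy=taxonomy, rng_seed=29,
        length_range=(100, 160), scenario_sequence=scenario_sequence,
    )
    calls = simulate_calls(
        corpus.truth, [("TargetP", 1.0, 0.0), ("Localizer", 1.0, 0.0)], rng_seed=1
    )
    plastid = set(consensus_targeting(calls).loc[lambda s: s].index)
    table, census = classify_all(
        _truth_clusters(corpus), corpus.species_of, plastid, taxonomy
    )
    counts = table["category"].value_counts().to_dict()
    assert counts.get("conserved", 0) == 8
    assert counts.get("semi_conserved", 0) == 12
    assert counts.get("nptp", 0) == 12
    assert counts.get("unclassified", 0) == 8  # non-plastid families
    # census columns mirror the per-species summary layout
    assert set(census.columns) == {
        "species", "total_clusters", "plastid_clusters",
        "unique_plastid_clusters", "single_species_clusters", "nptps",
    }
    assert census["nptps"].sum() == 12


def test_noisy_calls_keep_conserved_recall_with_exemption(taxonomy):
    """Large conserved families survive predictor false negatives because
    four non-plastid homologs count as likely targeting."""
    corpus = simulate_corpus(
        n_families=40, taxonomy=taxonomy, rng_seed=37,
        length_range=(100, 140), paralog_mean=6.0,
        scenario_sequence=["conserved"] * 40,
    )
    calls = simulate_calls(
        corpus.truth,
        [("TargetP", 0.61, 0.02), ("Localizer", 0.61, 0.02)],
        rng_seed=41,
    )
    # consensus of two independent 0.61-sensitivity predictors is harsher
    # than one predictor; score each alone to isolate the exemption effect
    plastid = set(calls.index[calls["TargetP"]])
    table, _ = classify_all(
        _truth_clusters(corpus), corpus.species_of, plastid, taxonomy
    )
    recall = (table["category"] == "conserved").mean()
    assert recall >= 0.8


def test_empty_cluster_set_yields_empty_tables(taxonomy):
    table, census = classify_all([], {}, set(), taxonomy)
    assert table.empty
    assert census["total_clusters"].sum() == 0
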