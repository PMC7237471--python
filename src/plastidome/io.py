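"""Readers and writers for the external formats the pipeline touches.

Covers protein FASTA, BLAST tabular (outfmt 6), native TargetP v1.1 and
Localizer v1.0.2 output dialects plus a generic call TSV, cluster
membership tables, and the taxonomy configuration (YAML).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import LINEAGE_LEVELS, ProteinRecord, SimilarityHit, Taxonomy, Cluster

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_blast_tab",
    "write_blast_tab",
    "read_predictor_table",
    "read_calls",
    "write_calls",
    "merge_call_tables",
    "read_taxonomy",
    "write_taxonomy",
    "read_cluster_table",
    "write_cluster_table",
]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(
    path: str | Path,
    species: str = "unknown",
    header_regex: str | None = None,
) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased and a single trailing ``*`` stop character is
    stripped.  The species code is supplied per file; alternatively a
    ``header_regex`` with named groups ``id`` (and optionally ``species``)
    extracts both from the header line.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    pattern = re.compile(header_regex) if header_regex else None
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        rec_id, rec_species = entry.id, species
        if pattern is not None:
            m = pattern.match(entry.description)
            if m is None:
                raise ValueError(f"header {entry.description!r} does not match regex")
            rec_id = m.group("id")
            if "species" in pattern.groupindex:
                rec_species = m.group("species")
        if rec_id in seen:
            raise ValueError(f"duplicate protein id {rec_id!r} in {path}")
        seen.add(rec_id)
        records.append(ProteinRecord(id=rec_id, species=rec_species, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    entries = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(entries, str(path), "fasta")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)

_OUTFMT6_NCOL = 12


def read_blast_tab(
    path: str | Path,
    length_lookup: Mapping[str, int],
) -> list[SimilarityHit]:
    """Parse a 12-column BLAST outfmt-6 table into similarity hits.

    Coverage is derived from the alignment spans and the supplied sequence
    lengths: ``query_cov = 100 * (qend - qstart + 1) / qlen`` and likewise
    for the target.  Coordinates are 1-based inclusive; reverse-style spans
    (start > end) are normalized by absolute span.  Ranks are assigned by
    file order within each query.
    """
    hits: list[SimilarityHit] = []
    rank_counter: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _OUTFMT6_NCOL:
                raise ValueError(
                    f"{path}:{lineno}: expected {_OUTFMT6_NCOL} columns, got {len(cols)}"
                )
            q, t = cols[0], cols[1]
            for name in (q, t):
                if name not in length_lookup:
                    raise KeyError(f"{path}:{lineno}: id {name!r} missing from length lookup")
            pident = float(cols[2])
            qstart, qend, sstart, send = (int(cols[i]) for i in (6, 7, 8, 9))
            qspan = abs(qend - qstart) + 1
            tspan = abs(send - sstart) + 1
            qcov = min(100.0, 100.0 * qspan / length_lookup[q])
            tcov = min(100.0, 100.0 * tspan / length_lookup[t])
            rank = rank_counter.get(q, 0) + 1
            rank_counter[q] = rank
            hits.append(
                SimilarityHit(
                    query=q, target=t, identity=pident,
                    query_cov=qcov, target_cov=tcov,
                    bitscore=float(cols[11]), rank=rank,
                )
            )
    return hits


def write_blast_tab(
    hits: Iterable[SimilarityHit],
    path: str | Path,
    length_lookup: Mapping[str, int],
) -> None:
    """Write hits as outfmt-6 rows, reconstructing spans from coverages."""
    with open(path, "w") as fh:
        for h in hits:
            qlen, tlen = length_lookup[h.query], length_lookup[h.target]
            qspan = max(1, round(h.query_cov / 100.0 * qlen))
            tspan = max(1, round(h.target_cov / 100.0 * tlen))
            aln = max(qspan, tspan)
            mismatch = round(aln * (1 - h.identity / 100.0))
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query, h.target, f"{h.identity:.2f}", aln, mismatch, 0,
                        1, qspan, 1, tspan, "1e-10", f"{h.bitscore:.1f}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Predictor call tables

_DIALECTS = ("targetp", "localizer", "generic")

_FLOAT_RE = re.compile(r"^-?\d+(\.\d+)?$")


def read_predictor_table(
    path: str | Path,
    dialect: str,
    predictor: str | None = None,
) -> pd.DataFrame:
    """Read one predictor output file into a boolean call-table fragment.

    Returns a DataFrame indexed by protein id with one boolean column per
    predictor (``True`` = plastid).  Dialects:

    ``targetp``
        TargetP v1.1 plain-text table; the ``Loc`` column value ``C`` means
        chloroplast, any other location code maps to non-plastid.
    ``localizer``
        Localizer v1.0.2 tab table whose chloroplast column is ``Y (score)``
        or ``-``.
    ``generic``
        TSV of ``protein_id<TAB>predictor<TAB>call`` with call in
        {plastid, other}; covers any further predictor.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if dialect == "generic":
        return read_calls(path)

    name = predictor or dialect.capitalize().replace("Targetp", "TargetP")
    if dialect == "targetp":
        name = predictor or "TargetP"
        calls = _read_targetp(path)
    else:
        name = predictor or "Localizer"
        calls = _read_localizer(path)
    frame = pd.DataFrame({name: pd.Series(calls, dtype=bool)})
    frame.index.name = "protein_id"
    return frame


def _read_targetp(path: str | Path) -> dict[str, bool]:
    """TargetP v1.1 whitespace table: Name Len cTP mTP SP other Loc RC."""
    calls: dict[str, bool] = {}
    with open(path) as fh:
        for line in fh:
            tokens = line.split()
            if len(tokens) < 8 or set(line.strip()) <= {"-"}:
                continue
            # data rows carry four scores then a location code and RC class
            if not all(_FLOAT_RE.match(t) for t in tokens[1:6]):
                continue
            name, loc = tokens[0], tokens[6]
            call = loc == "C"
            if name in calls and calls[name] != call:
                raise ValueError(f"conflicting TargetP calls for {name!r}")
            calls[name] = call
    if not calls:
        raise ValueError(f"no TargetP data rows in {path}")
    return calls


def _read_localizer(path: str | Path) -> dict[str, bool]:
    """Localizer v1.0.2 tab table: Identifier, Chloroplast, Mito, Nucleus."""
    calls: dict[str, bool] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = [c.strip() for c in line.split("\t")]
            if len(cols) < 2 or cols[0].lower() in ("identifier", "id"):
                continue
            name = cols[0]
            call = cols[1].upper().startswith("Y")
            if name in calls and calls[name] != call:
                raise ValueError(f"conflicting Localizer calls for {name!r}")
            calls[name] = call
    if not calls:
        raise ValueError(f"no Localizer data rows in {path}")
    return calls


def read_calls(path: str | Path) -> pd.DataFrame:
    """Read the generic call TSV (protein_id, predictor, call)."""
    table = pd.read_csv(
        path, sep="\t", header=None, names=["protein_id", "predictor", "call"],
        comment="#", skip_blank_lines=True,
    )
    if table.empty:
        raise ValueError(f"no call rows in {path}")
    # tolerate a header row
    if table.iloc[0]["protein_id"] == "protein_id":
        table = table.iloc[1:]
    table["plastid"] = table["call"].str.strip().str.lower() == "plastid"
    dup = table.groupby(["protein_id", "predictor"])["plastid"].nunique()
    conflicts = dup[dup > 1]
    if not conflicts.empty:
        pid, pred = conflicts.index[0]
        raise ValueError(f"conflicting calls for ({pid!r}, {pred!r})")
    frame = (
        table.drop_duplicates(["protein_id", "predictor"])
        .pivot(index="protein_id", columns="predictor", values="plastid")
    )
    frame.columns.name = None
    return frame.astype("boolean")


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    """Write a boolean call table in the generic TSV layout."""
    with open(path, "w") as fh:
        for pid, row in calls.iterrows():
            for pred in calls.columns:
                val = row[pred]
                if pd.isna(val):
                    continue
                fh.write(f"{pid}\t{pred}\t{'plastid' if val else 'other'}\n")


def merge_call_tables(fragments: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Outer-join call-table fragments (one per predictor file)."""
    if not fragments:
        raise ValueError("no call tables to merge")
    merged = fragments[0]
    for frag in fragments[1:]:
        overlap = merged.columns.intersection(frag.columns)
        if len(overlap):
            raise ValueError(f"duplicate predictor columns: {list(overlap)}")
        merged = merged.join(frag, how="outer")
    return merged


# ---------------------------------------------------------------------------
# Taxonomy config

def read_taxonomy(path: str | Path) -> Taxonomy:
    """Read a YAML taxonomy config.

    Layout::

        outgroup: Atr
        species:
          Osa: {clade: monocot, subclade: commelinid, family: Poaceae}
          ...
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "species" not in doc:
        raise ValueError(f"{path}: taxonomy config must map 'species'")
    lineages: dict[str, tuple[str, str, str]] = {}
    for sp, entry in doc["species"].items():
        if not isinstance(entry, dict) or not entry.get("clade"):
            raise ValueError(f"{path}: species {sp!r} has no clade")
        lineages[sp] = tuple(
            str(entry.get(level, entry["clade"])) for level in LINEAGE_LEVELS
        )
    outgroup = doc.get("outgroup") or next(iter(lineages))
    return Taxonomy(lineages=lineages, outgroup=outgroup)


def write_taxonomy(taxonomy: Taxonomy, path: str | Path) -> None:
    doc = {
        "outgroup": taxonomy.outgroup,
        "species": {
            sp: dict(zip(LINEAGE_LEVELS, lineage))
            for sp, lineage in taxonomy.lineages.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Cluster membership tables

def write_cluster_table(
    clusters: Iterable[Cluster],
    path: str | Path,
    species_of: Mapping[str, str],
    plastid_set: Iterable[str] = (),
) -> None:
    """Write cluster membership TSV: cluster_id, protein_id, species, plastid_flag."""
    plastid = set(plastid_set)
    with open(path, "w") as fh:
        fh.write("cluster_id\tprotein_id\tspecies\tplastid_flag\n")
        for cluster in clusters:
            for member in cluster.members:
                flag = "1" if member in plastid else "0"
                fh.write(f"{cluster.id}\t{member}\t{species_of[member]}\t{flag}\n")


def read_cluster_table(
    path: str | Path,
) -> tuple[list[Cluster], dict[str, str], set[str]]:
    """Read a cluster membership TSV back into clusters + lookups."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cluster_id", "protein_id", "species", "plastid_flag"}
    if not required <= set(table.columns):
        raise ValueError(f"{path}: missing columns {required - set(table.columns)}")
    clusters = [
        Cluster(cid, tuple(group["protein_id"]))
        for cid, group in table.groupby("cluster_id", sort=True)
    ]
    species_of = dict(zip(table["protein_id"], table["species"]))
    plastid = set(table.loc[table["plastid_flag"] == "1", "protein_id"])
    return clusters, species_of, plastid
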