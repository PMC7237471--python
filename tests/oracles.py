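"""Independent brute-force re-implementations used as test oracles.

Each function follows the plain-language definition of an operation
directly, without sharing code paths (graph library, caching, prescreens)
with the implementation under test.
"""

from __future__ import annotations

from plastidome.greedy import pairwise_identity


# --- union-find, hand-rolled (independent of networkx) ---------------------

class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra

    def partition(self):
        groups = {}
        for x in self.parent:
            groups.setdefault(self.find(x), set()).add(x)
        return {frozenset(g) for g in groups.values()}


def components_oracle(edges, all_ids):
    uf = UnionFind(all_ids)
    for a, b in edges:
        uf.union(a, b)
    return uf.partition()


# --- reciprocal best hits ---------------------------------------------------

def _hit_ok(h, min_id, min_cov):
    return h.identity > min_id and h.query_cov > min_cov and h.target_cov > min_cov


def rbh_oracle(hits_ab, hits_ba, min_id=40.0, min_cov=40.0):
    """All-pairs check of the reciprocal-best-hit definition."""

    def best(hits, query):
        surviving = [
            h for h in hits
            if h.query == query and not h.is_self and _hit_ok(h, min_id, min_cov)
        ]
        if not surviving:
            return None
        return min(surviving, key=lambda h: (-h.bitscore, -h.identity, h.target))

    edges = set()
    queries_a = {h.query for h in hits_ab}
    for a in queries_a:
        fwd = best(hits_ab, a)
        if fwd is None:
            continue
        back = best(hits_ba, fwd.target)
        if back is not None and back.target == a:
            edges.add(frozenset((a, fwd.target)))
    return edges


def intra_oracle(self_hits, min_id=90.0, min_cov=90.0, top_k=10):
    """Direct check of the top-k reciprocal 'better hit' definition."""
    per_query = {}
    for h in self_hits:
        if not h.is_self:
            per_query.setdefault(h.query, []).append(h)
    for hits in per_query.values():
        hits.sort(key=lambda h: h.rank)
    edges = set()
    for a, hits_a in per_query.items():
        for h in hits_a[:top_k]:
            if not (h.identity >= min_id and h.query_cov >= min_cov and h.target_cov >= min_cov):
                continue
            b = h.target
            for back in per_query.get(b, [])[:top_k]:
                if (
                    back.target == a
                    and back.identity >= min_id
                    and back.query_cov >= min_cov
                    and back.target_cov >= min_cov
                ):
                    edges.add(frozenset((a, b)))
    return edges


# --- trimming ---------------------------------------------------------------

def trim_oracle(members, hit_lookup, plastid_set, min_id=40.0, min_cov=40.0):
    plastid = set(members) & set(plastid_set)
    if not plastid:
        return set(members)
    kept = set(plastid)
    for m in members:
        for p in plastid:
            entry = hit_lookup.get(tuple(sorted((m, p))))
            if m != p and entry and entry[0] >= min_id and entry[1] >= min_cov:
                kept.add(m)
    return kept


# --- greedy centroid pass ---------------------------------------------------

def greedy_oracle(records, identity, qcov, tcov=0.0, mode="first"):
    """Naive centroid scan using pairwise_identity directly (no caching,
    no score prescreen)."""
    ordered = sorted(records, key=lambda r: (-r.length, r.id))
    clusters = []  # (centroid record, member id list)
    seen = set()
    for rec in ordered:
        if rec.id in seen:
            continue
        seen.add(rec.id)
        candidates = []
        for centroid, members in clusters:
            st = pairwise_identity(rec.sequence, centroid.sequence)
            if st.identity >= identity and st.query_cov >= qcov and st.target_cov >= tcov:
                candidates.append((st.identity, centroid, members))
                if mode == "first":
                    break
        if not candidates:
            clusters.append((rec, [rec.id]))
        elif mode == "first":
            candidates[0][2].append(rec.id)
        else:
            max(candidates, key=lambda c: c[0])[2].append(rec.id)
    return {frozenset(members) for _, members in clusters}


# --- conservation rules -----------------------------------------------------

def classify_oracle(profile_counts, taxonomy, min_species=13, fn_exempt=4,
                    min_clade=2, min_nptp=3):
    """Literal walk of the published classification rules.

    ``profile_counts``: species -> (n_plastid, n_non_plastid).
    Returns (category, label).
    """
    present = [sp for sp, (p, n) in profile_counts.items() if p + n > 0]
    if len(present) <= 1:
        return ("discarded_single_species", None)
    plastid_sp = sorted(sp for sp in present if profile_counts[sp][0] > 0)

    def likely(sp):
        p, n = profile_counts[sp]
        return p > 0 or n >= fn_exempt

    if len(present) >= min_species and all(likely(sp) for sp in present) and plastid_sp:
        return ("conserved", None)

    og = taxonomy.outgroup
    if plastid_sp == [og]:
        if profile_counts[og][0] >= min_clade:
            return ("semi_conserved", taxonomy.clade_of(og))
    elif plastid_sp and len(plastid_sp) >= min_clade:
        og_p, og_n = profile_counts.get(og, (0, 0))
        if og_p == 0 and og_n < fn_exempt:
            for level in ("family", "subclade", "clade"):
                labels = {taxonomy.label(sp, level) for sp in plastid_sp}
                if len(labels) == 1:
                    label = next(iter(labels))
                    if og not in taxonomy.members(level, label):
                        return ("semi_conserved", label)

    if len(present) >= min_nptp and len(plastid_sp) == 1:
        return ("nptp", plastid_sp[0])
    return ("unclassified", None)
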