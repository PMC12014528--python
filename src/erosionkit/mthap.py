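"""Mitochondrial haplotypes: diversity, permutation testing, networks.

Collapses an epoch/population-labelled alignment into distinct haplotypes,
computes Nei's haplotype diversity Hd = n/(n-1) (1 - sum p_i^2), compares
two groups with a label-permutation test on the difference in Hd, and
builds median-joining networks (minimum spanning network plus inferred
column-majority median vectors, epsilon = 0).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

MISSING_CHARS = frozenset("-N?")


@dataclass
class MissingPolicy:
    """Column masking rule: columns with more than ``max_col_missing`` of
    sequences missing (gap/N) are masked out; sequences still containing
    missing characters afterwards are excluded."""

    max_col_missing: float = 0.1


@dataclass
class HaplotypeTable:
    """Collapsed haplotypes with per-individual epoch/population labels."""

    alignment_length: int
    haplotypes: dict[str, str]  # hap id -> (masked) sequence
    assignments: pd.DataFrame  # columns: individual, epoch, pop, haplotype
    excluded: list[str] = field(default_factory=list)
    masked_columns: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.assignments)

    def counts(self, by: str | None = None) -> pd.Series | pd.DataFrame:
        if by is None:
            return self.assignments["haplotype"].value_counts()
        return self.assignments.groupby([by, "haplotype"]).size().unstack(fill_value=0)

    def frequencies(self) -> pd.Series:
        c = self.counts()
        return c / c.sum()

    def subgroup(self, **labels) -> "HaplotypeTable":
        mask = pd.Series(True, index=self.assignments.index)
        for col, val in labels.items():
            mask &= self.assignments[col] == val
        sub = self.assignments[mask].reset_index(drop=True)
        used = set(sub["haplotype"])
        return HaplotypeTable(
            alignment_length=self.alignment_length,
            haplotypes={h: s for h, s in self.haplotypes.items() if h in used},
            assignments=sub,
            masked_columns=list(self.masked_columns),
        )


def call_haplotypes(
    records: Iterable[tuple[str, str, str, str]],
    missing_policy: MissingPolicy | None = None,
) -> HaplotypeTable:
    """Collapse labelled aligned sequences into distinct haplotypes.

    ``records`` are (name, epoch, pop, sequence) tuples over an equal-length
    alignment. Columns whose missing fraction exceeds the policy threshold
    are masked for everyone; sequences with residual missing characters are
    excluded (and reported on the table); identical remaining sequences
    share a haplotype id (H1, H2, ... in order of first appearance).
    """
    policy = missing_policy or MissingPolicy()
    recs = list(records)
    if not recs:
        raise ValueError("no sequences provided")
    length = len(recs[0][3])
    if any(len(r[3]) != length for r in recs):
        raise ValueError("sequences must be aligned to equal length")

    arr = np.array([list(r[3].upper()) for r in recs])
    missing = np.isin(arr, list(MISSING_CHARS))
    col_frac = missing.mean(axis=0)
    masked = col_frac > policy.max_col_missing
    keep_cols = ~masked

    rows = []
    excluded = []
    hap_ids: dict[str, str] = {}
    haplotypes: dict[str, str] = {}
    for (name, epoch, pop, _), row, miss in zip(recs, arr, missing):
        if miss[keep_cols].any():
            excluded.append(name)
            continue
        seq = "".join(row[keep_cols])
        if seq not in hap_ids:
            hid = f"H{len(hap_ids) + 1}"
            hap_ids[seq] = hid
            haplotypes[hid] = seq
        rows.append({"individual": name, "epoch": epoch, "pop": pop,
                     "haplotype": hap_ids[seq]})
    return HaplotypeTable(
        alignment_length=length,
        haplotypes=haplotypes,
        assignments=pd.DataFrame(rows, columns=["individual", "epoch", "pop", "haplotype"]),
        excluded=excluded,
        masked_columns=list(np.flatnonzero(masked)),
    )


# ---------------------------------------------------------------------------
# haplotype diversity and the permutation test
# ---------------------------------------------------------------------------

def haplotype_diversity(table_or_counts) -> float:
    """Nei's haplotype diversity Hd = n/(n-1) (1 - sum p_i^2)."""
    if isinstance(table_or_counts, HaplotypeTable):
        counts = table_or_counts.counts().to_numpy(dtype=float)
    else:
        counts = np.asarray(table_or_counts, dtype=float)
    counts = counts[counts > 0]
    n = counts.sum()
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2 individuals")
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def _hd_from_codes(codes: np.ndarray, n_haps: int) -> float:
    n = codes.size
    p = np.bincount(codes, minlength=n_haps) / n
    return n / (n - 1) * (1.0 - float(np.sum(p**2)))


@dataclass
class PermutationResult:
    observed: float  # delta Hd = Hd_A - Hd_B
    null: np.ndarray
    n_permutations: int
    p_value: float
    seed: int
    sidedness: str


def permutation_test_hd(
    table_a: HaplotypeTable,
    table_b: HaplotypeTable,
    n_permutations: int = 10_000,
    seed: int = 0,
    sidedness: str = "two-sided",
) -> PermutationResult:
    """Group-label permutation test on the haplotype-diversity difference.

    Individuals are the exchangeable unit: pooled haplotype assignments are
    randomly re-split into groups of the original sizes, delta Hd recomputed
    each time, and the add-one p-value (1 + #extreme) / (1 + n_permutations)
    returned. Default sidedness is two-sided on |delta Hd|.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if n_permutations < 100:
        import warnings

        warnings.warn("fewer than 100 permutations gives a very coarse p-value",
                      stacklevel=2)
    if sidedness not in ("two-sided", "greater", "less"):
        raise ValueError("sidedness must be two-sided, greater or less")
    if table_a.n < 2 or table_b.n < 2:
        raise ValueError("both groups need n >= 2")

    # pool by sequence: haplotype ids are per-table labels and may collide
    seq_a = table_a.assignments["haplotype"].map(table_a.haplotypes)
    seq_b = table_b.assignments["haplotype"].map(table_b.haplotypes)
    all_seqs = sorted(set(seq_a) | set(seq_b))
    code = {s: i for i, s in enumerate(all_seqs)}
    a = seq_a.map(code).to_numpy()
    b = seq_b.map(code).to_numpy()
    n_haps = len(all_seqs)
    n_a = a.size
    observed = _hd_from_codes(a, n_haps) - _hd_from_codes(b, n_haps)

    pool = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        rng.shuffle(pool)
        null[i] = _hd_from_codes(pool[:n_a], n_haps) - _hd_from_codes(pool[n_a:], n_haps)

    eps = 1e-12
    if sidedness == "two-sided":
        extreme = np.abs(null) >= np.abs(observed) - eps
    elif sidedness == "greater":
        extreme = null >= observed - eps
    else:
        extreme = null <= observed + eps
    p = (1 + int(extreme.sum())) / (1 + n_permutations)
    return PermutationResult(
        observed=observed, null=null, n_permutations=n_permutations,
        p_value=p, seed=seed, sidedness=sidedness,
    )


# ---------------------------------------------------------------------------
# median-joining networks
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _msn_edges(seqs: list[str]) -> list[tuple[int, int, int]]:
    """Minimum spanning network (epsilon = 0): every edge that occurs in
    some minimum spanning tree, i.e. (u, v, w) such that u and v are not
    connected using only edges strictly shorter than w."""
    n = len(seqs)
    dist = [[_hamming(seqs[i], seqs[j]) for j in range(n)] for i in range(n)]
    pairs = sorted(
        ((dist[i][j], i, j) for i in range(n) for j in range(i + 1, n)),
    )
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = []
    k = 0
    while k < len(pairs):
        w = pairs[k][0]
        level = []
        while k < len(pairs) and pairs[k][0] == w:
            level.append(pairs[k])
            k += 1
        # membership decided against components formed by strictly smaller weights
        added = [(u, v) for _, u, v in level if find(u) != find(v)]
        edges.extend((u, v, w) for u, v in added)
        for u, v in added:
            parent[find(u)] = find(v)
    return edges


def _mst_length(seqs: list[str]) -> int:
    g = nx.Graph()
    g.add_nodes_from(range(len(seqs)))
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            g.add_edge(i, j, weight=_hamming(seqs[i], seqs[j]))
    return int(sum(d["weight"] for _, _, d in
                   nx.minimum_spanning_edges(g, data=True))) if len(seqs) > 1 else 0


def _column_majority(a: str, b: str, c: str) -> str:
    out = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            out.append(x)  # three-way tie: keep the first sequence's state
    return "".join(out)


def median_joining_network(
    table: HaplotypeTable, epsilon: int = 0, max_medians: int = 64
) -> nx.Graph:
    """Median-joining haplotype network (epsilon = 0).

    Starts from the minimum spanning network over observed haplotypes, then
    repeatedly proposes the column-wise majority consensus of connected node
    triplets and keeps the proposal that most reduces the total minimum
    spanning length, until no median helps; inferred medians that end with
    degree < 3 are pruned. Nodes carry ``sequence``, ``observed``, ``count``
    and per-epoch count attributes; edge weights are Hamming distances.
    """
    if epsilon != 0:
        raise NotImplementedError("only epsilon = 0 is supported")
    hap_items = sorted(table.haplotypes.items())
    names = [h for h, _ in hap_items]
    seqs = [s for _, s in hap_items]
    counts = table.counts()
    by_epoch = (
        table.assignments.groupby(["haplotype", "epoch"]).size()
        if "epoch" in table.assignments
        else None
    )

    observed_flags = [True] * len(seqs)
    n_median = 0
    if len(seqs) > 1:
        while n_median < max_medians:
            current_len = _mst_length(seqs)
            edges = _msn_edges(seqs)
            adj = {i: set() for i in range(len(seqs))}
            for u, v, _ in edges:
                adj[u].add(v)
                adj[v].add(u)
            best = None
            seen = set(seqs)
            for u in range(len(seqs)):
                for v, w in itertools.combinations(sorted(adj[u]), 2):
                    med = _column_majority(seqs[u], seqs[v], seqs[w])
                    if med in seen:
                        continue
                    new_len = _mst_length(seqs + [med])
                    if new_len < current_len and (best is None or new_len < best[0]):
                        best = (new_len, med)
            if best is None:
                break
            seqs.append(best[1])
            names.append(f"median{n_median + 1}")
            observed_flags.append(False)
            n_median += 1

        # prune medians that never reached degree 3
        while True:
            edges = _msn_edges(seqs)
            deg = {i: 0 for i in range(len(seqs))}
            for u, v, _ in edges:
                deg[u] += 1
                deg[v] += 1
            drop = [i for i in range(len(seqs))
                    if not observed_flags[i] and deg[i] < 3]
            if not drop:
                break
            for i in sorted(drop, reverse=True):
                del seqs[i], names[i], observed_flags[i]

    g = nx.Graph()
    for name, seq, obs in zip(names, seqs, observed_flags):
        attrs = {
            "sequence": seq,
            "observed": obs,
            "count": int(counts.get(name, 0)) if obs else 0,
        }
        if obs and by_epoch is not None and name in by_epoch.index.get_level_values(0):
            for epoch, c in by_epoch[name].items():
                attrs[f"count_{epoch}"] = int(c)
        g.add_node(name, **attrs)
    if len(seqs) > 1:
        for u, v, w in _msn_edges(seqs):
            g.add_edge(names[u], names[v], weight=int(w))
    return g


def network_edge_table(g: nx.Graph) -> pd.DataFrame:
    rows = [
        {"node_a": u, "node_b": v, "mutations": d["weight"]}
        for u, v, d in g.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["node_a", "node_b", "mutations"])
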