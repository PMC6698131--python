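"""Real-valued evolutionary-trace (rvET) ranking of alignment columns.

The rvET score of column ``i`` is

    rho_i = 1 + sum_{n=1}^{N-1} (1/n) * sum_{g=1}^{n} H(g, i)

where the n-group partition is obtained by dissolving the n-1 highest
internal nodes of a rooted grouping tree, and ``H(g, i)`` is the natural-log
Shannon entropy of column ``i`` within group ``g`` over a 21-state alphabet
(20 amino acids plus the gap).  A column invariant across all sequences
scores exactly 1 (the most conserved possible value); scores grow with
variability, weighted toward variation that cuts across the tree's top-level
groups.  Residues of a reference sequence are then ranked by score, with
tie-aware ranks, coverage (fraction of residues at or below a score) and the
column's symbol variability -- the classic trace report table.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, InputError
from .msa import GAP, Alignment, ReferenceMapping, map_to_reference
from .seqdef import AMINO_ACIDS

_SYMBOLS = AMINO_ACIDS + GAP
_SYMBOL_INDEX = {s: i for i, s in enumerate(_SYMBOLS)}


@dataclass(frozen=True)
class TraceRow:
    rank: int
    residue_number: int
    alignment_position: int
    residue: str
    coverage: float
    variability: str
    rvet_score: float


@dataclass(frozen=True)
class TraceResult:
    """Per-residue trace of one cluster, sorted by rank."""

    reference_id: str
    name: str
    length: int
    rows: tuple[TraceRow, ...]

    def row_at_position(self, alignment_position: int) -> Optional[TraceRow]:
        for row in self.rows:
            if row.alignment_position == alignment_position:
                return row
        return None

    def to_dataframe(self, rounded: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "Rank": r.rank,
                    "Residue number": r.residue_number,
                    "Alignment position": r.alignment_position,
                    "Residue": r.residue,
                    "Coverage": round(r.coverage, 5) if rounded else r.coverage,
                    "Variability": r.variability,
                    "rvET score": round(r.rvet_score, 2) if rounded else r.rvet_score,
                }
                for r in self.rows
            ]
        )
        return df


# ---------------------------------------------------------------------------
# Grouping tree


def _percent_mismatch(row_a: str, row_b: str) -> float:
    """Fractional mismatch over columns where both rows are ungapped."""
    shared = mism = 0
    for sa, sb in zip(row_a, row_b):
        if sa != GAP and sb != GAP:
            shared += 1
            if sa != sb:
                mism += 1
    return mism / shared if shared else 1.0


def identity_distance_tree(aln: Alignment) -> dendropy.Tree:
    """Rooted ultrametric UPGMA tree on pairwise fractional-mismatch distances.

    Deterministic: merge order breaks distance ties by the lexicographically
    smallest cluster pair.  Leaf depths are equal (half the merge height).
    """
    if aln.n_rows < 2:
        raise InputError("need >= 2 sequences for a grouping tree")
    ids = sorted(aln.ids)
    dist = {
        frozenset((a, b)): _percent_mismatch(aln.row(a), aln.row(b))
        for i, a in enumerate(ids)
        for b in ids[i + 1 :]
    }
    # cluster state: (sorted member tuple, newick string, height, size)
    clusters: dict[tuple[str, ...], tuple[str, float, int]] = {
        (sid,): (sid, 0.0, 1) for sid in ids
    }

    def avg_link(c1: tuple[str, ...], c2: tuple[str, ...]) -> float:
        return sum(dist[frozenset((a, b))] for a in c1 for b in c2) / (
            len(c1) * len(c2)
        )

    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                d = avg_link(keys[i], keys[j])
                cand = (d, keys[i], keys[j])
                if best is None or cand < best:
                    best = cand
        d, k1, k2 = best  # type: ignore[misc]
        nwk1, h1, n1 = clusters.pop(k1)
        nwk2, h2, n2 = clusters.pop(k2)
        height = d / 2.0
        merged = tuple(sorted(k1 + k2))
        newick = (
            f"({nwk1}:{height - h1:.10f},{nwk2}:{height - h2:.10f})"
        )
        clusters[merged] = (newick, height, n1 + n2)
    final_newick = next(iter(clusters.values()))[0] + ";"
    tree = dendropy.Tree.get(data=final_newick, schema="newick", rooting="force-rooted")
    return tree


# ---------------------------------------------------------------------------
# rvET scores


def _node_height(node, cache: dict) -> float:
    """Max path length from node down to any descendant leaf (edges default 1)."""
    if node in cache:
        return cache[node]
    if node.is_leaf():
        cache[node] = 0.0
        return 0.0
    h = max(
        _node_height(ch, cache) + (ch.edge.length if ch.edge.length is not None else 1.0)
        for ch in node.child_nodes()
    )
    cache[node] = h
    return h


def rvet_scores(aln: Alignment, tree: dendropy.Tree) -> np.ndarray:
    """Per-column rvET score rho over the alignment, given a rooted grouping tree.

    Internal nodes are dissolved from the highest down (height = maximal
    distance to a descendant leaf; ties broken by pre-order), each dissolution
    refining the partition of sequences into groups.  Every partition with
    n <= N-1 groups contributes (1/n) times the summed within-group column
    entropies.  On a strictly binary tree this is exactly the n = 1..N-1
    schedule; a multifurcating node adds several groups at once and the skipped
    group counts contribute nothing.
    """
    leaf_labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if set(leaf_labels) != set(aln.ids):
        diff = set(leaf_labels) ^ set(aln.ids)
        raise ConsistencyError(f"tree leaves and alignment ids differ: {sorted(diff)}")
    n_rows, n_cols = aln.n_rows, aln.n_columns
    codes = np.array(
        [[_SYMBOL_INDEX[s] for s in row] for row in aln.rows], dtype=np.int64
    )
    row_index = {sid: i for i, sid in enumerate(aln.ids)}

    # Per-node column entropies, computed bottom-up from additive counts.
    col_range = np.arange(n_cols)
    counts: dict = {}
    entropy: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            c = np.zeros((21, n_cols))
            c[codes[row_index[node.taxon.label]], col_range] = 1.0
        else:
            c = np.zeros((21, n_cols))
            for ch in node.child_nodes():
                c += counts[ch]
        counts[node] = c
        total = c.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = c / total
            logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
        entropy[node] = -(p * logp).sum(axis=0)

    heights: dict = {}
    _node_height(tree.seed_node, heights)
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    order = {n: i for i, n in enumerate(tree.preorder_node_iter())}
    internal.sort(key=lambda n: (-heights[n], order[n]))

    scores = np.ones(n_cols)
    group_entropy_sum = entropy[tree.seed_node].copy()
    n_groups = 1
    for node in internal:
        if n_groups <= n_rows - 1:
            scores += group_entropy_sum / n_groups
        # dissolve this node into its children
        group_entropy_sum += (
            sum(entropy[ch] for ch in node.child_nodes()) - entropy[node]
        )
        n_groups += len(node.child_nodes()) - 1
        if n_groups > n_rows - 1:
            break
    else:
        # all internal nodes dissolved; remaining partitions are all-singleton
        if n_groups <= n_rows - 1:
            scores += group_entropy_sum / n_groups
    return scores


# ---------------------------------------------------------------------------
# Rank / coverage / variability


def column_variability(aln: Alignment, col: int) -> str:
    """Distinct column symbols by decreasing frequency, ties alphabetical."""
    counts = Counter(aln.column(col))
    return "".join(sorted(counts, key=lambda s: (-counts[s], s)))


def rank_coverage(
    aln: Alignment,
    reference_id: str,
    scores: Sequence[float],
    mapping: Optional[ReferenceMapping] = None,
    name: Optional[str] = None,
) -> TraceResult:
    """Tie-aware trace table over the reference sequence's residues.

    Residues are sorted by ascending score (ties by residue number); tied
    exact scores share the minimal rank of their block, and coverage is the
    fraction of reference residues scoring at or below the residue's score.
    """
    if mapping is None:
        mapping = map_to_reference(aln, reference_id)
    ref_row = aln.row(reference_id)
    items = [
        (mapping.column_to_residue[col], col, float(scores[col]))
        for col in sorted(mapping.column_to_residue)
    ]
    length = len(items)
    if length == 0:
        raise InputError(f"reference {reference_id!r} has no ungapped columns")
    all_scores = np.array([s for _, _, s in items])
    items.sort(key=lambda t: (t[2], t[0]))
    rows = []
    for resnum, col, score in items:
        rank = int((all_scores < score).sum()) + 1
        coverage = int((all_scores <= score).sum()) / length
        rows.append(
            TraceRow(
                rank=rank,
                residue_number=resnum,
                alignment_position=col,
                residue=ref_row[col],
                coverage=coverage,
                variability=column_variability(aln, col),
                rvet_score=score,
            )
        )
    return TraceResult(reference_id, name or reference_id, length, tuple(rows))


def compute_trace(
    aln: Alignment,
    reference_id: str,
    tree: Optional[dendropy.Tree] = None,
    name: Optional[str] = None,
) -> TraceResult:
    """End-to-end trace: grouping tree (UPGMA identity tree unless supplied),
    rvET scores, and the rank/coverage table for the reference sequence."""
    if tree is None:
        tree = identity_distance_tree(aln)
    scores = rvet_scores(aln, tree)
    return rank_coverage(aln, reference_id, scores, name=name)


def top_fraction(trace: TraceResult, fraction: float) -> tuple[TraceRow, ...]:
    """The round(fraction * L) lowest-score residues (round-half-even).

    Ties at the boundary are included in score order, then residue-number
    order, truncated to the count.
    """
    if not 0 < fraction <= 1:
        raise InputError("fraction must be in (0, 1]")
    count = round(round(fraction * trace.length, 9))
    ordered = sorted(trace.rows, key=lambda r: (r.rvet_score, r.residue_number))
    return tuple(ordered[:count])


def compare_traces(
    reference: TraceResult,
    others: Sequence[TraceResult],
    fraction: float = 0.30,
) -> pd.DataFrame:
    """Cross-cluster trace comparison over the reference's top fraction.

    Rows are the reference trace's top-fraction residues; for each other
    trace the rank, coverage, variability and score at the *same alignment
    position* are reported (positions stay comparable because sub-alignments
    are never column-re-compacted).  Positions absent from another trace are
    flagged missing (NaN).
    """
    rows = []
    for ref_row in top_fraction(reference, fraction):
        entry = {
            f"{reference.name}:rank": ref_row.rank,
            "residue_number": ref_row.residue_number,
            "alignment_position": ref_row.alignment_position,
            "residue": ref_row.residue,
            f"{reference.name}:coverage": round(ref_row.coverage, 5),
            f"{reference.name}:variability": ref_row.variability,
            f"{reference.name}:rvet_score": round(ref_row.rvet_score, 2),
        }
        for other in others:
            match = other.row_at_position(ref_row.alignment_position)
            prefix = other.name
            if match is None:
                entry[f"{prefix}:rank"] = np.nan
                entry[f"{prefix}:coverage"] = np.nan
                entry[f"{prefix}:variability"] = ""
                entry[f"{prefix}:rvet_score"] = np.nan
            else:
                entry[f"{prefix}:rank"] = match.rank
                entry[f"{prefix}:coverage"] = round(match.coverage, 5)
                entry[f"{prefix}:variability"] = match.variability
                entry[f"{prefix}:rvet_score"] = round(match.rvet_score, 2)
        rows.append(entry)
    return pd.DataFrame(rows)


def write_trace_tsv(trace: TraceResult, path) -> None:
    trace.to_dataframe(rounded=True).to_csv(path, sep="\t", index=False)


def write_residue_scores(trace: TraceResult, path) -> None:
    """Two-column per-residue score table for 3D colouring in molecular viewers."""
    df = pd.DataFrame(
        sorted(
            ((r.residue_number, r.rvet_score) for r in trace.rows),
        ),
        columns=["residue_number", "score"],
    )
    df.to_csv(path, sep="\t", index=False)
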