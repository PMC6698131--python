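"""FAST: clade-specificity and conservation statistics over alignment columns.

For a column ``i`` and a symbol ``a``, the "amino-acid cluster" is the set of
sequences carrying ``a`` at ``i`` (identity grouping; a physicochemical
grouping can be plugged in via ``symbol_classes``).  Its specificity is the
lowest one-sided Fisher (hypergeometric upper-tail) probability of its overlap
with any monophyletic group of the guide tree, and the specificity score is
-log10 of that probability.  Column conservation is one minus the normalised
Shannon entropy of the 21-symbol distribution (20 amino acids plus the gap
state).  Both statistics drive an HSV colouring of the alignment: hue from the
tree position of the cluster's median member, saturation from specificity,
value (darkness) from conservation -- conserved columns go dark, clade-specific
clusters go saturated.
"""

from __future__ import annotations

import colorsys
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .exceptions import ConsistencyError, InputError
from .msa import GAP, Alignment

N_SYMBOLS = 21  # 20 amino acids + gap state


@dataclass(frozen=True)
class CladeSet:
    """Monophyletic leaf-id sets of a rooted tree, in pre-order.

    Singletons and the full leaf set are excluded: only proper internal
    structure can witness specificity.
    """

    clades: tuple[frozenset[str], ...]

    def __len__(self) -> int:
        return len(self.clades)

    def __iter__(self):
        return iter(self.clades)


@dataclass(frozen=True)
class SpecificityCell:
    column: int
    symbol: str
    best_clade: Optional[frozenset[str]]
    fisher_p: float
    spec_score: float
    members: frozenset[str]


@dataclass(frozen=True)
class ColumnScore:
    column: int
    conservation: float


@dataclass(frozen=True)
class ColorCell:
    hue: float  # degrees in [0, 360)
    saturation: float  # [0, 1]
    value: float  # [0, 1]

    def to_rgb(self) -> tuple[float, float, float]:
        return colorsys.hsv_to_rgb(self.hue / 360.0, self.saturation, self.value)


def enumerate_tree_clusters(
    tree: dendropy.Tree, alignment_ids: Optional[Sequence[str]] = None
) -> CladeSet:
    """One clade per internal node (pre-order), excluding root set and singletons.

    When ``alignment_ids`` is given the tree leaves must match it exactly;
    the error lists the symmetric difference otherwise.
    """
    leaf_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if alignment_ids is not None:
        diff = leaf_labels ^ set(alignment_ids)
        if diff:
            raise ConsistencyError(
                f"tree leaves and alignment ids differ: {sorted(diff)}"
            )
    clades: list[frozenset[str]] = []
    seen: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        members = frozenset(
            leaf.taxon.label for leaf in node.leaf_iter()
        )
        if 2 <= len(members) <= len(leaf_labels) - 1 and members not in seen:
            clades.append(members)
            seen.add(members)
    return CladeSet(tuple(clades))


def fisher_enrichment_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X is the overlap between a random n-subset and a fixed K-subset of an
    N-element population; equivalently the one-sided Fisher exact test for
    enrichment of a symbol cluster (size n) within a clade (size K).
    """
    if not (0 <= n <= N and 0 <= K <= N):
        raise InputError(f"inconsistent counts: n={n}, K={K}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise InputError(f"overlap k={k} outside [0, min({n}, {K})]")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def best_specificity(
    aln: Alignment,
    col: int,
    symbol: str,
    clades: CladeSet,
    symbol_classes: Optional[Mapping[str, str]] = None,
) -> SpecificityCell:
    """Lowest Fisher probability of the symbol's cluster against any clade.

    Ties among clades are broken by smallest clade, then by pre-order (the
    order clades appear in the CladeSet).  An empty clade set yields p = 1 by
    convention.  ``symbol_classes`` optionally maps symbols to class labels so
    that physicochemically equivalent residues form one cluster.
    """
    column = aln.column(col)
    key = symbol_classes.get(symbol, symbol) if symbol_classes else symbol
    if symbol_classes:
        members = frozenset(
            sid
            for sid, sym in zip(aln.ids, column)
            if symbol_classes.get(sym, sym) == key
        )
    else:
        members = frozenset(sid for sid, sym in zip(aln.ids, column) if sym == symbol)
    if not members:
        raise InputError(f"symbol {symbol!r} absent from column {col}")
    n = len(members)
    N = aln.n_rows
    best: Optional[tuple[float, int, int, frozenset[str]]] = None
    for order, clade in enumerate(clades):
        k = len(members & clade)
        p = fisher_enrichment_p(k, n, len(clade), N)
        key = (p, len(clade), order, clade)
        if best is None or key[:3] < best[:3]:
            best = key
    if best is None:
        best_p, best_clade = 1.0, None
    else:
        best_p, best_clade = best[0], best[3]
    spec = -math.log10(best_p) if best_p > 0 else math.inf
    return SpecificityCell(col, symbol, best_clade, best_p, spec, members)


def specificity_table(
    aln: Alignment,
    clades: CladeSet,
    symbol_classes: Optional[Mapping[str, str]] = None,
) -> dict[tuple[int, str], SpecificityCell]:
    """best_specificity for every (column, observed symbol) pair."""
    cells: dict[tuple[int, str], SpecificityCell] = {}
    for col in range(aln.n_columns):
        for symbol in sorted(set(aln.column(col))):
            cells[(col, symbol)] = best_specificity(
                aln, col, symbol, clades, symbol_classes
            )
    return cells


def column_conservation(aln: Alignment, col: int) -> ColumnScore:
    """1 - H/ln(21), H the natural-log Shannon entropy over 21 symbols.

    Invariant columns score 1; a column spread uniformly over all 21 symbols
    scores 0.  The gap is a bona fide 21st state.
    """
    column = aln.column(col)
    counts = np.bincount(
        [_SYMBOL_INDEX[s] for s in column], minlength=N_SYMBOLS
    ).astype(float)
    freqs = counts[counts > 0] / len(column)
    entropy = float(-(freqs * np.log(freqs)).sum())
    return ColumnScore(col, 1.0 - entropy / math.log(N_SYMBOLS))


_SYMBOL_INDEX = {s: i for i, s in enumerate("ACDEFGHIKLMNPQRSTVWY" + GAP)}


def conservation_profile(aln: Alignment) -> list[ColumnScore]:
    return [column_conservation(aln, c) for c in range(aln.n_columns)]


def default_saturation_cap(
    cells: Mapping[tuple[int, str], SpecificityCell], percentile: float = 99.0
) -> float:
    """Saturation cap: a high percentile of the finite specificity scores."""
    scores = [c.spec_score for c in cells.values() if math.isfinite(c.spec_score)]
    if not scores or max(scores) == 0:
        return 1.0
    return float(np.percentile(scores, percentile)) or 1.0


def colorize(
    aln: Alignment,
    leaf_order: Sequence[str],
    cells: Mapping[tuple[int, str], SpecificityCell],
    column_scores: Sequence[ColumnScore],
    saturation_cap: Optional[float] = None,
    hue_span: float = 270.0,
    value_floor: float = 0.2,
) -> list[list[ColorCell]]:
    """HSV colour matrix (rows x columns) of the alignment.

    Sequence k of N (in tree-leaf order) has base hue ``hue_span * k/(N-1)``
    (a red-to-violet rainbow).  A cell's hue is the base hue of the median
    member of its symbol cluster (lower median on even counts), its saturation
    is ``min(1, spec_score/saturation_cap)``, and its value is
    ``1 - (1-value_floor) * conservation`` -- so fully conserved columns render
    at the dark value floor with zero saturation.
    """
    missing = set(aln.ids) - set(leaf_order)
    if missing:
        raise ConsistencyError(f"leaf order misses ids: {sorted(missing)}")
    if saturation_cap is None:
        saturation_cap = default_saturation_cap(cells)
    order_index = {sid: i for i, sid in enumerate(leaf_order)}
    n = len(leaf_order)
    cons = {cs.column: cs.conservation for cs in column_scores}
    matrix: list[list[ColorCell]] = []
    for sid, row in zip(aln.ids, aln.rows):
        out_row = []
        for col, sym in enumerate(row):
            cell = cells[(col, sym)]
            ranks = sorted(order_index[m] for m in cell.members)
            median_k = ranks[(len(ranks) - 1) // 2]  # lower median
            hue = hue_span * median_k / (n - 1) if n > 1 else 0.0
            sat = min(1.0, cell.spec_score / saturation_cap) if saturation_cap else 0.0
            val = 1.0 - (1.0 - value_floor) * cons[col]
            out_row.append(ColorCell(hue % 360.0, sat, val))
        matrix.append(out_row)
    return matrix


def report_positions(
    cells: Mapping[tuple[int, str], SpecificityCell],
    column_scores: Sequence[ColumnScore],
    conservation_threshold: float = 0.8,
    specificity_threshold: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Conserved-core and specificity-determining-position (SDP) tables.

    Conserved core: columns whose conservation meets the threshold.
    SDP table: (column, symbol, clade, p, score) rows with spec_score at or
    above the threshold, sorted by score descending.
    """
    core = pd.DataFrame(
        [
            {"column": cs.column, "conservation": cs.conservation}
            for cs in column_scores
            if cs.conservation >= conservation_threshold
        ],
        columns=["column", "conservation"],
    )
    sdp_rows = [
        {
            "column": c.column,
            "symbol": c.symbol,
            "clade": ",".join(sorted(c.best_clade)) if c.best_clade else "",
            "fisher_p": c.fisher_p,
            "spec_score": c.spec_score,
        }
        for c in cells.values()
        if c.spec_score >= specificity_threshold
    ]
    sdp = pd.DataFrame(
        sdp_rows, columns=["column", "symbol", "clade", "fisher_p", "spec_score"]
    ).sort_values(
        ["spec_score", "column", "symbol"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return core, sdp


def score_table(
    aln: Alignment,
    cells: Mapping[tuple[int, str], SpecificityCell],
    column_scores: Sequence[ColumnScore],
) -> pd.DataFrame:
    """Flat per-(column, symbol) TSV-ready table of all FAST statistics."""
    cons = {cs.column: cs.conservation for cs in column_scores}
    rows = [
        {
            "column": c.column,
            "symbol": c.symbol,
            "clade": ",".join(sorted(c.best_clade)) if c.best_clade else "",
            "fisher_p": c.fisher_p,
            "spec_score": c.spec_score,
            "conservation": cons[c.column],
        }
        for c in cells.values()
    ]
    return pd.DataFrame(
        rows,
        columns=["column", "symbol", "clade", "fisher_p", "spec_score", "conservation"],
    ).sort_values(["column", "symbol"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# SVG rendering


def render_svg(
    aln: Alignment,
    colors: Sequence[Sequence[ColorCell]],
    path,
    cell_w: int = 12,
    cell_h: int = 16,
    label_w: int = 120,
) -> None:
    """Write the coloured alignment as a static SVG file."""
    width = label_w + aln.n_columns * cell_w
    height = aln.n_rows * cell_h
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'font-family="monospace" font-size="{cell_h - 4}px">'
    ]
    for r, (sid, row) in enumerate(zip(aln.ids, aln.rows)):
        y = r * cell_h
        parts.append(
            f'<text x="2" y="{y + cell_h - 4}">{sid}</text>'
        )
        for c, sym in enumerate(row):
            cell = colors[r][c]
            rf, gf, bf = cell.to_rgb()
            fill = f"rgb({int(rf * 255)},{int(gf * 255)},{int(bf * 255)})"
            x = label_w + c * cell_w
            parts.append(f'<rect x="{x}" y="{y}" width="{cell_w}" height="{cell_h}" fill="{fill}"/>')
            text_fill = "#fff" if cell.value < 0.5 else "#000"
            parts.append(
                f'<text x="{x + 2}" y="{y + cell_h - 4}" fill="{text_fill}">{sym}</text>'
            )
    parts.append("</svg>")
    with open(path, "w") as fh:
        fh.write("\n".join(parts))
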