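"""Synthetic fixtures with planted ground truth.

Three generators emulate the statistical structure the analysis modules
assume, without any biological realism beyond what the statistics exercise:

* ``make_sdp_alignment`` -- alignments with planted conserved columns and
  specificity-determining positions (clade-specific invariant symbols over a
  uniform random background), plus the matching balanced clade tree;
* ``make_helix_bundle`` -- families of helical CA traces, jittered within a
  cluster and rigidly deformed between clusters, emulating two structural
  fold groups separated on a known RMSD scale;
* ``make_annotations`` -- keyword tables with a controlled number of
  annotated members inside and outside a target cluster.

All generators are pure functions of their parameters and seed, and emit the
planted truth alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np

from .exceptions import InputError
from .msa import Alignment
from .seqdef import AMINO_ACIDS
from .structclass import CoordinateSet

_AA = np.array(list(AMINO_ACIDS))


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth emitted next to generated data."""

    sdp_columns: tuple[tuple[int, int, str], ...] = ()  # (column, clade index, symbol)
    conserved_columns: tuple[int, ...] = ()
    clade_members: tuple[tuple[str, ...], ...] = ()
    cluster_assignment: Mapping[str, int] = field(default_factory=dict)
    planted_rmsd_scale: float = 0.0

    def to_json(self, path: Path | str) -> None:
        payload = {
            "sdp_columns": [list(t) for t in self.sdp_columns],
            "conserved_columns": list(self.conserved_columns),
            "clade_members": [list(c) for c in self.clade_members],
            "cluster_assignment": dict(self.cluster_assignment),
            "planted_rmsd_scale": self.planted_rmsd_scale,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def make_sdp_alignment(
    n_clades: int = 2,
    seqs_per_clade: int = 4,
    n_columns: int = 60,
    n_sdp: int = 5,
    n_conserved: int = 10,
    noise_rate: float = 0.0,
    seed: int = 0,
) -> tuple[Alignment, dendropy.Tree, PlantedTruth]:
    """Alignment with planted conserved and SDP columns, plus its clade tree.

    Conserved columns are invariant across all sequences.  Each SDP column is
    assigned one clade and carries a fixed symbol inside it; every other clade
    receives a different fixed symbol there, so the column is perfectly
    clade-correlated before noise.  Remaining columns are uniform random.
    Per-cell mutation noise replaces a cell with a uniform random amino acid
    at ``noise_rate``.  The tree is balanced with unit branch lengths -- the
    clade structure, not branch lengths, is what the statistics consume.
    """
    if n_sdp + n_conserved > n_columns:
        raise InputError("n_sdp + n_conserved exceeds n_columns")
    if not 0 <= noise_rate < 0.5:
        raise InputError("noise_rate must be in [0, 0.5)")
    if n_clades < 2 or seqs_per_clade < 1:
        raise InputError("need >= 2 clades and >= 1 sequence per clade")
    rng = np.random.default_rng(seed)
    n_rows = n_clades * seqs_per_clade
    ids = tuple(
        f"c{ci}s{si}" for ci in range(n_clades) for si in range(seqs_per_clade)
    )
    clade_members = tuple(
        tuple(f"c{ci}s{si}" for si in range(seqs_per_clade)) for ci in range(n_clades)
    )
    clade_of_row = np.repeat(np.arange(n_clades), seqs_per_clade)

    cols = rng.permutation(n_columns)
    conserved_cols = tuple(sorted(int(c) for c in cols[:n_conserved]))
    sdp_cols = tuple(sorted(int(c) for c in cols[n_conserved : n_conserved + n_sdp]))

    matrix = _AA[rng.integers(0, 20, size=(n_rows, n_columns))]
    for col in conserved_cols:
        matrix[:, col] = rng.choice(_AA)
    sdp_truth = []
    for k, col in enumerate(sdp_cols):
        owner = k % n_clades
        symbols = rng.permutation(_AA)[:n_clades]
        for ci in range(n_clades):
            matrix[clade_of_row == ci, col] = symbols[ci]
        sdp_truth.append((col, owner, str(symbols[owner])))
    if noise_rate > 0:
        mask = rng.random((n_rows, n_columns)) < noise_rate
        matrix[mask] = _AA[rng.integers(0, 20, size=int(mask.sum()))]

    aln = Alignment(ids, tuple("".join(row) for row in matrix))
    newick = (
        "("
        + ",".join(
            "(" + ",".join(f"{sid}:1" for sid in members) + "):1"
            for members in clade_members
        )
        + ");"
    )
    tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
    truth = PlantedTruth(
        sdp_columns=tuple(sdp_truth),
        conserved_columns=conserved_cols,
        clade_members=clade_members,
    )
    return aln, tree, truth


def make_helix_bundle(
    n_clusters: int = 2,
    members_per_cluster: int = 4,
    n_residues: int = 40,
    within_sigma: float = 0.3,
    between_shift: float = 5.0,
    seed: int = 0,
) -> tuple[list[CoordinateSet], PlantedTruth]:
    """Clusters of jittered helical CA traces with a planted separation scale.

    Each cluster starts from a common 3D helix (2.3 A radius, 1.5 A rise per
    residue); cluster c rigidly displaces the middle third of residues by
    ``between_shift`` angstroms along a cluster-specific direction, and every
    member adds isotropic Gaussian jitter of ``within_sigma`` angstroms per
    coordinate.  Intra-cluster RMSDs scale with within_sigma, inter-cluster
    RMSDs with between_shift, so a cutoff between the two scales recovers the
    planted partition.
    """
    if n_clusters < 1 or members_per_cluster < 1 or n_residues < 4:
        raise InputError("non-positive or too-small sizes")
    if not within_sigma < between_shift:
        raise InputError("within_sigma must be smaller than between_shift")
    rng = np.random.default_rng(seed)
    t = np.arange(n_residues)
    base = np.stack(
        [2.3 * np.cos(t * 1.75), 2.3 * np.sin(t * 1.75), 1.5 * t], axis=1
    )
    lo, hi = n_residues // 3, 2 * n_residues // 3
    structures: list[CoordinateSet] = []
    assignment: dict[str, int] = {}
    for ci in range(n_clusters):
        deformed = base.copy()
        if ci > 0:
            angle = 2 * np.pi * ci / n_clusters
            direction = np.array([np.cos(angle), np.sin(angle), 0.0])
            deformed[lo:hi] += between_shift * direction
        for mi in range(members_per_cluster):
            sid = f"k{ci}m{mi}"
            jitter = rng.normal(0.0, within_sigma, size=base.shape)
            structures.append(
                CoordinateSet(
                    sid, deformed + jitter, tuple(range(1, n_residues + 1))
                )
            )
            assignment[sid] = ci
    frac = (hi - lo) / n_residues
    truth = PlantedTruth(
        cluster_assignment=assignment,
        planted_rmsd_scale=float(between_shift * np.sqrt(frac)),
    )
    return structures, truth


def make_trace_benchmark(
    n_seqs: int = 43,
    n_residues: int = 90,
) -> tuple[Alignment, dendropy.Tree]:
    """Deterministic gapless alignment + caterpillar grouping tree with a
    controlled trace tie structure.

    The first sequence is the reference (no gaps, so reference length equals
    the column count).  Columns are laid out as: nine invariant columns
    (eight cysteine-like, one aspartate-like -- the family's conserved
    scaffold pattern), three columns sharing one identical single-divergence
    pattern (an exact three-way score tie), and a background of two-symbol
    divergence compositions that are pairwise distinct, so every background
    column gets a distinct rvET score.  With the default sizes the trace
    exhibits a nine-way tie at rank 1, a three-way tie at rank 10 and an
    untied residue at rank 27.
    """
    if n_seqs < 8 or n_residues < 13:
        raise InputError("benchmark needs >= 8 sequences and >= 13 columns")
    ids = [f"s{i:02d}" for i in range(n_seqs)]
    rows = [["L"] * n_residues for _ in range(n_seqs)]
    invariant_letters = "CCCCCCCCD"
    for j, letter in enumerate(invariant_letters):
        for r in range(n_seqs):
            rows[r][j] = letter
    for j, (base, divergent) in enumerate([("V", "A"), ("G", "S"), ("I", "V")], start=9):
        for r in range(n_seqs):
            rows[r][j] = base
        rows[0][j] = divergent
    # Background: distinct (d, e) divergence compositions at the deep end of
    # the caterpillar, giving pairwise distinct entropies hence scores.
    compositions: list[tuple[int, int]] = []
    total = 3
    n_background = n_residues - 12
    while len(compositions) < n_background:
        for e in range(1, total // 2 + 1):
            d = total - e
            if d >= 2 and d + e <= n_seqs - 1:
                compositions.append((d, e))
                if len(compositions) == n_background:
                    break
        total += 1
    for j, (d, e) in enumerate(compositions, start=12):
        for r in range(d):
            rows[r][j] = "F"
        for r in range(d, d + e):
            rows[r][j] = "Y"
    aln = Alignment(tuple(ids), tuple("".join(r) for r in rows))
    newick = f"({ids[0]}:1,{ids[1]}:1)"
    for k in range(2, n_seqs):
        newick = f"({newick}:1,{ids[k]}:1)"
    tree = dendropy.Tree.get(
        data=newick + ";", schema="newick", rooting="force-rooted"
    )
    return aln, tree


def make_annotations(
    ids: Sequence[str],
    target_cluster: Sequence[str],
    n_in_cluster: int,
    n_outside: int,
    keyword: str = "defense",
    seed: int = 0,
) -> dict[str, frozenset[str]]:
    """Keyword table: exactly n_in_cluster annotated ids inside the target
    cluster and n_outside elsewhere, sampled without replacement."""
    rng = np.random.default_rng(seed)
    inside = [i for i in ids if i in set(target_cluster)]
    outside = [i for i in ids if i not in set(target_cluster)]
    if n_in_cluster > len(inside) or n_outside > len(outside):
        raise InputError("requested more annotated ids than available")
    chosen = list(rng.choice(inside, size=n_in_cluster, replace=False)) + list(
        rng.choice(outside, size=n_outside, replace=False)
    )
    return {sid: frozenset({keyword}) for sid in chosen}
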