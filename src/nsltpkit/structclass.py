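"""Structural classification of C-alpha coordinate sets.

Pairwise structural distances are RMSDs after optimal rigid-body (Kabsch)
superposition over supplied residue correspondences; the matrix feeds a
neighbor-joining distance tree for display, a complete-linkage cutoff
clustering (every member pair of a cluster within the cutoff, matching the
sub-tree-at-cutoff reading of the structure tree), medoid representatives,
and keyword-annotation enrichment reports over the resulting partitions.

Correspondences are consumed, not computed: in the intended data flow they
come from the shared non-gap columns of a structure-based sequence alignment.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .exceptions import (
    ConsistencyError,
    FormatError,
    GeometryError,
    InputError,
    LookupIdError,
)
from .msa import GAP, Alignment

#: Default cutoff sweep: 11.5 A (everything in one cluster) down to 0.5 A.
DEFAULT_SWEEP = tuple(np.round(np.arange(11.5, 0.49, -0.5), 1))


@dataclass(frozen=True)
class CoordinateSet:
    """CA coordinates (angstroms) of one structure, one point per residue."""

    id: str
    ca_coordinates: np.ndarray  # (n, 3) float
    residue_numbers: tuple[int, ...]

    def __post_init__(self) -> None:
        coords = np.asarray(self.ca_coordinates, dtype=float)
        object.__setattr__(self, "ca_coordinates", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InputError(f"{self.id}: coordinates must be (n, 3)")
        if not np.all(np.isfinite(coords)):
            raise InputError(f"{self.id}: non-finite coordinates")
        if len(self.residue_numbers) != len(coords):
            raise InputError(f"{self.id}: residue_numbers length mismatch")
        if any(b <= a for a, b in zip(self.residue_numbers, self.residue_numbers[1:])):
            raise InputError(f"{self.id}: residue_numbers not strictly increasing")

    def __len__(self) -> int:
        return len(self.residue_numbers)

    def index_of_residue(self, residue_number: int) -> int:
        try:
            return self.residue_numbers.index(residue_number)
        except ValueError:
            raise LookupIdError(
                f"{self.id}: residue {residue_number} not present"
            ) from None


@dataclass(frozen=True)
class Correspondence:
    """Paired 0-based coordinate indices (index in A, index in B)."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        a_side = [a for a, _ in self.pairs]
        b_side = [b for _, b in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise InputError("correspondence repeats an index within one side")

    def flipped(self) -> "Correspondence":
        return Correspondence(tuple((b, a) for a, b in self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class SuperpositionResult:
    """Proper rotation + translation mapping B onto A, with the residual RMSD."""

    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,)
    rmsd: float

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class RMSDMatrix:
    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.ids), len(self.ids)):
            raise InputError("matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-9):
            raise InputError("RMSD matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-9):
            raise InputError("RMSD matrix diagonal must be zero")
        if (v < -1e-12).any():
            raise InputError("RMSD matrix must be non-negative")

    def distance(self, a: str, b: str) -> float:
        try:
            i, j = self.ids.index(a), self.ids.index(b)
        except ValueError as exc:
            raise LookupIdError(str(exc)) from None
        return float(self.values[i, j])


@dataclass(frozen=True)
class StructureCluster:
    member_ids: tuple[str, ...]
    cutoff: float
    medoid_id: str


# ---------------------------------------------------------------------------
# Superposition


def kabsch_superpose(
    a: CoordinateSet, b: CoordinateSet, corr: Correspondence
) -> SuperpositionResult:
    """Least-squares rigid superposition of B onto A over paired atoms.

    Centroid alignment followed by SVD of the cross-covariance, with the
    reflection corrected so the rotation is proper (det +1).  Requires at
    least three non-collinear pairs.
    """
    if len(corr) < 3:
        raise GeometryError(f"need >= 3 pairs, got {len(corr)}")
    pa = a.ca_coordinates[[i for i, _ in corr.pairs]]
    pb = b.ca_coordinates[[j for _, j in corr.pairs]]
    ca_, cb_ = pa.mean(axis=0), pb.mean(axis=0)
    qa, qb = pa - ca_, pb - cb_
    if min(np.linalg.matrix_rank(qa, tol=1e-9), np.linalg.matrix_rank(qb, tol=1e-9)) < 2:
        raise GeometryError("degenerate (collinear) point configuration")
    h = qb.T @ qa
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr_mat = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr_mat @ u.T
    translation = ca_ - rotation @ cb_
    residuals = qa - qb @ rotation.T
    rmsd = float(np.sqrt((residuals**2).sum() / len(corr)))
    return SuperpositionResult(rotation, translation, rmsd)


def residue_pair_distance(
    a: CoordinateSet,
    b: CoordinateSet,
    superposition: SuperpositionResult,
    residue_a: int,
    residue_b: int,
) -> float:
    """Distance (A) between a residue of A and a residue of superposed B."""
    pa = a.ca_coordinates[a.index_of_residue(residue_a)]
    pb = superposition.transform(b.ca_coordinates[b.index_of_residue(residue_b)])
    return float(np.linalg.norm(pa - pb))


# ---------------------------------------------------------------------------
# Correspondences


def correspondence_from_alignment(
    aln: Alignment,
    id_a: str,
    id_b: str,
    structures: Optional[Mapping[str, CoordinateSet]] = None,
) -> Correspondence:
    """Pairs from the shared non-gap columns of a structure-based alignment.

    Column c contributes a pair when both rows are ungapped there; indices are
    positions in each sequence's ungapped residue order, which is also the
    coordinate order of the matching CoordinateSet.
    """
    row_a, row_b = aln.row(id_a), aln.row(id_b)
    pairs = []
    ia = ib = 0
    for sa, sb in zip(row_a, row_b):
        if sa != GAP and sb != GAP:
            pairs.append((ia, ib))
        if sa != GAP:
            ia += 1
        if sb != GAP:
            ib += 1
    if structures is not None:
        for sid, n in ((id_a, ia), (id_b, ib)):
            if len(structures[sid]) != n:
                raise ConsistencyError(
                    f"{sid}: alignment has {n} residues, structure has "
                    f"{len(structures[sid])}"
                )
    return Correspondence(tuple(pairs))


def read_correspondences(path: Path | str) -> dict[tuple[str, str], Correspondence]:
    """Read a correspondence TSV with columns idA, idxA, idB, idxB (0-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"idA": str, "idB": str})
    out: dict[tuple[str, str], Correspondence] = {}
    for (ida, idb), grp in df.groupby(["idA", "idB"], sort=False):
        out[(ida, idb)] = Correspondence(
            tuple(zip(grp["idxA"].astype(int), grp["idxB"].astype(int)))
        )
    return out


def write_correspondences(
    corrs: Mapping[tuple[str, str], Correspondence], path: Path | str
) -> None:
    rows = [
        {"idA": ida, "idxA": i, "idB": idb, "idxB": j}
        for (ida, idb), corr in corrs.items()
        for i, j in corr.pairs
    ]
    pd.DataFrame(rows, columns=["idA", "idxA", "idB", "idxB"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Pairwise matrix and distance tree


def pairwise_rmsd_matrix(
    structures: Sequence[CoordinateSet],
    correspondences: Mapping[tuple[str, str], Correspondence],
) -> RMSDMatrix:
    """Kabsch RMSD for every structure pair; symmetric by construction.

    A correspondence may be supplied under either key order; missing pairs
    raise a coverage error naming the pair.
    """
    ids = tuple(s.id for s in structures)
    by_id = {s.id: s for s in structures}
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            key = (ids[i], ids[j])
            if key in correspondences:
                corr = correspondences[key]
            elif key[::-1] in correspondences:
                corr = correspondences[key[::-1]].flipped()
            else:
                raise LookupIdError(f"no correspondence for pair {key}")
            rmsd = kabsch_superpose(by_id[ids[i]], by_id[ids[j]], corr).rmsd
            values[i, j] = values[j, i] = rmsd
    return RMSDMatrix(ids, values)


def identity_correspondences(
    structures: Sequence[CoordinateSet],
) -> dict[tuple[str, str], Correspondence]:
    """All-vs-all identity correspondences for equal-length coordinate sets."""
    lengths = {len(s) for s in structures}
    if len(lengths) > 1:
        raise ConsistencyError("structures differ in length")
    n = lengths.pop()
    ident = Correspondence(tuple((i, i) for i in range(n)))
    return {
        (a.id, b.id): ident
        for i, a in enumerate(structures)
        for b in structures[i + 1 :]
    }


def build_distance_tree(m: RMSDMatrix) -> dendropy.Tree:
    """Neighbor-joining tree from the RMSD matrix (Newick-ready).

    NJ is exact on additive matrices: leaf-to-leaf path lengths then reproduce
    the input distances.  The tree is used for display and clustering context,
    mirroring a minimum-evolution tree's role.
    """
    if len(m.ids) < 3:
        raise InputError("need >= 3 structures for a distance tree")
    buf = io.StringIO()
    buf.write("," + ",".join(m.ids) + "\n")
    for i, sid in enumerate(m.ids):
        buf.write(sid + "," + ",".join(f"{v:.12g}" for v in m.values[i]) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    return pdm.nj_tree()


def tree_path_distance(tree: dendropy.Tree, a: str, b: str) -> float:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in pdm.taxon_iter()}
    return float(pdm.patristic_distance(taxa[a], taxa[b]))


# ---------------------------------------------------------------------------
# Cutoff clustering


def _complete_linkage(m: RMSDMatrix, cutoff: float) -> list[tuple[str, ...]]:
    """Agglomerative complete linkage, merging while the smallest
    complete-linkage distance is within the cutoff.

    Ties on distance are broken by the lexicographically smallest cluster
    pair, making the partition deterministic.
    """
    clusters: list[tuple[str, ...]] = [(sid,) for sid in sorted(m.ids)]
    idx = {sid: i for i, sid in enumerate(m.ids)}

    def link(c1: tuple[str, ...], c2: tuple[str, ...]) -> float:
        return max(m.values[idx[a], idx[b]] for a in c1 for b in c2)

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = link(clusters[i], clusters[j])
                key = (d, clusters[i], clusters[j])
                if best is None or key < best:
                    best = key
        assert best is not None
        if best[0] > cutoff:
            break
        merged = tuple(sorted(best[1] + best[2]))
        clusters = [c for c in clusters if c not in (best[1], best[2])]
        clusters.append(merged)
        clusters.sort()
    return sorted(clusters)


def cut_clusters(m: RMSDMatrix, cutoff: float) -> list[StructureCluster]:
    """Partition at a cutoff: within every cluster all pairs are <= cutoff (A)."""
    if cutoff <= 0:
        raise InputError("cutoff must be positive")
    partition = _complete_linkage(m, cutoff)
    return [
        StructureCluster(members, cutoff, select_medoid(members, m))
        for members in partition
    ]


def cutoff_sweep(
    m: RMSDMatrix, cutoffs: Sequence[float] = DEFAULT_SWEEP
) -> dict[float, list[StructureCluster]]:
    """Partitions over a decreasing cutoff schedule (default 11.5 -> 0.5 A)."""
    return {float(c): cut_clusters(m, float(c)) for c in cutoffs}


def select_medoid(member_ids: Sequence[str], m: RMSDMatrix) -> str:
    """Member minimising the summed distance to all others; ties lexicographic."""
    if not member_ids:
        raise InputError("empty member set")
    idx = {sid: i for i, sid in enumerate(m.ids)}
    for sid in member_ids:
        if sid not in idx:
            raise LookupIdError(f"member {sid!r} absent from matrix")
    return min(
        member_ids,
        key=lambda sid: (
            sum(m.values[idx[sid], idx[o]] for o in member_ids if o != sid),
            sid,
        ),
    )


# ---------------------------------------------------------------------------
# Annotation enrichment


def annotation_enrichment(
    partition: Sequence[StructureCluster] | Sequence[Sequence[str]],
    annotations: Mapping[str, Iterable[str]],
    keywords: Sequence[str],
) -> pd.DataFrame:
    """Keyword-annotation enrichment per cluster.

    An id is "annotated" when it carries any of the listed keywords.  Reported
    per cluster: size, annotated member count, fraction of the cluster
    annotated, and the fraction of ALL annotated ids (across every cluster)
    captured by the cluster.
    """
    if not keywords:
        raise InputError("keyword list must be non-empty")
    kw = set(keywords)

    def members_of(cluster) -> tuple[str, ...]:
        return tuple(cluster.member_ids) if isinstance(cluster, StructureCluster) else tuple(cluster)

    def is_annotated(sid: str) -> bool:
        return bool(kw & set(annotations.get(sid, ())))

    universe = [sid for cluster in partition for sid in members_of(cluster)]
    total_annotated = sum(is_annotated(sid) for sid in universe)
    rows = []
    for ci, cluster in enumerate(partition):
        members = members_of(cluster)
        annotated = sum(is_annotated(sid) for sid in members)
        rows.append(
            {
                "cluster_id": ci,
                "size": len(members),
                "medoid": cluster.medoid_id
                if isinstance(cluster, StructureCluster)
                else "",
                "annotated_count": annotated,
                "annotated_fraction": annotated / len(members) if members else 0.0,
                "captured_fraction": annotated / total_annotated
                if total_annotated
                else 0.0,
                "members": ",".join(members),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "size",
            "medoid",
            "annotated_count",
            "annotated_fraction",
            "captured_fraction",
            "members",
        ],
    )


# ---------------------------------------------------------------------------
# I/O


def read_ca_coordinates(path: Path | str, structure_id: Optional[str] = None) -> CoordinateSet:
    """CA coordinates from PDB-format ATOM records.

    First model only; first alternate location per residue; residues numbered
    by their PDB residue sequence numbers.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    sid = structure_id or path.stem
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure(sid, str(path))
    model = next(structure.get_models())
    coords, numbers = [], []
    for chain in model:
        for residue in chain:
            if "CA" in residue:
                atom = residue["CA"]
                if atom.is_disordered():
                    atom = atom.disordered_get_list()[0]
                coords.append(atom.coord)
                numbers.append(residue.id[1])
    if not coords:
        raise FormatError(f"{path}: no CA atoms found")
    return CoordinateSet(sid, np.asarray(coords, dtype=float), tuple(numbers))


def write_ca_pdb(cs: CoordinateSet, path: Path | str) -> None:
    """Write CA-only PDB ATOM records (one chain, GLY placeholders)."""
    with open(path, "w") as fh:
        for i, (num, xyz) in enumerate(zip(cs.residue_numbers, cs.ca_coordinates), 1):
            x, y, z = xyz
            fh.write(
                f"ATOM  {i:5d}  CA  GLY A{num:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")


def write_rmsd_matrix(m: RMSDMatrix, path: Path | str) -> None:
    pd.DataFrame(m.values, index=list(m.ids), columns=list(m.ids)).to_csv(
        path, sep="\t"
    )


def read_rmsd_matrix(path: Path | str) -> RMSDMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RMSDMatrix(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float))


def cluster_report(
    sweep: Mapping[float, Sequence[StructureCluster]],
    annotations: Optional[Mapping[str, Iterable[str]]] = None,
    keywords: Sequence[str] = ("defense", "resistance"),
) -> pd.DataFrame:
    """Flat report over a cutoff sweep, one row per cluster."""
    frames = []
    for cutoff in sorted(sweep, reverse=True):
        clusters = sweep[cutoff]
        if annotations is not None:
            df = annotation_enrichment(clusters, annotations, keywords)
        else:
            df = annotation_enrichment(clusters, {}, list(keywords))
        df.insert(1, "cutoff", cutoff)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
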