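"""The two integrative workflows, wired from the analysis modules.

Method 1 (sequence -> structure -> function): family filtering, per-clade
consensus building, then FAST specificity/conservation reports and the
coloured alignment.

Method 2 (function -> structure -> sequence): pairwise RMSD matrix, distance
tree, cutoff-sweep clustering with annotation enrichment, medoid selection,
and rvET traces of selected clusters compared against a reference cluster.

Every run can write a manifest (tool version, configuration, input digests)
so identical inputs and configuration reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import pandas as pd

from . import __version__
from . import fast as fast_mod
from . import msa, seqdef, structclass, trace as trace_mod
from .exceptions import InputError


def _digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    outdir: Path | str,
    config: Mapping,
    inputs: Iterable[Path | str] = (),
) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "nsltpkit",
        "version": __version__,
        "config": {k: str(v) for k, v in dict(config).items()},
        "inputs": {str(p): _digest(Path(p)) for p in inputs if Path(p).exists()},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


@dataclass
class Method1Result:
    filter_report: pd.DataFrame
    consensus: dict[str, msa.ConsensusSequence]
    score_table: pd.DataFrame
    conserved_core: pd.DataFrame
    sdp_table: pd.DataFrame
    colors: list


def run_method1(
    sequences: Sequence[seqdef.MatureSequence],
    alignment: msa.Alignment,
    tree: dendropy.Tree,
    conservation_threshold: float = 0.8,
    specificity_threshold: float = 2.0,
    saturation_cap: Optional[float] = None,
    outdir: Optional[Path | str] = None,
) -> Method1Result:
    """Filter -> per-clade consensus -> FAST. Deterministic given its inputs."""
    report = seqdef.filter_report(sequences)
    clades = fast_mod.enumerate_tree_clusters(tree, alignment.ids)
    consensus = {"all": msa.build_consensus(alignment)}
    for i, clade in enumerate(clades):
        sub = msa.subset_alignment(alignment, sorted(clade))
        consensus[f"clade_{i}"] = msa.build_consensus(sub)
    cells = fast_mod.specificity_table(alignment, clades)
    cons = fast_mod.conservation_profile(alignment)
    core, sdp = fast_mod.report_positions(
        cells, cons, conservation_threshold, specificity_threshold
    )
    leaf_order = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    colors = fast_mod.colorize(alignment, leaf_order, cells, cons, saturation_cap)
    scores = fast_mod.score_table(alignment, cells, cons)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
        for name, consensus_seq in consensus.items():
            msa.write_consensus(consensus_seq, name, outdir / f"consensus_{name}.fasta")
        scores.to_csv(outdir / "fast_scores.tsv", sep="\t", index=False)
        core.to_csv(outdir / "conserved_core.tsv", sep="\t", index=False)
        sdp.to_csv(outdir / "sdp_table.tsv", sep="\t", index=False)
        fast_mod.render_svg(alignment, colors, outdir / "colored_alignment.svg")
    return Method1Result(report, consensus, scores, core, sdp, colors)


@dataclass
class Method2Result:
    rmsd_matrix: structclass.RMSDMatrix
    tree_newick: str
    sweep: dict[float, list[structclass.StructureCluster]]
    enrichment: pd.DataFrame
    traces: dict[str, trace_mod.TraceResult]
    comparison: Optional[pd.DataFrame]


def run_method2(
    structures: Sequence[structclass.CoordinateSet],
    correspondences: Mapping[tuple[str, str], structclass.Correspondence],
    master_alignment: msa.Alignment,
    annotations: Mapping[str, Iterable[str]],
    keywords: Sequence[str] = ("defense", "resistance"),
    cutoffs: Sequence[float] = structclass.DEFAULT_SWEEP,
    trace_cutoff: Optional[float] = None,
    top_fraction: float = 0.30,
    outdir: Optional[Path | str] = None,
) -> Method2Result:
    """RMSD matrix -> tree -> cutoff sweep -> enrichment -> medoid traces.

    Traces are computed for every multi-member cluster of the partition at
    ``trace_cutoff`` (default: the smallest swept cutoff keeping at least one
    multi-member cluster); each cluster's medoid is its reference sequence,
    and the most-enriched cluster's trace is compared against the others.
    """
    m = structclass.pairwise_rmsd_matrix(structures, correspondences)
    tree = structclass.build_distance_tree(m)
    newick = tree.as_string(schema="newick").strip()
    sweep = structclass.cutoff_sweep(m, cutoffs)
    enrichment = structclass.cluster_report(sweep, annotations, keywords)

    if trace_cutoff is None:
        candidates = [
            c
            for c in sorted(sweep)
            if any(len(cl.member_ids) > 1 for cl in sweep[c])
        ]
        if not candidates:
            raise InputError("no cutoff in the sweep keeps a multi-member cluster")
        trace_cutoff = candidates[0]
    partition = sweep[float(trace_cutoff)]

    traces: dict[str, trace_mod.TraceResult] = {}
    scored = []
    for ci, cluster in enumerate(partition):
        if len(cluster.member_ids) < 2:
            continue
        sub = msa.subset_alignment(master_alignment, list(cluster.member_ids))
        name = f"cluster_{ci}"
        traces[name] = trace_mod.compute_trace(
            sub, cluster.medoid_id, name=name
        )
        annotated = sum(
            1
            for sid in cluster.member_ids
            if set(keywords) & set(annotations.get(sid, ()))
        )
        scored.append((annotated / len(cluster.member_ids), name))
    comparison = None
    if len(traces) >= 1 and scored:
        scored.sort(reverse=True)
        ref_name = scored[0][1]
        others = [traces[n] for _, n in scored[1:]]
        comparison = trace_mod.compare_traces(traces[ref_name], others, top_fraction)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        structclass.write_rmsd_matrix(m, outdir / "rmsd_matrix.tsv")
        (outdir / "structure_tree.nwk").write_text(newick + "\n")
        enrichment.to_csv(outdir / "cluster_report.tsv", sep="\t", index=False)
        for name, tr in traces.items():
            trace_mod.write_trace_tsv(tr, outdir / f"trace_{name}.tsv")
            trace_mod.write_residue_scores(tr, outdir / f"scores_{name}.tsv")
        if comparison is not None:
            comparison.to_csv(outdir / "trace_comparison.tsv", sep="\t", index=False)
    return Method2Result(m, newick, sweep, enrichment, traces, comparison)
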