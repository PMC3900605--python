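"""End-to-end orchestration: similarity -> network/clusters -> distance ->
NJ tree -> patristic separation -> optional marker congruence.

Every stage writes its outputs as soon as it finishes, so a failing stage
leaves partial results behind; the provenance log records parameters, seeds
and input digests sufficient to re-run any stage identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path


from . import __version__
from . import io as pkio
from .congruence import icong, mast_null_distribution
from .network import build_attraction_graph, extract_clusters, layout_fr
from .records import GenomeRecord
from .simulate import CommunityConfig, simulate_marker_families, simulate_phage_community
from .similarity import fragmented_similarity, to_distance
from .trees import (
    alignment_distance_matrix,
    group_separation,
    is_monophyletic,
    nj_tree,
    patristic_matrix,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parameters of the end-to-end analysis.

    Defaults mirror the published analysis settings where stated: fragment
    size 50 / step 25 for the translated genome comparison, BLASTn-style word
    size 7 with an e-value ceiling of 1e-5 for the similarity network, and
    10000 force-directed layout rounds.
    """

    input_fasta: str | None = None
    community: CommunityConfig | None = None
    outdir: str = "phagekit_out"
    fragment_size: int = 50
    step: int = 25
    word_size: int = 7
    graph_e_ceiling: float = 1e-5
    fragment_e_ceiling: float = 1e-3
    p_cutoff: float = 1e-5
    layout_dims: int = 2
    layout_iterations: int = 10000
    n_markers: int = 0
    marker_sites: int = 1000
    marker_rate: float = 0.3
    congruence_null_reps: int = 200
    seed: int = 0


@dataclass
class PipelineReport:
    outdir: Path
    genomes: list[GenomeRecord]
    similarity: object = None
    distance: object = None
    graph: object = None
    clusters: object = None
    tree: object = None
    patristic: object = None
    separation: object = None
    congruence: list = field(default_factory=list)
    truth_labels: dict | None = None
    summary: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run the full comparative analysis described by ``config``.

    Input genomes come either from ``input_fasta`` or from a synthetic
    community simulated with ``config.community``. With fewer than 3 genomes,
    network clustering is skipped with a notice while pairwise similarity is
    still emitted.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    provenance: dict = {
        "phagekit_version": __version__,
        "seed": config.seed,
        "config": {
            k: v for k, v in asdict(config).items() if k != "outdir"
        },
    }
    report = PipelineReport(outdir=out, genomes=[])
    stage = "input"
    try:
        if config.community is not None:
            truth = simulate_phage_community(config.community)
            report.genomes = truth.genomes
            report.truth_labels = dict(truth.group_labels)
            pkio.write_fasta(truth.genomes, out / "genomes.fasta")
            _dump_json(truth.group_labels, out / "truth_labels.json")
            generating_tree = truth.generating_tree
        elif config.input_fasta:
            report.genomes = pkio.read_fasta(config.input_fasta)
            provenance["input_sha256"] = _sha256(Path(config.input_fasta))
            generating_tree = None
        else:
            raise ValueError("config needs input_fasta or a community")
        if len(report.genomes) < 2:
            raise ValueError("need at least two genomes")

        stage = "similarity"
        sim = fragmented_similarity(
            report.genomes,
            fragment_size=config.fragment_size,
            step=config.step,
            e_ceiling=config.fragment_e_ceiling,
        )
        report.similarity = sim
        pkio.write_matrix_tsv(sim.labels, sim.values, out / "similarity.tsv")
        dist = to_distance(sim)
        report.distance = dist
        pkio.write_matrix_tsv(dist.labels, dist.values, out / "distance.tsv")
        pkio.write_phylip_distances(dist.labels, dist.values, out / "distance.phylip")

        stage = "network"
        if len(report.genomes) >= 3:
            graph = build_attraction_graph(
                report.genomes,
                e_ceiling=config.graph_e_ceiling,
                word_size=config.word_size,
            )
            report.graph = graph
            with open(out / "graph_edges.tsv", "w") as fh:
                fh.write("node_a\tnode_b\tp_value\tattraction\n")
                for a, b, d in sorted(graph.graph.edges(data=True)):
                    fh.write(f"{a}\t{b}\t{d['p_value']:.6e}\t{d['attraction']:.6f}\n")
            embedding = layout_fr(
                graph,
                dims=config.layout_dims,
                iterations=config.layout_iterations,
                seed=config.seed,
            )
            with open(out / "layout.tsv", "w") as fh:
                axes = "xyz"[: config.layout_dims]
                fh.write("node\t" + "\t".join(axes) + "\n")
                for node in sorted(embedding.coordinates):
                    coords = "\t".join(f"{c:.6f}" for c in embedding.coordinates[node])
                    fh.write(f"{node}\t{coords}\n")
            clusters = extract_clusters(graph, p_cutoff=config.p_cutoff)
            report.clusters = clusters
            with open(out / "clusters.tsv", "w") as fh:
                fh.write("node\tcluster\tsingleton\n")
                for node in sorted(clusters.labels):
                    fh.write(
                        f"{node}\t{clusters.labels[node]}\t"
                        f"{int(node in clusters.singletons)}\n"
                    )
        else:
            logger.warning("fewer than 3 genomes: network clustering skipped")

        stage = "tree"
        newick = None
        pm = None
        if len(report.genomes) >= 3:
            tree = nj_tree(dist)
            report.tree = tree
            newick = tree.as_string(schema="newick").strip()
            (out / "phylogenomic_tree.nwk").write_text(newick + "\n")
            pm = patristic_matrix(tree)
            report.patristic = pm
            pkio.write_matrix_tsv(pm.labels, pm.values, out / "patristic.tsv")
        else:
            logger.warning("fewer than 3 genomes: tree building skipped")

        stage = "separation"
        groups = None
        if report.truth_labels is not None:
            groups = report.truth_labels
        elif report.clusters is not None:
            groups = report.clusters.labels
        if groups is not None and pm is not None:
            sep = group_separation(pm, groups)
            report.separation = sep
            _dump_json(
                {
                    "within_max": sep.within_max,
                    "between_mean": {f"{g}|{h}": v for (g, h), v in sep.between_mean.items()},
                    "separated": {f"{g}|{h}": v for (g, h), v in sep.separated.items()},
                },
                out / "separation.json",
            )

        stage = "congruence"
        if config.n_markers >= 2 and generating_tree is not None:
            markers = simulate_marker_families(
                generating_tree,
                n_markers=config.n_markers,
                site_counts=config.marker_sites,
                rate_scale=config.marker_rate,
                seed=config.seed + 1,
            )
            marker_trees = []
            for m, family in enumerate(markers):
                pkio.write_protein_fasta(family, out / f"marker{m + 1}.faa")
                mtree = nj_tree(alignment_distance_matrix(family))
                (out / f"marker{m + 1}.nwk").write_text(
                    mtree.as_string(schema="newick").strip() + "\n"
                )
                marker_trees.append(mtree)
            n_shared = len(marker_trees[0].taxon_namespace)
            null = mast_null_distribution(
                n_shared, config.congruence_null_reps, seed=config.seed + 2
            )
            table = []
            for i in range(len(marker_trees)):
                for j in range(i + 1, len(marker_trees)):
                    res = icong(marker_trees[i], marker_trees[j], null_sizes=null,
                                seed=config.seed + 2)
                    table.append(
                        {
                            "marker_a": i + 1,
                            "marker_b": j + 1,
                            "mast_size": res.mast_size,
                            "icong": res.icong,
                            "p_value": res.p_value,
                            "n_common_leaves": res.n_common_leaves,
                        }
                    )
            report.congruence = table
            _dump_json(table, out / "congruence.json")

        stage = "summary"
        summary: dict = {"n_genomes": len(report.genomes)}
        if newick is not None:
            summary["tree_newick"] = newick
        if report.clusters is not None:
            summary["clusters"] = report.clusters.labels
            summary["singletons"] = sorted(report.clusters.singletons)
        if report.truth_labels is not None:
            summary["truth_labels"] = report.truth_labels
            if report.tree is not None:
                group_names = sorted(
                    {g for g in report.truth_labels.values() if g != "outgroup"}
                )
                summary["group_monophyly"] = {
                    g: is_monophyletic(
                        report.tree,
                        {k for k, v in report.truth_labels.items() if v == g},
                    )
                    for g in group_names
                }
        if report.separation is not None:
            summary["separated"] = {
                f"{g}|{h}": v for (g, h), v in report.separation.separated.items()
            }
        report.summary = summary
        _dump_json(summary, out / "summary.json")
        _dump_json(provenance, out / "provenance.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return report
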