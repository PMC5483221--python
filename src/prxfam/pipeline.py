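"""End-to-end workflow orchestration.

Each stage reads and writes only declared files under a run directory,
so any stage can be re-run in isolation and reproduces its outputs
bit-identically for the same config and inputs. A JSON run manifest
records the config snapshot, package version, and a SHA-256 checksum
per output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cre import (
    PromoterGroup,
    compare_groups,
    comparison_json,
    comparison_report,
    group_common,
    rank_frequency,
)
from .expression import (
    aggregate_tissue_means,
    calls_to_frame,
    classify_pattern,
    read_expression_tsv,
    top_k_coexpressed,
    write_expression_tsv,
)
from .motifs import (
    MotifLibrary,
    PromoterRecord,
    PromoterSet,
    build_incidence,
    hits_to_frame,
    hits_to_gff3,
    scan_promoters,
)
from .network import (
    InteractionTable,
    build_network,
    export_graphml,
    export_node_edge_tsv,
    export_sif,
    hub_summary,
    overlay_coexpression,
)
from .phylo import (
    AlignedProteinSet,
    assign_subgroups,
    bootstrap_support,
    p_distance_matrix,
    write_newick,
)
from .simulate import (
    SynthConfig,
    gen_expression_compendium,
    gen_interaction_expression,
    gen_interaction_table,
    gen_motif_library,
    gen_promoter_set,
    gen_protein_family,
    group_gene_ids,
    write_promoters_fasta,
    write_protein_fasta,
)

log = logging.getLogger("prxfam")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


class Manifest:
    """Accumulates per-stage output checksums for the run manifest."""

    def __init__(self, config: dict):
        self.payload: dict = {
            "tool": "prxfam",
            "version": __version__,
            "config": config,
            "stages": {},
        }

    def record(self, stage: str, outputs: list[Path]) -> None:
        self.payload["stages"][stage] = {
            str(Path(p).name): _sha256(p) for p in outputs
        }
        log.info("stage %s: %d outputs", stage, len(outputs))

    def write(self, path: Path) -> None:
        Path(path).write_text(json.dumps(self.payload, indent=2, sort_keys=True))


def read_promoters_fasta(path) -> PromoterSet:
    from Bio import SeqIO

    return PromoterSet(
        PromoterRecord(gene_id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    )


def stage_generate(config: SynthConfig, outdir: Path) -> dict:
    """Generate every synthetic input plus the merged truth bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    library = gen_motif_library(config.n_decoy_motifs, seed=config.seed)
    matrix, truth_e = gen_expression_compendium(config)
    promoters, truth_p = gen_promoter_set(config, library)
    aligned, true_newick, truth_t = gen_protein_family(config)
    table, truth_i = gen_interaction_table(config)
    net_expr = gen_interaction_expression(config, truth_i)

    truth = truth_e.merge(truth_p).merge(truth_t).merge(truth_i)

    write_expression_tsv(matrix, outdir / "expression.tsv", outdir / "tissue_map.tsv")
    library.to_frame().to_csv(outdir / "motif_library.tsv", sep="\t", index=False)
    write_promoters_fasta(promoters, outdir / "promoters.fasta", outdir / "promoters.bed")
    write_protein_fasta(aligned, outdir / "proteins.fasta")
    (outdir / "true_tree.nwk").write_text(true_newick + "\n")
    table.to_tsv(outdir / "interactions.tsv")
    write_expression_tsv(
        net_expr, outdir / "network_expression.tsv", outdir / "network_tissue_map.tsv"
    )
    (outdir / "truth.json").write_text(truth.to_json())
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(config))
    )
    ids_a, ids_b = group_gene_ids(config)
    pd.DataFrame(
        {"gene_id": ids_a + ids_b, "group": ["A"] * len(ids_a) + ["B"] * len(ids_b)}
    ).to_csv(outdir / "groups.tsv", sep="\t", index=False)
    return {"truth": truth, "outputs": sorted(outdir.iterdir())}


def stage_expression(expression, tissue_map, outdir, delta=2.0, floor=6.0):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m = read_expression_tsv(expression, tissue_map)
    profiles = aggregate_tissue_means(m)
    profiles.to_csv(outdir / "tissue_profiles.tsv", sep="\t", index_label="gene_id")
    calls = classify_pattern(profiles, delta=delta, floor=floor)
    calls_to_frame(calls).to_csv(outdir / "class_calls.tsv", sep="\t", index=False)
    return [outdir / "tissue_profiles.tsv", outdir / "class_calls.tsv"]


def stage_coexpr(expression, tissue_map, bait, k, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m = read_expression_tsv(expression, tissue_map)
    group = top_k_coexpressed(m, bait, k)
    out = outdir / f"coexpr_{bait}.tsv"
    pd.DataFrame(group.members, columns=["gene_id", "pcc"]).to_csv(
        out, sep="\t", index=False
    )
    return [out]


def stage_phylo(alignment, outdir, replicates=500, seed=0, exemplars=None):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aligned = AlignedProteinSet.from_fasta(alignment)
    d = p_distance_matrix(aligned)
    d.to_csv(outdir / "distances.tsv", sep="\t", index_label="taxon")
    tree = bootstrap_support(aligned, replicates=replicates, seed=seed)
    write_newick(tree, outdir / "tree.nwk")
    outputs = [outdir / "distances.tsv", outdir / "tree.nwk"]
    if exemplars:
        assignment = assign_subgroups(tree, exemplars)
        pd.DataFrame(
            sorted(assignment.labels.items()), columns=["taxon", "subgroup"]
        ).to_csv(outdir / "subgroups.tsv", sep="\t", index=False)
        outputs.append(outdir / "subgroups.tsv")
    return outputs


def stage_scan(promoters_fasta, library_tsv, outdir, strands="both"):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    promoters = read_promoters_fasta(promoters_fasta)
    library = MotifLibrary.from_frame(pd.read_csv(library_tsv, sep="\t"))
    hits = scan_promoters(promoters, library, strands=strands)
    hits_to_frame(hits).to_csv(outdir / "hits.tsv", sep="\t", index=False)
    (outdir / "hits.gff3").write_text(hits_to_gff3(hits, promoters))
    inc = build_incidence(promoters, library, strands=strands)
    inc.to_csv(outdir / "incidence.tsv", sep="\t", index_label="motif")
    return [outdir / "hits.tsv", outdir / "hits.gff3", outdir / "incidence.tsv"]


def stage_compare(incidence_tsv, groups_tsv, outdir, mode="all_members"):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inc = pd.read_csv(incidence_tsv, sep="\t", index_col=0)
    gdf = pd.read_csv(groups_tsv, sep="\t")
    labels = list(dict.fromkeys(gdf["group"]))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    groups = [
        PromoterGroup(
            label=str(lbl),
            members=[str(g) for g in gdf.loc[gdf["group"] == lbl, "gene_id"]],
        )
        for lbl in labels
    ]
    common = [group_common(inc, g, mode=mode) for g in groups]
    cmp = compare_groups(common[0], common[1], groups[0].label, groups[1].label)
    comparison_report(cmp, inc, groups[0], groups[1]).to_csv(
        outdir / "cre_comparison.tsv", sep="\t", index=False
    )
    (outdir / "cre_comparison.json").write_text(comparison_json(cmp))
    ranked = rank_frequency(inc, cmp.unique_a, groups[0])
    pd.DataFrame(ranked, columns=["motif", "count"]).to_csv(
        outdir / "unique_a_ranked.tsv", sep="\t", index=False
    )
    return [
        outdir / "cre_comparison.tsv",
        outdir / "cre_comparison.json",
        outdir / "unique_a_ranked.tsv",
    ]


def stage_network(
    edges_tsv, hubs, outdir, expression=None, tissue_map=None, threshold=0.5
):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = InteractionTable.from_tsv(edges_tsv)
    g = build_network(table, hubs)
    if expression and tissue_map:
        m = read_expression_tsv(expression, tissue_map)
        g = overlay_coexpression(g, m, threshold=threshold)
    export_sif(g, outdir / "network.sif")
    export_graphml(g, outdir / "network.graphml")
    export_node_edge_tsv(g, outdir / "nodes.tsv", outdir / "edges.tsv")
    summary = hub_summary(g)
    (outdir / "hub_summary.json").write_text(
        json.dumps(
            {
                "degrees": summary.degrees,
                "union": summary.union,
                "interaction_rows": summary.interaction_rows,
            },
            indent=2,
        )
    )
    return [
        outdir / "network.sif",
        outdir / "network.graphml",
        outdir / "nodes.tsv",
        outdir / "edges.tsv",
        outdir / "hub_summary.json",
    ]


def run_workflow(
    config: SynthConfig,
    outdir: Path,
    bootstrap_replicates: int = 500,
    delta: float = 2.0,
    floor: float = 6.0,
    pcc_threshold: float = 0.5,
) -> Manifest:
    """All-synthetic end-to-end run mirroring the study's stage order:
    phylogeny + meta-expression, co-expression grouping, promoter
    scanning, group CRE comparison, then network overlay."""
    outdir = Path(outdir)
    gen_dir = outdir / "inputs"
    manifest = Manifest(dataclasses.asdict(config))

    gen = stage_generate(config, gen_dir)
    manifest.record("generate", gen["outputs"])

    expr_out = stage_expression(
        gen_dir / "expression.tsv", gen_dir / "tissue_map.tsv",
        outdir / "expression", delta=delta, floor=floor,
    )
    manifest.record("expression", expr_out)

    ids_a, ids_b = group_gene_ids(config)
    coexpr_out = []
    for bait, k in ((ids_a[0], len(ids_a) - 1), (ids_b[0], len(ids_b) - 1)):
        coexpr_out += stage_coexpr(
            gen_dir / "expression.tsv", gen_dir / "tissue_map.tsv",
            bait, k, outdir / "coexpr",
        )
    manifest.record("coexpr", coexpr_out)

    exemplars = {
        f"SG{c + 1}_t1": f"SG{c + 1}" for c in range(config.n_clades)
    }
    phylo_out = stage_phylo(
        gen_dir / "proteins.fasta", outdir / "phylo",
        replicates=bootstrap_replicates, seed=config.seed, exemplars=exemplars,
    )
    manifest.record("phylo", phylo_out)

    scan_out = stage_scan(
        gen_dir / "promoters.fasta", gen_dir / "motif_library.tsv",
        outdir / "scan",
    )
    manifest.record("scan", scan_out)

    compare_out = stage_compare(
        outdir / "scan" / "incidence.tsv", gen_dir / "groups.tsv",
        outdir / "compare",
    )
    manifest.record("compare", compare_out)

    hubs = list(gen["truth"].hub_partners)
    network_out = stage_network(
        gen_dir / "interactions.tsv", hubs, outdir / "network",
        expression=gen_dir / "network_expression.tsv",
        tissue_map=gen_dir / "network_tissue_map.tsv",
        threshold=pcc_threshold,
    )
    manifest.record("network", network_out)

    manifest.write(outdir / "manifest.json")
    return manifest
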