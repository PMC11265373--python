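"""End-to-end orchestration from a config to a reproducible report bundle.

Stage order mirrors the analysis: genomes -> POCP / telomere / RIP screens
-> BGCs -> gene-cluster families -> presence/absence -> ecology statistics
and rarefaction -> pathway grouping -> ancestral-state reconstruction and
event calling -> tanglegram.  Every stage communicates with the next only
through the files it writes; a JSON manifest records input hashes, the seed,
parameters, and the stages run, so deterministic stages are bit-reproducible
from the manifest alone.

The single pipeline seed fans out to per-stage sub-seeds through
``numpy.random.SeedSequence(seed, spawn_key=(stage_index,))``, so toggling
stages never shifts the randomness of the stages that still run.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import ecology, gcf, genome_stats, pathways, pocp
from .cophylo import entanglement, profile_dendrogram
from .io import (
    read_bgc_table,
    read_fasta,
    read_gff3,
    read_metadata,
    read_newick,
    read_orthology,
    write_bgc_table,
    write_fasta,
    write_gff3,
    write_newick,
    write_orthology,
    write_presence_absence,
)
from .simulate import (
    SimConfig,
    emit_bgcs_from_traits,
    evolve_binary_traits,
    simulate_tree,
    synth_assembly,
    synth_orthology,
)
from .tree import Phylogeny

ALL_STAGES = (
    "genomes",
    "telomeres",
    "rip",
    "windows",
    "pocp",
    "gcf",
    "ecology",
    "pathways",
    "asr",
    "tanglegram",
)


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    steps: tuple[str, ...] = ALL_STAGES
    # input paths; any left None is taken from the synthetic bundle
    fasta: dict[str, Path] = field(default_factory=dict)
    gff3: dict[str, Path] = field(default_factory=dict)
    bgc_table: Path | None = None
    orthology_totals: Path | None = None
    orthology_pairs: Path | None = None
    tree_file: Path | None = None
    metadata: Path | None = None
    simulate_missing: bool = True
    sim: SimConfig | None = None
    gcf_cutoff: float = 0.5
    n_permutations: int = 999
    figures: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.steps) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for path in list(self.fasta.values()) + list(self.gff3.values()) + [
            self.bgc_table, self.orthology_totals, self.orthology_pairs,
            self.tree_file, self.metadata,
        ]:
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    import numpy as np

    k = ALL_STAGES.index(stage)
    return int(np.random.SeedSequence(seed, spawn_key=(k,)).generate_state(1)[0] % (2**31))


def demo_dataset(out_dir: str | Path, seed: int = 20260101) -> dict:
    """Write the packaged demo bundle: 12 strains, 40 pathways, fixed seed.

    Returns a dict of paths plus the in-memory ground truth.  The bundle
    mirrors the scale ratios of a real symbiont survey at desk scale.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = SimConfig(seed=seed, n_strains=12, n_pathways=40)
    tree = simulate_tree(config)
    matrix, truth = evolve_binary_traits(tree, config)
    bgcs = emit_bgcs_from_traits(matrix, config)
    orthology, _ = synth_orthology(config, tree=tree)
    assembly, annotation, asm_truth = synth_assembly(config, rip_fraction=0.2)

    write_newick(tree, out / "species_tree.nwk")
    write_bgc_table(bgcs, out / "bgcs.tsv")
    write_orthology(orthology, out / "orthology_totals.tsv", out / "orthology_pairs.tsv")
    write_fasta(assembly, out / "synthetic_assembly.fasta")
    write_gff3(annotation, out / "synthetic_assembly.gff3")
    # simple two-level metadata derived from the top split of the tree
    left = tree.tip_set(tree.root.children[0])
    meta = pd.DataFrame(
        {
            "strain_id": tree.tip_labels,
            "genus": ["GenusA" if s in left else "GenusB" for s in tree.tip_labels],
            "agriculture": [
                "lower" if s in left else "higher" for s in tree.tip_labels
            ],
        }
    )
    meta.to_csv(out / "metadata.tsv", sep="\t", index=False)
    truth_json = {
        "gain_nodes": truth.gain_nodes,
        "loss_nodes": truth.loss_nodes,
        "telomere_copies": asm_truth.telomere_copies,
        "rip_spans": asm_truth.rip_spans,
    }
    (out / "sim_truth.json").write_text(json.dumps(truth_json, indent=1))
    write_presence_absence(matrix, out / "true_presence_absence.tsv")
    return {
        "dir": out,
        "tree": tree,
        "matrix": matrix,
        "truth": truth,
        "assembly": assembly,
        "annotation": annotation,
        "assembly_truth": asm_truth,
        "orthology": orthology,
        "bgcs": bgcs,
        "metadata": meta,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stages": [],
        "inputs": {},
        "parameters": {
            "gcf_cutoff": config.gcf_cutoff,
            "n_permutations": config.n_permutations,
        },
        "outputs": {},
    }

    def record(stage: str, **outputs: Path) -> None:
        manifest["stages"].append(stage)
        for name, path in outputs.items():
            manifest["outputs"][f"{stage}.{name}"] = {
                "path": str(path),
                "sha256": _sha256(path),
            }

    def persist_manifest() -> None:
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    # ----- inputs (synthesised when absent) --------------------------------
    sim = config.sim or SimConfig(seed=_stage_seed(config.seed, "genomes"))
    stage = "setup"
    try:
        if config.tree_file:
            tree: Phylogeny = read_newick(config.tree_file)
            manifest["inputs"]["tree"] = _sha256(config.tree_file)
        else:
            tree = simulate_tree(sim)
        matrix_true = None
        if config.bgc_table:
            bgcs = read_bgc_table(config.bgc_table)
            manifest["inputs"]["bgc_table"] = _sha256(config.bgc_table)
        else:
            matrix_true, _truth = evolve_binary_traits(tree, sim)
            bgcs = emit_bgcs_from_traits(matrix_true, sim)
        if config.orthology_totals and config.orthology_pairs:
            orthology = read_orthology(config.orthology_totals, config.orthology_pairs)
        else:
            orthology, _ = synth_orthology(sim, tree=tree)
        if config.fasta:
            assemblies = {g: read_fasta(p, genome_id=g) for g, p in config.fasta.items()}
            annotations = {g: read_gff3(p, genome_id=g) for g, p in config.gff3.items()}
        else:
            asm, ann, _ = synth_assembly(sim, rip_fraction=0.2)
            assemblies, annotations = {asm.genome_id: asm}, {ann.genome_id: ann}
        if config.metadata:
            metadata = read_metadata(config.metadata)
        else:
            left = tree.tip_set(tree.root.children[0])
            metadata = None
            groups = {s: ("A" if s in left else "B") for s in tree.tip_labels}
    except Exception as err:  # pragma: no cover - error path
        manifest["error"] = {"stage": stage, "message": str(err)}
        persist_manifest()
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err
    if config.metadata:
        groups = {s: metadata.genus(s) for s in tree.tip_labels}

    pa_matrix = None
    families = None
    pathway_list = None
    try:
        for stage in config.steps:
            if stage == "genomes":
                write_newick(tree, out / "species_tree.nwk")
                record(stage, tree=out / "species_tree.nwk")
            elif stage == "telomeres":
                frames = []
                for g, asm in assemblies.items():
                    rep = genome_stats.scan_telomeres(asm)
                    df = rep.per_contig.copy()
                    df.insert(0, "genome_id", g)
                    frames.append(df)
                path = out / "telomeres.tsv"
                pd.concat(frames).to_csv(path, sep="\t")
                record(stage, report=path)
            elif stage == "rip":
                rows = []
                for g, asm in assemblies.items():
                    rep = genome_stats.scan_rip(asm)
                    rows.append(
                        {
                            "genome_id": g,
                            "affected_fraction": rep.affected_fraction,
                            "affected_bp": rep.affected_bp,
                            "genome_length": rep.genome_length,
                        }
                    )
                path = out / "rip.tsv"
                pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
                record(stage, report=path)
            elif stage == "windows":
                frames = []
                for g, asm in assemblies.items():
                    df = genome_stats.window_stats(asm, annotations.get(g))
                    df.insert(0, "genome_id", g)
                    frames.append(df)
                path = out / "window_stats.tsv"
                pd.concat(frames).to_csv(path, sep="\t", index=False)
                record(stage, report=path)
            elif stage == "pocp":
                table = pocp.compute_pocp(orthology)
                calls = pocp.classify_pairs(table)
                mpath, cpath = out / "pocp_matrix.tsv", out / "pocp_calls.tsv"
                table.matrix.to_csv(mpath, sep="\t")
                calls.to_csv(cpath, sep="\t", index=False)
                record(stage, matrix=mpath, calls=cpath)
            elif stage == "gcf":
                cfg = gcf.GcfConfig(distance_cutoff=config.gcf_cutoff)
                families = gcf.cluster_gcfs(bgcs, cfg)
                pa_matrix = gcf.build_presence_absence(
                    families, bgcs, strains=tree.tip_labels
                )
                fpath = out / "families.tsv"
                pd.DataFrame(
                    [
                        {
                            "gcf_id": f.gcf_id,
                            "n_members": len(f.member_bgc_ids),
                            "modal_class": f.modal_class,
                            "representative": f.representative_bgc_id,
                            "members": ",".join(f.member_bgc_ids),
                        }
                        for f in families
                    ]
                ).to_csv(fpath, sep="\t", index=False)
                papath = out / "presence_absence.tsv"
                write_presence_absence(pa_matrix, papath)
                rpath = out / "rank_abundance.tsv"
                gcf.rank_abundance(pa_matrix).to_csv(rpath, sep="\t", index=False)
                group_lists: dict[str, list[str]] = {}
                for s, gv in groups.items():
                    group_lists.setdefault(gv, []).append(s)
                rarepath = out / "rarefaction.tsv"
                gcf.rarefaction(pa_matrix, group_lists).to_csv(rarepath, sep="\t", index=False)
                record(stage, families=fpath, presence_absence=papath,
                       rank_abundance=rpath, rarefaction=rarepath)
            elif stage == "ecology":
                if pa_matrix is None:
                    raise RuntimeError("ecology stage needs the gcf stage")
                dist = ecology.jaccard_distance(pa_matrix)
                sseed = _stage_seed(config.seed, stage)
                ord_res = ecology.nmds(dist, seed=sseed)
                an = ecology.anosim(dist, groups, config.n_permutations, seed=sseed)
                pm = ecology.permanova(dist, groups, config.n_permutations, seed=sseed)
                dpath = out / "jaccard.tsv"
                dist.to_csv(dpath, sep="\t")
                npath = out / "nmds.tsv"
                ord_res.coordinates.to_csv(npath, sep="\t")
                spath = out / "ecology_stats.tsv"
                pd.DataFrame(
                    [
                        {"test": "ANOSIM", "statistic": an.r, "p_value": an.p_value,
                         "n_permutations": an.n_permutations},
                        {"test": "PERMANOVA_F", "statistic": pm.pseudo_f, "p_value": pm.p_value,
                         "n_permutations": pm.n_permutations},
                        {"test": "PERMANOVA_R2", "statistic": pm.r_squared, "p_value": pm.p_value,
                         "n_permutations": pm.n_permutations},
                    ]
                ).to_csv(spath, sep="\t", index=False)
                record(stage, jaccard=dpath, nmds=npath, stats=spath)
            elif stage == "pathways":
                if families is None or pa_matrix is None:
                    raise RuntimeError("pathways stage needs the gcf stage")
                pathway_list = pathways.group_pathways(families, bgcs, pa_matrix)
                ppath = out / "pathways.tsv"
                pd.DataFrame(
                    [
                        {
                            "pathway_id": p.pathway_id,
                            "n_gcfs": len(p.member_gcf_ids),
                            "gcfs": ",".join(p.member_gcf_ids),
                            "n_strains": int(p.presence.sum()),
                        }
                        for p in pathway_list
                    ]
                ).to_csv(ppath, sep="\t", index=False)
                record(stage, pathways=ppath)
            elif stage == "asr":
                if pathway_list is None:
                    raise RuntimeError("asr stage needs the pathways stage")
                marg_rows, event_rows = [], []
                event_maps = []
                for p in pathway_list:
                    model = pathways.fit_mk1(tree, p.presence)
                    marg = pathways.reconstruct_marginals(tree, p.presence, model)
                    em = pathways.call_events(marg, tree, pathway_id=p.pathway_id)
                    event_maps.append(em)
                    for node_id, row in marg.probabilities.iterrows():
                        marg_rows.append(
                            {"pathway_id": p.pathway_id, "node_id": node_id,
                             "p_present": row["present"], "mu": model.mu}
                        )
                    event_rows.append(
                        {
                            "pathway_id": p.pathway_id,
                            "acquisitions": ",".join(em.acquisition_nodes),
                            "losses": ",".join(em.loss_nodes),
                            "hgt_flag": em.hgt_flag,
                        }
                    )
                mpath, epath = out / "asr_marginals.tsv", out / "asr_events.tsv"
                pd.DataFrame(marg_rows).to_csv(mpath, sep="\t", index=False)
                pd.DataFrame(event_rows).to_csv(epath, sep="\t", index=False)
                tpath = out / "asr_node_tallies.tsv"
                pathways.tally_events(event_maps, tree).to_csv(tpath, sep="\t")
                record(stage, marginals=mpath, events=epath, tallies=tpath)
            elif stage == "tanglegram":
                if pa_matrix is None:
                    raise RuntimeError("tanglegram stage needs the gcf stage")
                dend = profile_dendrogram(pa_matrix, metric="jaccard", method="upgma")
                res = entanglement(tree, dend)
                tpath = out / "tanglegram.tsv"
                pd.DataFrame(
                    {
                        "position": range(1, len(res.order_a) + 1),
                        "species_tree_order": res.order_a,
                        "profile_dendrogram_order": res.order_b,
                    }
                ).to_csv(tpath, sep="\t", index=False)
                spath = out / "entanglement.json"
                spath.write_text(json.dumps({"entanglement": res.entanglement,
                                             "L": res.norm_exponent}))
                record(stage, orders=tpath, score=spath)
        if config.figures:
            _write_figures(out, pa_matrix, tree)
    except Exception as err:
        manifest["error"] = {"stage": stage, "message": str(err)}
        persist_manifest()
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err
    persist_manifest()
    return manifest


def _write_figures(out: Path, pa_matrix, tree) -> None:  # pragma: no cover - plotting
    from . import plots

    if pa_matrix is not None:
        plots.presence_absence_heatmap(pa_matrix, out / "presence_absence.png")
        rare = gcf.rarefaction(pa_matrix, with_variance=False)
        plots.rarefaction_curves(rare, out / "rarefaction.png")
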