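"""End-to-end orchestration of the rate-dispersion analysis.

Stages: topology-congruence gate → per-gene branch-length estimation (when
alignments are given) → Kr/Kc → GMM pattern clustering at each scheme K →
decile / Kendall / EC / random-forest reports.  Every stage writes a TSV;
a run manifest records the full configuration and seeds so a rerun
reproduces every output, and completed stages are skipped when their
manifest entry is unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .krkc import CLASSIFICATIONS, krkc_ratio
from .pattern_clustering import fit_gmm, normalize_branch_vectors
from .phylo_engine import Alignment, optimize_branch_lengths, poisson_model
from .rate_selection import (
    clusters_per_decile,
    ec_cluster_representation,
    exclusion_sensitivity,
    fit_importance_classifier,
    rank_into_deciles,
    rate_dispersion_test,
)
from .topology_clustering import classical_mds, gap_statistic, pairwise_topology_distances
from .trees_io import GeneTree, Topology, read_tree_table

logger = logging.getLogger(__name__)

DEFAULT_SCHEMES = (20, 30, 40, 50, 100)


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run (YAML-serializable)."""

    trees: str | None = None          # tree table TSV
    alignments: str | None = None     # directory of per-gene FASTA files
    annotations: str | None = None    # TSV: gene_id, ec_class
    out_dir: str = "phylopace_run"
    cluster_schemes: tuple[int, ...] = DEFAULT_SCHEMES
    exclude_slowest: int = 2
    seed: int = 0
    gap_k_max: int = 50
    gap_n_reference: int = 50
    model: str = "poisson"            # "poisson" or a model-file path
    gamma_categories: int = 4
    gamma_shape: float | None = None  # co-estimated per gene when None
    optimization_restarts: int = 10
    optimization_tol: float = 1e-6
    classification: str = "charge"
    skip_topology_gate: bool = False
    force_past_gate: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        if isinstance(cfg.cluster_schemes, list):
            cfg.cluster_schemes = tuple(int(k) for k in cfg.cluster_schemes)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cluster_schemes"] = list(self.cluster_schemes)
        return d


class TopologyGateError(RuntimeError):
    """Raised when the gene trees are not topologically congruent."""


def topology_gate(
    gene_trees: "list[tuple[str, object]] | list[GeneTree]",
    k_max: int = 50,
    n_reference: int = 50,
    seed: int = 0,
) -> dict:
    """Congruence check: PH85 distances → MDS → PAM + Gap statistic.

    Passes when the Gap statistic supports a single cluster of topologies
    (all trees can then share one reference topology).
    """
    D = pairwise_topology_distances(gene_trees)
    if np.all(D.values == 0):
        # identical topologies: the Gap machinery is degenerate by design
        return {
            "passed": True,
            "chosen_k": 1,
            "distances": D,
            "embedding": None,
            "gap": None,
        }
    emb = classical_mds(D, dims=2)
    k_max = min(k_max, len(D.ids))
    curve = gap_statistic(emb.coordinates, k_max=k_max, n_reference=n_reference, seed=seed)
    return {
        "passed": curve.chosen_k == 1,
        "chosen_k": curve.chosen_k,
        "distances": D,
        "embedding": emb,
        "gap": curve,
    }


def _stage_key(name: str, payload: dict) -> str:
    return hashlib.sha256(
        json.dumps({"stage": name, **payload}, sort_keys=True, default=str).encode()
    ).hexdigest()


class _Stages:
    """Tiny resumability helper: skip a stage whose key and outputs exist."""

    def __init__(self, out_dir: str):
        self.out_dir = out_dir
        self.path = os.path.join(out_dir, "stages.json")
        self.done = {}
        if os.path.exists(self.path):
            with open(self.path) as fh:
                self.done = json.load(fh)

    def fresh(self, name: str, key: str, outputs: list[str]) -> bool:
        return self.done.get(name) == key and all(
            os.path.exists(os.path.join(self.out_dir, o)) for o in outputs
        )

    def mark(self, name: str, key: str) -> None:
        self.done[name] = key
        with open(self.path, "w") as fh:
            json.dump(self.done, fh, indent=1, sort_keys=True)


def run_all(config: RunConfig) -> str:
    """Run every applicable stage; returns the run directory."""
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    stages = _Stages(out)
    log: list[dict] = []

    def note(stage, **kw):
        entry = {"stage": stage, **kw}
        log.append(entry)
        logger.info("%s", entry)

    def stamp(stage, t0, **kw):
        note(stage, wall_seconds=round(time.time() - t0, 3), **kw)

    if config.trees is None and config.alignments is None:
        raise ValueError("config needs trees and/or alignments")

    cfg = config.to_dict()
    rng = np.random.default_rng(config.seed)
    seeds = {
        name: int(s)
        for name, s in zip(
            ("gate", "fit", "gmm", "forest"),
            rng.integers(0, 2**31 - 1, size=4),
        )
    }

    manifest = {"version": __version__, "config": cfg, "stage_seeds": seeds}
    with open(os.path.join(out, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    # ---- load inputs -----------------------------------------------------
    alignments: dict[str, Alignment] = {}
    if config.alignments:
        for name in sorted(os.listdir(config.alignments)):
            if name.endswith((".fasta", ".fa", ".faa")):
                aln = Alignment.from_fasta(os.path.join(config.alignments, name))
                alignments[aln.gene_id] = aln

    gene_trees: list[GeneTree] = []
    reference: Topology | None = None
    if config.trees:
        parsed = read_tree_table(config.trees)
        note("load_trees", n_trees=len(parsed))

        # ---- topology gate ----------------------------------------------
        if not config.skip_topology_gate and len(parsed) >= 2:
            t0 = time.time()
            gate = topology_gate(
                parsed, k_max=config.gap_k_max,
                n_reference=config.gap_n_reference, seed=seeds["gate"],
            )
            gate["distances"] and _write_distances(gate, out)
            stamp("topology_gate", t0, chosen_k=gate["chosen_k"], passed=gate["passed"])
            if not gate["passed"] and not config.force_past_gate:
                _write_log(out, log)
                raise TopologyGateError(
                    f"gene-tree topologies form {gate['chosen_k']} clusters; "
                    "use force_past_gate to proceed anyway"
                )
        reference = Topology.from_tree(parsed[0][1])
        gene_trees = [GeneTree.from_phylo_tree(g, t, reference) for g, t in parsed]

    # ---- branch-length estimation ---------------------------------------
    if config.alignments and not config.trees:
        raise ValueError(
            "branch-length estimation needs a shared topology: provide a "
            "tree table whose first tree carries the reference topology"
        )
    if config.alignments and config.trees:
        t0 = time.time()
        fname = "fitted_trees.tsv"
        key = _stage_key("fit", {**cfg, "seed": seeds["fit"]})
        if stages.fresh("fit", key, [fname]):
            note("fit_branch_lengths", skipped=True)
            from .trees_io import read_tree_table as _rt

            refit = _rt(os.path.join(out, fname))
            gene_trees = [GeneTree.from_phylo_tree(g, t, reference) for g, t in refit]
        else:
            model = _load_model(config)
            fitted = []
            for gt in gene_trees:
                if gt.gene_id not in alignments:
                    note("fit_branch_lengths", gene=gt.gene_id, skipped="no alignment")
                    fitted.append(gt)
                    continue
                fitted.append(
                    optimize_branch_lengths(
                        alignments[gt.gene_id], reference, model,
                        tol=config.optimization_tol,
                        n_restarts=config.optimization_restarts,
                        optimize_gamma=config.gamma_shape is None
                        and config.gamma_categories > 1,
                        seed=seeds["fit"], gene_id=gt.gene_id,
                    )
                )
            gene_trees = fitted
            from .trees_io import write_tree_table

            write_tree_table(os.path.join(out, fname), gene_trees)
            stages.mark("fit", key)
            stamp("fit_branch_lengths", t0, n_genes=len(gene_trees))

    # ---- Kr/Kc -----------------------------------------------------------
    krkc_df = None
    if alignments:
        t0 = time.time()
        classification = CLASSIFICATIONS[config.classification]
        rows = []
        for gid in sorted(alignments):
            r = krkc_ratio(alignments[gid], classification)
            rows.append(
                {
                    "gene_id": gid, "n_radical": r.n_radical,
                    "n_conservative": r.n_conservative,
                    "n_comparisons": r.n_comparisons,
                    "ratio_normalized": r.ratio, "ratio_raw": r.ratio_raw,
                }
            )
        krkc_df = pd.DataFrame(rows)
        krkc_df.to_csv(os.path.join(out, "krkc.tsv"), sep="\t", index=False)
        stamp("krkc", t0, n_genes=len(rows))
    else:
        note("krkc", skipped="no alignments provided")

    # ---- pattern clustering & rate analysis ------------------------------
    pm = normalize_branch_vectors(gene_trees)
    if pm.dropped:
        note("normalize", dropped=list(pm.dropped))
    tree_lengths = {gt.gene_id: gt.tree_length for gt in gene_trees if gt.gene_id in pm.gene_ids}
    deciles = rank_into_deciles(tree_lengths)
    deciles.to_csv(os.path.join(out, "deciles.tsv"), sep="\t", index=False)

    annotations = None
    if config.annotations:
        annotations = pd.read_csv(config.annotations, sep="\t")

    hist_rows, kendall_rows, assign_rows, ec_frames, importance_rows = [], [], [], [], []
    for K in config.cluster_schemes:
        if K > len(pm.gene_ids):
            note("cluster_patterns", scheme=K, skipped="K exceeds gene count")
            continue
        t0 = time.time()
        assignment = fit_gmm(pm, K, seed=seeds["gmm"])
        for gid, lab, resp in zip(
            assignment.gene_ids, assignment.labels,
            assignment.responsibilities.max(axis=1),
        ):
            assign_rows.append(
                {"gene_id": gid, "K": K, "label": int(lab), "max_responsibility": float(resp)}
            )
        rep = clusters_per_decile(deciles, assignment)
        hist_rows.append(rep)
        kt = rate_dispersion_test(rep)
        kendall_rows.append(
            {"scheme": K, "excluded_deciles": 0, "tau": kt.tau, "p_value": kt.p_value, "n": kt.n}
        )
        if config.exclude_slowest:
            ke = exclusion_sensitivity(deciles, assignment, config.exclude_slowest)
            kendall_rows.append(
                {
                    "scheme": K, "excluded_deciles": config.exclude_slowest,
                    "tau": ke.tau, "p_value": ke.p_value, "n": ke.n,
                }
            )
        if annotations is not None:
            ec = ec_cluster_representation(annotations, assignment)
            ec.insert(0, "scheme", K)
            ec_frames.append(ec)
        if krkc_df is not None:
            feats = deciles[["gene_id", "tree_length"]].merge(
                krkc_df[["gene_id", "ratio_normalized"]], on="gene_id", how="left"
            )
            feats = feats.rename(columns={"ratio_normalized": "krkc"})
            if annotations is not None:
                feats = feats.merge(annotations, on="gene_id", how="left")
                feats = feats.rename(columns={"ec_class": "ec"})
            else:
                feats["ec"] = pd.NA
            label_of = assignment.label_of()
            feats = feats[feats["gene_id"].isin(label_of)]
            labels = [label_of[g] for g in feats["gene_id"]]
            if len(set(labels)) >= 2:
                rep_imp = fit_importance_classifier(feats, labels, seed=seeds["forest"])
                for name, v in rep_imp.importances.items():
                    importance_rows.append(
                        {
                            "scheme": K, "feature": name, "gini_importance": v,
                            "gini_importance_normalized": rep_imp.importances_normalized[name],
                            "single_feature_oob_accuracy": rep_imp.single_feature_accuracy[name],
                            "oob_accuracy": rep_imp.oob_accuracy,
                        }
                    )
        stamp("cluster_patterns", t0, scheme=K)

    pd.DataFrame(assign_rows).to_csv(os.path.join(out, "assignments.tsv"), sep="\t", index=False)
    if hist_rows:
        pd.concat(hist_rows).to_csv(os.path.join(out, "clusters_per_decile.tsv"), sep="\t", index=False)
    pd.DataFrame(kendall_rows).to_csv(os.path.join(out, "kendall.tsv"), sep="\t", index=False)
    if ec_frames:
        pd.concat(ec_frames).to_csv(os.path.join(out, "ec_summary.tsv"), sep="\t", index=False)
    if importance_rows:
        pd.DataFrame(importance_rows).to_csv(os.path.join(out, "importance.tsv"), sep="\t", index=False)

    _write_log(out, log)
    return out


def _write_distances(gate: dict, out: str) -> None:
    D = gate["distances"]
    pd.DataFrame(D.values, index=D.ids, columns=D.ids).to_csv(
        os.path.join(out, "topology_distances.tsv"), sep="\t"
    )
    if gate["embedding"] is not None:
        emb = gate["embedding"]
        pd.DataFrame(
            {"gene_id": emb.ids, "x": emb.coordinates[:, 0], "y": emb.coordinates[:, 1]}
        ).to_csv(os.path.join(out, "topology_mds.tsv"), sep="\t", index=False)
    if gate["gap"] is not None:
        g = gate["gap"]
        pd.DataFrame({"k": g.k_values, "gap": g.gap, "sd": g.sd}).to_csv(
            os.path.join(out, "gap_curve.tsv"), sep="\t", index=False
        )


def _write_log(out: str, log: list[dict]) -> None:
    with open(os.path.join(out, "run_log.jsonl"), "w") as fh:
        for entry in log:
            fh.write(json.dumps(entry, default=str) + "\n")


def _load_model(config: RunConfig):
    shape = config.gamma_shape
    ncat = config.gamma_categories
    if config.model == "poisson":
        return poisson_model(gamma_shape=shape or (1.0 if ncat > 1 else None), n_categories=ncat)
    from .phylo_engine import load_model_file

    return load_model_file(config.model, gamma_shape=shape, n_categories=ncat)
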