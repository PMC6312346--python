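"""End-to-end orchestration: classify -> correlate -> cluster -> ancestral -> conserve.

Consumes a dataset directory in the layout :func:`mztevo.simulate.write_fixture`
emits (per-species ``expr_<sp>.tsv``, ``samples.tsv``, ``isoform_map.tsv``,
``orthologs.tsv``, ``tree.nwk``) and writes stage outputs plus a manifest
with a config hash into the output directory.
"""

from __future__ import annotations

import hashlib
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancestral, comparative, conserve, io
from .classify import ClassifierConfig, classify_species
from .trees import read_tree


@dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    presence_threshold: float = 1.0
    fold: float = 2.0
    alpha: float = 0.05
    min_species: int = 12
    posterior_threshold: float = 0.90
    significance_method: str = "welch"
    roles: dict | None = None  # outgroup/basal/subgenus for conservation
    seed: int = 0
    verbose: bool = False
    extras: dict = field(default_factory=dict)


def _log(cfg: RunConfig, msg: str, t0: float) -> None:
    if cfg.verbose:
        print(f"[mzt +{time.perf_counter() - t0:7.2f}s] {msg}", file=sys.stderr)


def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(yaml.safe_dump(asdict(cfg), sort_keys=True).encode()).hexdigest()[:16]


def group_level_calls(gene_calls: pd.DataFrame, orthologs: pd.DataFrame, species: str) -> pd.DataFrame:
    """Re-index one species' gene-level calls by ortholog group; groups with a
    blank ortholog in this species are dropped."""
    ids = orthologs[species].dropna()
    sub = gene_calls.loc[ids.to_numpy()]
    sub.index = ids.index
    return sub


def run_pipeline(cfg: RunConfig) -> dict:
    t0 = time.perf_counter()
    in_dir = Path(cfg.input_dir)
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in ("samples.tsv", "isoform_map.tsv", "orthologs.tsv", "tree.nwk"):
        if not (in_dir / name).exists():
            raise FileNotFoundError(f"required input missing: {in_dir / name}")

    sheet = io.read_sample_sheet(str(in_dir / "samples.tsv"))
    isoform_map = io.read_isoform_map(str(in_dir / "isoform_map.tsv"))
    orthologs = io.read_ortholog_table(str(in_dir / "orthologs.tsv"))
    tree = read_tree(str(in_dir / "tree.nwk"), species=list(orthologs.columns))
    clf = ClassifierConfig(
        presence_threshold=cfg.presence_threshold, fold=cfg.fold, alpha=cfg.alpha
    )

    gene_calls: dict[str, pd.DataFrame] = {}
    conditions: dict[str, pd.DataFrame] = {}
    for sp in orthologs.columns:
        path = in_dir / f"expr_{sp}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"expression table missing: {path}")
        table = io.read_expression_table(str(path), sheet)
        iso_calls, gcalls = classify_species(
            table, isoform_map, sp, clf, method=cfg.significance_method
        )
        gene_calls[sp] = gcalls
        gene_table = io.aggregate_isoforms_to_genes(table, isoform_map)
        conditions[sp] = io.mean_by_condition(gene_table)[sp]
        out = pd.concat([iso_calls.drop(columns="gene"), gcalls])
        out.index.name = "feature_id"
        out.to_csv(out_dir / f"calls_{sp}.tsv", sep="\t")
        _log(cfg, f"classified {sp}: {len(gcalls)} genes", t0)

    filtered = io.filter_ortholog_groups(orthologs, min_species=cfg.min_species)
    grouped = {
        sp: group_level_calls(gene_calls[sp], filtered, sp) for sp in filtered.columns
    }

    # correlation matrix + clustering over all (species, stage) conditions
    blocks = {}
    for stage in io.STAGES:
        mat = io.ortholog_matrix(conditions, filtered, stage)
        for sp in mat.columns:
            blocks[f"{sp}|{stage}"] = mat[sp]
    cond_matrix = pd.DataFrame(blocks)
    corr = comparative.correlation_matrix(cond_matrix)
    corr.to_csv(out_dir / "correlation_matrix.tsv", sep="\t")
    clustering = comparative.hierarchical_cluster(corr)
    pd.DataFrame(
        clustering["linkage"], columns=["left", "right", "height", "count"]
    ).to_csv(out_dir / "linkage.tsv", sep="\t", index=False)
    _log(cfg, "correlation and clustering done", t0)

    # ancestral reconstruction per stage
    chars = ancestral.encode_characters(conditions, filtered, cfg.presence_threshold)
    freqs = ancestral.character_frequencies(chars)
    all_events = []
    models = {}
    for stage in io.STAGES:
        states, idx = ancestral.states_array(chars, tree, stage)
        model = ancestral.fit_rates(tree, states)
        models[stage] = model
        post = ancestral.marginal_posteriors(tree, states, model)
        events = ancestral.call_transitions(
            tree, post, list(idx), states, threshold=cfg.posterior_threshold
        )
        events.insert(0, "stage", stage)
        all_events.append(events)
    events = pd.concat(all_events).rename(columns={"character": "gene"})
    events.to_csv(out_dir / "transitions.tsv", sep="\t", index=False)
    _log(cfg, f"ancestral reconstruction: {len(events)} events", t0)

    conservation = None
    if cfg.roles:
        roles = conserve.SpeciesRoleConfig(
            outgroup=cfg.roles["outgroup"],
            basal=cfg.roles["basal"],
            subgenus=tuple(cfg.roles["subgenus"]),
        )
        calls_by_group = pd.DataFrame(
            {sp: grouped[sp]["category"] for sp in grouped}
        )
        conservation = conserve.conservation_table(calls_by_group, roles)
        conservation.to_csv(out_dir / "conservation.tsv", sep="\t")
        _log(cfg, "conservation table written", t0)

    manifest = {
        "config": asdict(cfg),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "character_frequencies": {
            "present": freqs[0], "absent": freqs[1], "unknown": freqs[2]
        },
        "rates": {
            st: {"q01": m.q01, "q10": m.q10} for st, m in models.items()
        },
        "n_transition_events": int(len(events)),
        "versions": {
            "mztevo": __import__("mztevo").__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out_dir / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return {
        "manifest": manifest,
        "events": events,
        "gene_calls": gene_calls,
        "grouped_calls": grouped,
        "conservation": conservation,
        "clustering": clustering,
    }
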