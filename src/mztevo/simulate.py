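"""Ground-truthed synthetic datasets for the whole pipeline.

The generator emulates the statistical structure the analysis assumes:
presence/absence characters for two embryonic stages evolve independently
along a 14-tip phylogeny under the two-state Markov model; present genes get
lognormal FPKM with multiplicative lognormal replicate noise; absent genes
are zero with an optional sub-threshold uniform "leak"; a configurable
fraction of genes carries stage-specific isoforms (one maternal-class and
one zygotic-class isoform, the ALT pattern) and another fraction is
predominant at one stage (a fold change on gene totals); orthologs go
missing (blank) at a configurable per-(group, species) rate.

Defaults are calibrated so that observed character-state frequencies are
approximately (present, absent, unknown) = (0.715, 0.219, 0.0656): the
stationary present-state probability q01/(q01+q10) = 1.0/1.307 = 0.765
times the non-missing fraction 0.9344 gives 0.715.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (
    ExpressionTable,
    STAGES,
    mean_by_condition,
    write_expression_table,
    write_ortholog_table,
)
from .trees import Tree, read_tree, write_tree

#: 14-tip default phylogeny: a melanogaster-subgroup-like clade with two
#: sister pairs, an ananassae-like lineage, an obscura-like trio, a basal
#: Sophophora tip, and a distant two-tip subgenus clade.  Unit-free branch
#: lengths, roughly clock-like.
DEFAULT_TREE = (
    "((((((mel:0.06,(sim:0.03,(sec:0.02,mau:0.02):0.01):0.03):0.02,"
    "((yak:0.04,san:0.04):0.02,ere:0.06):0.02):0.10,ana:0.18):0.06,"
    "((pse:0.02,per:0.02):0.04,mir:0.06):0.18):0.05,wil:0.30):0.12,"
    "(vir:0.25,moj:0.25):0.17);"
)


@dataclass(frozen=True)
class SimulationConfig:
    newick: str = DEFAULT_TREE
    n_genes: int = 2000
    q01: float = 1.0
    q10: float = 0.307
    root_prior: tuple[float, float] | None = None  # None -> stationary
    present_log_mean: float = 3.0  # natural-log scale; median FPKM ~ 20
    present_log_sd: float = 1.0
    leak_prob: float = 0.1
    leak_max: float = 0.5
    replicate_cv: float = 0.2
    n_replicates: int = 3
    missing_rate: float = 0.0656
    alt_fraction: float = 0.10
    predominant_fraction: float = 0.10
    predominant_fold: float = 8.0
    max_isoforms: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("leak_prob", "missing_rate", "alt_fraction", "predominant_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.q01 <= 0 or self.q10 <= 0:
            raise ValueError("rates must be positive")
        if self.replicate_cv < 0 or self.leak_max < 0:
            raise ValueError("replicate_cv and leak_max must be >= 0")


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    tree: Tree
    gene_names: list[str]
    node_states: dict[str, np.ndarray]  # stage -> (n_nodes, n_genes) int8
    missing: np.ndarray  # (n_genes, n_tips) bool
    orthologs: pd.DataFrame
    expression: dict[str, ExpressionTable]
    isoform_map: pd.Series
    truth_genes: pd.DataFrame  # per kept (gene, species): states, category, alt
    events: pd.DataFrame  # true branch transitions

    def conditions(self) -> dict[str, pd.DataFrame]:
        """Per-species condition matrices (gene-id x stage mean FPKM)."""
        from .io import aggregate_isoforms_to_genes

        out = {}
        for sp, tbl in self.expression.items():
            genes = aggregate_isoforms_to_genes(tbl, self.isoform_map)
            out[sp] = mean_by_condition(genes)[sp]
        return out

    def character_matrix(self) -> pd.DataFrame:
        """Truth-based character matrix (tip states with blanks as unknown)."""
        tips = self.tree.tips
        blocks = []
        for stage in STAGES:
            tip_states = self.node_states[stage][tips, :].T.astype(np.int8)
            tip_states = np.where(self.missing, -1, tip_states)
            df = pd.DataFrame(tip_states, index=self.gene_names, columns=self.tree.tip_labels)
            df.index = pd.MultiIndex.from_product(
                [df.index, [stage]], names=["gene", "stage"]
            )
            blocks.append(df)
        return pd.concat(blocks).sort_index().astype(np.int8)


def simulate_presence(
    tree: Tree,
    q01: float,
    q10: float,
    root_prior: tuple[float, float] | None,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve n binary characters down the tree; returns (n_nodes, n) states."""
    from .ancestral import MkModel

    model = MkModel(q01=q01, q10=q10, root_prior=root_prior)
    states = np.zeros((tree.n_nodes, n), dtype=np.int8)
    prior = model.prior
    states[tree.root] = rng.random(n) < prior[1]
    for v in tree.preorder():
        if v == tree.root:
            continue
        P = model.transition_matrix(tree.blen[v])
        parent = states[tree.parent[v]]
        p_one = np.where(parent == 1, P[1, 1], P[0, 1])
        states[v] = rng.random(n) < p_one
    return states


def true_transitions(tree: Tree, node_states: dict[str, np.ndarray], gene_names: list[str]) -> pd.DataFrame:
    """Branch-level true gain/loss events from simulated node states."""
    rows = []
    for stage, states in node_states.items():
        for v in range(tree.n_nodes - 1):
            u = tree.parent[v]
            diff = states[u] != states[v]
            for g in np.nonzero(diff)[0]:
                direction = "gain" if states[v][g] == 1 else "loss"
                rows.append((gene_names[g], stage, tree.labels[u], tree.labels[v], direction))
    return pd.DataFrame(rows, columns=["gene", "stage", "parent", "child", "direction"])


def inject_missing_orthologs(
    orthologs: pd.DataFrame,
    missing_rate: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Blank each (group, species) entry independently with the given rate."""
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    mask = rng.random(orthologs.shape) < missing_rate
    out = orthologs.copy()
    out[mask] = np.nan
    return out


def _truth_categories(m2: np.ndarray, m5: np.ndarray, threshold: float, fold: float) -> np.ndarray:
    """Category implied by noiseless designed means; the stage difference is
    'significant' whenever the designed means differ at all."""
    p2 = m2 >= threshold
    p5 = m5 >= threshold
    out = np.full(m2.shape, "MZ", dtype=object)
    out[~p2 & ~p5] = "N"
    out[p2 & ~p5] = "M"
    out[~p2 & p5] = "Z"
    both = p2 & p5
    differ = m2 != m5
    out[both & differ & (m2 >= fold * m5)] = "PM"
    out[both & differ & (m5 >= fold * m2)] = "PZ"
    return out


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate a complete dataset plus truth tables (see module docstring)."""
    rng = np.random.default_rng(cfg.seed)
    tree = read_tree(cfg.newick)
    species = tree.tip_labels
    n_tips = len(species)
    n = cfg.n_genes
    genes = [f"g{i:05d}" for i in range(n)]

    node_states = {
        stage: simulate_presence(tree, cfg.q01, cfg.q10, cfg.root_prior, n, rng)
        for stage in STAGES
    }
    events = true_transitions(tree, node_states, genes)

    # gene archetypes (shared across species)
    u = rng.random(n)
    alt_gene = u < cfg.alt_fraction
    pred_gene = (~alt_gene) & (u < cfg.alt_fraction + cfg.predominant_fraction)
    pred_is_pm = rng.random(n) < 0.5
    n_iso = np.where(alt_gene, 2, rng.integers(1, cfg.max_isoforms + 1, size=n))
    proportions = [
        np.sort(rng.dirichlet(np.full(k, 3.0)))[::-1] for k in n_iso
    ]
    missing = rng.random((n, n_tips)) < cfg.missing_rate
    base = rng.lognormal(cfg.present_log_mean, cfg.present_log_sd, (n_tips, n))
    noise_sd = float(np.sqrt(np.log1p(cfg.replicate_cv**2)))

    # flat isoform layout shared by all species
    iso_gene_idx = np.repeat(np.arange(n), n_iso)
    iso_rank = np.concatenate([np.arange(k) for k in n_iso])
    iso_prop = np.concatenate(proportions)

    tip_of = {sp: tree.tips[k] for k, sp in enumerate(species)}
    orthologs = pd.DataFrame(
        {sp: [f"{g}@{sp}" for g in genes] for sp in species}, index=pd.Index(genes, name="ref_gene")
    )
    orthologs = orthologs.where(~missing, np.nan)

    expression: dict[str, ExpressionTable] = {}
    iso_maps = []
    truth_rows = []
    for k, sp in enumerate(species):
        s2 = node_states["stage2"][tip_of[sp]]
        s5 = node_states["stage5"][tip_of[sp]]
        b = base[k]
        leak2 = (rng.random(n) < cfg.leak_prob) * rng.uniform(0, cfg.leak_max, n)
        leak5 = (rng.random(n) < cfg.leak_prob) * rng.uniform(0, cfg.leak_max, n)
        m2 = np.where(s2 == 1, b, leak2)
        m5 = np.where(s5 == 1, b, leak5)
        both = (s2 == 1) & (s5 == 1)
        m5 = np.where(pred_gene & pred_is_pm & both, b / cfg.predominant_fold, m5)
        m2 = np.where(pred_gene & ~pred_is_pm & both, b / cfg.predominant_fold, m2)

        # isoform designed means; ALT genes realized where present at both stages
        iso_m2 = iso_prop * m2[iso_gene_idx]
        iso_m5 = iso_prop * m5[iso_gene_idx]
        alt_real = alt_gene & both
        a_mask = alt_real[iso_gene_idx]
        iso_m2[a_mask & (iso_rank == 0)] = b[iso_gene_idx][a_mask & (iso_rank == 0)]
        iso_m2[a_mask & (iso_rank == 1)] = 0.0
        iso_m5[a_mask & (iso_rank == 0)] = 0.0
        iso_m5[a_mask & (iso_rank == 1)] = b[iso_gene_idx][a_mask & (iso_rank == 1)]

        keep_iso = ~missing[iso_gene_idx, k]
        iso_ids = [
            f"{genes[g]}@{sp}.{r}" for g, r in zip(iso_gene_idx[keep_iso], iso_rank[keep_iso])
        ]
        gene_ids = [f"{genes[g]}@{sp}" for g in iso_gene_idx[keep_iso]]
        iso_maps.append(pd.Series(gene_ids, index=pd.Index(iso_ids, name="isoform")))

        reps = {}
        for stage, iso_m in (("stage2", iso_m2), ("stage5", iso_m5)):
            noise = rng.lognormal(
                -noise_sd**2 / 2, noise_sd, (iso_m.size, cfg.n_replicates)
            )
            mat = iso_m[:, None] * noise
            for r in range(cfg.n_replicates):
                reps[f"{sp}_{stage}_r{r + 1}"] = mat[keep_iso, r]
        values = pd.DataFrame(reps, index=pd.Index(iso_ids, name="feature_id"))
        samples = pd.DataFrame(
            {
                "species": sp,
                "stage": [c.split("_")[1] for c in values.columns],
                "replicate": [int(c.rsplit("r", 1)[1]) for c in values.columns],
            },
            index=pd.Index(values.columns, name="sample_id"),
        )
        expression[sp] = ExpressionTable(values=values, samples=samples)

        cat = _truth_categories(m2, m5, threshold=1.0, fold=2.0)
        alt_true = alt_real & (b >= 1.0)
        kept = ~missing[:, k]
        for g in np.nonzero(kept)[0]:
            truth_rows.append(
                (genes[g], sp, int(s2[g]), int(s5[g]), m2[g], m5[g], cat[g], bool(alt_true[g]))
            )

    truth_genes = pd.DataFrame(
        truth_rows,
        columns=["gene", "species", "s2_state", "s5_state", "s2_mean", "s5_mean", "category", "alt"],
    )
    return SimulatedDataset(
        config=cfg,
        tree=tree,
        gene_names=genes,
        node_states=node_states,
        missing=missing,
        orthologs=orthologs,
        expression=expression,
        isoform_map=pd.concat(iso_maps),
        truth_genes=truth_genes,
        events=events,
    )


def simulate_character_matrix(cfg: SimulationConfig) -> pd.DataFrame:
    """Character matrix only (no expression): fast path for large gene counts."""
    rng = np.random.default_rng(cfg.seed)
    tree = read_tree(cfg.newick, path=False)
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    node_states = {
        stage: simulate_presence(tree, cfg.q01, cfg.q10, cfg.root_prior, cfg.n_genes, rng)
        for stage in STAGES
    }
    missing = rng.random((cfg.n_genes, len(tree.tips))) < cfg.missing_rate
    ds = SimulatedDataset(
        config=cfg, tree=tree, gene_names=genes, node_states=node_states,
        missing=missing, orthologs=pd.DataFrame(), expression={},
        isoform_map=pd.Series(dtype=object), truth_genes=pd.DataFrame(),
        events=pd.DataFrame(),
    )
    return ds.character_matrix()


def config_hash(cfg: SimulationConfig) -> str:
    return hashlib.sha256(
        yaml.safe_dump(asdict(cfg), sort_keys=True).encode()
    ).hexdigest()[:16]


def write_fixture(directory: str | Path, cfg: SimulationConfig) -> SimulatedDataset:
    """Simulate and write a complete on-disk fixture plus truth tables.

    Emits per-species expression TSVs, a sample sheet, the isoform map, the
    ortholog table, the tree, truth tables and a YAML manifest recording the
    config and seed.  Identical configs produce byte-identical fixtures.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(cfg)
    sheets = []
    for sp, tbl in ds.expression.items():
        write_expression_table(tbl, directory / f"expr_{sp}.tsv")
        sheets.append(tbl.samples.reset_index())
    pd.concat(sheets).to_csv(directory / "samples.tsv", sep="\t", index=False)
    ds.isoform_map.rename("gene").to_csv(directory / "isoform_map.tsv", sep="\t")
    write_ortholog_table(ds.orthologs, directory / "orthologs.tsv")
    write_tree(ds.tree, str(directory / "tree.nwk"))
    ds.truth_genes.to_csv(directory / "truth_genes.tsv", sep="\t", index=False)
    ds.events.to_csv(directory / "truth_events.tsv", sep="\t", index=False)
    manifest = {"config": asdict(cfg), "config_hash": config_hash(cfg), "seed": cfg.seed}
    with open(directory / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return ds
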