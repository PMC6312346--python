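"""Cross-species correlation and clustering of early-embryo transcriptomes.

Comparisons operate on ortholog-group-level mean FPKM.  The two selection
modes mirror the two ways a stage-restricted class can be shared between a
species pair: ``shared_in_both`` keeps ortholog groups with the class in both
species, ``in_either`` keeps groups with the class in at least one.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

CATEGORY_STAGE = {
    "stage2": "stage2",
    "stage5": "stage5",
    "maternal_only": "stage2",
    "zygotic_only": "stage5",
}
CATEGORY_CALL = {"maternal_only": "M", "zygotic_only": "Z"}


@dataclass
class CorrelationResult:
    species_a: str
    species_b: str
    selection: str  # stage2 / stage5 / maternal_only / zygotic_only
    mode: str  # shared_in_both / in_either
    rho: float | None
    n_genes: int


def spearman(x, y) -> float | None:
    """Spearman rank correlation; None when undefined (constant input)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("spearman needs two equal-length vectors of size >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def _select_genes(
    a: pd.DataFrame,
    b: pd.DataFrame,
    selection: str,
    mode: str,
    presence_threshold: float,
) -> pd.Index:
    shared = a.index.intersection(b.index)
    a = a.loc[shared]
    b = b.loc[shared]
    if selection in ("stage2", "stage5"):
        col = f"{'s2' if selection == 'stage2' else 's5'}_mean"
        in_a = a[col] >= presence_threshold
        in_b = b[col] >= presence_threshold
    else:
        call = CATEGORY_CALL[selection]
        in_a = a["category"] == call
        in_b = b["category"] == call
    if mode == "shared_in_both":
        keep = in_a & in_b
    elif mode == "in_either":
        keep = in_a | in_b
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return shared[keep]


def pairwise_category_correlation(
    a: pd.DataFrame,
    b: pd.DataFrame,
    selection: str,
    mode: str = "shared_in_both",
    species_a: str = "a",
    species_b: str = "b",
    presence_threshold: float = 1.0,
) -> CorrelationResult:
    """Spearman rho between two species over a selected gene class.

    ``a`` and ``b`` are group-level frames (index = ortholog group) with
    columns ``s2_mean, s5_mean, category``; groups with a blank ortholog in
    either species must already carry NaN/absent rows and are excluded by the
    index intersection.  The FPKM means compared are those of the stage the
    selection refers to (maternal classes -> stage 2, zygotic -> stage 5).
    """
    genes = _select_genes(a, b, selection, mode, presence_threshold)
    col = f"{'s2' if CATEGORY_STAGE[selection] == 'stage2' else 's5'}_mean"
    if len(genes) < 2:
        return CorrelationResult(species_a, species_b, selection, mode, None, len(genes))
    rho = spearman(a.loc[genes, col], b.loc[genes, col])
    return CorrelationResult(species_a, species_b, selection, mode, rho, len(genes))


def correlation_matrix(conditions: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Spearman matrix over condition columns (species x stage).

    ``conditions`` is features x conditions; rows with any NaN (blank
    orthologs) are dropped listwise so every pair uses the same gene set.
    """
    mat = conditions.dropna()
    if mat.shape[1] < 2:
        raise ValueError("need at least two conditions")
    corr = mat.corr(method="spearman")
    np.fill_diagonal(corr.to_numpy(), 1.0)
    return corr


def hierarchical_cluster(corr: pd.DataFrame, method: str = "average") -> dict:
    """Agglomerative clustering of conditions on distance 1 - rho.

    Returns ``{"linkage": ndarray, "labels": list, "metric": str,
    "method": str}``; deterministic given its input.
    """
    arr = corr.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-8):
        raise ValueError("correlation matrix must be square and symmetric")
    dist = 1.0 - (arr + arr.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method=method)
    return {
        "linkage": linkage,
        "labels": [str(c) if not isinstance(c, tuple) else "|".join(c) for c in corr.columns],
        "metric": "1 - spearman rho",
        "method": method,
    }


def top_split(clustering: dict) -> tuple[set[str], set[str]]:
    """Leaf label bipartition induced by the final (topmost) merge."""
    flat = hierarchy.fcluster(clustering["linkage"], t=2, criterion="maxclust")
    labels = clustering["labels"]
    one = {lbl for lbl, k in zip(labels, flat) if k == 1}
    two = {lbl for lbl, k in zip(labels, flat) if k == 2}
    return one, two


def alt_conservation_count(alt_flags: pd.DataFrame, min_fraction: float = 2 / 3) -> pd.DataFrame:
    """Count species with the ALT state per ortholog group.

    ``alt_flags`` is groups x species with True/False/NaN (NaN = blank
    ortholog).  Returns a frame with ``n_alt`` and ``conserved`` (count at
    least ceil(min_fraction * n_species)).
    """
    n_species = alt_flags.shape[1]
    counts = alt_flags.notna().to_numpy() & alt_flags.fillna(0).to_numpy().astype(bool)
    counts = pd.Series(counts.sum(axis=1), index=alt_flags.index)
    need = ceil(min_fraction * n_species)
    return pd.DataFrame({"n_alt": counts, "conserved": counts >= need})


def shared_stage_restricted_counts(
    a_categories: pd.Series,
    b_categories: pd.Series,
) -> tuple[int, int]:
    """(# maternal-only in both, # zygotic-only in both) over shared groups."""
    shared = a_categories.index.intersection(b_categories.index)
    a = a_categories.loc[shared]
    b = b_categories.loc[shared]
    n_m = int(((a == "M") & (b == "M")).sum())
    n_z = int(((a == "Z") & (b == "Z")).sum())
    return n_m, n_z
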