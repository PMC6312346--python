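"""Stage-category classification of isoforms and genes across the MZT.

Each feature is assigned one of six categories from its mean FPKM at the two
embryonic timepoints (stage 2 = purely maternal transcripts, stage 5 = after
zygotic genome activation):

* ``M``  maternal-only: present at stage 2, absent at stage 5;
* ``Z``  zygotic-only: absent at stage 2, present at stage 5;
* ``PM`` predominantly maternal: present at both, >= fold higher at stage 2,
  with the stage difference significant (q < alpha);
* ``PZ`` predominantly zygotic: the mirror image;
* ``MZ`` present at both stages, predominant at neither;
* ``N``  not present at either stage.

"Present" means mean FPKM >= presence threshold (default 1).  Significance
is a two-sided Welch test on log2(FPKM + 1) replicate values, Benjamini-
Hochberg adjusted across all features of a species; an exact mean-difference
permutation test is available for very small replicate numbers.  A gene with
at least one maternal-class (M/PM) and one zygotic-class (Z/PZ) isoform is
flagged ALT (stage-specific isoform usage).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionTable, STAGES, aggregate_isoforms_to_genes

CATEGORIES = ("M", "PM", "MZ", "PZ", "Z", "N")
MATERNAL_CLASS = frozenset({"M", "PM"})
ZYGOTIC_CLASS = frozenset({"Z", "PZ"})


@dataclass(frozen=True)
class ClassifierConfig:
    presence_threshold: float = 1.0
    unique_hi_threshold: float = 3.0
    fold: float = 2.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.presence_threshold <= 0:
            raise ValueError("presence_threshold must be > 0")
        if self.unique_hi_threshold < self.presence_threshold:
            raise ValueError("unique_hi_threshold must be >= presence_threshold")
        if self.fold < 1:
            raise ValueError("fold must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def is_present(fpkm: float, threshold: float) -> bool:
    """Presence is FPKM greater than or equal to the threshold."""
    return fpkm >= threshold


def _welch_p(s2: np.ndarray, s5: np.ndarray) -> np.ndarray:
    """Two-sided Welch p per row on log2(FPKM+1); degenerate zero-variance
    rows get p=1 when the means agree and p=0 when they differ."""
    import warnings

    a = np.log2(s2 + 1.0)
    b = np.log2(s5 + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant rows trip scipy's precision-loss warning; handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    diff = a.mean(axis=1) - b.mean(axis=1)
    degenerate = ~np.isfinite(p)
    p[degenerate & (diff == 0)] = 1.0
    p[degenerate & (diff != 0)] = 0.0
    return p


def _permutation_p(s2: np.ndarray, s5: np.ndarray) -> np.ndarray:
    """Exact two-sided permutation p on the mean difference of log2(FPKM+1),
    enumerating all replicate-to-stage assignments."""
    n2 = s2.shape[1]
    pooled = np.log2(np.concatenate([s2, s5], axis=1) + 1.0)
    total = pooled.shape[1]
    idx_sets = list(combinations(range(total), n2))
    out = np.empty(pooled.shape[0])
    for i, row in enumerate(pooled):
        obs = abs(row[:n2].mean() - row[n2:].mean())
        count = 0
        for idx in idx_sets:
            mask = np.zeros(total, dtype=bool)
            mask[list(idx)] = True
            stat = abs(row[mask].mean() - row[~mask].mean())
            if stat >= obs - 1e-12:
                count += 1
        out[i] = count / len(idx_sets)
    return out


def stage_significance(
    s2_reps: pd.DataFrame,
    s5_reps: pd.DataFrame,
    method: str = "welch",
) -> pd.Series:
    """Per-feature q-values for the stage 2 vs stage 5 contrast.

    Rows are features, columns replicates.  Features with fewer than two
    replicates at either stage get q = NaN (and can never be PM/PZ).
    BH adjustment runs jointly across all testable features.
    """
    if not s2_reps.index.equals(s5_reps.index):
        raise ValueError("stage replicate tables must share the feature index")
    q = pd.Series(np.nan, index=s2_reps.index, name="q_value")
    if s2_reps.shape[1] < 2 or s5_reps.shape[1] < 2:
        return q
    a = s2_reps.to_numpy(dtype=float)
    b = s5_reps.to_numpy(dtype=float)
    if method == "welch":
        p = _welch_p(a, b)
    elif method == "permutation":
        if a.shape[1] > 4 or b.shape[1] > 4:
            raise ValueError("exact permutation test supported for <= 4 replicates per stage")
        p = _permutation_p(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    q[:] = multipletests(p, method="fdr_bh")[1]
    return q


def classify_feature(
    s2_mean: float,
    s5_mean: float,
    q: float | None,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> str:
    """Six-way category for one feature from its stage means and q-value."""
    return classify_features(
        np.asarray([s2_mean], dtype=float),
        np.asarray([s5_mean], dtype=float),
        np.asarray([np.nan if q is None else q], dtype=float),
        cfg,
    )[0]


def classify_features(
    s2_mean: np.ndarray,
    s5_mean: np.ndarray,
    q: np.ndarray,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> np.ndarray:
    """Vectorized six-way classification (see module docstring for rules)."""
    s2 = np.asarray(s2_mean, dtype=float)
    s5 = np.asarray(s5_mean, dtype=float)
    qv = np.asarray(q, dtype=float)
    if (s2 < 0).any() or (s5 < 0).any():
        raise ValueError("FPKM means must be non-negative")
    p2 = s2 >= cfg.presence_threshold
    p5 = s5 >= cfg.presence_threshold
    sig = np.where(np.isnan(qv), False, qv < cfg.alpha)
    out = np.full(s2.shape, "MZ", dtype=object)
    out[~p2 & ~p5] = "N"
    out[p2 & ~p5] = "M"
    out[~p2 & p5] = "Z"
    both = p2 & p5
    out[both & sig & (s2 >= cfg.fold * s5)] = "PM"
    out[both & sig & (s5 >= cfg.fold * s2)] = "PZ"
    return out


def detect_alt(isoform_categories) -> bool:
    """ALT: >= 1 maternal-class and >= 1 zygotic-class isoform in one gene."""
    cats = set(isoform_categories)
    if not cats:
        raise ValueError("detect_alt needs at least one isoform call")
    return bool(cats & MATERNAL_CLASS) and bool(cats & ZYGOTIC_CLASS)


def classify_table(
    table: ExpressionTable,
    species: str,
    cfg: ClassifierConfig = ClassifierConfig(),
    method: str = "welch",
    level: str = "isoform",
) -> pd.DataFrame:
    """Category calls for every feature of one species.

    Returns a frame indexed by feature with columns
    ``level, category, s2_mean, s5_mean, q_value``.
    """
    reps = {st: table.replicates(species, st) for st in STAGES}
    for st in STAGES:
        if reps[st].shape[1] == 0:
            raise ValueError(f"no {st} replicates for species {species!r}")
    q = stage_significance(reps["stage2"], reps["stage5"], method=method)
    s2 = reps["stage2"].mean(axis=1)
    s5 = reps["stage5"].mean(axis=1)
    cat = classify_features(s2.to_numpy(), s5.to_numpy(), q.to_numpy(), cfg)
    return pd.DataFrame(
        {
            "level": level,
            "category": cat,
            "s2_mean": s2,
            "s5_mean": s5,
            "q_value": q,
        }
    )


def classify_species(
    isoform_table: ExpressionTable,
    isoform_map: pd.Series,
    species: str,
    cfg: ClassifierConfig = ClassifierConfig(),
    method: str = "welch",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Isoform- and gene-level calls plus the per-gene ALT flag.

    Gene-level categories are computed from gene totals (isoform FPKM sums),
    never from isoform calls; the ALT flag is the only quantity derived from
    isoform categories.
    """
    iso_calls = classify_table(isoform_table, species, cfg, method, level="isoform")
    gene_table = aggregate_isoforms_to_genes(isoform_table, isoform_map)
    gene_calls = classify_table(gene_table, species, cfg, method, level="gene")
    genes = isoform_map.loc[iso_calls.index]
    alt = iso_calls.groupby(genes.to_numpy())["category"].apply(detect_alt)
    gene_calls["alt"] = alt.reindex(gene_calls.index).fillna(False).astype(bool)
    iso_calls["gene"] = genes.to_numpy()
    return iso_calls, gene_calls


def unique_representation(
    row: pd.Series,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> str | None:
    """Species uniquely representing a gene at one stage, if any.

    ``row`` holds per-species mean FPKM for one ortholog group at one stage
    (NaN = blank ortholog).  Returns the species iff exactly one species
    exceeds the high threshold (FPKM > 3, strict) and every other non-blank
    species is below the presence threshold (FPKM < 1).
    """
    vals = row.dropna()
    hi = vals[vals > cfg.unique_hi_threshold]
    if len(hi) != 1:
        return None
    others = vals.drop(hi.index)
    if (others < cfg.presence_threshold).all():
        return str(hi.index[0])
    return None


def category_enrichment(
    subset_flag: np.ndarray,
    category_flag: np.ndarray,
) -> tuple[float, float]:
    """Two-sided Fisher exact test of a gene category against a gene subset.

    Returns (odds ratio, p).  With a zero cell the odds ratio uses a 0.5
    continuity correction (Haldane-Anscombe); the p-value is exact either
    way.  Degenerate margins give p = 1.
    """
    subset = np.asarray(subset_flag, dtype=bool)
    cat = np.asarray(category_flag, dtype=bool)
    if subset.shape != cat.shape or subset.size == 0:
        raise ValueError("flags must be non-empty and aligned")
    a = int(np.sum(subset & cat))
    b = int(np.sum(subset & ~cat))
    c = int(np.sum(~subset & cat))
    d = int(np.sum(~subset & ~cat))
    table = np.array([[a, b], [c, d]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        import warnings

        warnings.warn("degenerate 2x2 margin; Fisher p is 1 by convention")
        return np.nan, 1.0
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p)


def structure_summary(
    records: pd.DataFrame,
    calls: pd.DataFrame,
) -> dict:
    """Exon/intron structure means per category and M+PM vs Z+PZ rank-sum tests.

    ``records`` has columns ``exon_count, exonic_length, intronic_length``
    indexed by feature; ``calls`` supplies the ``category`` column on the
    same ids.  Returns ``{"means": DataFrame, "tests": dict}`` where tests
    maps metric -> two-sided Mann-Whitney p (absent when a class is empty).
    """
    metrics = ["exon_count", "exonic_length", "intronic_length"]
    shared = records.index.intersection(calls.index)
    rec = records.loc[shared, metrics]
    cat = calls.loc[shared, "category"]
    means = rec.groupby(cat.to_numpy()).mean()
    maternal = rec[cat.isin(MATERNAL_CLASS)]
    zygotic = rec[cat.isin(ZYGOTIC_CLASS)]
    tests: dict[str, float | None] = {}
    for metric in metrics:
        if len(maternal) == 0 or len(zygotic) == 0:
            tests[metric] = None
            continue
        _, p = stats.mannwhitneyu(
            maternal[metric], zygotic[metric], alternative="two-sided"
        )
        tests[metric] = float(p)
    return {"means": means, "tests": tests}
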