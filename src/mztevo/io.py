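"""Reading, writing and deterministic aggregation of expression inputs.

All tabular interchange is plain UTF-8 TSV:

* expression: first column ``feature_id``, remaining columns sample ids;
* sample sheet: columns ``sample_id, species, stage, replicate[, sex]``;
* isoform map: columns ``isoform, gene``;
* ortholog table: first column ``ref_gene``, one column per species, empty
  string marking a missing or non-unique ortholog;
* annotations: columns ``gene, species, chromosome, muller, unannotated``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STAGES = ("stage2", "stage5")


class DataError(ValueError):
    pass


@dataclass
class ExpressionTable:
    """FPKM matrix (features x samples) with per-sample metadata.

    ``values`` is a DataFrame indexed by feature id with one column per
    sample; ``samples`` is indexed by sample id with columns
    ``species, stage, replicate`` (and optionally ``sex``).
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            self.samples = self.samples.loc[list(self.values.columns)]
        bad = ~np.isfinite(self.values.to_numpy(dtype=float))
        if bad.any():
            raise DataError("expression values must be finite")
        if (self.values.to_numpy() < 0).any():
            raise DataError("expression values must be non-negative")

    @property
    def species(self) -> list[str]:
        return sorted(self.samples["species"].unique())

    def replicates(self, species: str, stage: str) -> pd.DataFrame:
        """Feature x replicate FPKM sub-matrix for one (species, stage)."""
        cols = self.samples.index[
            (self.samples["species"] == species) & (self.samples["stage"] == stage)
        ]
        return self.values[list(cols)]


def read_sample_sheet(path: str) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "species", "stage", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise DataError(f"sample sheet missing columns: {sorted(missing)}")
    bad_stage = set(sheet["stage"]) - set(STAGES)
    if bad_stage:
        raise DataError(f"unknown stages in sample sheet: {sorted(bad_stage)}")
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise DataError(f"duplicate sample ids: {dups}")
    sheet["replicate"] = sheet["replicate"].astype(int)
    if (sheet["replicate"] < 1).any():
        raise DataError("replicate numbers must be positive integers")
    return sheet.set_index("sample_id")


def read_expression_table(path: str, sample_sheet: str | pd.DataFrame) -> ExpressionTable:
    """Read a wide FPKM TSV and join sample metadata.

    Every sample column must appear in the sheet; negative or non-numeric
    cells are rejected with the offending row and column named.
    """
    sheet = sample_sheet if isinstance(sample_sheet, pd.DataFrame) else read_sample_sheet(sample_sheet)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.columns[0] != "feature_id":
        # tolerate Cuffnorm-style first column (e.g. "tracking_id")
        raw = raw.rename(columns={raw.columns[0]: "feature_id"})
    raw = raw.set_index("feature_id")
    unknown = [c for c in raw.columns if c not in sheet.index]
    if unknown:
        raise DataError(f"sample column(s) absent from sample sheet: {unknown}")
    values = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        try:
            values[col] = raw[col].astype(float)
        except ValueError as exc:
            raise DataError(f"non-numeric FPKM in column {col!r}: {exc}") from exc
    arr = values.to_numpy()
    if not np.isfinite(arr).all() or (arr < 0).any():
        bad = np.argwhere(~(np.isfinite(arr) & (arr >= 0)))[0]
        raise DataError(
            f"invalid FPKM {arr[bad[0], bad[1]]!r} at feature "
            f"{values.index[bad[0]]!r}, sample {values.columns[bad[1]]!r}"
        )
    return ExpressionTable(values=values, samples=sheet.loc[list(values.columns)])


def write_expression_table(table: ExpressionTable, path: str) -> None:
    out = table.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_isoform_map(path: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"isoform", "gene"} <= set(df.columns):
        raise DataError("isoform map needs columns: isoform, gene")
    if df["isoform"].duplicated().any():
        raise DataError("isoform map assigns some isoform to multiple genes")
    return df.set_index("isoform")["gene"]


def aggregate_isoforms_to_genes(table: ExpressionTable, isoform_map: pd.Series) -> ExpressionTable:
    """Gene-level FPKM as the per-sample sum over each gene's isoforms."""
    missing = table.values.index.difference(isoform_map.index)
    if len(missing):
        raise DataError(f"isoforms absent from map: {list(missing[:5])}")
    genes = isoform_map.loc[table.values.index]
    summed = table.values.groupby(genes.to_numpy()).sum()
    summed.index.name = "feature_id"
    return ExpressionTable(values=summed, samples=table.samples)


def mean_by_condition(table: ExpressionTable) -> pd.DataFrame:
    """Mean replicate FPKM per (species, stage).

    Returns a DataFrame indexed by feature with MultiIndex columns
    (species, stage); conditions without samples are absent.
    """
    cols = {}
    for (sp, st), sub in table.samples.groupby(["species", "stage"], sort=True):
        cols[(sp, st)] = table.values[list(sub.index)].mean(axis=1)
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["species", "stage"])
    return out


def condition_by_species(conditions: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a (species, stage) condition matrix into per-species frames."""
    return {
        sp: conditions[sp]
        for sp in conditions.columns.get_level_values("species").unique()
    }


def read_ortholog_table(path: str) -> pd.DataFrame:
    """Ortholog groups: index ``ref_gene``, one column per species, NaN = blank."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "ref_gene":
        raise DataError("ortholog table must start with a ref_gene column")
    df = df.set_index("ref_gene")
    return df.replace("", np.nan)


def write_ortholog_table(orthologs: pd.DataFrame, path: str) -> None:
    out = orthologs.fillna("")
    out.index.name = "ref_gene"
    out.to_csv(path, sep="\t")


def read_annotations(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    need = {"gene", "species"}
    if not need <= set(df.columns):
        raise DataError("annotation table needs at least columns: gene, species")
    if "unannotated" in df.columns:
        df["unannotated"] = df["unannotated"].isin(("1", "true", "True", "yes"))
    return df


def group_species_count(orthologs: pd.DataFrame) -> pd.Series:
    return orthologs.notna().sum(axis=1)


def filter_ortholog_groups(orthologs: pd.DataFrame, min_species: int = 12) -> pd.DataFrame:
    """Keep groups with one-to-one orthologs in at least ``min_species`` species."""
    if min_species > orthologs.shape[1]:
        raise DataError(
            f"min_species={min_species} exceeds the {orthologs.shape[1]} species present"
        )
    return orthologs[group_species_count(orthologs) >= min_species]


def filter_autosomal(
    orthologs: pd.DataFrame,
    annotations: pd.DataFrame,
    removal_rules: list[tuple[str, str]],
) -> pd.DataFrame:
    """Drop every group with >= 1 ortholog matching a (species, chromosome-or-
    Muller-label) removal rule, e.g. sex-linked arms."""
    unknown = {sp for sp, _ in removal_rules} - set(orthologs.columns)
    if unknown:
        raise DataError(f"removal rules name unknown species: {sorted(unknown)}")
    drop = pd.Series(False, index=orthologs.index)
    for sp, label in removal_rules:
        ann = annotations[annotations["species"] == sp]
        flagged = set()
        for col in ("chromosome", "muller"):
            if col in ann.columns:
                flagged |= set(ann.loc[ann[col] == label, "gene"])
        drop |= orthologs[sp].isin(flagged)
    return orthologs[~drop]


def ortholog_matrix(
    conditions: dict[str, pd.DataFrame],
    orthologs: pd.DataFrame,
    stage: str,
) -> pd.DataFrame:
    """Mean FPKM at one stage per (ortholog group x species); NaN where blank.

    ``conditions`` maps species to per-species condition frames with stage
    columns indexed by species-local gene ids.
    """
    missing = [sp for sp in orthologs.columns if sp not in conditions]
    if missing:
        raise DataError(f"species in ortholog table but not in expression: {missing}")
    out = pd.DataFrame(index=orthologs.index, columns=orthologs.columns, dtype=float)
    for sp in orthologs.columns:
        ids = orthologs[sp]
        present = ids.notna()
        lookup = conditions[sp][stage]
        unknown_ids = set(ids[present]) - set(lookup.index)
        if unknown_ids:
            raise DataError(
                f"ortholog ids for {sp} missing from expression: "
                f"{sorted(unknown_ids)[:5]}"
            )
        out.loc[present, sp] = lookup.loc[ids[present]].to_numpy()
    return out
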