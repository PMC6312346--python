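"""Deeply conserved stage-restricted gene sets.

Given per-species category calls on ortholog groups (including a distant
outgroup), two nested conserved sets are defined for a stage-restricted
category (zygotic-only by default, maternal-only via the same machinery):

* loose set — the category in the outgroup and in at least one ingroup
  species;
* core set — the category in the outgroup, in the basal ingroup species,
  and in at least one member of a designated early-diverging subgenus set.

The mean number of *additional* ingroup species sharing the category
excludes the species used to establish membership: for the loose set the
outgroup plus one qualifying ingroup species; for the core set the
outgroup, the basal species and every qualifying subgenus member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

CATEGORY_CALL = {"zygotic_only": "Z", "maternal_only": "M"}


@dataclass(frozen=True)
class SpeciesRoleConfig:
    outgroup: str
    basal: str
    subgenus: tuple[str, ...]
    ingroup: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.subgenus:
            raise ValueError("subgenus set must be non-empty")
        if self.outgroup in self.ingroup:
            raise ValueError("outgroup cannot be an ingroup species")


def _call(category: str) -> str:
    return CATEGORY_CALL.get(category, category)


def _validate(calls: pd.DataFrame, roles: SpeciesRoleConfig) -> list[str]:
    known = set(calls.columns)
    referenced = {roles.outgroup, roles.basal, *roles.subgenus, *roles.ingroup}
    missing = referenced - known
    if missing:
        raise ValueError(f"roles reference unknown species: {sorted(missing)}")
    ingroup = list(roles.ingroup) if roles.ingroup else [
        c for c in calls.columns if c != roles.outgroup
    ]
    return ingroup


def loose_conserved_set(
    calls: pd.DataFrame,
    roles: SpeciesRoleConfig,
    category: str = "zygotic_only",
) -> pd.Index:
    """Groups with the category in the outgroup and >= 1 ingroup species."""
    ingroup = _validate(calls, roles)
    call = _call(category)
    in_out = calls[roles.outgroup] == call
    in_any = (calls[ingroup] == call).any(axis=1)
    return calls.index[in_out & in_any]


def core_conserved_set(
    calls: pd.DataFrame,
    roles: SpeciesRoleConfig,
    category: str = "zygotic_only",
) -> pd.Index:
    """Groups with the category in outgroup AND basal AND >= 1 subgenus species."""
    _validate(calls, roles)
    call = _call(category)
    keep = (
        (calls[roles.outgroup] == call)
        & (calls[roles.basal] == call)
        & (calls[list(roles.subgenus)] == call).any(axis=1)
    )
    return calls.index[keep]


def mean_additional_species(
    gene_set: pd.Index,
    calls: pd.DataFrame,
    roles: SpeciesRoleConfig,
    category: str = "zygotic_only",
    membership: str = "loose",
) -> float | None:
    """Mean count of other ingroup species sharing the category.

    Species used as membership criteria are excluded per gene (see module
    docstring).  Unknown (NaN) calls count in neither numerator nor
    denominator.  Returns None for an empty gene set.
    """
    if len(gene_set) == 0:
        return None
    ingroup = _validate(calls, roles)
    call = _call(category)
    flags = calls.loc[gene_set, ingroup] == call
    counts = flags.sum(axis=1).astype(float)
    if membership == "loose":
        counts -= 1  # the single qualifying ingroup species
    elif membership == "core":
        defining = [roles.basal, *roles.subgenus]
        counts -= (calls.loc[gene_set, defining] == call).sum(axis=1)
    else:
        raise ValueError(f"unknown membership rule {membership!r}")
    if (counts < 0).any():
        raise ValueError("gene set contains genes outside the membership rule")
    return float(counts.mean())


def conservation_table(
    calls: pd.DataFrame,
    roles: SpeciesRoleConfig,
    category: str = "zygotic_only",
) -> pd.DataFrame:
    """Per-gene summary: ingroup species count plus core/loose flags."""
    ingroup = _validate(calls, roles)
    call = _call(category)
    loose = set(loose_conserved_set(calls, roles, category))
    core = set(core_conserved_set(calls, roles, category))
    return pd.DataFrame(
        {
            "n_species": (calls[ingroup] == call).sum(axis=1),
            "core_flag": calls.index.isin(core),
            "loose_flag": calls.index.isin(loose),
        },
        index=calls.index,
    )
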