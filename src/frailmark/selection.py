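"""In silico candidate harvesting and knowledge-base filtering.

The funnel: harvest the union of genes from a chosen list of gene-set terms
(GMT format, standing in for GO biological processes tied to muscle aging),
then intersect with a curated biomarker knowledge base.  A gene is
*described* if it carries at least one record of any kind, and *qualified*
if at least one single record simultaneously matches the population,
sample-type and validity facets and shares at least one value with the
allowed conditions and roles.  Values within a facet are alternatives (OR);
facets combine conjunctively (AND).  Matching is case-insensitive after
whitespace normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


class GMTParseError(ValueError):
    """Malformed GMT line (fewer than three tab-separated fields)."""


@dataclass
class GeneSetCollection:
    """term_id -> (term_name, frozenset of member genes)."""

    sets: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def all_genes(self) -> set:
        out: set = set()
        for _, members in self.sets.values():
            out |= members
        return out


@dataclass(frozen=True)
class FilterCriteria:
    """Allowed values per knowledge-base facet; every set must be non-empty."""

    allowed_population: frozenset
    allowed_sample_type: frozenset
    allowed_validity: frozenset
    allowed_conditions: frozenset
    allowed_roles: frozenset

    def __post_init__(self) -> None:
        for name in (
            "allowed_population", "allowed_sample_type", "allowed_validity",
            "allowed_conditions", "allowed_roles",
        ):
            vals = getattr(self, name)
            object.__setattr__(self, name, frozenset(_norm(v) for v in vals))
            if not getattr(self, name):
                raise ValueError(f"FilterCriteria.{name} must be non-empty (would reject everything)")

    @classmethod
    def from_dict(cls, d: dict) -> "FilterCriteria":
        return cls(
            allowed_population=frozenset(d["population"]),
            allowed_sample_type=frozenset(d["sample_type"]),
            allowed_validity=frozenset(d["validity"]),
            allowed_conditions=frozenset(d["conditions"]),
            allowed_roles=frozenset(d["roles"]),
        )


def _norm(value: str) -> str:
    return " ".join(str(value).split()).lower()


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one term per line, ``term<TAB>description<TAB>member...``.

    Duplicate members within a term are collapsed; blank lines are skipped.
    Raises :class:`GMTParseError` with the 1-based line number on malformed
    lines.
    """
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            term_id, name, *members = fields
            members = frozenset(m for m in members if m)
            sets[term_id] = (name, members)
    return GeneSetCollection(sets=sets)


def harvest_genes(collection: GeneSetCollection, term_ids) -> set:
    """Union of member sets over ``term_ids`` (order-independent).

    Raises ``KeyError`` naming the first unknown term id.
    """
    out: set = set()
    for term_id in term_ids:
        if term_id not in collection.sets:
            raise KeyError(f"unknown gene-set term id: {term_id!r}")
        out |= collection.sets[term_id][1]
    return out


def read_knowledge_base(path) -> pd.DataFrame:
    """Read a knowledge-base TSV (multi-valued fields '|'-separated)."""
    kb = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"gene_symbol", "population", "sample_type", "validity", "conditions", "roles"}
    missing = required - set(kb.columns)
    if missing:
        raise ValueError(f"knowledge base {path} missing columns: {sorted(missing)}")
    return kb


def _split_multi(value: str) -> set:
    return {_norm(v) for v in str(value).split("|") if v.strip()}


def filter_biomarkers(
    genes: set, kb: pd.DataFrame, criteria: FilterCriteria
) -> tuple[set, set]:
    """Apply the knowledge-base funnel to ``genes``.

    Returns ``(described_set, qualified_set)``: genes with at least one
    record of any kind, and genes with at least one record that matches all
    five facets of ``criteria`` on its own.  ``qualified ⊆ described ⊆ genes``.
    """
    if not genes:
        raise ValueError("filter_biomarkers requires a non-empty gene set")
    genes = set(genes)
    sub = kb[kb["gene_symbol"].isin(genes)]
    described = set(sub["gene_symbol"])
    if sub.empty:
        return described, set()

    pop_ok = sub["population"].map(_norm).isin(criteria.allowed_population)
    type_ok = sub["sample_type"].map(_norm).isin(criteria.allowed_sample_type)
    val_ok = sub["validity"].map(_norm).isin(criteria.allowed_validity)
    cond_ok = sub["conditions"].map(lambda v: bool(_split_multi(v) & criteria.allowed_conditions))
    role_ok = sub["roles"].map(lambda v: bool(_split_multi(v) & criteria.allowed_roles))
    qualifying = pop_ok & type_ok & val_ok & cond_ok & role_ok
    qualified = set(sub.loc[qualifying, "gene_symbol"])
    return described, qualified


def qualifying_record_counts(kb: pd.DataFrame, criteria: FilterCriteria) -> pd.Series:
    """Number of qualifying records per gene (genes with >=1 such record)."""
    if kb.empty:
        return pd.Series(dtype=int)
    pop_ok = kb["population"].map(_norm).isin(criteria.allowed_population)
    type_ok = kb["sample_type"].map(_norm).isin(criteria.allowed_sample_type)
    val_ok = kb["validity"].map(_norm).isin(criteria.allowed_validity)
    cond_ok = kb["conditions"].map(lambda v: bool(_split_multi(v) & criteria.allowed_conditions))
    role_ok = kb["roles"].map(lambda v: bool(_split_multi(v) & criteria.allowed_roles))
    ok = kb[pop_ok & type_ok & val_ok & cond_ok & role_ok]
    return ok.groupby("gene_symbol").size()
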