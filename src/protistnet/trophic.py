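"""Rule-based trophic functional annotation of protist OTUs.

OTUs are assigned to four trophic categories — autotroph, heterotroph,
mixotroph, parasite — or NA, by matching their ranked lineage against a
rule table. Rules apply at a stated rank (species > genus > family > group)
and the most specific matching rule wins. The shipped default rules encode
the group-level conventions used for coastal protist metabarcoding surveys:
among chloroplast-bearing groups only diatoms (Bacillariophyta) and
Mamiellophyceae are scored as strict autotrophs, all other plastid-bearing
groups as mixotrophs; Syndiniales, Labyrinthulea and Oomycota as parasites;
aplastidic grazer groups as heterotrophs; unresolved placeholder taxa as NA.
Everything finer (species-level literature calls) is user data supplied as
an extra rule TSV, not code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .otu import OtuTable, OtuTableError, check_metadata_binding

logger = logging.getLogger(__name__)

CATEGORIES = ("autotroph", "heterotroph", "mixotroph", "parasite", "NA")
RANK_SPECIFICITY = {"species": 0, "genus": 1, "family": 2, "group": 3}


@dataclass(frozen=True)
class TrophicRule:
    taxon_pattern: str
    rank: str
    category: str

    def __post_init__(self) -> None:
        if self.rank not in RANK_SPECIFICITY:
            raise ValueError(f"unknown rank {self.rank!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def default_rules() -> list[TrophicRule]:
    """The shipped group-level rule table."""
    with resources.files("protistnet.data").joinpath("trophic_rules.tsv").open() as fh:
        return read_rules(fh)


def read_rules(source) -> list[TrophicRule]:
    df = pd.read_csv(source, sep="\t", dtype=str, comment="#")
    needed = {"taxon", "rank", "category"}
    if not needed <= set(df.columns):
        raise OtuTableError(f"rule table needs columns {sorted(needed)}")
    rules = [TrophicRule(r.taxon, r.rank, r.category) for r in df.itertuples()]
    validate_rules(rules)
    return rules


def validate_rules(rules: list[TrophicRule]) -> None:
    """Conflicting rules at the same (taxon, rank) are a loud error."""
    seen: dict[tuple[str, str], str] = {}
    for rule in rules:
        key = (rule.taxon_pattern.lower(), rule.rank)
        if key in seen and seen[key] != rule.category:
            raise OtuTableError(
                f"conflicting trophic rules for {rule.taxon_pattern!r} at rank "
                f"{rule.rank}: {seen[key]} vs {rule.category}"
            )
        seen[key] = rule.category


def assign_trophic(
    taxonomy: dict[str, str], rules: list[TrophicRule] | None = None
) -> dict[str, str]:
    """Map each OTU's semicolon-joined lineage to a trophic category.

    The most specific matching rule (species > genus > family > group) wins;
    lineages matching no rule, and empty lineages, get NA. Assignment is
    independent of the rule list's order.
    """
    if rules is None:
        rules = default_rules()
    validate_rules(rules)
    # index rules by lowercase pattern for token matching
    by_pattern: dict[str, list[TrophicRule]] = {}
    for rule in rules:
        by_pattern.setdefault(rule.taxon_pattern.lower(), []).append(rule)
    out: dict[str, str] = {}
    for otu, lineage in taxonomy.items():
        if not lineage or not str(lineage).strip():
            logger.warning("OTU %s has an empty lineage -> NA", otu)
            out[otu] = "NA"
            continue
        tokens = [t.strip() for t in str(lineage).split(";") if t.strip()]
        best: TrophicRule | None = None
        for tok in tokens:
            for rule in by_pattern.get(tok.lower(), []):
                if best is None or (
                    RANK_SPECIFICITY[rule.rank] < RANK_SPECIFICITY[best.rank]
                ):
                    best = rule
        out[otu] = best.category if best is not None else "NA"
    return out


def trophic_composition(
    table: OtuTable, metadata: pd.DataFrame, categories: dict[str, str]
) -> pd.DataFrame:
    """Relative read abundance per trophic category per (habitat, date).

    Fractions include NA and sum to 1 within each (habitat, date) group.
    """
    meta = check_metadata_binding(table, metadata)
    missing = [o for o in table.otu_ids if o not in categories]
    if missing:
        raise OtuTableError(
            f"{len(missing)} OTUs without a trophic category (e.g. {missing[:3]})"
        )
    cat = pd.Series({o: categories[o] for o in table.otu_ids})
    rows = []
    for (habitat, date), grp in meta.groupby(["habitat", "date"], sort=False):
        samples = grp["sample_id"].tolist()
        reads = table.counts[samples].sum(axis=1)
        total = float(reads.sum())
        if total == 0:
            raise OtuTableError(f"group (habitat={habitat}, date={date}) has no reads")
        rec = {"habitat": habitat, "date": date}
        for c in CATEGORIES:
            rec[c] = float(reads[cat == c].sum() / total)
        rows.append(rec)
    return pd.DataFrame(rows).set_index(["habitat", "date"])
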