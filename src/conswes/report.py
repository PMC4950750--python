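"""Cohort-level accounting: diagnostic categories, rates, phenotype tallies.

Each family receives exactly one diagnostic category.  The known-gene rate
sums the three known-gene categories; the overall potential diagnostic rate
additionally counts families with a novel candidate gene.  Phenotype groups
may overlap, so group percentages need not sum to 100.

Percentages are reported both at one decimal and rounded half-up to an
integer; where a published figure rounds differently from half-up, the exact
one-decimal value makes the discrepancy visible instead of hiding it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = [
    "FamilyOutcome",
    "CATEGORIES",
    "KNOWN_GENE_CATEGORIES",
    "PHENOTYPE_GROUPS",
    "round_half_up",
    "diagnostic_rates",
    "phenotype_tallies",
    "read_outcomes",
    "summary_text",
]

CATEGORIES = (
    "known_variant_known_gene",
    "novel_variant_known_gene",
    "known_gene_phenotypic_expansion",
    "novel_candidate_gene",
    "unsolved",
)
KNOWN_GENE_CATEGORIES = CATEGORIES[:3]

PHENOTYPE_GROUPS = (
    "syndromic_brain_malformation",
    "nonsyndromic_brain_malformation",
    "syndromic_DD_ID",
    "nonsyndromic_DD_ID",
    "corpus_callosum",
    "cortical_dysgenesis",
    "microcephaly",
    "hindbrain",
    "white_matter",
)
STRUCTURAL_GROUPS = PHENOTYPE_GROUPS[:2] + PHENOTYPE_GROUPS[4:]


@dataclass(frozen=True)
class FamilyOutcome:
    family_id: str
    category: str
    phenotype_groups: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown diagnostic category {self.category!r}")
        bad = set(self.phenotype_groups) - set(PHENOTYPE_GROUPS)
        if bad:
            raise ValueError(f"unknown phenotype groups {sorted(bad)}")


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties away from zero (half-up)."""
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def _pct(count: int, n: int) -> tuple[float, int]:
    pct = 100.0 * count / n
    return round(pct, 1), round_half_up(pct)


def diagnostic_rates(outcomes: list[FamilyOutcome]) -> pd.DataFrame:
    """Per-category counts/percentages plus the two aggregate rates.

    Rows: one per category, then ``known_gene`` (the three known-gene
    categories combined) and ``overall_potential`` (known-gene plus novel
    candidate families).  Raises on an empty cohort.
    """
    n = len(outcomes)
    if n == 0:
        raise ValueError("empty cohort: no family outcomes")
    seen = [o.family_id for o in outcomes]
    if len(set(seen)) != n:
        raise ValueError("duplicate family outcomes")
    counts = {c: 0 for c in CATEGORIES}
    for o in outcomes:
        counts[o.category] += 1
    rows = []
    for cat in CATEGORIES:
        p1, pi = _pct(counts[cat], n)
        rows.append((cat, counts[cat], p1, pi))
    known = sum(counts[c] for c in KNOWN_GENE_CATEGORIES)
    overall = known + counts["novel_candidate_gene"]
    for label, cnt in (("known_gene", known), ("overall_potential", overall)):
        p1, pi = _pct(cnt, n)
        rows.append((label, cnt, p1, pi))
    return pd.DataFrame(rows, columns=["category", "count", "percent", "percent_rounded"])


def phenotype_tallies(outcomes: list[FamilyOutcome]) -> pd.DataFrame:
    """Per-group counts and percentages over all families (groups overlap)."""
    n = len(outcomes)
    rows = []
    for group in PHENOTYPE_GROUPS:
        cnt = sum(group in o.phenotype_groups for o in outcomes)
        p1, pi = _pct(cnt, n) if n else (0.0, 0)
        rows.append((group, cnt, p1, pi))
    structural = sum(
        bool(set(o.phenotype_groups) & set(STRUCTURAL_GROUPS)) for o in outcomes
    )
    ddid_only = n - structural
    for label, cnt in (("any_structural_malformation", structural), ("dd_id_only", ddid_only)):
        p1, pi = _pct(cnt, n) if n else (0.0, 0)
        rows.append((label, cnt, p1, pi))
    return pd.DataFrame(rows, columns=["group", "count", "percent", "percent_rounded"])


def read_outcomes(path) -> list[FamilyOutcome]:
    """Read an outcomes TSV (family_id, category, phenotype_groups '|'-joined)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for r in df.itertuples(index=False):
        groups = frozenset(g for g in r.phenotype_groups.split("|") if g)
        out.append(FamilyOutcome(r.family_id, r.category, groups))
    return out


def summary_text(outcomes: list[FamilyOutcome]) -> str:
    """Human-readable cohort summary."""
    rates = diagnostic_rates(outcomes)
    tallies = phenotype_tallies(outcomes)
    n = len(outcomes)
    get = lambda cat: rates.loc[rates["category"] == cat].iloc[0]
    known = get("known_gene")
    overall = get("overall_potential")
    lines = [
        f"Cohort of {n} families.",
        f"Molecular diagnosis in known disease genes: {known['count']}/{n} "
        f"({known['percent']:.1f} %).",
        f"Potential molecular diagnostic rate incl. novel candidates: "
        f"{overall['count']}/{n} ({overall['percent']:.1f} %).",
        "",
        "Per-category counts:",
    ]
    for cat in CATEGORIES:
        row = get(cat)
        lines.append(f"  {cat}: {row['count']} ({row['percent']:.1f} %)")
    lines.append("")
    lines.append("Phenotype groups (families may belong to several):")
    for r in tallies.itertuples(index=False):
        lines.append(f"  {r.group}: {r.count} ({r.percent:.1f} %)")
    return "\n".join(lines) + "\n"
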