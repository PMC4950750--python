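"""Weighted evidence scoring of novel candidate disease genes.

Eight boolean criteria, each with a fixed weight, sum to a 0-13 score:

====  ============================================================  ======
 key   criterion                                                    weight
====  ============================================================  ======
  a    gene found in multiple families with similar phenotypes        3
  b    human interactors/paralogs with overlapping features           2
  c    animal models of the gene/interactors with overlapping         2
       features
  d    genomic region associated with the phenotype                   1
  e    loss-of-function variant                                       2
  f    predicted deleterious by multiple programs                     1
  g    rare in multiple databases                                     1
  h    expressed in the affected tissues/organs                       1
====  ============================================================  ======

Variants in novel candidate genes are never classified beyond the
uncertain-significance family of labels, regardless of evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

__all__ = [
    "CriterionVector",
    "CandidateScore",
    "VariantClassification",
    "CRITERION_WEIGHTS",
    "MAX_SCORE",
    "score_candidate",
    "rank_cohort",
    "classify_variant",
]

CRITERION_WEIGHTS: dict[str, int] = {
    "multiple_families": 3,
    "human_interactor_paralog_phenotype": 2,
    "animal_model_phenotype": 2,
    "genomic_region_association": 1,
    "lof_variant": 2,
    "multi_program_deleterious": 1,
    "rare_in_multiple_databases": 1,
    "expressed_in_affected_tissue": 1,
}
MAX_SCORE = sum(CRITERION_WEIGHTS.values())  # 13

KNOWN_GENE_LABELS = (
    "pathogenic",
    "likely_pathogenic",
    "VUS",
    "VUS_favoring_likely_pathogenic",
    "likely_benign",
    "benign",
)
NOVEL_GENE_LABELS = ("VUS", "VUS_favoring_likely_pathogenic")


@dataclass(frozen=True)
class CriterionVector:
    """Explicit truth value for each of the eight criteria (no missing)."""

    multiple_families: bool = False
    human_interactor_paralog_phenotype: bool = False
    animal_model_phenotype: bool = False
    genomic_region_association: bool = False
    lof_variant: bool = False
    multi_program_deleterious: bool = False
    rare_in_multiple_databases: bool = False
    expressed_in_affected_tissue: bool = False

    def as_dict(self) -> dict[str, bool]:
        return {f.name: bool(getattr(self, f.name)) for f in fields(self)}


@dataclass(frozen=True)
class CandidateScore:
    gene: str
    criteria: CriterionVector
    total_points: int
    rank_band: str  # red > orange > yellow > green


@dataclass(frozen=True)
class VariantClassification:
    label: str
    novel_gene: bool


def _band(total: int) -> str:
    # quartiles of the 0-13 range; presentation only
    if total >= 10:
        return "red"
    if total >= 7:
        return "orange"
    if total >= 4:
        return "yellow"
    return "green"


def score_candidate(gene: str, cv: CriterionVector) -> CandidateScore:
    """Weighted sum of the criterion booleans (0-13)."""
    total = sum(w for name, w in CRITERION_WEIGHTS.items() if getattr(cv, name))
    return CandidateScore(gene=gene, criteria=cv, total_points=total, rank_band=_band(total))


def rank_cohort(scores: list[CandidateScore]) -> list[CandidateScore]:
    """Descending by score; ties broken alphabetically by gene symbol."""
    return sorted(scores, key=lambda s: (-s.total_points, s.gene))


def classify_variant(known_gene: bool, evidence_label: str) -> VariantClassification:
    """Attach a clinical-interpretation label.

    Known genes pass the supplied label through; variants in novel candidate
    genes are confined to VUS / VUS-favoring-likely-pathogenic, and requesting
    a definitive label for one is an error.
    """
    if evidence_label not in KNOWN_GENE_LABELS:
        raise ValueError(f"unknown classification label {evidence_label!r}")
    if known_gene:
        return VariantClassification(evidence_label, novel_gene=False)
    if evidence_label not in NOVEL_GENE_LABELS:
        raise ValueError(
            f"variants in novel candidate genes are restricted to {NOVEL_GENE_LABELS}; "
            f"got {evidence_label!r}"
        )
    return VariantClassification(evidence_label, novel_gene=True)
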