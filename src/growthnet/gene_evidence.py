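"""Gene-level evidence scoring, combined-score merging and confidence tiers.

Each gene carries 8 boolean evidence categories (association studies, copy
number variants, growth-related GO terms, protein-protein interaction with a
growth gene, mouse model, zebrafish model, a prior exome study, chondrocyte
expression).  The count of true categories is merged with the best surviving
variant class per family into a combined score on a 1-4 scale:

    score = clamp(1 + (variant_class - 3) + [categories >= 3] + [categories >= 6], 1, 4)

exposed as an explicit (class x category-count) lookup table so an
alternative decision table can be dropped in.  A gene's score is reported as
the min-max range across its families and as the maximum.

Genes are tiered: high confidence requires at least 2 independent families
and a maximum combined score >= 3; otherwise a gene with score >= 2 or any
functional evidence is a medium-confidence candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import log_filter, percent

EVIDENCE_CATEGORIES = (
    "association_study",
    "copy_number_variant",
    "go_growth_term",
    "ppi_growth_gene",
    "mouse_model",
    "zebrafish_model",
    "prior_exome_study",
    "chondrocyte_expression",
)

_TRUTHY = {"1", "true", "yes", "t", "y"}
_FALSY = {"0", "false", "no", "f", "n"}


@dataclass(frozen=True)
class GeneEvidenceProfile:
    gene: str
    flags: Mapping[str, bool]

    @property
    def category_count(self) -> int:
        return sum(bool(self.flags[c]) for c in EVIDENCE_CATEGORIES)


@dataclass
class CandidateGene:
    """Per-gene aggregate across families (one output row of the pipeline)."""

    gene: str
    n_families: int
    class_tally: Mapping[int, int]  # {3: n_VUS, 4: n_likely_path, 5: n_path}
    category_count: int
    score_min: int
    score_max: int
    tier: str = "unassigned"
    previously_reported: bool = False
    families: frozenset = frozenset()

    def __post_init__(self):
        if self.n_families < 1:
            raise ValueError(f"{self.gene}: candidate without any family")
        if not (1 <= self.score_min <= self.score_max <= 4):
            raise ValueError(f"{self.gene}: combined score outside [1, 4]")


@dataclass
class TierThresholds:
    min_families_high: int = 2
    high_score_min: int = 3
    medium_score_min: int = 2


DEFAULT_TIERS = TierThresholds()


def build_evidence_profile(gene: str, row: Mapping[str, object]) -> GeneEvidenceProfile:
    """Parse one evidence-table row into a profile; errors name gene+column."""
    flags = {}
    for category in EVIDENCE_CATEGORIES:
        if category not in row:
            raise ValueError(f"gene {gene}: missing evidence column {category!r}")
        raw = row[category]
        if isinstance(raw, (bool,)) or raw in (0, 1):
            flags[category] = bool(raw)
            continue
        text = str(raw).strip().lower()
        if text in _TRUTHY:
            flags[category] = True
        elif text in _FALSY:
            flags[category] = False
        else:
            raise ValueError(f"gene {gene}: unparseable boolean {raw!r} in column {category!r}")
    return GeneEvidenceProfile(gene=gene, flags=flags)


def default_score_table() -> dict[tuple[int, int], int]:
    """The combined-score decision table as an explicit 3x9 lookup."""
    table = {}
    for variant_class in (3, 4, 5):
        for categories in range(9):
            raw = 1 + (variant_class - 3) + (categories >= 3) + (categories >= 6)
            table[(variant_class, categories)] = min(max(raw, 1), 4)
    return table


DEFAULT_SCORE_TABLE = default_score_table()


def combine_scores(
    variant_class: int,
    category_count: int,
    table: Mapping[tuple[int, int], int] | None = None,
) -> int:
    """Per-family combined score from the best variant class and category count."""
    if variant_class < 3:
        raise ValueError("benign variants must be excluded before scoring")
    if variant_class > 5:
        raise ValueError(f"variant class {variant_class} outside 3..5")
    if not 0 <= category_count <= 8:
        raise ValueError(f"category count {category_count} outside 0..8")
    table = table or DEFAULT_SCORE_TABLE
    return table[(variant_class, category_count)]


def gene_score_range(
    best_class_per_family: Mapping[str, int],
    category_count: int,
    table: Mapping[tuple[int, int], int] | None = None,
) -> tuple[int, int]:
    """(min, max) combined score across a gene's families."""
    if not best_class_per_family:
        raise ValueError("no families")
    scores = [
        combine_scores(c, category_count, table) for c in best_class_per_family.values()
    ]
    return min(scores), max(scores)


def aggregate_candidates(
    classified: pd.DataFrame,
    profiles: Mapping[str, GeneEvidenceProfile],
    table: Mapping[tuple[int, int], int] | None = None,
) -> list[CandidateGene]:
    """Collapse surviving (class >= III) variants into per-gene candidates.

    ``classified`` needs FAMILY, GENE and variant_class columns; genes absent
    from ``profiles`` get category count 0.
    """
    surviving = classified[classified.variant_class >= 3]
    log_filter("gene_evidence.aggregate_candidates", len(classified), len(surviving))
    candidates = []
    for gene, group in surviving.groupby("GENE", sort=True):
        best = group.groupby("FAMILY").variant_class.max().to_dict()
        categories = profiles[gene].category_count if gene in profiles else 0
        lo, hi = gene_score_range(best, categories, table)
        tally = group.variant_class.value_counts().to_dict()
        candidates.append(
            CandidateGene(
                gene=gene,
                n_families=len(best),
                class_tally={c: int(tally.get(c, 0)) for c in (3, 4, 5)},
                category_count=categories,
                score_min=lo,
                score_max=hi,
                families=frozenset(best),
            )
        )
    return candidates


def tier_genes(
    candidates: Sequence[CandidateGene],
    thresholds: TierThresholds = DEFAULT_TIERS,
) -> list[CandidateGene]:
    """Assign high/medium/rejected confidence tiers (deterministic, idempotent)."""
    tiered = []
    for cand in candidates:
        if (
            cand.n_families >= thresholds.min_families_high
            and cand.score_max >= thresholds.high_score_min
        ):
            tier = "high"
        elif cand.score_max >= thresholds.medium_score_min or cand.category_count > 0:
            tier = "medium"
        else:
            tier = "rejected"
        tiered.append(replace(cand, tier=tier))
    return tiered


def summarize_cohort(
    candidates: Sequence[CandidateGene],
    n_families_total: int,
    *,
    n_families_with_candidate: int | None = None,
    classified: pd.DataFrame | None = None,
) -> dict:
    """Cohort bookkeeping: tier counts, yield and reported-gene percentages.

    Families with a candidate are counted from the candidates' family-id sets
    when available, or passed explicitly (fixture rows carry only counts).
    Mode and consequence fractions are derived from the classified-variant
    table when one is supplied.
    """
    accepted = [c for c in candidates if c.tier in ("high", "medium", "unassigned")]
    if n_families_with_candidate is None:
        families = frozenset().union(*(c.families for c in accepted)) if accepted else frozenset()
        n_families_with_candidate = len(families)
    n_reported = sum(1 for c in accepted if c.previously_reported)
    summary = {
        "n_families_total": n_families_total,
        "n_families_with_candidate": n_families_with_candidate,
        "pct_families_with_candidate": percent(n_families_with_candidate, n_families_total),
        "n_candidate_genes": len(accepted),
        "n_high_confidence": sum(1 for c in candidates if c.tier == "high"),
        "n_medium_confidence": sum(1 for c in candidates if c.tier == "medium"),
        "n_rejected": sum(1 for c in candidates if c.tier == "rejected"),
        "n_previously_reported": n_reported,
        "pct_previously_reported": percent(n_reported, len(accepted), 1) if accepted else 0.0,
    }
    if classified is not None and len(classified):
        surviving = classified[classified.variant_class >= 3]
        summary["inheritance_mode_fractions"] = _label_fractions(surviving.inheritance)
        summary["consequence_fractions"] = _label_fractions(surviving.CSQ)
    return summary


def _label_fractions(column: pd.Series) -> dict[str, float]:
    labels = column.astype(str).str.split(",").explode()
    labels = labels[~labels.isin(["unresolved", "mendel_error"])]
    if labels.empty:
        return {}
    counts = labels.value_counts()
    return {k: round(float(v / counts.sum()), 4) for k, v in counts.items()}
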