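"""Trio inheritance detection and five-class variant classification.

Inheritance patterns in a child/mother/father trio:

* de novo — the child carries an alternate allele absent from both parents
  (heterozygous on autosomes; hemizygous alternate on the male X);
* homozygous — child homozygous alternate with both parents heterozygous
  carriers;
* compound heterozygous — at least two heterozygous variants in the same gene
  with opposite parental origin (origin is taken from the parents' genotypes
  only; a variant carried by both parents is phase-unknown and not counted);
* X-linked recessive — X-chromosome variant, hemizygous alternate male child,
  heterozygous mother, reference father;
* dominant inherited — the child is heterozygous and at least one parent
  carries the allele.

Mendelian-inconsistent genotypes (e.g. a homozygous-alternate child with a
homozygous-reference parent) are flagged ``mendel_error`` and excluded from
pattern labels.  Families without parental genotypes pass through as
``unresolved`` for the affected-only mode-of-inheritance screen.

Variants are then classified on the ACMG-style five-class scale (I benign ...
V pathogenic) by a configurable, frequency-dominant rule table; classes I and
II are excluded before any gene-level evaluation.  The pseudoautosomal
regions of X are ignored: every X variant is treated as hemizygous in males.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from ._util import log_filter

MALE, FEMALE = 1, 2

CONSEQUENCES = (
    "missense", "nonsense", "frameshift", "splice", "inframe_indel",
    "synonymous", "other",
)
LOF_CONSEQUENCES = frozenset({"nonsense", "frameshift", "splice"})
DENOVO_LIKE = frozenset({"de_novo", "homozygous", "x_linked_recessive", "compound_het"})

CLASS_NAMES = {1: "benign", 2: "likely_benign", 3: "VUS", 4: "likely_pathogenic", 5: "pathogenic"}


@dataclass(frozen=True)
class VariantRecord:
    """One called variant in one family, with genotypes and annotations."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    af: float | None  # population allele frequency; None = absent from controls
    genotypes: Mapping[str, str]  # role ("child"/"mother"/"father") -> GT string
    family_id: str

    def __post_init__(self):
        if self.af is not None and not 0 <= self.af <= 1:
            raise ValueError(f"af {self.af} outside [0, 1]")
        if self.pos < 1:
            raise ValueError(f"pos {self.pos} must be 1-based")

    @property
    def on_x(self) -> bool:
        return str(self.chrom).removeprefix("chr").upper() == "X"


@dataclass
class ClassifiedVariant:
    variant: VariantRecord
    inheritance: frozenset
    variant_class: int
    structural_override: bool = False
    note: str = ""

    def __post_init__(self):
        if self.variant_class not in (1, 2, 3, 4, 5):
            raise ValueError(f"variant_class {self.variant_class} outside 1..5")


@dataclass
class RuleTable:
    """Frequency-dominant classification rules (ACMG-like defaults).

    class I when af >= ``benign_af``; class II when ``likely_benign_af`` <=
    af < ``benign_af`` and the consequence is not loss-of-function; class V
    for loss-of-function with a de-novo-like pattern; class IV for inherited
    loss-of-function or de novo missense; class III otherwise.  Missing af is
    treated as 0 (absence from controls is the strongest rarity signal).
    """

    benign_af: float = 0.01
    likely_benign_af: float = 0.001
    lof_consequences: frozenset = LOF_CONSEQUENCES
    denovo_like: frozenset = DENOVO_LIKE

    @classmethod
    def from_yaml(cls, path) -> "RuleTable":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {"benign_af", "likely_benign_af", "lof_consequences", "denovo_like"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown rule-table keys: {sorted(unknown)}")
        for key in ("lof_consequences", "denovo_like"):
            if key in data:
                data[key] = frozenset(data[key])
        return cls(**data)


DEFAULT_RULES = RuleTable()


# --- genotype helpers --------------------------------------------------------

def parse_genotype(gt: str) -> tuple | None:
    """Parse a GT string to a tuple of allele indices; None when missing.

    Diploid calls are "0/0", "0/1", "1/1" (| accepted); hemizygous calls are
    single-allele "0" or "1"; "." or "./." is missing.
    """
    gt = gt.strip()
    if gt in ("", ".", "./.", ".|."):
        return None
    alleles = gt.replace("|", "/").split("/")
    if len(alleles) not in (1, 2) or any(a not in ("0", "1") for a in alleles):
        raise ValueError(f"bad genotype string {gt!r}")
    return tuple(int(a) for a in alleles)


def _carries_alt(alleles) -> bool:
    return alleles is not None and 1 in alleles


def _is_het(alleles) -> bool:
    return alleles is not None and len(alleles) == 2 and sorted(alleles) == [0, 1]


def _is_hom_alt(alleles) -> bool:
    return alleles is not None and all(a == 1 for a in alleles)


def _is_hom_ref(alleles) -> bool:
    return alleles is not None and all(a == 0 for a in alleles)


def _mendel_inconsistent(child, mother, father, male_hemi: bool) -> bool:
    if child is None:
        return False
    if male_hemi:
        # a hemizygous boy's X allele comes from the mother; a reference call
        # with a homozygous-alternate mother is impossible (the alternate
        # child / reference mother case is a legal de novo)
        return mother is not None and _is_hom_ref(child) and _is_hom_alt(mother)
    checks = []
    if _is_hom_alt(child) and len(child) == 2:
        # both alleles must come from carrier parents
        checks.append(mother is not None and not _carries_alt(mother))
        checks.append(father is not None and not _carries_alt(father))
    if _is_hom_ref(child) and len(child) == 2:
        checks.append(mother is not None and _is_hom_alt(mother))
        checks.append(father is not None and _is_hom_alt(father))
    if _is_het(child):
        # two homozygous-alternate parents force a homozygous child; two
        # reference parents with a het child is a legal de novo
        checks.append(
            mother is not None and father is not None
            and _is_hom_alt(mother) and _is_hom_alt(father)
        )
    return any(checks)


# --- operations --------------------------------------------------------------

def detect_inheritance(
    variants: Sequence[VariantRecord],
    *,
    child_sex: int,
    has_parents: bool = True,
) -> list[frozenset]:
    """Label each variant of one family/gene group with inheritance patterns.

    Returns one (possibly multi-element) label set per input variant, in
    order.  Affected-only families yield ``{"unresolved"}`` throughout.
    """
    if not has_parents:
        return [frozenset({"unresolved"})] * len(variants)

    labels: list[set] = [set() for _ in variants]
    maternal: list[int] = []
    paternal: list[int] = []

    for i, v in enumerate(variants):
        child = parse_genotype(v.genotypes.get("child", "."))
        mother = parse_genotype(v.genotypes.get("mother", "."))
        father = parse_genotype(v.genotypes.get("father", "."))
        male_hemi = v.on_x and child_sex == MALE

        if _mendel_inconsistent(child, mother, father, male_hemi):
            labels[i] = {"mendel_error"}
            continue
        if child is None or mother is None or father is None:
            continue  # -> unresolved

        if male_hemi:
            if _carries_alt(child):
                if not _carries_alt(mother):
                    labels[i].add("de_novo")
                elif _is_het(mother) and not _carries_alt(father):
                    labels[i].add("x_linked_recessive")
                else:
                    labels[i].add("dominant_inherited")
            continue

        if _is_het(child) and not _carries_alt(mother) and not _carries_alt(father):
            labels[i].add("de_novo")
        if _is_hom_alt(child) and len(child) == 2 and _is_het(mother) and _is_het(father):
            labels[i].add("homozygous")
        if _is_het(child) and (_carries_alt(mother) or _carries_alt(father)):
            labels[i].add("dominant_inherited")
            if _carries_alt(mother) and not _carries_alt(father):
                maternal.append(i)
            elif _carries_alt(father) and not _carries_alt(mother):
                paternal.append(i)
            # both parents carriers -> phase unknown, not counted

    if maternal and paternal:
        for i in maternal + paternal:
            labels[i].add("compound_het")

    return [frozenset(s) if s else frozenset({"unresolved"}) for s in labels]


def classify_variant(
    variant: VariantRecord,
    inheritance: frozenset,
    rules: RuleTable = DEFAULT_RULES,
) -> ClassifiedVariant:
    """Assign the five-class label from (af, consequence, inheritance).

    Deterministic given the rule table, and monotone: raising the allele
    frequency never moves a variant toward pathogenic.
    """
    consequence = variant.consequence
    if consequence not in CONSEQUENCES:
        warnings.warn(f"unknown consequence {consequence!r}; classified as VUS")
        return ClassifiedVariant(variant, frozenset(inheritance), 3,
                                 note="unknown consequence")
    af = variant.af or 0.0
    lof = consequence in rules.lof_consequences
    if af >= rules.benign_af:
        cls = 1
    elif af >= rules.likely_benign_af and not lof:
        cls = 2
    elif lof and inheritance & rules.denovo_like:
        cls = 5
    elif lof or (consequence == "missense" and "de_novo" in inheritance):
        cls = 4
    else:
        cls = 3
    return ClassifiedVariant(variant, frozenset(inheritance), cls)


def apply_structural_override(cv: ClassifiedVariant, note: str = "") -> ClassifiedVariant:
    """Manual structural reclassification: may only raise class III to IV."""
    if cv.variant_class != 3:
        raise ValueError("structural override applies only to class III (VUS)")
    return replace(cv, variant_class=4, structural_override=True,
                   note=note or "structural reclassification")


def exclude_benign(classified: Sequence[ClassifiedVariant]) -> list[ClassifiedVariant]:
    """Drop benign / likely benign (classes I-II); order preserved."""
    kept = [cv for cv in classified if cv.variant_class >= 3]
    log_filter("variant_assessment.exclude_benign", len(classified), len(kept))
    return kept


def screen_affected_only(
    classified: Sequence[ClassifiedVariant],
    gene_modes: Mapping[str, str],
    *,
    child_sex: int,
) -> list[ClassifiedVariant]:
    """Mode-of-inheritance screen for families without parental genotypes.

    ``gene_modes`` maps candidate gene -> required zygosity: "mono_allelic",
    "bi_allelic" or "hemizygous".  Variants in unlisted genes are skipped
    with a warning.  Bi-allelic compatibility means a homozygous-alternate
    call or >= 2 heterozygous variants in the gene.
    """
    by_gene: dict[str, list[ClassifiedVariant]] = {}
    for cv in classified:
        by_gene.setdefault(cv.variant.gene, []).append(cv)

    matching: list[ClassifiedVariant] = []
    for gene, group in sorted(by_gene.items()):
        if gene not in gene_modes:
            warnings.warn(f"gene {gene!r} has no expected-mode annotation; skipped")
            continue
        mode = gene_modes[gene]
        if mode not in ("mono_allelic", "bi_allelic", "hemizygous"):
            raise ValueError(f"gene {gene!r}: unknown expected mode {mode!r}")
        child_gts = [parse_genotype(cv.variant.genotypes.get("child", ".")) for cv in group]
        n_het = sum(1 for gt in child_gts if _is_het(gt))
        for cv, gt in zip(group, child_gts):
            if gt is None or not _carries_alt(gt):
                continue
            if mode == "mono_allelic" and _is_het(gt):
                matching.append(cv)
            elif mode == "bi_allelic" and (_is_hom_alt(gt) or (_is_het(gt) and n_het >= 2)):
                matching.append(cv)
            elif mode == "hemizygous" and cv.variant.on_x and child_sex == MALE and _carries_alt(gt):
                matching.append(cv)
    log_filter("variant_assessment.screen_affected_only", len(classified), len(matching))
    return matching


def classify_cohort(
    variants: pd.DataFrame,
    pedigree: pd.DataFrame,
    rules: RuleTable = DEFAULT_RULES,
) -> pd.DataFrame:
    """Detect inheritance and classify every variant of a cohort table.

    ``variants`` follows the VCF-like TSV layout (FAMILY, CHROM, POS, REF,
    ALT, GENE, CSQ, AF, GT_child, GT_mother, GT_father); ``pedigree`` is the
    parsed PED table.  Returns the input with ``inheritance`` (comma-joined
    labels) and ``variant_class`` columns appended, benign classes included
    (use :func:`exclude_benign` downstream).
    """
    ped_info = {}
    for fam, group in pedigree.groupby("family"):
        children = group[(group.affected == 2) & ((group.father != "0") | (group.mother != "0"))]
        affected = group[group.affected == 2]
        has_parents = len(children) > 0
        child = children.iloc[0] if has_parents else affected.iloc[0]
        ped_info[fam] = (int(child.sex), has_parents)

    rows = []
    for (fam, gene), group in variants.groupby(["FAMILY", "GENE"], sort=False):
        sex, has_parents = ped_info[fam]
        records = [
            VariantRecord(
                chrom=str(r.CHROM), pos=int(r.POS), ref=r.REF, alt=r.ALT,
                gene=gene, consequence=r.CSQ,
                af=None if pd.isna(r.AF) else float(r.AF),
                genotypes={"child": r.GT_child, "mother": r.GT_mother, "father": r.GT_father},
                family_id=fam,
            )
            for r in group.itertuples()
        ]
        labels = detect_inheritance(records, child_sex=sex, has_parents=has_parents)
        for (_, row), rec, lab in zip(group.iterrows(), records, labels):
            cv = classify_variant(rec, lab, rules)
            out = row.copy()
            out["inheritance"] = ",".join(sorted(lab))
            out["variant_class"] = cv.variant_class
            rows.append(out)
    result = pd.DataFrame(rows).reset_index(drop=True)
    log_filter("variant_assessment.classify_cohort", len(variants), len(result))
    return result
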