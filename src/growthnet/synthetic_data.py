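"""Synthetic cohorts, annotation corpora and evidence flags with known truth.

The generator emulates the study conditions of a short-stature trio-exome
cohort so every downstream stage can be tested against planted ground truth:

* trio genotype patterns for the four screened inheritance modes (de novo,
  compound heterozygous, homozygous, X-linked recessive), mixed at the
  cohort's observed mode frequencies, with a configurable fraction of
  affected-only families (no parental genotypes);
* rare causal allele frequencies versus a common-frequency background of
  benign variants, so the frequency-dominant classifier is exercised;
* the observed consequence-type distribution (missense-dominated);
* a term-by-gene annotation corpus with planted blocks of correlated terms
  (shared gene sets) among random null terms, plus a growth-gene list in
  which the block genes are over-represented at a configurable fold;
* Bernoulli gene-level evidence flags.

One root seed drives three independent derived streams (cohort, annotation,
evidence) so each stage can be regenerated on its own; identical
configuration and seed reproduce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import ConfigurationError
from .enrichment import TermAnnotation
from .variant_assessment import (
    DEFAULT_RULES,
    MALE,
    FEMALE,
    RuleTable,
    VariantRecord,
    classify_variant,
)

INHERITANCE_MODES = ("de_novo", "comp_het", "homozygous", "x_linked")
CONSEQUENCE_TYPES = ("missense", "nonsense", "splice", "inframe_indel")

_MODE_LABEL = {
    "de_novo": "de_novo",
    "comp_het": "compound_het",
    "homozygous": "homozygous",
    "x_linked": "x_linked_recessive",
}

VARIANT_COLUMNS = (
    "FAMILY", "CHROM", "POS", "REF", "ALT", "GENE", "CSQ", "AF",
    "GT_child", "GT_mother", "GT_father",
)

_STREAMS = ("cohort", "annotation", "evidence")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort and annotation corpus.

    The inheritance mix defaults to the observed cohort mode frequencies
    (dominant-acting de novo 71%, X-linked recessive 17%, with the ~11%
    recessive remainder split evenly between homozygous and compound
    heterozygous and rounded so the vector sums to one); the consequence mix
    to the observed 78/15/6/1 missense/nonsense/splice/in-frame split.
    """

    n_families: int = 254
    n_genes: int = 2000
    n_terms: int = 300
    planted_cluster_blocks: tuple = ((6, 40), (8, 40), (10, 40))
    inheritance_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "de_novo": 0.71, "comp_het": 0.06, "homozygous": 0.06, "x_linked": 0.17,
        }
    )
    consequence_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "missense": 0.78, "nonsense": 0.15, "splice": 0.06, "inframe_indel": 0.01,
        }
    )
    rare_af_range: tuple = (0.0, 1e-4)
    common_af_range: tuple = (0.01, 0.2)
    evidence_flag_prob: float | Mapping[str, float] = 0.1
    affected_only_fraction: float = 69 / 254
    background_variants: int = 50
    missing_af_fraction: float = 0.25
    term_size: int = 40
    growth_list_size: int = 200
    enrichment_fold: float = 4.0
    block_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_families < 1:
            raise ConfigurationError("n_families must be >= 1")
        for name, mix, keys in (
            ("inheritance_mix", self.inheritance_mix, INHERITANCE_MODES),
            ("consequence_mix", self.consequence_mix, CONSEQUENCE_TYPES),
        ):
            if set(mix) != set(keys):
                raise ConfigurationError(f"{name} must have keys {keys}")
            if any(p < 0 for p in mix.values()) or abs(sum(mix.values()) - 1) > 1e-9:
                raise ConfigurationError(f"{name} proportions must be >= 0 and sum to 1")
        if not self.rare_af_range[1] < self.common_af_range[0]:
            raise ConfigurationError(
                "rare_af_range upper bound must be below common_af_range lower bound"
            )
        probs = (
            self.evidence_flag_prob.values()
            if isinstance(self.evidence_flag_prob, Mapping)
            else [self.evidence_flag_prob]
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ConfigurationError("evidence_flag_prob must lie in [0, 1]")
        for frac_name in ("affected_only_fraction", "missing_af_fraction", "block_noise"):
            if not 0 <= getattr(self, frac_name) <= 1:
                raise ConfigurationError(f"{frac_name} must lie in [0, 1]")
        total_block_genes = sum(shared for _, shared in self.planted_cluster_blocks)
        if any(shared > self.n_genes for _, shared in self.planted_cluster_blocks):
            raise ConfigurationError("planted_cluster_blocks: block larger than gene universe")
        if total_block_genes > self.n_genes:
            raise ConfigurationError("planted_cluster_blocks exceed the gene universe")
        if sum(n for n, _ in self.planted_cluster_blocks) > self.n_terms:
            raise ConfigurationError("planted_cluster_blocks exceed n_terms")
        if self.growth_list_size > self.n_genes:
            raise ConfigurationError("growth_list_size exceeds n_genes")
        if self.enrichment_fold * self.growth_list_size > self.n_genes:
            raise ConfigurationError(
                "enrichment_fold too large for growth_list_size / n_genes"
            )


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(stage)])


def gene_universe(config: SimulationConfig) -> list[str]:
    return [f"GENE{i:05d}" for i in range(1, config.n_genes + 1)]


_BASES = np.array(["A", "C", "G", "T"])


def _causal_genotypes(mode: str, affected_only: bool) -> list[dict]:
    """Genotype dictionaries (one per causal variant) for a planted mode."""
    if affected_only:
        child = {"de_novo": "0/1", "homozygous": "1/1", "x_linked": "1"}.get(mode, "0/1")
        n = 2 if mode == "comp_het" else 1
        return [{"child": child, "mother": ".", "father": "."} for _ in range(n)]
    if mode == "de_novo":
        return [{"child": "0/1", "mother": "0/0", "father": "0/0"}]
    if mode == "homozygous":
        return [{"child": "1/1", "mother": "0/1", "father": "0/1"}]
    if mode == "comp_het":
        return [
            {"child": "0/1", "mother": "0/1", "father": "0/0"},
            {"child": "0/1", "mother": "0/0", "father": "0/1"},
        ]
    if mode == "x_linked":
        return [{"child": "1", "mother": "0/1", "father": "0"}]
    raise ConfigurationError(f"unknown inheritance mode {mode!r}")


def _intended_class(
    mode: str, consequence: str, af: float | None, rules: RuleTable
) -> int:
    record = VariantRecord(
        chrom="X" if mode == "x_linked" else "1", pos=1, ref="A", alt="C",
        gene="G", consequence=consequence, af=af, genotypes={}, family_id="F",
    )
    return classify_variant(record, frozenset({_MODE_LABEL[mode]}), rules).variant_class


def generate_trio_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort: variant table, pedigree and planted-truth table.

    Every family receives one planted causal event (two variants for
    compound heterozygous) with trio genotypes matching its mode, plus
    ``background_variants`` common-frequency inherited variants.  A
    configurable fraction of families is affected-only (no parents).
    Returns ``(variants, pedigree, truth)`` data frames.
    """
    rng = _rng(config, "cohort")
    genes = np.array(gene_universe(config))
    modes = list(config.inheritance_mix)
    mode_p = np.array([config.inheritance_mix[m] for m in modes])
    consequences = list(config.consequence_mix)
    cons_p = np.array([config.consequence_mix[c] for c in consequences])

    variant_rows: list[dict] = []
    ped_rows: list[dict] = []
    truth_rows: list[dict] = []

    for i in range(1, config.n_families + 1):
        fid = f"FAM{i:04d}"
        affected_only = bool(rng.random() < config.affected_only_fraction)
        mode = modes[rng.choice(len(modes), p=mode_p)]
        sex = MALE if mode == "x_linked" else (MALE if rng.random() < 0.5 else FEMALE)

        if affected_only:
            ped_rows.append(
                {"family": fid, "individual": f"{fid}_C", "father": "0",
                 "mother": "0", "sex": sex, "affected": 2}
            )
        else:
            ped_rows.extend([
                {"family": fid, "individual": f"{fid}_C", "father": f"{fid}_F",
                 "mother": f"{fid}_M", "sex": sex, "affected": 2},
                {"family": fid, "individual": f"{fid}_F", "father": "0",
                 "mother": "0", "sex": MALE, "affected": 1},
                {"family": fid, "individual": f"{fid}_M", "father": "0",
                 "mother": "0", "sex": FEMALE, "affected": 1},
            ])

        gene_idx = rng.choice(len(genes), size=config.background_variants + 1, replace=False)
        causal_gene = str(genes[gene_idx[0]])
        chrom = "X" if mode == "x_linked" else str(rng.integers(1, 23))
        genotypes = _causal_genotypes(mode, affected_only)
        classes = []
        for gt in genotypes:
            consequence = consequences[rng.choice(len(consequences), p=cons_p)]
            missing = rng.random() < config.missing_af_fraction
            af = None if missing else float(rng.uniform(*config.rare_af_range))
            ref, alt = rng.choice(4, size=2, replace=False)
            variant_rows.append(
                {"FAMILY": fid, "CHROM": chrom, "POS": int(rng.integers(1, 50_000_000)),
                 "REF": _BASES[ref], "ALT": _BASES[alt], "GENE": causal_gene,
                 "CSQ": consequence, "AF": np.nan if af is None else af,
                 "GT_child": gt["child"], "GT_mother": gt["mother"],
                 "GT_father": gt["father"]}
            )
            classes.append(_intended_class(mode, consequence, af, DEFAULT_RULES))
        truth_rows.append(
            {"FAMILY": fid, "GENE": causal_gene, "mode": mode,
             "affected_only": affected_only, "n_variants": len(genotypes),
             "intended_class": max(classes)}
        )

        for g in gene_idx[1:]:
            af = float(rng.uniform(*config.common_af_range))
            m_gt = rng.binomial(1, af, size=2)
            f_gt = rng.binomial(1, af, size=2)
            if affected_only:
                child_alleles = rng.binomial(1, af, size=2)
                gt = {"child": f"{min(child_alleles)}/{max(child_alleles)}",
                      "mother": ".", "father": "."}
            else:
                alleles = sorted((m_gt[rng.integers(2)], f_gt[rng.integers(2)]))
                gt = {"child": f"{alleles[0]}/{alleles[1]}",
                      "mother": f"{min(m_gt)}/{max(m_gt)}",
                      "father": f"{min(f_gt)}/{max(f_gt)}"}
            ref, alt = rng.choice(4, size=2, replace=False)
            consequence = consequences[rng.choice(len(consequences), p=cons_p)]
            variant_rows.append(
                {"FAMILY": fid, "CHROM": str(rng.integers(1, 23)),
                 "POS": int(rng.integers(1, 50_000_000)),
                 "REF": _BASES[ref], "ALT": _BASES[alt], "GENE": str(genes[g]),
                 "CSQ": consequence, "AF": af, "GT_child": gt["child"],
                 "GT_mother": gt["mother"], "GT_father": gt["father"]}
            )

    variants = pd.DataFrame(variant_rows, columns=list(VARIANT_COLUMNS))
    pedigree = pd.DataFrame(ped_rows)
    truth = pd.DataFrame(truth_rows)
    return variants, pedigree, truth


def generate_annotation_corpus(
    config: SimulationConfig,
) -> tuple[list[TermAnnotation], list[str], pd.DataFrame]:
    """Annotation corpus with planted correlated term blocks and a growth list.

    Each planted block holds terms built from one shared gene set (disjoint
    across blocks); with ``block_noise`` r each shared gene is swapped for a
    random outside gene with probability r, so noiseless blocks have pairwise
    kappa 1.  Remaining terms are random null gene sets.  The growth-gene
    list over-represents block genes at ``enrichment_fold`` times the
    background rate.  Returns ``(terms, growth_genes, truth)`` where truth
    maps each term to its planted block (-1 for null terms).
    """
    rng = _rng(config, "annotation")
    genes = np.array(gene_universe(config))
    pool = rng.permutation(config.n_genes)
    terms: list[TermAnnotation] = []
    truth_rows: list[dict] = []

    offset = 0
    total_block_genes = sum(shared for _, shared in config.planted_cluster_blocks)
    outside = pool[total_block_genes:]  # swap targets never touch any block
    block_gene_idx: list[np.ndarray] = []
    for b, (n_block_terms, n_shared) in enumerate(config.planted_cluster_blocks):
        shared = pool[offset:offset + n_shared]
        offset += n_shared
        block_gene_idx.append(shared)
        for j in range(n_block_terms):
            members = shared.copy()
            if config.block_noise > 0:
                swap = rng.random(n_shared) < config.block_noise
                members[swap] = rng.choice(outside, size=int(swap.sum()), replace=False)
            term_id = f"BLK{b:02d}_T{j:02d}"
            terms.append(
                TermAnnotation(term_id=term_id, source="GO_BP",
                               genes=frozenset(genes[members]),
                               description=f"planted block {b}")
            )
            truth_rows.append({"term_id": term_id, "block": b})

    n_null = config.n_terms - len(terms)
    for j in range(n_null):
        members = rng.choice(config.n_genes, size=config.term_size, replace=False)
        term_id = f"NULL{j:04d}"
        terms.append(
            TermAnnotation(term_id=term_id, source="GO_BP",
                           genes=frozenset(genes[members]), description="null term")
        )
        truth_rows.append({"term_id": term_id, "block": -1})

    block_union = (
        np.concatenate(block_gene_idx) if block_gene_idx else np.array([], dtype=int)
    )
    in_list_prob = config.enrichment_fold * config.growth_list_size / config.n_genes
    picked = block_union[rng.random(len(block_union)) < in_list_prob]
    non_block = np.setdiff1d(np.arange(config.n_genes), block_union)
    n_fill = config.growth_list_size - len(picked)
    if n_fill < 0:
        picked = rng.choice(picked, size=config.growth_list_size, replace=False)
        n_fill = 0
    fill = rng.choice(non_block, size=n_fill, replace=False)
    growth = sorted(str(g) for g in genes[np.concatenate([picked, fill]).astype(int)])
    return terms, growth, pd.DataFrame(truth_rows)


def generate_evidence_flags(config: SimulationConfig, gene_names: Iterable[str]) -> pd.DataFrame:
    """Bernoulli evidence flags: one row per gene, 8 boolean columns."""
    from .gene_evidence import EVIDENCE_CATEGORIES

    rng = _rng(config, "evidence")
    gene_names = list(gene_names)
    probs = (
        {c: config.evidence_flag_prob[c] for c in EVIDENCE_CATEGORIES}
        if isinstance(config.evidence_flag_prob, Mapping)
        else {c: config.evidence_flag_prob for c in EVIDENCE_CATEGORIES}
    )
    data = {"gene": gene_names}
    for category in EVIDENCE_CATEGORIES:
        data[category] = rng.binomial(1, probs[category], size=len(gene_names))
    return pd.DataFrame(data)
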