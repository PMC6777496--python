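"""Readers and writers for the pipeline's file formats, plus configuration.

Formats are deliberately minimal and text-only: tab-separated tables with
explicit headers (UTF-8, no Excel dialects), GMT gene sets, standard
six-column PED, plain gene lists and YAML configuration.  Gene symbols are
upper-cased on ingest.  The variant table is a VCF-like TSV with columns
FAMILY, CHROM, POS (1-based), REF, ALT, GENE, CSQ, AF, GT_child, GT_mother,
GT_father; a FAMILY column is carried so one table can hold a whole cohort.
A full VCF 4.x parser (INFO/FORMAT semantics) is out of scope; a real-VCF
import shim is a documented extension point.

Every CLI run writes a ``manifest.json`` (input checksums, configuration
hash, seed, package version) sufficient to reproduce outputs byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import re
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from ._util import ConfigurationError
from .annotation_clustering import ClusteringParams, TermCluster
from .enrichment import EnrichmentResult, TermAnnotation
from .gene_evidence import EVIDENCE_CATEGORIES, CandidateGene
from .synthetic_data import VARIANT_COLUMNS

_GT_RE = re.compile(r"^([01.])([/|][01.])?$")


class FormatError(ValueError):
    """Malformed input file; the message carries the line/row number."""


# --- GMT ---------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[TermAnnotation]:
    """Read gene sets: one term per line (name, description, genes...)."""
    terms = []
    seen = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs term, description, >=1 gene")
            term_id, description, *genes = parts
            genes = [g.strip().upper() for g in genes if g.strip()]
            if not genes:
                raise FormatError(f"{path}:{lineno}: term {term_id!r} has no genes")
            if term_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate term {term_id!r}")
            seen.add(term_id)
            if len(set(genes)) != len(genes):
                warnings.warn(f"{path}:{lineno}: duplicate genes in term {term_id!r} deduplicated")
            source = description if description in (
                "GO_BP", "GO_MF", "GO_CC", "KEGG", "UP_KEYWORDS", "OMIM_DISEASE"
            ) else "GO_BP"
            terms.append(
                TermAnnotation(term_id=term_id, source=source,
                               genes=frozenset(genes), description=description)
            )
    return terms


def write_gmt(terms: Sequence[TermAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in terms:
            fh.write("\t".join([t.term_id, t.description or t.source, *sorted(t.genes)]))
            fh.write("\n")


# --- gene lists --------------------------------------------------------------

def read_gene_list(path: str | Path) -> list[str]:
    """Plain text, one gene per line; upper-cased, deduplicated, sorted."""
    with open(path, encoding="utf-8") as fh:
        genes = {line.strip().upper() for line in fh if line.strip()}
    return sorted(genes)


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(set(genes)):
            fh.write(f"{g}\n")


# --- variants + PED ----------------------------------------------------------

def read_variants(path: str | Path) -> pd.DataFrame:
    """Read the VCF-like variant TSV with field validation."""
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str, "FAMILY": str})
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    for i, row in enumerate(df.itertuples(), start=2):
        if not (isinstance(row.POS, (int,)) or float(row.POS).is_integer()) or row.POS < 1:
            raise FormatError(f"{path}: row {i}: POS must be a 1-based integer")
        for col in ("GT_child", "GT_mother", "GT_father"):
            gt = str(getattr(row, col))
            if gt in ("nan", ""):
                continue
            if not _GT_RE.match(gt):
                raise FormatError(f"{path}: row {i}: bad genotype {gt!r} in {col}")
        if not pd.isna(row.AF) and not 0 <= float(row.AF) <= 1:
            raise FormatError(f"{path}: row {i}: AF outside [0, 1]")
    df["GENE"] = df["GENE"].str.upper()
    for col in ("GT_mother", "GT_father"):
        df[col] = df[col].fillna(".")
    return df


def write_variants(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_ped(path: str | Path) -> pd.DataFrame:
    """Standard six-column PED (family, individual, father, mother, sex, affected)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["family", "individual", "father", "mother", "sex", "affected"]
    if list(df.columns[:6]) != required:
        raise FormatError(f"{path}: PED header must be {required}")
    for i, row in enumerate(df.itertuples(), start=2):
        if row.sex not in ("1", "2"):
            raise FormatError(f"{path}: row {i}: sex must be 1 (male) or 2 (female)")
        if row.affected not in ("1", "2"):
            raise FormatError(f"{path}: row {i}: affected must be 1 or 2")
    df["sex"] = df["sex"].astype(int)
    df["affected"] = df["affected"].astype(int)
    return df


def write_ped(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# --- evidence ----------------------------------------------------------------

def read_evidence(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = ({"gene"} | set(EVIDENCE_CATEGORIES)) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing evidence columns {sorted(missing)}")
    df["gene"] = df["gene"].str.upper()
    return df


def write_evidence(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# --- enrichment / cluster / candidate tables ---------------------------------

def write_enrichment(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"term_id": r.term_id, "a": r.a, "A": r.A, "b": r.b, "B": r.B,
             "p_raw": r.p_raw, "fdr": r.fdr, "odds_ratio": r.odds_ratio,
             "fold_enrichment": r.fold_enrichment}
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_enrichment(path: str | Path) -> list[EnrichmentResult]:
    df = pd.read_csv(path, sep="\t")
    return [
        EnrichmentResult(
            term_id=r.term_id, a=int(r.a), A=int(r.A), b=int(r.b), B=int(r.B),
            p_raw=float(r.p_raw), fdr=float(r.fdr),
            odds_ratio=float(r.odds_ratio), fold_enrichment=float(r.fold_enrichment),
        )
        for r in df.itertuples()
    ]


def write_clusters(clusters: Sequence[TermCluster], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"cluster_id": c.cluster_id, "representative_label": c.representative_label,
             "n_terms": c.n_terms, "gene_union_size": len(c.gene_union),
             "enrichment_score": c.enrichment_score,
             "mean_fold_enrichment": c.mean_fold_enrichment,
             "member_terms": ",".join(sorted(c.member_terms)),
             "gene_union": ",".join(sorted(c.gene_union))}
            for c in clusters
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_clusters(path: str | Path) -> list[TermCluster]:
    df = pd.read_csv(path, sep="\t")
    return [
        TermCluster(
            cluster_id=r.cluster_id,
            member_terms=frozenset(str(r.member_terms).split(",")),
            representative_label=r.representative_label,
            gene_union=frozenset(str(r.gene_union).split(",")),
            enrichment_score=float(r.enrichment_score),
            mean_fold_enrichment=float(r.mean_fold_enrichment),
        )
        for r in df.itertuples()
    ]


def write_candidates(candidates: Sequence[CandidateGene], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"gene": c.gene, "n_families": c.n_families,
             "n_class_V": c.class_tally.get(5, 0), "n_class_IV": c.class_tally.get(4, 0),
             "n_class_III": c.class_tally.get(3, 0), "category_count": c.category_count,
             "score_min": c.score_min, "score_max": c.score_max, "tier": c.tier,
             "previously_reported": int(c.previously_reported)}
            for c in candidates
        ]
    ).to_csv(path, sep="\t", index=False)


def read_candidates(path: str | Path) -> list[CandidateGene]:
    df = pd.read_csv(path, sep="\t")
    return [
        CandidateGene(
            gene=r.gene, n_families=int(r.n_families),
            class_tally={5: int(r.n_class_V), 4: int(r.n_class_IV), 3: int(r.n_class_III)},
            category_count=int(r.category_count),
            score_min=int(r.score_min), score_max=int(r.score_max),
            tier=str(r.tier) if hasattr(r, "tier") else "unassigned",
            previously_reported=bool(getattr(r, "previously_reported", False)),
        )
        for r in df.itertuples()
    ]


# --- configuration -----------------------------------------------------------

_PIPELINE_KEYS = {
    "variants", "ped", "evidence", "gmt", "growth_genes", "background",
    "rules", "scoring", "clustering", "alpha", "seed",
}
_PATH_KEYS = ("variants", "ped", "evidence", "gmt", "growth_genes", "background", "rules")


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full pipeline run."""

    variants: Path
    ped: Path
    evidence: Path
    gmt: Path
    growth_genes: Path
    background: Path
    rules: Path | None = None
    scoring: Mapping | None = None
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    alpha: float = 0.05
    seed: int = 0


def read_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load and validate the YAML pipeline configuration.

    Unknown keys are rejected; every referenced file must exist.
    """
    base = Path(path).parent
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - _PIPELINE_KEYS
    if unknown:
        raise ConfigurationError(f"unknown pipeline config keys: {sorted(unknown)}")
    kwargs: dict = {}
    for key in _PATH_KEYS:
        if key in data and data[key] is not None:
            p = Path(data[key])
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise ConfigurationError(f"{key}: file not found: {p}")
            kwargs[key] = p
    if "clustering" in data:
        kwargs["clustering"] = ClusteringParams(**data["clustering"])
    for key in ("alpha", "seed", "scoring"):
        if key in data:
            kwargs[key] = data[key]
    missing = {"variants", "ped", "evidence", "gmt", "growth_genes", "background"} - set(kwargs)
    if missing:
        raise ConfigurationError(f"pipeline config missing required keys: {sorted(missing)}")
    return PipelineConfig(**kwargs)


# --- run manifest ------------------------------------------------------------

def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(outdir: str | Path, inputs: Mapping[str, str | Path],
                   config: Mapping, seed: int) -> Path:
    """Record input checksums, configuration hash and seed for reproduction."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "version": __version__,
        "seed": seed,
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in sorted(inputs.items())
        },
        "config": config,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    manifest = outdir / "manifest.json"
    with open(manifest, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
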