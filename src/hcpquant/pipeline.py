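"""End-to-end orchestration: read -> filter -> validate -> quantify ->
physchem -> risk/enrichment -> summarize -> write.

Two entry points: :func:`analyze` works on in-memory objects (what the
tests and the synthetic generator use); :func:`run_pipeline` is the
file-driven variant behind the command line, configured by a YAML/JSON
run config and writing the full report set plus a manifest.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import filtering, io_formats, physchem, quantitation, risk_enrichment, summarize
from .filtering import FilterTrace, IdentifiedProtein
from .io_formats import (
    FilterConfig,
    PeptideEvidence,
    ProteinRecord,
    RiskList,
    StudyDesign,
)
from .quantitation import QuantResult

log = logging.getLogger("hcpquant")


@dataclass(frozen=True)
class AnalysisResult:
    evidence_surviving: list[PeptideEvidence]
    traces: dict[str, list[FilterTrace]]  # per product
    identified: list[IdentifiedProtein]
    annotation_trace: FilterTrace | None
    quant: list[QuantResult]
    profiles: dict[str, physchem.PhysChemProfile]
    risk: dict[str, risk_enrichment.RiskAnnotation]
    enrichment: list[risk_enrichment.EnrichmentResult]
    summary: summarize.CohortSummary


def analyze(
    evidence: Sequence[PeptideEvidence],
    *,
    records: Mapping[str, ProteinRecord],
    product_records: Sequence[ProteinRecord],
    design: StudyDesign,
    filter_cfg: FilterConfig = FilterConfig(),
    annotations: Mapping[str, frozenset[str]] | None = None,
    risk_list: RiskList | None = None,
    class_map: Mapping[str, str] | None = None,
    thresholds: Sequence[float] = summarize.DEFAULT_THRESHOLDS,
    enrichment_alpha: float = 0.01,
    enrichment_min_count: int = 3,
    top_k: int = 3,
    global_top_set: bool = False,
    replicate_unit: str = "digest",
) -> AnalysisResult:
    """Run the full analysis on in-memory evidence.

    ``records`` must contain every accession needed for sequence lookup
    (host proteome subset, contaminants, products, Hi3 standard).
    """
    contaminant_db = [r for r in records.values() if r.is_contaminant]
    descriptions = {acc: r.description for acc, r in records.items()}
    product_ids = {r.accession for r in product_records}
    product_seq_of = {r.accession: r.sequence for r in product_records}
    exclude = product_ids | {design.hi3_accession}

    surviving: list[PeptideEvidence] = []
    hi3_surviving: list[PeptideEvidence] = []
    traces: dict[str, list[FilterTrace]] = {}
    by_product: dict[str, list[PeptideEvidence]] = {}
    for ev in evidence:
        by_product.setdefault(ev.product_id, []).append(ev)
    for pid in sorted(by_product):
        prod_seq = product_seq_of.get(pid, "")
        ev_in = by_product[pid]
        # the spiked standard bypasses the cascade: it must be present in
        # every run and is not itself an analyte
        hi3_ev = [e for e in ev_in if design.hi3_accession in e.accessions]
        ev_in = [e for e in ev_in if design.hi3_accession not in e.accessions]
        ev_out, tr = filtering.run_cascade(
            ev_in,
            contaminant_db=contaminant_db,
            product_seqs=[prod_seq] if prod_seq else [],
            design=design,
            cfg=filter_cfg,
            description_lookup=descriptions,
        )
        traces[pid] = tr
        for stage in tr:
            log.info(
                "product %s stage %-18s in=%d removed=%d out=%d",
                pid, stage.stage, stage.peptides_in, stage.peptides_removed,
                stage.peptides_out,
            )
        surviving.extend(ev_out)
        hi3_surviving.extend(hi3_ev)

    identified = filtering.validate_identifications(
        surviving, filter_cfg, design, exclude_accessions=exclude
    )
    annotation_trace = None
    if filter_cfg.annotation_exclusion_terms or filter_cfg.iglike_exclusion_accessions \
            or filter_cfg.use_iglike_keywords:
        ann_records = {
            acc: dataclasses.replace(
                rec, annotation_terms=(annotations or {}).get(acc, rec.annotation_terms)
            )
            for acc, rec in records.items()
        }
        identified, annotation_trace = filtering.annotation_exclusion_filter(
            identified, ann_records, filter_cfg
        )

    quant = quantitation.quantify_product(
        surviving + hi3_surviving,
        identified,
        design,
        records,
        top_k=top_k,
        global_top_set=global_top_set,
        replicate_unit=replicate_unit,
    )

    identified_accs = sorted(
        {p.accession for p in identified if p.identified}
    )
    profiles = {
        acc: physchem.profile(records[acc])
        for acc in identified_accs
        if acc in records and records[acc].sequence
    }

    risk: dict[str, risk_enrichment.RiskAnnotation] = {}
    enrichment: list[risk_enrichment.EnrichmentResult] = []
    if risk_list is not None:
        risk = risk_enrichment.flag_risk(
            identified_accs, records, risk_list, annotations or {}
        )
    if annotations:
        background = dict(annotations)
        gene_list = [a for a in identified_accs if a in background]
        enrichment = risk_enrichment.enrich_terms(
            gene_list, background, alpha=enrichment_alpha, min_count=enrichment_min_count
        )

    summary = summarize.summarize_cohort(
        quant,
        class_map or {pid: "unclassified" for pid in by_product},
        thresholds,
    )
    return AnalysisResult(
        evidence_surviving=surviving,
        traces=traces,
        identified=identified,
        annotation_trace=annotation_trace,
        quant=quant,
        profiles=profiles,
        risk=risk,
        enrichment=enrichment,
        summary=summary,
    )


def result_tables(result: AnalysisResult) -> dict[str, pd.DataFrame]:
    """Render every report as a stable-schema DataFrame."""
    quant_rows = [
        {
            "product_id": q.product_id,
            "accession": q.accession,
            "mode": q.mode,
            "n_unique_peptides": q.n_unique_peptides,
            "per_digest_conc_ng_mg": ";".join(repr(v) for v in q.per_digest_conc),
            "mean_conc_ng_mg": q.mean_conc,
            "sd_conc_ng_mg": q.sd_conc,
            "cv_percent": q.cv_percent,
            "n_digests_used": q.n_digests_used,
            "molecular_weight_da": q.molecular_weight_da,
        }
        for q in result.quant
    ]
    phys_rows = [
        {
            "accession": p.accession,
            "molecular_weight_da": p.molecular_weight_da,
            "gravy": p.gravy,
            "pI": p.pI,
            "aliphatic_index": p.aliphatic_index,
            "instability_index": p.instability_index,
            "hydrophilic": p.hydrophilic,
            "stable": p.stable,
        }
        for p in result.profiles.values()
    ]
    risk_rows = [
        {
            "accession": r.accession,
            "status": r.status,
            "best_match_accession": r.best_match_accession or "",
            "kappa": r.kappa,
            "overlap": r.overlap,
        }
        for r in result.risk.values()
    ]
    enr_rows = [
        {
            "term": e.term,
            "list_hits": e.list_hits,
            "list_size": e.list_size,
            "background_hits": e.background_hits,
            "background_size": e.background_size,
            "ease_p": e.ease_p,
            "bh_adjusted_p": e.bh_adjusted_p,
            "significant": e.significant,
        }
        for e in result.enrichment
    ]
    trace_rows = [
        {
            "product_id": pid,
            "stage": t.stage,
            "peptides_in": t.peptides_in,
            "peptides_removed": t.peptides_removed,
            "peptides_out": t.peptides_out,
        }
        for pid, trs in sorted(result.traces.items())
        for t in trs
    ]
    totals_rows = [
        {"product_id": pid, **vals}
        for pid, vals in sorted(result.summary.per_product_totals.items())
    ]
    return {
        "quant": pd.DataFrame(
            quant_rows,
            columns=[
                "product_id", "accession", "mode", "n_unique_peptides",
                "per_digest_conc_ng_mg", "mean_conc_ng_mg", "sd_conc_ng_mg",
                "cv_percent", "n_digests_used", "molecular_weight_da",
            ],
        ),
        "instance_table": result.summary.instance_table,
        "per_product_totals": pd.DataFrame(
            totals_rows,
            columns=["product_id", "n_identified", "n_quantified", "total_ng_mg"],
        ),
        "physchem": pd.DataFrame(
            phys_rows,
            columns=[
                "accession", "molecular_weight_da", "gravy", "pI",
                "aliphatic_index", "instability_index", "hydrophilic", "stable",
            ],
        ),
        "risk": pd.DataFrame(
            risk_rows,
            columns=["accession", "status", "best_match_accession", "kappa", "overlap"],
        ),
        "enrichment": pd.DataFrame(
            enr_rows,
            columns=[
                "term", "list_hits", "list_size", "background_hits",
                "background_size", "ease_p", "bh_adjusted_p", "significant",
            ],
        ),
        "filter_trace": pd.DataFrame(
            trace_rows,
            columns=["product_id", "stage", "peptides_in", "peptides_removed", "peptides_out"],
        ),
        "class_membership": result.summary.class_membership.reset_index(),
    }


@dataclass(frozen=True)
class RunConfig:
    """File-level configuration for a full pipeline run."""

    evidence: Path
    host_fasta: Path
    products_fasta: Path
    out_dir: Path
    contaminants_fasta: Path | None = None
    hi3_fasta: Path | None = None
    annotations: Path | None = None
    risk_list: Path | None = None
    class_map: Path | None = None
    design: StudyDesign = field(default_factory=StudyDesign)
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)
    thresholds: tuple[float, ...] = summarize.DEFAULT_THRESHOLDS
    enrichment_alpha: float = 0.01
    enrichment_min_count: int = 3
    top_k: int = 3
    global_top_set: bool = False
    replicate_unit: str = "digest"
    seed: int = 0


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML (or JSON) key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base = Path(path).parent

    def _path(key: str, required: bool = False) -> Path | None:
        value = raw.pop(key, None)
        if value is None:
            if required:
                raise KeyError(f"run config missing required path {key!r}")
            return None
        p = Path(value)
        return p if p.is_absolute() else base / p

    kwargs: dict = {
        "evidence": _path("evidence", required=True),
        "host_fasta": _path("host_fasta", required=True),
        "products_fasta": _path("products_fasta", required=True),
        "out_dir": _path("out_dir") or (base / "reports"),
        "contaminants_fasta": _path("contaminants_fasta"),
        "hi3_fasta": _path("hi3_fasta"),
        "annotations": _path("annotations"),
        "risk_list": _path("risk_list"),
        "class_map": _path("class_map"),
    }
    if "design" in raw:
        kwargs["design"] = StudyDesign(**raw.pop("design"))
    if "filter" in raw:
        fc = raw.pop("filter")
        for key in ("contaminant_keywords", "iglike_exclusion_accessions",
                    "iglike_keywords", "annotation_exclusion_terms"):
            if key in fc:
                fc[key] = tuple(fc[key])
        kwargs["filter_cfg"] = FilterConfig(**fc)
    if "thresholds" in raw:
        kwargs["thresholds"] = tuple(float(t) for t in raw.pop("thresholds"))
    for key in ("enrichment_alpha", "enrichment_min_count", "top_k",
                "global_top_set", "replicate_unit", "seed"):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if raw:
        raise KeyError(f"unknown run-config keys: {sorted(raw)}")
    return RunConfig(**kwargs)


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline from files and write the report set."""
    for name in ("evidence", "host_fasta", "products_fasta"):
        p = getattr(cfg, name)
        if not Path(p).exists():
            raise FileNotFoundError(f"{name} file not found: {p}")
    evidence = io_formats.read_peptide_table(cfg.evidence)
    host = io_formats.read_fasta(cfg.host_fasta)
    products = io_formats.read_fasta(cfg.products_fasta)
    contaminants = (
        io_formats.read_fasta(cfg.contaminants_fasta, is_contaminant=True)
        if cfg.contaminants_fasta
        else []
    )
    hi3 = io_formats.read_fasta(cfg.hi3_fasta, is_standard=True) if cfg.hi3_fasta else []
    records = {r.accession: r for r in host}
    records.update({r.accession: r for r in contaminants})
    records.update({r.accession: r for r in products})
    records.update({r.accession: r for r in hi3})
    annotations = io_formats.read_annotations(cfg.annotations) if cfg.annotations else None
    risk_list = io_formats.read_risk_list(cfg.risk_list) if cfg.risk_list else None
    class_map = io_formats.read_class_map(cfg.class_map) if cfg.class_map else None

    result = analyze(
        evidence,
        records=records,
        product_records=products,
        design=cfg.design,
        filter_cfg=cfg.filter_cfg,
        annotations=annotations,
        risk_list=risk_list,
        class_map=class_map,
        thresholds=cfg.thresholds,
        enrichment_alpha=cfg.enrichment_alpha,
        enrichment_min_count=cfg.enrichment_min_count,
        top_k=cfg.top_k,
        global_top_set=cfg.global_top_set,
        replicate_unit=cfg.replicate_unit,
    )
    manifest = {
        "config": dataclasses.asdict(cfg),
        "n_evidence_in": len(evidence),
        "n_evidence_surviving": len(result.evidence_surviving),
        "n_identified": sum(1 for p in result.identified if p.identified),
        "n_quantified": sum(1 for q in result.quant if q.mode == "quantified"),
    }
    return io_formats.write_reports(result_tables(result), cfg.out_dir, manifest)
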