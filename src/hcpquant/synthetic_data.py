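"""Synthetic peptide-evidence generator with known ground truth.

Emulates the measurement structure the pipeline assumes: a cohort of
biotherapeutic products, each analysed as three digests x two
injections; host-cell proteins spanning roughly 0.2-350 ng/mg
(log-uniform); tryptic peptides (Trypsin/P, bounded missed cleavages,
length 7-30) whose observed intensity follows

    I = scale * fmol_on_column * RF_peptide * penalty^mc * exp(eps_run)

with a log-normal per-peptide response factor RF (fixed across runs — a
peptide's ionisation response is a property of the peptide), a
multiplicative per-run noise term, an abundance penalty per missed
cleavage, and intensity-dependent logistic dropout. A three-peptide Hi3
standard of fixed molar amount and unit response factor is spiked into
every run. Planted artefacts exercise every filter: contaminant (cRAP
keratin/trypsin/albumin) peptides, a host keratin absent from the
contaminant database, shared peptides carrying two accessions, and
product-degradation peptides that are verbatim substrings of the
product sequence.

Synthetic proteins are concatenations of tryptic "blocks" (a stretch of
non-K/R residues closed by K or R), so every protein is guaranteed a
known number of fully cleaved peptides inside the searchable length
range. With all noise off the Top3 sum of any quantifiable protein is
exactly ``3 * scale * fmol``, making pipeline output equal ground truth
to machine precision — the construction, not a tolerance, provides the
oracle.

Random draws are made for every candidate observation regardless of the
noise magnitudes (common random numbers), so datasets generated at
different sigma but the same seed are directly comparable.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import parser as pyt_parser

from .io_formats import (
    PeptideEvidence,
    ProteinRecord,
    RiskList,
    RiskListEntry,
    StudyDesign,
    write_annotations,
    write_class_map,
    write_fasta,
    write_peptide_table,
    write_risk_list,
)
from .physchem import molecular_weight
from .quantitation import NG_PER_FMOL_DA

TRYPSIN_P_RULE = r"[KR]"
_NON_KR = "ACDEFGHILMNPQSTVWY"


def digest_in_silico(
    sequence: str,
    missed_cleavages: int = 2,
    length_range: tuple[int, int] = (7, 30),
) -> list[str]:
    """Tryptic digest (Trypsin/P: cleave after every K/R, also before P).

    Returns the unique peptides with at most ``missed_cleavages`` missed
    cleavage sites and length inside ``length_range``, sorted for
    deterministic order.
    """
    lo, hi = length_range
    peptides = pyt_parser.cleave(sequence, TRYPSIN_P_RULE, missed_cleavages)
    return sorted(p for p in peptides if lo <= len(p) <= hi)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the targeted experimental design: 5 products, on
    average 20 HCPs each, true concentrations log-uniform on
    0.2-350 ng/mg, response-factor sigma 0.5 and injection sigma 0.2,
    and 40 planted degradation + 30 contaminant peptides per product.
    ``intensity_scale`` is the detector response in counts per fmol.
    """

    seed: int = 0
    n_products: int = 5
    product_classes: tuple[str, ...] = ("IgG1", "IgG2", "IgG4", "Fc-fusion", "bispecific")
    host_pool_size: int = 100
    n_hcps_per_product_mean: float = 20.0
    true_conc_range_ng_mg: tuple[float, float] = (0.2, 350.0)
    response_factor_sigma: float = 0.5
    injection_sigma: float = 0.2
    dropout_midpoint_intensity: float | None = 2e4
    dropout_width: float = 1.0
    fraction_shared_peptides: float = 0.05
    n_product_degradation_peptides: int = 40
    n_contaminant_peptides: int = 30
    missed_cleavages: int = 1
    missed_cleavage_penalty: float = 0.1
    peptide_length_range: tuple[int, int] = (7, 30)
    blocks_per_protein: tuple[int, int] = (8, 16)
    intensity_scale: float = 1e6
    n_annotation_terms: int = 60
    terms_per_protein: tuple[int, int] = (2, 8)
    n_risk_listed: int = 5
    design: StudyDesign = field(default_factory=StudyDesign)

    def __post_init__(self) -> None:
        lo, hi = self.peptide_length_range
        if not (1 <= lo <= hi):
            raise ValueError("infeasible peptide length range")
        if hi < 7:
            raise ValueError("length range admits no tryptic block peptides")
        if self.n_products < 1 or self.host_pool_size < 1:
            raise ValueError("cohort sizes must be positive")
        if min(self.true_conc_range_ng_mg) <= 0:
            raise ValueError("true concentrations must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Planted quantities and labels for every artefact in the dataset."""

    concentrations: pd.DataFrame  # product_id, accession, true_conc_ng_mg, true_fmol_on_column, mw_da
    degradation_sequences: dict[str, frozenset[str]]  # per product
    degradation_accessions: frozenset[str]
    contaminant_sequences: frozenset[str]
    contaminant_accessions: frozenset[str]
    shared_sequences: frozenset[str]
    host_keratin_accession: str
    histone_accession: str
    listed_risk_accessions: frozenset[str]
    related_risk_accessions: frozenset[str]

    def true_conc(self, product_id: str, accession: str) -> float:
        df = self.concentrations
        row = df[(df.product_id == product_id) & (df.accession == accession)]
        if row.empty:
            raise KeyError((product_id, accession))
        return float(row.true_conc_ng_mg.iloc[0])


@dataclass(frozen=True)
class SyntheticDataset:
    config: GeneratorConfig
    evidence: list[PeptideEvidence]
    host_records: list[ProteinRecord]
    contaminant_records: list[ProteinRecord]
    product_records: list[ProteinRecord]
    hi3_record: ProteinRecord
    annotations: dict[str, frozenset[str]]
    risk_list: RiskList
    class_map: dict[str, str]
    ground_truth: GroundTruth

    @property
    def design(self) -> StudyDesign:
        return self.config.design

    def all_records(self) -> dict[str, ProteinRecord]:
        out = {r.accession: r for r in self.host_records}
        out.update({r.accession: r for r in self.contaminant_records})
        out.update({r.accession: r for r in self.product_records})
        out[self.hi3_record.accession] = self.hi3_record
        return out


def _random_block(rng: np.random.Generator, length_range: tuple[int, int]) -> str:
    lo, hi = max(length_range[0], 7), min(length_range[1], 30)
    n = int(rng.integers(lo, hi + 1))
    body = "".join(rng.choice(list(_NON_KR), size=n - 1))
    tail = "K" if rng.random() < 0.5 else "R"
    return body + tail


def _random_protein(
    rng: np.random.Generator, cfg: GeneratorConfig, taken: set[str]
) -> tuple[str, list[str]]:
    """A block-structured protein and its guaranteed tryptic peptides."""
    n_blocks = int(rng.integers(cfg.blocks_per_protein[0], cfg.blocks_per_protein[1] + 1))
    blocks: list[str] = []
    seen: set[str] = set()
    while len(blocks) < n_blocks:
        b = _random_block(rng, cfg.peptide_length_range)
        if b not in seen and b not in taken:
            blocks.append(b)
            seen.add(b)
    taken |= seen
    return "".join(blocks), blocks


def _detect_prob(intensity: float, cfg: GeneratorConfig) -> float:
    mid = cfg.dropout_midpoint_intensity
    if not mid or mid <= 0:
        return 1.0
    z = (np.log(intensity) - np.log(mid)) / cfg.dropout_width
    return float(1.0 / (1.0 + np.exp(-z)))


def generate_dataset(cfg: GeneratorConfig) -> SyntheticDataset:
    """Generate a full synthetic cohort. Deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    design = cfg.design
    taken_peptides: set[str] = set()

    # --- host pool -------------------------------------------------------
    host_records: list[ProteinRecord] = []
    peptides_of: dict[str, list[str]] = {}
    terms_universe = [f"GO:{i + 1:07d}" for i in range(cfg.n_annotation_terms)]
    annotations: dict[str, frozenset[str]] = {}
    for i in range(cfg.host_pool_size):
        acc = f"HP{i:04d}"
        seq, blocks = _random_protein(rng, cfg, taken_peptides)
        if i == 0:
            desc = "Histone H4"
        elif i == 1:
            desc = "Keratin, type I cytoskeletal 9"
        else:
            desc = f"Synthetic host protein {i}"
        host_records.append(ProteinRecord(accession=acc, description=desc, sequence=seq))
        peptides_of[acc] = blocks
        n_terms = int(rng.integers(cfg.terms_per_protein[0], cfg.terms_per_protein[1] + 1))
        annotations[acc] = frozenset(
            str(t) for t in rng.choice(terms_universe, size=n_terms, replace=False)
        )
    histone_acc = host_records[0].accession
    keratin_acc = host_records[1].accession

    # --- contaminant database (cRAP-style) -------------------------------
    cont_descs = [
        "Keratin, type II cytoskeletal 1",
        "Trypsin precursor (Sus scrofa)",
        "Serum albumin (Bos taurus)",
    ]
    contaminant_records = []
    for j, desc in enumerate(cont_descs):
        seq, blocks = _random_protein(rng, cfg, taken_peptides)
        acc = f"CRAP{j + 1:03d}"
        contaminant_records.append(
            ProteinRecord(accession=acc, description=desc, sequence=seq, is_contaminant=True)
        )
        peptides_of[acc] = blocks

    # --- Hi3 standard -----------------------------------------------------
    hi3_blocks = [_random_block(rng, (10, 12)) for _ in range(3)]
    hi3_record = ProteinRecord(
        accession=design.hi3_accession,
        description="Hi3 E. coli-style peptide standard (synthetic)",
        sequence="".join(hi3_blocks),
        is_standard=True,
    )

    # --- products ---------------------------------------------------------
    product_records = []
    class_map: dict[str, str] = {}
    for p in range(cfg.n_products):
        pid = f"PROD{p + 1:02d}"
        seq, _ = _random_protein(rng, cfg, taken_peptides)
        seq = seq + _random_protein(rng, cfg, taken_peptides)[0]  # ~2x length, mAb-sized
        product_records.append(
            ProteinRecord(accession=pid, description=f"Biotherapeutic product {pid}", sequence=seq)
        )
        class_map[pid] = cfg.product_classes[p % len(cfg.product_classes)]

    # --- risk list --------------------------------------------------------
    listed = [r.accession for r in host_records[2 : 2 + cfg.n_risk_listed]]
    entries = [
        RiskListEntry(
            accession=acc,
            name=f"Listed high-risk {acc}",
            risk="aggregation/fragmentation",
            annotation_terms=annotations[acc],
        )
        for acc in listed
    ]
    # external entries whose term profiles duplicate two pool proteins, so
    # those proteins flag as functionally related under a different accession
    related: list[str] = []
    for rec in host_records[2 + cfg.n_risk_listed :]:
        if len(annotations[rec.accession]) >= 3 and len(related) < 2:
            related.append(rec.accession)
            entries.append(
                RiskListEntry(
                    accession=f"EXT{len(related):03d}",
                    name=f"External high-risk twin of {rec.accession}",
                    risk="immunogenicity",
                    annotation_terms=annotations[rec.accession],
                )
            )
    risk_list = RiskList(entries=tuple(entries))

    # --- per-product evidence --------------------------------------------
    evidence: list[PeptideEvidence] = []
    truth_rows: list[dict] = []
    degradation_sequences: dict[str, frozenset[str]] = {}
    deg_accessions: set[str] = set()
    shared_sequences: set[str] = set()
    contaminant_sequences: set[str] = set()
    lo_c, hi_c = cfg.true_conc_range_ng_mg
    host_accessions = [r.accession for r in host_records]
    runs = [
        (d, i)
        for d in range(1, design.n_digests + 1)
        for i in range(1, design.n_injections + 1)
    ]

    deg_records: list[ProteinRecord] = []
    for prod in product_records:
        pid = prod.accession
        n_hcps = max(1, int(rng.poisson(cfg.n_hcps_per_product_mean)))
        n_hcps = min(n_hcps, cfg.host_pool_size)
        chosen = [str(a) for a in rng.choice(host_accessions, size=n_hcps, replace=False)]

        # peptide-level plan: candidate peptides with mc counts, RF draws,
        # shared-accession marks
        plan: list[tuple[str, str, frozenset[str], float, int]] = []
        for acc in chosen:
            conc = float(np.exp(rng.uniform(np.log(lo_c), np.log(hi_c))))
            rec = next(r for r in host_records if r.accession == acc)
            mw = molecular_weight(rec.sequence)
            fmol = conc * design.product_mass_on_column_mg / (mw * NG_PER_FMOL_DA)
            truth_rows.append(
                {
                    "product_id": pid,
                    "accession": acc,
                    "true_conc_ng_mg": conc,
                    "true_fmol_on_column": fmol,
                    "mw_da": mw,
                }
            )
            base = peptides_of[acc]
            mc_of = {pep: 0 for pep in base}
            for pep in digest_in_silico(
                rec.sequence, cfg.missed_cleavages, cfg.peptide_length_range
            ):
                if pep not in mc_of:
                    # block construction: extra peptides are concatenations
                    # of >=2 blocks, i.e. carry >=1 missed cleavage
                    mc_of[pep] = 1
            # shared marks: keep at least 4 fully cleaved peptides unshared
            n_shared = int(cfg.fraction_shared_peptides * len(base))
            n_shared = min(n_shared, max(0, len(base) - 4))
            shared_marks = {
                str(s) for s in rng.choice(sorted(base), size=n_shared, replace=False)
            } if n_shared else set()
            for pep in sorted(mc_of):
                rf_z = float(rng.standard_normal())
                accs = {acc}
                if pep in shared_marks:
                    other = str(rng.choice([a for a in host_accessions if a != acc]))
                    accs.add(other)
                    shared_sequences.add(pep)
                plan.append((acc, pep, frozenset(accs), rf_z, mc_of[pep]))

        # planted degradation peptides: verbatim substrings of the product
        deg_seqs: set[str] = set()
        attempts = 0
        while len(deg_seqs) < cfg.n_product_degradation_peptides and attempts < 10_000:
            attempts += 1
            L = int(rng.integers(7, 19))
            start = int(rng.integers(0, len(prod.sequence) - L + 1))
            deg_seqs.add(prod.sequence[start : start + L])
        degradation_sequences[pid] = frozenset(deg_seqs)
        deg_plan = []
        for j, pep in enumerate(sorted(deg_seqs)):
            dacc = f"DEG_{pid}_{j // 3:03d}"
            deg_plan.append((dacc, pep))
        for dacc in sorted({a for a, _ in deg_plan}):
            if dacc not in deg_accessions:
                deg_accessions.add(dacc)
                seq, _ = _random_protein(rng, cfg, taken_peptides)
                deg_records.append(
                    ProteinRecord(
                        accession=dacc,
                        description="Synthetic degradation-carrier record",
                        sequence=seq,
                    )
                )

        # planted contaminant peptides (cRAP accessions + host keratin)
        cont_plan: list[tuple[str, str]] = []
        cont_pool = [
            (rec.accession, pep)
            for rec in contaminant_records
            for pep in peptides_of[rec.accession]
        ] + [(keratin_acc, pep) for pep in peptides_of[keratin_acc][:4]]
        idx = rng.choice(len(cont_pool), size=min(cfg.n_contaminant_peptides, len(cont_pool)), replace=False)
        for ii in sorted(int(x) for x in idx):
            cont_plan.append(cont_pool[ii])
            contaminant_sequences.add(cont_pool[ii][1])

        # emit runs with common random numbers across sigma settings
        scale = cfg.intensity_scale
        fmol_of = {
            (r["accession"]): r["true_fmol_on_column"]
            for r in truth_rows
            if r["product_id"] == pid
        }
        for d, i in runs:
            for acc, pep, accs, rf_z, mc in plan:
                eps = float(rng.standard_normal())
                u = float(rng.random())
                intensity = (
                    scale
                    * fmol_of[acc]
                    * np.exp(cfg.response_factor_sigma * rf_z)
                    * cfg.missed_cleavage_penalty**mc
                    * np.exp(cfg.injection_sigma * eps)
                )
                if u >= _detect_prob(intensity, cfg):
                    continue
                evidence.append(
                    PeptideEvidence(
                        product_id=pid,
                        digest_id=d,
                        injection_id=i,
                        sequence=pep,
                        accessions=accs,
                        intensity=float(intensity),
                    )
                )
            for dacc, pep in deg_plan:
                eps = float(rng.standard_normal())
                intensity = 5e4 * np.exp(cfg.injection_sigma * eps)
                evidence.append(
                    PeptideEvidence(
                        product_id=pid,
                        digest_id=d,
                        injection_id=i,
                        sequence=pep,
                        accessions=frozenset({dacc}),
                        intensity=float(intensity),
                    )
                )
            for cacc, pep in cont_plan:
                eps = float(rng.standard_normal())
                intensity = 2e5 * np.exp(cfg.injection_sigma * eps)
                evidence.append(
                    PeptideEvidence(
                        product_id=pid,
                        digest_id=d,
                        injection_id=i,
                        sequence=pep,
                        accessions=frozenset({cacc}),
                        intensity=float(intensity),
                    )
                )
            # Hi3 spike: unit response factor, never dropped
            for pep in hi3_blocks:
                eps = float(rng.standard_normal())
                intensity = scale * design.hi3_fmol_on_column * np.exp(
                    cfg.injection_sigma * eps
                )
                evidence.append(
                    PeptideEvidence(
                        product_id=pid,
                        digest_id=d,
                        injection_id=i,
                        sequence=pep,
                        accessions=frozenset({design.hi3_accession}),
                        intensity=float(intensity),
                    )
                )

    host_records = host_records + deg_records
    truth = GroundTruth(
        concentrations=pd.DataFrame(
            truth_rows,
            columns=["product_id", "accession", "true_conc_ng_mg", "true_fmol_on_column", "mw_da"],
        ),
        degradation_sequences=degradation_sequences,
        degradation_accessions=frozenset(deg_accessions),
        contaminant_sequences=frozenset(contaminant_sequences),
        contaminant_accessions=frozenset(
            [r.accession for r in contaminant_records] + [keratin_acc]
        ),
        shared_sequences=frozenset(shared_sequences),
        host_keratin_accession=keratin_acc,
        histone_accession=histone_acc,
        listed_risk_accessions=frozenset(listed),
        related_risk_accessions=frozenset(related),
    )
    return SyntheticDataset(
        config=cfg,
        evidence=evidence,
        host_records=host_records,
        contaminant_records=contaminant_records,
        product_records=product_records,
        hi3_record=hi3_record,
        annotations=annotations,
        risk_list=risk_list,
        class_map=class_map,
        ground_truth=truth,
    )


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset in every format ``io_formats`` can read back."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "evidence": out / "evidence.tsv",
        "host_fasta": out / "host.fasta",
        "contaminants_fasta": out / "contaminants.fasta",
        "products_fasta": out / "products.fasta",
        "hi3_fasta": out / "hi3.fasta",
        "annotations": out / "annotations.tsv",
        "risk_list": out / "risk_list.tsv",
        "class_map": out / "class_map.tsv",
        "ground_truth": out / "ground_truth.tsv",
        "config": out / "generator_config.json",
    }
    write_peptide_table(ds.evidence, paths["evidence"])
    write_fasta(ds.host_records, paths["host_fasta"])
    write_fasta(ds.contaminant_records, paths["contaminants_fasta"])
    write_fasta(ds.product_records, paths["products_fasta"])
    write_fasta([ds.hi3_record], paths["hi3_fasta"])
    write_annotations(ds.annotations, paths["annotations"])
    write_risk_list(ds.risk_list, paths["risk_list"])
    write_class_map(ds.class_map, paths["class_map"])
    ds.ground_truth.concentrations.to_csv(paths["ground_truth"], sep="\t", index=False)
    cfg_dict = dataclasses.asdict(ds.config)
    with open(paths["config"], "w") as fh:
        json.dump(cfg_dict, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return paths
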