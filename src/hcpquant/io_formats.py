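"""Readers and writers for every external artifact of the HCP pipeline.

Canonical tabular schema for peptide evidence (TSV or CSV):

    product_id, digest_id, injection_id, sequence, modified_sequence,
    accessions (semicolon-separated), intensity

Search-engine exports with different column names are mapped onto this
schema through a *dialect* (a ``canonical -> actual`` column-name mapping).
Sequence databases are plain FASTA with the accession as the first header
token. Reports are TSV; the run manifest is JSON.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

EVIDENCE_COLUMNS = (
    "product_id",
    "digest_id",
    "injection_id",
    "sequence",
    "modified_sequence",
    "accessions",
    "intensity",
)

_REQUIRED_COLUMNS = tuple(c for c in EVIDENCE_COLUMNS if c != "modified_sequence")


class FormatError(ValueError):
    """A file does not conform to the expected tabular/FASTA layout."""


class ValidationError(ValueError):
    """A parsed record violates a domain invariant."""


@dataclass(frozen=True)
class PeptideEvidence:
    """One observed peptide in one product / digest / injection run.

    ``intensity`` is the summed fragment-ion PSM area for this stripped
    sequence in this run; modified forms and charge states are pooled.
    """

    product_id: str
    digest_id: int
    injection_id: int
    sequence: str
    accessions: frozenset[str]
    intensity: float
    modified_sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError("peptide sequence must be non-empty")
        bad = set(self.sequence) - CANONICAL_AA
        if bad:
            raise ValidationError(
                f"non-canonical residue(s) {sorted(bad)} in peptide {self.sequence!r}"
            )
        if self.intensity < 0:
            raise ValidationError(
                f"negative intensity {self.intensity} for peptide {self.sequence!r}"
            )

    @property
    def run_id(self) -> tuple[str, int, int]:
        return (self.product_id, self.digest_id, self.injection_id)


@dataclass(frozen=True)
class ProteinRecord:
    """A database protein: accession, description, sequence, annotations."""

    accession: str
    description: str = ""
    sequence: str = ""
    gene: str | None = None
    annotation_terms: frozenset[str] = frozenset()
    is_contaminant: bool = False
    is_standard: bool = False

    def __post_init__(self) -> None:
        bad = set(self.sequence) - CANONICAL_AA
        if bad:
            raise ValidationError(
                f"non-canonical residue(s) {sorted(bad)} in record {self.accession}"
            )


@dataclass(frozen=True)
class StudyDesign:
    """Replicate layout and the constants of the concentration formula.

    ``hi3_fmol_on_column`` defaults to 50 fmol: a 500 fmol spike
    reconstituted in 50 uL with 5 uL loaded per injection.
    ``product_mass_on_column_mg`` defaults to 5e-4 mg (500 ng loads).
    """

    n_digests: int = 3
    n_injections: int = 2
    hi3_fmol_on_column: float = 50.0
    product_mass_on_column_mg: float = 5e-4
    hi3_accession: str = "HI3STD"

    def __post_init__(self) -> None:
        if self.n_digests < 1 or self.n_injections < 1:
            raise ValidationError("replicate counts must be >= 1")
        if self.hi3_fmol_on_column <= 0 or self.product_mass_on_column_mg <= 0:
            raise ValidationError("on-column amounts must be positive")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and lists steering the peptide/protein filter cascade."""

    min_unique_peptides_id: int = 2
    min_unique_peptides_quant: int = 3
    product_filter_min_length: int = 6  # "longer than 5 amino acids"
    product_filter_min_coverage: float = 0.8  # strict >
    product_filter_identity: float = 1.0
    contaminant_keywords: tuple[str, ...] = ("keratin",)
    iglike_exclusion_accessions: tuple[str, ...] = ()
    iglike_keywords: tuple[str, ...] = ("ig-like", "immunoglobulin")
    use_iglike_keywords: bool = True
    annotation_exclusion_terms: tuple[str, ...] = ()
    require_same_digest_pair: bool = False

    def __post_init__(self) -> None:
        if self.min_unique_peptides_quant < self.min_unique_peptides_id:
            raise ValidationError("min peptides for quant must be >= min for ID")
        if not 0 <= self.product_filter_min_coverage <= 1:
            raise ValidationError("coverage threshold must be a fraction")


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_peptide_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> list[PeptideEvidence]:
    """Read a peptide/PSM evidence table and aggregate to peptide-run level.

    Rows sharing (product, digest, injection, stripped sequence) are pooled
    by summing intensity across modified forms and charge states. ``dialect``
    maps canonical column names to the file's actual column names.
    """
    df = _read_table(path)
    dialect = dict(dialect or {})
    rename = {dialect.get(c, c): c for c in EVIDENCE_COLUMNS}
    df = df.rename(columns=rename)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    if "modified_sequence" not in df.columns:
        df["modified_sequence"] = ""

    records: dict[tuple[str, int, int, str], dict] = {}
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        try:
            intensity = float(row.intensity)
        except ValueError as exc:
            raise ValidationError(f"row {pos}: unparseable intensity {row.intensity!r}") from exc
        if intensity < 0:
            raise ValidationError(f"row {pos}: negative intensity {intensity}")
        key = (str(row.product_id), int(row.digest_id), int(row.injection_id), row.sequence)
        accs = frozenset(a for a in str(row.accessions).split(";") if a)
        slot = records.get(key)
        if slot is None:
            records[key] = {
                "intensity": intensity,
                "accessions": accs,
                "modified": {row.modified_sequence} if row.modified_sequence else set(),
            }
        else:
            slot["intensity"] += intensity
            slot["accessions"] = slot["accessions"] | accs
            if row.modified_sequence:
                slot["modified"].add(row.modified_sequence)
    out = []
    for (product, digest, injection, sequence), slot in sorted(records.items()):
        mods = sorted(slot["modified"])
        out.append(
            PeptideEvidence(
                product_id=product,
                digest_id=digest,
                injection_id=injection,
                sequence=sequence,
                accessions=slot["accessions"],
                intensity=slot["intensity"],
                modified_sequence=mods[0] if len(mods) == 1 else None,
            )
        )
    return out


def write_peptide_table(evidence: Iterable[PeptideEvidence], path: str | Path) -> None:
    """Write evidence in the canonical TSV schema (round-trips exactly)."""
    rows = [
        {
            "product_id": ev.product_id,
            "digest_id": ev.digest_id,
            "injection_id": ev.injection_id,
            "sequence": ev.sequence,
            "modified_sequence": ev.modified_sequence or "",
            "accessions": ";".join(sorted(ev.accessions)),
            "intensity": repr(ev.intensity),
        }
        for ev in evidence
    ]
    df = pd.DataFrame(rows, columns=list(EVIDENCE_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def read_fasta(
    path: str | Path,
    *,
    is_contaminant: bool = False,
    is_standard: bool = False,
) -> list[ProteinRecord]:
    """Read a FASTA database into ProteinRecords.

    The accession is the first whitespace-delimited token of the header;
    the rest of the header line becomes the description. Sequences are
    uppercased; duplicate accessions and non-canonical residues are errors.
    """
    out: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id
        if accession in seen:
            raise FormatError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        description = rec.description[len(rec.id):].strip()
        out.append(
            ProteinRecord(
                accession=accession,
                description=description,
                sequence=str(rec.seq).upper(),
                is_contaminant=is_contaminant,
                is_standard=is_standard,
            )
        )
    return out


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.accession} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_annotations(path: str | Path) -> dict[str, frozenset[str]]:
    """Read an accession -> annotation-term mapping (TSV: accession, terms ';'-joined)."""
    df = _read_table(path)
    if not {"accession", "terms"} <= set(df.columns):
        raise FormatError("annotation file needs columns: accession, terms")
    return {
        str(r.accession): frozenset(t for t in str(r.terms).split(";") if t)
        for r in df.itertuples(index=False)
    }


def write_annotations(annotations: Mapping[str, frozenset[str]], path: str | Path) -> None:
    rows = [
        {"accession": acc, "terms": ";".join(sorted(terms))}
        for acc, terms in sorted(annotations.items())
    ]
    pd.DataFrame(rows, columns=["accession", "terms"]).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class RiskListEntry:
    accession: str
    name: str = ""
    risk: str = ""
    annotation_terms: frozenset[str] = frozenset()


@dataclass(frozen=True)
class RiskList:
    """A curated list of high-risk HCPs (BPDG-style), accession-unique."""

    entries: tuple[RiskListEntry, ...]

    def __post_init__(self) -> None:
        accs = [e.accession for e in self.entries]
        if len(accs) != len(set(accs)):
            raise ValidationError("risk list accessions must be unique")

    @property
    def accessions(self) -> frozenset[str]:
        return frozenset(e.accession for e in self.entries)


def read_risk_list(path: str | Path) -> RiskList:
    """Read a risk list TSV: accession, name, risk, terms (';'-joined)."""
    df = _read_table(path)
    if "accession" not in df.columns:
        raise FormatError("risk list needs an 'accession' column")
    entries = tuple(
        RiskListEntry(
            accession=str(r.accession),
            name=str(getattr(r, "name_", getattr(r, "name", ""))),
            risk=str(getattr(r, "risk", "")),
            annotation_terms=frozenset(
                t for t in str(getattr(r, "terms", "")).split(";") if t
            ),
        )
        for r in df.itertuples(index=False)
    )
    return RiskList(entries=entries)


def write_risk_list(risk_list: RiskList, path: str | Path) -> None:
    rows = [
        {
            "accession": e.accession,
            "name": e.name,
            "risk": e.risk,
            "terms": ";".join(sorted(e.annotation_terms)),
        }
        for e in risk_list.entries
    ]
    pd.DataFrame(rows, columns=["accession", "name", "risk", "terms"]).to_csv(
        path, sep="\t", index=False
    )


def read_class_map(path: str | Path) -> dict[str, str]:
    """Read the product -> therapeutic-class map (TSV: product_id, product_class)."""
    df = _read_table(path)
    if not {"product_id", "product_class"} <= set(df.columns):
        raise FormatError("class map needs columns: product_id, product_class")
    return {str(r.product_id): str(r.product_class) for r in df.itertuples(index=False)}


def write_class_map(class_map: Mapping[str, str], path: str | Path) -> None:
    rows = [{"product_id": p, "product_class": c} for p, c in sorted(class_map.items())]
    pd.DataFrame(rows, columns=["product_id", "product_class"]).to_csv(
        path, sep="\t", index=False
    )


def write_reports(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    manifest: Mapping | None = None,
) -> dict[str, Path]:
    """Write named report tables as TSV plus a JSON run manifest.

    Empty tables produce headers-only files; the manifest is always written.
    Output is deterministic: identical inputs give byte-identical bodies.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        written[name] = path
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(_jsonable(dict(manifest or {})), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["manifest"] = manifest_path
    return written


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (frozenset, set)):
        return sorted(_jsonable(v) for v in obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
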