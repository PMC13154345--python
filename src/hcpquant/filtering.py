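"""Peptide filter cascade and protein-identification validation.

The cascade runs in a fixed order per product:

1. contaminant removal (sample-preparation contaminants and keratins),
2. shared-peptide removal (survivors are the *unique* peptides),
3. replicate consistency (kept only if seen in both injections of at
   least one digest),
4. product-similarity exclusion (peptides attributable to degradation
   of the biotherapeutic itself).

A protein identification is valid with >= 2 surviving unique peptides;
>= 3 unique peptides make it quantifiable by Top3.
"""

from __future__ import annotations

from collections import defaultdict
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

from .io_formats import FilterConfig, PeptideEvidence, ProteinRecord, StudyDesign


@dataclass(frozen=True)
class FilterTrace:
    """Provenance of one cascade stage: counts and removed records."""

    stage: str
    peptides_in: int
    peptides_removed: int
    removed_records: tuple[tuple[str, str], ...] = ()  # (sequence, reason)

    def __post_init__(self) -> None:
        if not 0 <= self.peptides_removed <= self.peptides_in:
            raise ValueError("trace counts must satisfy in >= removed >= 0")

    @property
    def peptides_out(self) -> int:
        return self.peptides_in - self.peptides_removed


@dataclass(frozen=True)
class IdentifiedProtein:
    """A per-product protein call after the peptide cascade."""

    product_id: str
    accession: str
    unique_peptides: frozenset[str]
    identified: bool
    quantifiable: bool

    def __post_init__(self) -> None:
        if self.quantifiable and not self.identified:
            raise ValueError("quantifiable implies identified")


def _trace(
    stage: str,
    evidence: Sequence[PeptideEvidence],
    removed: list[tuple[PeptideEvidence, str]],
) -> FilterTrace:
    return FilterTrace(
        stage=stage,
        peptides_in=len(evidence),
        peptides_removed=len(removed),
        removed_records=tuple((ev.sequence, reason) for ev, reason in removed),
    )


def remove_contaminant_peptides(
    evidence: Sequence[PeptideEvidence],
    contaminant_db: Iterable[ProteinRecord],
    keywords: Sequence[str] = ("keratin",),
    *,
    description_lookup: Mapping[str, str] | None = None,
) -> tuple[list[PeptideEvidence], FilterTrace]:
    """Drop peptides attributable to sample-preparation contaminants.

    A peptide is removed if any of its accessions is in the contaminant
    database, if any of its accessions' descriptions matches a keyword
    (case-insensitive; catches host keratins absent from the cRAP-style
    database), or if its sequence occurs verbatim in a contaminant sequence.
    ``description_lookup`` supplies descriptions for host accessions.
    """
    db = list(contaminant_db)
    cont_accessions = {r.accession for r in db}
    cont_sequences = [r.sequence for r in db if r.sequence]
    descriptions = dict(description_lookup or {})
    for rec in db:
        descriptions.setdefault(rec.accession, rec.description)
    kw = [k.lower() for k in keywords]

    kept: list[PeptideEvidence] = []
    removed: list[tuple[PeptideEvidence, str]] = []
    for ev in evidence:
        if ev.accessions & cont_accessions:
            removed.append((ev, "SPPC"))
            continue
        desc_hit = next(
            (
                k
                for acc in sorted(ev.accessions)
                for k in kw
                if k in descriptions.get(acc, "").lower()
            ),
            None,
        )
        if desc_hit is not None:
            removed.append((ev, desc_hit))
            continue
        if any(ev.sequence in seq for seq in cont_sequences):
            removed.append((ev, "SPPC-sequence"))
            continue
        kept.append(ev)
    return kept, _trace("contaminants", evidence, removed)


def remove_shared_peptides(
    evidence: Sequence[PeptideEvidence],
) -> tuple[list[PeptideEvidence], FilterTrace]:
    """Keep only peptides mapping to exactly one protein (unique peptides).

    Unmapped peptides (empty accession set) are removed too, with a
    distinct reason: they cannot support any protein.
    """
    kept: list[PeptideEvidence] = []
    removed: list[tuple[PeptideEvidence, str]] = []
    for ev in evidence:
        if len(ev.accessions) > 1:
            removed.append((ev, "shared"))
        elif not ev.accessions:
            removed.append((ev, "unmapped"))
        else:
            kept.append(ev)
    return kept, _trace("shared", evidence, removed)


def replicate_consistency_filter(
    evidence: Sequence[PeptideEvidence],
    design: StudyDesign,
) -> tuple[list[PeptideEvidence], FilterTrace]:
    """Keep a peptide only if some digest contains it in every injection.

    The rule is evaluated per (product, sequence); a peptide that passes
    is kept in *all* runs where it was observed, otherwise every
    observation of it is removed.
    """
    injections = set(range(1, design.n_injections + 1))
    seen: dict[tuple[str, str], dict[int, set[int]]] = defaultdict(lambda: defaultdict(set))
    for ev in evidence:
        if not 1 <= ev.digest_id <= design.n_digests or ev.injection_id not in injections:
            raise ValueError(
                f"run ({ev.digest_id},{ev.injection_id}) outside design "
                f"{design.n_digests}x{design.n_injections}"
            )
        seen[(ev.product_id, ev.sequence)][ev.digest_id].add(ev.injection_id)
    passing = {
        key
        for key, per_digest in seen.items()
        if any(obs >= injections for obs in per_digest.values())
    }
    kept: list[PeptideEvidence] = []
    removed: list[tuple[PeptideEvidence, str]] = []
    for ev in evidence:
        if (ev.product_id, ev.sequence) in passing:
            kept.append(ev)
        else:
            removed.append((ev, "replicate"))
    return kept, _trace("replicate", evidence, removed)


def longest_common_substring_length(a: str, b: str) -> int:
    """Length of the longest common substring of ``a`` and ``b``.

    Scans candidate lengths from ``min(len(a), len(b))`` downwards; the
    peptide side is short (<= ~30 residues) so this is fast in practice.
    """
    if not a or not b:
        return 0
    if len(a) > len(b):
        a, b = b, a
    for m in range(len(a), 0, -1):
        for start in range(0, len(a) - m + 1):
            if a[start : start + m] in b:
                return m
    return 0


def product_similarity_filter(
    evidence: Sequence[PeptideEvidence],
    product_seqs: Sequence[str],
    contaminant_seqs: Sequence[str] = (),
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[PeptideEvidence], FilterTrace]:
    """Remove peptides attributable to product degradation.

    The exclusion criterion — an exact-identity local match covering
    more than 80% of the peptide — is evaluated exactly: with no
    mismatches or gaps allowed, the best local alignment is the longest
    common substring, so a peptide of length L > 5 is removed iff
    LCS(peptide, target)/L strictly exceeds the coverage threshold
    against any product or contaminant sequence. This makes the
    BLAST-style screen deterministic and parameter-free.
    """
    targets = [s for s in list(product_seqs) + list(contaminant_seqs) if s]
    kept: list[PeptideEvidence] = []
    removed: list[tuple[PeptideEvidence, str]] = []
    min_len = cfg.product_filter_min_length
    for ev in evidence:
        L = len(ev.sequence)
        if L < min_len or not targets:
            kept.append(ev)
            continue
        best = max(longest_common_substring_length(ev.sequence, t) for t in targets)
        if best / L > cfg.product_filter_min_coverage:
            removed.append((ev, "product-similarity"))
        else:
            kept.append(ev)
    return kept, _trace("product-similarity", evidence, removed)


def run_cascade(
    evidence: Sequence[PeptideEvidence],
    *,
    contaminant_db: Iterable[ProteinRecord],
    product_seqs: Sequence[str],
    design: StudyDesign,
    cfg: FilterConfig = FilterConfig(),
    description_lookup: Mapping[str, str] | None = None,
    contaminant_seqs_for_similarity: Sequence[str] = (),
) -> tuple[list[PeptideEvidence], list[FilterTrace]]:
    """Run the full peptide-level cascade in its fixed order."""
    traces: list[FilterTrace] = []
    ev, tr = remove_contaminant_peptides(
        evidence, contaminant_db, cfg.contaminant_keywords,
        description_lookup=description_lookup,
    )
    traces.append(tr)
    ev, tr = remove_shared_peptides(ev)
    traces.append(tr)
    ev, tr = replicate_consistency_filter(ev, design)
    traces.append(tr)
    ev, tr = product_similarity_filter(
        ev, product_seqs, contaminant_seqs_for_similarity, cfg
    )
    traces.append(tr)
    return ev, traces


def validate_identifications(
    evidence: Sequence[PeptideEvidence],
    cfg: FilterConfig = FilterConfig(),
    design: StudyDesign = StudyDesign(),
    *,
    exclude_accessions: Iterable[str] = (),
) -> list[IdentifiedProtein]:
    """Call protein identifications from cascade-surviving evidence.

    Per product x accession: ``identified`` requires at least
    ``min_unique_peptides_id`` distinct surviving peptide sequences and
    ``quantifiable`` at least ``min_unique_peptides_quant``. With
    ``require_same_digest_pair`` set, identification additionally needs a
    single digest in which both injections contain that many of the
    protein's peptides. Product and standard accessions are excluded via
    ``exclude_accessions``.
    """
    excluded = set(exclude_accessions)
    peptides: dict[tuple[str, str], set[str]] = defaultdict(set)
    by_run: dict[tuple[str, str], dict[tuple[int, int], set[str]]] = defaultdict(
        lambda: defaultdict(set)
    )
    for ev in evidence:
        if len(ev.accessions) != 1:
            raise ValueError("validate_identifications expects unique peptides")
        (acc,) = ev.accessions
        if acc in excluded:
            continue
        key = (ev.product_id, acc)
        peptides[key].add(ev.sequence)
        by_run[key][(ev.digest_id, ev.injection_id)].add(ev.sequence)

    out: list[IdentifiedProtein] = []
    for (product, acc), seqs in sorted(peptides.items()):
        n = len(seqs)
        identified = n >= cfg.min_unique_peptides_id
        if identified and cfg.require_same_digest_pair:
            runs = by_run[(product, acc)]
            identified = any(
                all(
                    len(runs.get((d, i), ())) >= cfg.min_unique_peptides_id
                    for i in range(1, design.n_injections + 1)
                )
                for d in range(1, design.n_digests + 1)
            )
        quantifiable = identified and n >= cfg.min_unique_peptides_quant
        out.append(
            IdentifiedProtein(
                product_id=product,
                accession=acc,
                unique_peptides=frozenset(seqs),
                identified=identified,
                quantifiable=quantifiable,
            )
        )
    return out


def annotation_exclusion_filter(
    proteins: Sequence[IdentifiedProtein],
    records: Mapping[str, ProteinRecord],
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[IdentifiedProtein], FilterTrace]:
    """Exclude identified proteins by annotation term or Ig-like identity.

    Removes proteins whose annotation terms intersect the configured
    exclusion terms (e.g. desmosome / keratinization GO terms), whose
    accession is on the Ig-like exclusion list, or — when the keyword
    rule is enabled — whose description matches an Ig-like keyword.
    """
    excl_terms = set(cfg.annotation_exclusion_terms)
    excl_accs = set(cfg.iglike_exclusion_accessions)
    kw = [k.lower() for k in cfg.iglike_keywords] if cfg.use_iglike_keywords else []
    kept: list[IdentifiedProtein] = []
    removed: list[tuple[str, str]] = []
    for prot in proteins:
        rec = records.get(prot.accession)
        terms = rec.annotation_terms if rec else frozenset()
        desc = (rec.description if rec else "").lower()
        if terms & excl_terms:
            removed.append((prot.accession, "annotation-term"))
        elif prot.accession in excl_accs:
            removed.append((prot.accession, "iglike-list"))
        elif any(k in desc for k in kw):
            removed.append((prot.accession, "iglike-keyword"))
        else:
            kept.append(prot)
    trace = FilterTrace(
        stage="annotation-exclusion",
        peptides_in=len(proteins),
        peptides_removed=len(removed),
        removed_records=tuple(removed),
    )
    return kept, trace
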