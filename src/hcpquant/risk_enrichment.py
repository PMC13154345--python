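"""High-risk HCP flagging and EASE-score term enrichment.

Risk flagging mirrors the DAVID-style workflow used for biotherapeutic
impurity assessment: an identified HCP is *listed_high_risk* when its
accession appears on a curated high-risk list (BPDG-style);
*functionally_related* when its annotation-term vector agrees with some
listed entry at Cohen's kappa >= 0.5 with an overlap of >= 3 shared
terms (a protein functionally identical to a listed one but filed under
a different accession); *histone_smuggler* when it matches a histone
pattern (histones can carry other HCPs through purification); otherwise
*none*. Precedence is in that order.

Enrichment uses the EASE score — a conservative one-tailed Fisher exact
test with one observation removed from the gene-list hit cell — with
Benjamini-Hochberg control and a minimum-hit-count gate.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import ProteinRecord, RiskList


@dataclass(frozen=True)
class RiskAnnotation:
    accession: str
    status: str  # listed_high_risk | functionally_related | histone_smuggler | none
    best_match_accession: str | None = None
    kappa: float = 0.0
    overlap: int = 0

    def __post_init__(self) -> None:
        if self.status not in (
            "listed_high_risk",
            "functionally_related",
            "histone_smuggler",
            "none",
        ):
            raise ValueError(f"unknown risk status {self.status!r}")
        if self.status == "functionally_related" and not (
            self.kappa >= 0.5 and self.overlap >= 3
        ):
            raise ValueError("functionally_related requires kappa >= 0.5, overlap >= 3")


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    list_hits: int
    list_size: int
    background_hits: int
    background_size: int
    ease_p: float
    bh_adjusted_p: float
    significant: bool


def ease_score(list_hits: int, list_size: int, background_hits: int, background_size: int) -> float:
    """EASE score: upper-tail hypergeometric p with the hit cell debited by one.

    For k list hits out of an n-gene list, K background hits in an
    N-gene background, the score is P(X >= k-1) for hypergeometric X;
    k = 0 is defined as p = 1. Always >= the plain Fisher exact p.
    """
    k, n, K, N = list_hits, list_size, background_hits, background_size
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent 2x2 margins: k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    # P(X >= k-1) = sf(k-2); exact tail, no approximation
    return float(stats.hypergeom.sf(k - 2, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return [float(v) for v in stats.false_discovery_control(p, method="bh")]


def kappa_similarity(
    terms_a: Iterable[str], terms_b: Iterable[str], universe: Iterable[str]
) -> tuple[float, int]:
    """Cohen's kappa between two binary annotation vectors over a term universe.

    Agreement Po is the fraction of universe terms on which the two
    proteins agree (both annotated or both not); Pe is the expected
    agreement under independence. Degenerate Pe = 1 (both vectors
    constant) yields kappa 1 for identical vectors, else 0.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("kappa universe must be non-empty")
    a = frozenset(terms_a) & universe
    b = frozenset(terms_b) & universe
    n = len(universe)
    overlap = len(a & b)
    both_absent = n - len(a) - len(b) + overlap
    po = (overlap + both_absent) / n
    pe = (len(a) * len(b) + (n - len(a)) * (n - len(b))) / (n * n)
    if pe == 1.0:
        return (1.0 if a == b else 0.0), overlap
    return (po - pe) / (1.0 - pe), overlap


def enrich_terms(
    gene_list: Iterable[str],
    background_annotations: Mapping[str, frozenset[str]],
    *,
    alpha: float = 0.01,
    min_count: int = 3,
) -> list[EnrichmentResult]:
    """EASE enrichment of every background term in ``gene_list``.

    ``background_annotations`` maps every background accession to its
    annotation terms; the list must be a subset of the background. A
    term is significant when its B-H adjusted p <= ``alpha`` *and* it
    has at least ``min_count`` list hits. Results are sorted by adjusted
    p, then term id.
    """
    background = set(background_annotations)
    genes = set(gene_list)
    stray = genes - background
    if stray:
        raise ValueError(f"gene list members missing from background: {sorted(stray)[:5]}")
    n, N = len(genes), len(background)
    terms = sorted({t for terms in background_annotations.values() for t in terms})
    rows = []
    for term in terms:
        members = {acc for acc, ts in background_annotations.items() if term in ts}
        K = len(members)
        k = len(members & genes)
        rows.append((term, k, K, ease_score(k, n, K, N)))
    adj = bh_adjust([p for *_, p in rows]) if rows else []
    results = [
        EnrichmentResult(
            term=term,
            list_hits=k,
            list_size=n,
            background_hits=K,
            background_size=N,
            ease_p=p,
            bh_adjusted_p=q,
            significant=(q <= alpha and k >= min_count),
        )
        for (term, k, K, p), q in zip(rows, adj)
    ]
    results.sort(key=lambda r: (r.bh_adjusted_p, r.term))
    return results


def flag_risk(
    accessions: Iterable[str],
    records: Mapping[str, ProteinRecord],
    risk_list: RiskList,
    annotations: Mapping[str, frozenset[str]],
    universe: Iterable[str] | None = None,
    *,
    kappa_threshold: float = 0.5,
    min_overlap: int = 3,
    histone_pattern: str = "histone",
) -> dict[str, RiskAnnotation]:
    """Assign exactly one risk status to every identified accession.

    The kappa universe defaults to all terms annotated to any protein in
    ``annotations`` plus the risk-list entries' terms.
    """
    if universe is None:
        universe = set()
        for terms in annotations.values():
            universe |= terms
        for entry in risk_list.entries:
            universe |= entry.annotation_terms
    universe = frozenset(universe)
    hist_re = re.compile(histone_pattern, re.IGNORECASE)
    out: dict[str, RiskAnnotation] = {}
    for acc in sorted(set(accessions)):
        if acc in risk_list.accessions:
            out[acc] = RiskAnnotation(accession=acc, status="listed_high_risk")
            continue
        terms = annotations.get(acc, frozenset())
        qualifying: list[tuple[float, int, str]] = []
        if terms and universe:
            for entry in risk_list.entries:
                if not entry.annotation_terms:
                    continue
                kap, ov = kappa_similarity(terms, entry.annotation_terms, universe)
                if kap >= kappa_threshold and ov >= min_overlap:
                    qualifying.append((kap, ov, entry.accession))
        if qualifying:
            best_kappa, best_overlap, best_match = max(
                qualifying, key=lambda t: (t[0], t[1], t[2])
            )
            out[acc] = RiskAnnotation(
                accession=acc,
                status="functionally_related",
                best_match_accession=best_match,
                kappa=best_kappa,
                overlap=best_overlap,
            )
            continue
        rec = records.get(acc)
        haystacks = [rec.description if rec else "", (rec.gene or "") if rec else ""]
        if any(hist_re.search(h) for h in haystacks if h):
            out[acc] = RiskAnnotation(accession=acc, status="histone_smuggler")
        else:
            out[acc] = RiskAnnotation(accession=acc, status="none")
    return out
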