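"""Cohort- and product-level summaries of HCP quantitation results.

Reporting conventions: threshold fractions ("below X ng/mg") are strict
and computed over Top3-quantified instances only; Top2 estimates appear
in the instance table, flagged by mode, but never in threshold counts or
product totals. Class set comparisons are emitted as a binary
accession x class membership matrix (the data behind an UpSet plot).
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .quantitation import QuantResult

DEFAULT_THRESHOLDS = (1.0, 10.0, 20.0, 100.0)

INSTANCE_COLUMNS = (
    "product_id",
    "accession",
    "mean_conc_ng_mg",
    "sd_conc_ng_mg",
    "cv_percent",
    "n_unique_peptides",
    "n_digests_used",
    "mode",
)


@dataclass(frozen=True)
class CohortSummary:
    instance_table: pd.DataFrame
    per_product_totals: dict[str, dict[str, float]]
    threshold_fractions: dict[float, tuple[int, float]]
    extremes: tuple[tuple[str, str, float] | None, tuple[str, str, float] | None]
    incidence: dict[str, int]
    class_membership: pd.DataFrame


def instance_table(quant_results: Sequence[QuantResult]) -> pd.DataFrame:
    """One row per product x accession quantitation instance."""
    rows = [
        {
            "product_id": q.product_id,
            "accession": q.accession,
            "mean_conc_ng_mg": q.mean_conc,
            "sd_conc_ng_mg": q.sd_conc,
            "cv_percent": q.cv_percent,
            "n_unique_peptides": q.n_unique_peptides,
            "n_digests_used": q.n_digests_used,
            "mode": q.mode,
        }
        for q in sorted(quant_results, key=lambda q: (q.product_id, q.accession))
    ]
    return pd.DataFrame(rows, columns=list(INSTANCE_COLUMNS))


def summarize_cohort(
    quant_results: Sequence[QuantResult],
    class_map: Mapping[str, str],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> CohortSummary:
    """Compute the cohort summary from validated quantitation results.

    Every product present in the results must have a class in
    ``class_map``. Totals are exact column sums of quantified means.
    """
    for q in quant_results:
        if q.product_id not in class_map:
            raise KeyError(f"product {q.product_id!r} missing from class map")
    table = instance_table(quant_results)
    quantified = [q for q in quant_results if q.mode == "quantified"]

    per_product: dict[str, dict[str, float]] = {}
    for q in quant_results:
        slot = per_product.setdefault(
            q.product_id, {"n_identified": 0, "n_quantified": 0, "total_ng_mg": 0.0}
        )
        slot["n_identified"] += 1
        if q.mode == "quantified":
            slot["n_quantified"] += 1
            slot["total_ng_mg"] += q.mean_conc

    n_q = len(quantified)
    threshold_fractions = {}
    for t in thresholds:
        count = sum(1 for q in quantified if q.mean_conc < t)
        threshold_fractions[float(t)] = (count, count / n_q if n_q else 0.0)

    if quantified:
        hi = max(quantified, key=lambda q: (q.mean_conc, q.product_id, q.accession))
        lo = min(quantified, key=lambda q: (q.mean_conc, q.product_id, q.accession))
        extremes = (
            (hi.product_id, hi.accession, hi.mean_conc),
            (lo.product_id, lo.accession, lo.mean_conc),
        )
    else:
        extremes = (None, None)

    incidence: dict[str, int] = {}
    for acc in {q.accession for q in quant_results}:
        incidence[acc] = len({q.product_id for q in quant_results if q.accession == acc})

    classes = sorted(set(class_map[q.product_id] for q in quant_results))
    accessions = sorted(incidence)
    member = pd.DataFrame(False, index=accessions, columns=classes)
    for q in quant_results:
        member.loc[q.accession, class_map[q.product_id]] = True
    member.index.name = "accession"

    return CohortSummary(
        instance_table=table,
        per_product_totals=per_product,
        threshold_fractions=threshold_fractions,
        extremes=extremes,
        incidence=incidence,
        class_membership=member,
    )


def summarize_from_table(
    table: pd.DataFrame,
    class_map: Mapping[str, str],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> CohortSummary:
    """Recompute cohort statistics from a supplied instance table.

    Accepts a table in the :data:`INSTANCE_COLUMNS` layout (e.g. a
    previously written report or a supplementary result table mapped
    onto it) and rebuilds QuantResults before summarising, so the same
    code path serves fresh runs and re-analysis of published tables.
    """
    results = [
        QuantResult(
            product_id=str(r.product_id),
            accession=str(r.accession),
            molecular_weight_da=float(getattr(r, "molecular_weight_da", 0.0)) or 1.0,
            per_digest_conc=(),
            mean_conc=float(r.mean_conc_ng_mg),
            sd_conc=float(r.sd_conc_ng_mg),
            cv_percent=float(r.cv_percent),
            n_unique_peptides=int(r.n_unique_peptides),
            n_digests_used=int(r.n_digests_used),
            mode=str(r.mode),
        )
        for r in table.itertuples(index=False)
    ]
    return summarize_cohort(results, class_map, thresholds)


def molar_ratio_range(
    quant_results: Sequence[QuantResult],
    product_mw: Mapping[str, float],
) -> pd.Series:
    """Orders of magnitude between product and HCP molar amounts.

    Per quantified instance: log10 of (mol product per mg product) over
    (mol HCP per mg product), i.e. log10((1e6 / C) * (M_HCP / M_product))
    with C in ng/mg. Indexed by (product, accession).
    """
    values = {}
    for q in quant_results:
        if q.mode != "quantified" or q.mean_conc <= 0:
            continue
        if q.product_id not in product_mw:
            raise KeyError(f"missing product molecular weight for {q.product_id!r}")
        ratio = (1e6 / q.mean_conc) * (q.molecular_weight_da / product_mw[q.product_id])
        values[(q.product_id, q.accession)] = math.log10(ratio)
    return pd.Series(values, dtype=float).sort_index()


@dataclass(frozen=True)
class ReferenceComparison:
    n_common: int
    pearson_r: float  # after exclusions
    pearson_r_all: float  # without exclusions
    excluded: tuple[str, ...]


def compare_to_reference(
    own: Mapping[str, float],
    reference: Mapping[str, float],
    exclude: Sequence[str] = (),
    *,
    log_scale: bool = False,
) -> ReferenceComparison:
    """Pearson correlation of per-accession amounts against another study.

    Computed over accessions common to both mappings, both with and
    without the excluded accessions (outliers); optionally on log10
    concentrations. Fewer than 3 common accessions is an error.
    """
    common = sorted(set(own) & set(reference))
    if len(common) < 3:
        raise ValueError(f"only {len(common)} common accessions; correlation undefined")
    excl = set(exclude)
    kept = [a for a in common if a not in excl]
    if len(kept) < 3:
        raise ValueError("fewer than 3 common accessions remain after exclusion")

    def _vals(accs: list[str]) -> tuple[np.ndarray, np.ndarray]:
        x = np.array([own[a] for a in accs], dtype=float)
        y = np.array([reference[a] for a in accs], dtype=float)
        if log_scale:
            if np.any(x <= 0) or np.any(y <= 0):
                raise ValueError("log-scale comparison requires positive amounts")
            x, y = np.log10(x), np.log10(y)
        return x, y

    r_all = float(stats.pearsonr(*_vals(common)).statistic)
    r_kept = float(stats.pearsonr(*_vals(kept)).statistic)
    return ReferenceComparison(
        n_common=len(common),
        pearson_r=r_kept,
        pearson_r_all=r_all,
        excluded=tuple(sorted(excl & set(common))),
    )
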