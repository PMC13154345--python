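"""Hi3/Top3 absolute quantitation of host-cell proteins.

Each run's HCP signal is the summed intensity of its three most abundant
unique peptides (Top3); dividing by the corresponding Top3 sum of the
spiked Hi3 standard of known molar amount converts signal to femtomoles,
and the protein's molecular weight and the product mass loaded on column
convert that to ng HCP per mg product:

    C = (S_hcp / S_hi3) * F * M_w * 1e-6 / m

with F the Hi3 fmol on column, M_w the average protein mass in Da
(fmol x Da x 1e-6 = ng) and m the product mass on column in mg.

Replication: injections are averaged within each digest first, then the
mean/SD/CV are taken across digests — digestion is the replication unit.
Proteins with exactly two surviving unique peptides cannot be quantified
by Top3; their abundance is *estimated* from the two peptides only and
flagged as such.
"""

from __future__ import annotations

import math
from collections import defaultdict
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

from .filtering import IdentifiedProtein
from .io_formats import PeptideEvidence, ProteinRecord, StudyDesign
from .physchem import molecular_weight

NG_PER_FMOL_DA = 1e-6  # 1 fmol x 1 Da = 1e-15 g = 1e-6 ng


class StandardMissingError(RuntimeError):
    """The Hi3 standard is absent from a run that needs it."""


@dataclass(frozen=True)
class RunTop3:
    """The top-k unique peptides of one protein in one run."""

    product_id: str
    accession: str
    digest_id: int
    injection_id: int
    top_peptides: tuple[tuple[str, float], ...]
    short: bool = False  # fewer peptides observed than requested

    @property
    def top_sum(self) -> float | None:
        if not self.top_peptides:
            return None
        return sum(i for _, i in self.top_peptides)


@dataclass(frozen=True)
class QuantResult:
    product_id: str
    accession: str
    molecular_weight_da: float
    per_digest_conc: tuple[float, ...]
    mean_conc: float
    sd_conc: float
    cv_percent: float
    n_unique_peptides: int
    n_digests_used: int
    mode: str  # "quantified" (Top3) or "estimated" (Top2)

    def __post_init__(self) -> None:
        if self.mode not in ("quantified", "estimated"):
            raise ValueError(f"unknown quantitation mode {self.mode!r}")
        if self.mode == "quantified" and self.n_unique_peptides < 3:
            raise ValueError("Top3 quantitation requires >= 3 unique peptides")


def select_top_peptides(
    run_evidence: Sequence[PeptideEvidence], k: int = 3
) -> RunTop3:
    """Pick the ``k`` highest-intensity unique peptides of one run.

    ``run_evidence`` must belong to a single product x accession x run.
    Ties are broken lexicographically by sequence, so selection is
    deterministic. Fewer than ``k`` observed peptides yields a short,
    flagged selection; none yields an empty one.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not run_evidence:
        # degenerate: nothing observed in this run
        return RunTop3("", "", 0, 0, (), short=True)
    runs = {ev.run_id for ev in run_evidence}
    if len(runs) != 1:
        raise ValueError("select_top_peptides expects evidence from a single run")
    ranked = sorted(run_evidence, key=lambda ev: (-ev.intensity, ev.sequence))[:k]
    first = run_evidence[0]
    (acc,) = first.accessions if len(first.accessions) == 1 else (min(first.accessions),)
    return RunTop3(
        product_id=first.product_id,
        accession=acc,
        digest_id=first.digest_id,
        injection_id=first.injection_id,
        top_peptides=tuple((ev.sequence, ev.intensity) for ev in ranked),
        short=len(ranked) < k,
    )


def hi3_concentration(
    hcp_top_sum: float,
    hi3_top_sum: float,
    design: StudyDesign,
    mw_da: float,
) -> float:
    """Convert a Top3 intensity ratio into ng HCP per mg product."""
    if hi3_top_sum <= 0:
        raise StandardMissingError("Hi3 standard signal is zero; run unusable")
    if mw_da <= 0:
        raise ValueError("molecular weight must be positive")
    if hcp_top_sum < 0:
        raise ValueError("HCP signal must be non-negative")
    fmol = (hcp_top_sum / hi3_top_sum) * design.hi3_fmol_on_column
    return fmol * mw_da * NG_PER_FMOL_DA / design.product_mass_on_column_mg


def _group_by_run(
    evidence: Iterable[PeptideEvidence],
) -> dict[tuple[str, int, int], list[PeptideEvidence]]:
    grouped: dict[tuple[str, int, int], list[PeptideEvidence]] = defaultdict(list)
    for ev in evidence:
        grouped[ev.run_id].append(ev)
    return grouped


def quantify_product(
    evidence: Sequence[PeptideEvidence],
    identified: Sequence[IdentifiedProtein],
    design: StudyDesign,
    records: Mapping[str, ProteinRecord],
    *,
    top_k: int = 3,
    global_top_set: bool = False,
    replicate_unit: str = "digest",
) -> list[QuantResult]:
    """Quantify every identified protein against the per-run Hi3 standard.

    Default behaviour (``global_top_set=False``): the Top3 peptide set is
    chosen per run, which is robust to dropout; the alternative fixes one
    global top-k set per protein (by summed intensity across runs) and
    sums only those peptides in each run. ``replicate_unit`` selects
    whether SD/CV pool digests (default, n<=3) or all runs (n<=6).

    A run lacking the Hi3 standard raises :class:`StandardMissingError`
    naming the run. Runs where a protein shows fewer than the required
    number of peptides contribute no per-injection value.
    """
    if replicate_unit not in ("digest", "run"):
        raise ValueError("replicate_unit must be 'digest' or 'run'")
    by_acc: dict[tuple[str, str], list[PeptideEvidence]] = defaultdict(list)
    for ev in evidence:
        if len(ev.accessions) != 1:
            raise ValueError("quantify_product expects unique peptides")
        (acc,) = ev.accessions
        by_acc[(ev.product_id, acc)].append(ev)

    # Per-run Hi3 Top3 sums, required in every run that has any evidence.
    runs = sorted({ev.run_id for ev in evidence})
    hi3_sums: dict[tuple[str, int, int], float] = {}
    for run in runs:
        hi3_ev = [
            ev
            for ev in by_acc.get((run[0], design.hi3_accession), [])
            if ev.run_id == run
        ]
        if not hi3_ev:
            raise StandardMissingError(
                f"Hi3 standard {design.hi3_accession!r} absent from run "
                f"product={run[0]} digest={run[1]} injection={run[2]}"
            )
        hi3_sums[run] = select_top_peptides(hi3_ev, top_k).top_sum

    results: list[QuantResult] = []
    for prot in sorted(identified, key=lambda p: (p.product_id, p.accession)):
        if not prot.identified or prot.accession == design.hi3_accession:
            continue
        n_pep = len(prot.unique_peptides)
        if prot.quantifiable:
            mode, k_needed = "quantified", top_k
        elif n_pep == 2:
            mode, k_needed = "estimated", 2
        else:
            continue
        rec = records.get(prot.accession)
        if rec is None or not rec.sequence:
            raise KeyError(f"no sequence record for accession {prot.accession}")
        mw = molecular_weight(rec.sequence)
        prot_ev = [
            ev
            for ev in by_acc.get((prot.product_id, prot.accession), [])
            if ev.sequence in prot.unique_peptides
        ]
        global_set: frozenset[str] | None = None
        if global_top_set:
            pooled: dict[str, float] = defaultdict(float)
            for ev in prot_ev:
                pooled[ev.sequence] += ev.intensity
            ranked = sorted(pooled.items(), key=lambda kv: (-kv[1], kv[0]))[:k_needed]
            global_set = frozenset(s for s, _ in ranked)

        per_run: dict[tuple[int, int], float] = {}
        for run, run_ev in sorted(_group_by_run(prot_ev).items()):
            if global_set is not None:
                run_ev = [ev for ev in run_ev if ev.sequence in global_set]
            if len(run_ev) < k_needed:
                continue
            top = select_top_peptides(run_ev, k_needed)
            per_run[(run[1], run[2])] = hi3_concentration(
                top.top_sum, hi3_sums[run], design, mw
            )
        if not per_run:
            continue
        if replicate_unit == "digest":
            by_digest: dict[int, list[float]] = defaultdict(list)
            for (digest, _), conc in per_run.items():
                by_digest[digest].append(conc)
            values = [sum(v) / len(v) for _, v in sorted(by_digest.items())]
        else:
            values = [conc for _, conc in sorted(per_run.items())]
        mean = sum(values) / len(values)
        if len(values) > 1:
            sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (len(values) - 1))
        else:
            sd = 0.0
        cv = 100.0 * sd / mean if mean > 0 else 0.0
        results.append(
            QuantResult(
                product_id=prot.product_id,
                accession=prot.accession,
                molecular_weight_da=mw,
                per_digest_conc=tuple(values),
                mean_conc=mean,
                sd_conc=sd,
                cv_percent=cv,
                n_unique_peptides=n_pep,
                n_digests_used=len(values),
                mode=mode,
            )
        )
    return results
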