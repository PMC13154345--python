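"""ProtParam-style physicochemical descriptors for identified HCPs.

Five descriptors drive the downstream-behaviour profiling of host-cell
proteins: average molecular weight, GRAVY (Kyte-Doolittle grand average
of hydropathy), theoretical pI (Bjellqvist pKa set, bisection solver),
aliphatic index (Ikai) and instability index (Guruprasad). The constant
tables ship with the package (see ``_physchem_tables``) so results are
exactly reproducible offline. No post-translational modifications are
considered.

Classification conventions: *hydrophilic* means GRAVY strictly < 0;
*stable* means instability index strictly < 40.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass

from ._physchem_tables import (
    ALIPHATIC_COEF_ILE_LEU,
    ALIPHATIC_COEF_VAL,
    AVERAGE_RESIDUE_MASS_DA,
    DIWV,
    KYTE_DOOLITTLE,
    NEGATIVE_PKS,
    PK_CTERMINAL,
    PK_NTERMINAL,
    POSITIVE_PKS,
    WATER_MASS_DA,
)
from .io_formats import CANONICAL_AA, ProteinRecord


@dataclass(frozen=True)
class PhysChemProfile:
    accession: str
    molecular_weight_da: float
    gravy: float
    pI: float
    aliphatic_index: float
    instability_index: float

    @property
    def hydrophilic(self) -> bool:
        return self.gravy < 0

    @property
    def stable(self) -> bool:
        return self.instability_index < 40


def _check_sequence(sequence: str, min_length: int = 1) -> None:
    if len(sequence) < min_length:
        raise ValueError(f"sequence must have >= {min_length} residues")
    bad = set(sequence) - CANONICAL_AA
    if bad:
        raise ValueError(f"non-canonical residue(s): {sorted(bad)}")


def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    _check_sequence(sequence)
    return sum(KYTE_DOOLITTLE[a] for a in sequence) / len(sequence)


def molecular_weight(sequence: str) -> float:
    """Average molecular weight in Da: residue masses plus one water."""
    _check_sequence(sequence)
    return sum(AVERAGE_RESIDUE_MASS_DA[a] for a in sequence) + WATER_MASS_DA


def aliphatic_index(sequence: str) -> float:
    """Relative volume of aliphatic side chains (Ala, Val, Ile, Leu).

    AI = X(Ala) + 2.9 X(Val) + 3.9 (X(Ile) + X(Leu)), X in mole percent.
    """
    _check_sequence(sequence)
    n = len(sequence)
    x = {a: 100.0 * sequence.count(a) / n for a in "AVIL"}
    return x["A"] + ALIPHATIC_COEF_VAL * x["V"] + ALIPHATIC_COEF_ILE_LEU * (x["I"] + x["L"])


def instability_index(sequence: str) -> float:
    """Guruprasad instability index: (10/L) * sum of dipeptide weights."""
    _check_sequence(sequence, min_length=2)
    total = sum(DIWV[a][b] for a, b in zip(sequence, sequence[1:]))
    return 10.0 * total / len(sequence)


def net_charge(sequence: str, pH: float) -> float:
    """Net charge of the chain at a given pH (Henderson-Hasselbalch).

    Positive groups: N-terminus, Lys, Arg, His; negative groups:
    C-terminus, Asp, Glu, Cys, Tyr. Terminal pKa values depend on the
    terminal residue where Bjellqvist lists a specific value.
    """
    _check_sequence(sequence)
    counts = {a: sequence.count(a) for a in "KRHDECY"}
    positive = [(PK_NTERMINAL.get(sequence[0], POSITIVE_PKS["Nterm"]), 1)]
    positive += [(POSITIVE_PKS[a], counts[a]) for a in "KRH"]
    negative = [(PK_CTERMINAL.get(sequence[-1], NEGATIVE_PKS["Cterm"]), 1)]
    negative += [(NEGATIVE_PKS[a], counts[a]) for a in "DECY"]
    charge = sum(n / (1.0 + 10.0 ** (pH - pka)) for pka, n in positive)
    charge -= sum(n / (1.0 + 10.0 ** (pka - pH)) for pka, n in negative)
    return charge


def isoelectric_point(sequence: str, tol: float = 1e-4) -> float:
    """Theoretical pI: the pH at which the net charge vanishes.

    The charge is strictly decreasing in pH, so bisection on [0, 14]
    converges unconditionally; the interval is narrowed essentially to
    machine precision, which leaves |net_charge(pI)| well below ``tol``
    even for sequences with a very flat charge curve near the root.
    """
    _check_sequence(sequence)
    lo, hi = 0.0, 14.0
    for _ in range(60):
        pH = (lo + hi) / 2.0
        if net_charge(sequence, pH) > 0:
            lo = pH
        else:
            hi = pH
    pH = (lo + hi) / 2.0
    assert abs(net_charge(sequence, pH)) < tol
    return pH


def profile(record: ProteinRecord) -> PhysChemProfile:
    """Full five-descriptor profile of one protein record."""
    seq = record.sequence
    return PhysChemProfile(
        accession=record.accession,
        molecular_weight_da=molecular_weight(seq),
        gravy=gravy(seq),
        pI=isoelectric_point(seq),
        aliphatic_index=aliphatic_index(seq),
        instability_index=instability_index(seq),
    )


def profile_all(records: Iterable[ProteinRecord]) -> dict[str, PhysChemProfile]:
    return {rec.accession: profile(rec) for rec in records}
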