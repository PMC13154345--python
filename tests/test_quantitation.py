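import numpy as np
import pytest

from hcpquant.filtering import IdentifiedProtein
from hcpquant.io_formats import PeptideEvidence, ProteinRecord, StudyDesign
from hcpquant.quantitation import (
    StandardMissingError,
    hi3_concentration,
    quantify_product,
    select_top_peptides,
)

DESIGN = StudyDesign(n_digests=3, n_injections=2, hi3_fmol_on_column=50.0,
                     product_mass_on_column_mg=5e-4, hi3_accession="HI3STD")


def ev(seq, intensity, acc="A", digest=1, injection=1, product="P1"):
    return PeptideEvidence(product, digest, injection, seq, frozenset({acc}), intensity)


class TestSelectTopPeptides:
    def test_top3_sum_of_five(self):
        run = [ev(s, v) for s, v in zip(["AAK", "CCK", "DDK", "EEK", "FFK"], [5, 4, 3, 2, 1])]
        top = select_top_peptides(run, 3)
        assert top.top_sum == 12 and not top.short

    def test_fewer_than_k_flagged_short(self):
        top = select_top_peptides([ev("AAK", 7)], 3)
        assert top.top_sum == 7 and top.short

    def test_tie_broken_lexicographically(self):
        top = select_top_peptides([ev("CCK", 5), ev("AAK", 5)], 1)
        assert top.top_peptides == (("AAK", 5),)

    def test_agrees_with_sort_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 12))
            intensities = rng.integers(0, 6, size=n)  # many ties
            run = [ev("PEP" + "AG"[j % 2] * (j + 1) + "K", float(v))
                   for j, v in enumerate(intensities)]
            k = int(rng.integers(1, 5))
            oracle = sorted(run, key=lambda e: (-e.intensity, e.sequence))[:k]
            top = select_top_peptides(run, k)
            assert top.top_peptides == tuple((e.sequence, e.intensity) for e in oracle)


class TestHi3Concentration:
    def test_hand_arithmetic_oracle(self):
        # S_hcp = S_hi3, F = 50 fmol, Mw = 20 kDa, m = 5e-4 mg -> 2000 ng/mg
        assert hi3_concentration(1.0, 1.0, DESIGN, 20_000.0) == pytest.approx(2000.0)

    def test_zero_signal_gives_zero(self):
        assert hi3_concentration(0.0, 5.0, DESIGN, 20_000.0) == 0.0

    def test_linearity_in_spike_and_mass(self):
        base = hi3_concentration(2.0, 4.0, DESIGN, 30_000.0)
        double_f = StudyDesign(hi3_fmol_on_column=100.0)
        half = StudyDesign(product_mass_on_column_mg=1e-3)
        assert hi3_concentration(2.0, 4.0, double_f, 30_000.0) == pytest.approx(2 * base)
        assert hi3_concentration(2.0, 4.0, half, 30_000.0) == pytest.approx(base / 2)

    def test_missing_standard_is_error(self):
        with pytest.raises(StandardMissingError):
            hi3_concentration(1.0, 0.0, DESIGN, 20_000.0)


def _records():
    return {
        "A": ProteinRecord(accession="A", sequence="G" * 100),
        "B": ProteinRecord(accession="B", sequence="G" * 100),
        "HI3STD": ProteinRecord(accession="HI3STD", sequence="G" * 30, is_standard=True),
    }


def _hi3_everywhere(value=100.0):
    out = []
    for d in range(1, 4):
        for i in range(1, 3):
            for s in ("HAAAGGGK", "HCCCDDDK", "HEEEFFFK"):
                out.append(ev(s, value, "HI3STD", d, i))
    return out


def _protein_everywhere(acc, peps, value):
    out = []
    for d in range(1, 4):
        for i in range(1, 3):
            for s in peps:
                out.append(ev(s, value, acc, d, i))
    return out


def _identified(acc, peps, quantifiable=True):
    return IdentifiedProtein(
        product_id="P1", accession=acc, unique_peptides=frozenset(peps),
        identified=True, quantifiable=quantifiable,
    )


class TestQuantifyProduct:
    PEPS3 = ("AAAGGGK", "CCCDDDK", "EEEFFFK")

    def test_constant_signal_quantifies_exactly(self):
        evidence = _protein_everywhere("A", self.PEPS3, 50.0) + _hi3_everywhere(100.0)
        (q,) = quantify_product(evidence, [_identified("A", self.PEPS3)], DESIGN, _records())
        expected = hi3_concentration(150.0, 300.0, DESIGN, q.molecular_weight_da)
        assert q.mode == "quantified"
        assert q.per_digest_conc == (expected,) * 3
        assert q.sd_conc == 0.0 and q.n_digests_used == 3

    def test_single_digest_protein_reports_sd_zero(self):
        evidence = [ev(s, 50.0, "A", 2, i) for s in self.PEPS3 for i in (1, 2)]
        evidence += _hi3_everywhere()
        (q,) = quantify_product(evidence, [_identified("A", self.PEPS3)], DESIGN, _records())
        assert q.n_digests_used == 1 and q.sd_conc == 0.0

    def test_two_peptide_protein_estimated_with_top2(self):
        peps = self.PEPS3[:2]
        evidence = _protein_everywhere("B", peps, 60.0) + _hi3_everywhere(100.0)
        (q,) = quantify_product(
            evidence, [_identified("B", peps, quantifiable=False)], DESIGN, _records()
        )
        assert q.mode == "estimated"
        expected = hi3_concentration(120.0, 300.0, DESIGN, q.molecular_weight_da)
        assert q.mean_conc == pytest.approx(expected)

    def test_scale_invariance_per_run(self):
        evidence = _protein_everywhere("A", self.PEPS3, 50.0) + _hi3_everywhere(100.0)
        scaled = [
            PeptideEvidence(e.product_id, e.digest_id, e.injection_id, e.sequence,
                            e.accessions, e.intensity * (7.0 if e.digest_id == 2 else 1.0))
            for e in evidence
        ]
        (q1,) = quantify_product(evidence, [_identified("A", self.PEPS3)], DESIGN, _records())
        (q2,) = quantify_product(scaled, [_identified("A", self.PEPS3)], DESIGN, _records())
        assert q2.mean_conc == pytest.approx(q1.mean_conc)

    def test_linearity_in_hcp_intensity(self):
        evidence = _protein_everywhere("A", self.PEPS3, 50.0) + _hi3_everywhere(100.0)
        boosted = [
            PeptideEvidence(e.product_id, e.digest_id, e.injection_id, e.sequence,
                            e.accessions, e.intensity * (3.0 if "A" in e.accessions else 1.0))
            for e in evidence
        ]
        (q1,) = quantify_product(evidence, [_identified("A", self.PEPS3)], DESIGN, _records())
        (q2,) = quantify_product(boosted, [_identified("A", self.PEPS3)], DESIGN, _records())
        assert q2.mean_conc == pytest.approx(3 * q1.mean_conc)

    def test_hi3_absent_from_run_names_the_run(self):
        evidence = _protein_everywhere("A", self.PEPS3, 50.0)
        evidence += [e for e in _hi3_everywhere() if not (e.digest_id == 3 and e.injection_id == 2)]
        with pytest.raises(StandardMissingError, match="digest=3 injection=2"):
            quantify_product(evidence, [_identified("A", self.PEPS3)], DESIGN, _records())

    def test_runs_with_too_few_peptides_contribute_nothing(self):
        evidence = _protein_everywhere("A", self.PEPS3, 50.0)
        # digest 3 observes only two of the three peptides
        evidence = [
            e for e in evidence
            if not (e.digest_id == 3 and e.sequence == "EEEFFFK")
        ] + _hi3_everywhere()
        (q,) = quantify_product(evidence, [_identified("A", self.PEPS3)], DESIGN, _records())
        assert q.n_digests_used == 2


class TestPipelineRecovery:
    def test_noiseless_pipeline_recovers_truth(self, noiseless_ds, noiseless_result):
        truth = noiseless_ds.ground_truth.concentrations.set_index(
            ["product_id", "accession"]
        ).true_conc_ng_mg
        quantified = [q for q in noiseless_result.quant if q.mode == "quantified"]
        assert len(quantified) >= 20
        for q in quantified:
            t = truth.loc[(q.product_id, q.accession)]
            assert abs(q.mean_conc - t) / t < 1e-9
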