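import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcpquant.filtering import (
    annotation_exclusion_filter,
    longest_common_substring_length,
    product_similarity_filter,
    remove_contaminant_peptides,
    remove_shared_peptides,
    replicate_consistency_filter,
    run_cascade,
    validate_identifications,
)
from hcpquant.io_formats import (
    FilterConfig,
    PeptideEvidence,
    ProteinRecord,
    StudyDesign,
)

DESIGN = StudyDesign(n_digests=3, n_injections=2)


def ev(seq, accs=("A",), product="P1", digest=1, injection=1, intensity=1.0):
    return PeptideEvidence(product, digest, injection, seq, frozenset(accs), intensity)


def everywhere(seq, accs=("A",), product="P1"):
    """One observation of a peptide in every run of the default design."""
    return [
        ev(seq, accs, product, d, i)
        for d in range(1, DESIGN.n_digests + 1)
        for i in range(1, DESIGN.n_injections + 1)
    ]


CRAP = ProteinRecord(
    accession="CRAP001",
    description="Keratin, type II cytoskeletal 1",
    sequence="MMMWWWYYYKAAACCCDDDR",
    is_contaminant=True,
)


class TestContaminantFilter:
    def test_crap_accession_removed_as_sppc(self):
        kept, trace = remove_contaminant_peptides([ev("PEPTIDEK", ("CRAP001",))], [CRAP])
        assert kept == []
        assert trace.removed_records == (("PEPTIDEK", "SPPC"),)

    def test_host_keratin_removed_via_description_keyword(self):
        lookup = {"HK1": "Keratin, type I cytoskeletal 9"}
        kept, trace = remove_contaminant_peptides(
            [ev("PEPTIDEK", ("HK1",))], [CRAP], description_lookup=lookup
        )
        assert kept == []
        assert trace.removed_records[0][1] == "keratin"

    def test_contaminant_subsequence_removed(self):
        kept, _ = remove_contaminant_peptides([ev("MMMWWWYYYK", ("H1",))], [CRAP])
        assert kept == []

    def test_unrelated_peptide_kept(self):
        kept, trace = remove_contaminant_peptides([ev("PEPTIDEK", ("H1",))], [CRAP])
        assert len(kept) == 1 and trace.peptides_removed == 0

    def test_empty_database_is_noop(self):
        evidence = [ev("PEPTIDEK", ("H1",))]
        kept, trace = remove_contaminant_peptides(evidence, [])
        assert kept == evidence and trace.peptides_removed == 0


class TestSharedFilter:
    def test_multi_accession_removed_single_kept_unmapped_removed(self):
        evidence = [ev("AAAGGGK", ("A", "B")), ev("CCCDDDK", ("A",)), ev("EEEFFFK", ())]
        kept, trace = remove_shared_peptides(evidence)
        assert [e.sequence for e in kept] == ["CCCDDDK"]
        reasons = dict(trace.removed_records)
        assert reasons["AAAGGGK"] == "shared"
        assert reasons["EEEFFFK"] == "unmapped"


class TestReplicateFilter:
    def test_both_injections_of_one_digest_suffice(self):
        evidence = [ev("AAAGGGK", digest=1, injection=1), ev("AAAGGGK", digest=1, injection=2),
                    ev("AAAGGGK", digest=3, injection=1)]
        kept, _ = replicate_consistency_filter(evidence, DESIGN)
        assert len(kept) == 3  # kept everywhere it occurs

    def test_one_injection_per_digest_removed(self):
        evidence = [ev("AAAGGGK", digest=d, injection=1) for d in (1, 2, 3)]
        kept, trace = replicate_consistency_filter(evidence, DESIGN)
        assert kept == [] and trace.peptides_removed == 3

    def test_single_injection_design_keeps_single_observation(self):
        design = StudyDesign(n_digests=3, n_injections=1)
        kept, _ = replicate_consistency_filter([ev("AAAGGGK")], design)
        assert len(kept) == 1

    def test_out_of_range_run_ids_error(self):
        with pytest.raises(ValueError, match="outside design"):
            replicate_consistency_filter([ev("AAAGGGK", digest=9)], DESIGN)


PRODUCT = "MSAMPLERSTVVVGGGHHHKLLLNNNPPPQQQR"


class TestProductSimilarityFilter:
    def test_verbatim_substring_removed(self):
        kept, trace = product_similarity_filter([ev("SAMPLERS")], [PRODUCT])
        assert kept == [] and trace.peptides_removed == 1

    def test_coverage_boundary_is_strict(self):
        # length 10, LCS 8 -> 0.80 not > 0.80 -> kept
        kept, _ = product_similarity_filter([ev("SAMPLERSCC")], [PRODUCT])
        assert len(kept) == 1
        # length 10, LCS 9 -> 0.90 -> removed
        kept, _ = product_similarity_filter([ev("SAMPLERSTC")], [PRODUCT])
        assert kept == []

    def test_length_gate_spares_five_residue_substring(self):
        assert "AMPLE" in PRODUCT
        kept, _ = product_similarity_filter([ev("AMPLE")], [PRODUCT])
        assert len(kept) == 1

    def test_six_residue_substring_removed(self):
        kept, _ = product_similarity_filter([ev("SAMPLE")], [PRODUCT])
        assert kept == []

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACDG", min_size=1, max_size=30), st.data())
    def test_lcs_matches_substring_enumeration_oracle(self, pep, data):
        target = data.draw(st.text(alphabet="ACDG", min_size=1, max_size=60))
        oracle = max(
            (
                m
                for m in range(len(pep), 0, -1)
                for s in range(len(pep) - m + 1)
                if pep[s : s + m] in target
            ),
            default=0,
        )
        assert longest_common_substring_length(pep, target) == oracle


class TestCascade:
    def test_idempotence_of_each_stage(self, noisy_ds):
        evidence = [e for e in noisy_ds.evidence[:600]
                    if noisy_ds.design.hi3_accession not in e.accessions]
        db = noisy_ds.contaminant_records
        once, _ = remove_contaminant_peptides(evidence, db)
        twice, tr = remove_contaminant_peptides(once, db)
        assert twice == once and tr.peptides_removed == 0
        once, _ = remove_shared_peptides(evidence)
        twice, tr = remove_shared_peptides(once)
        assert twice == once and tr.peptides_removed == 0
        once, _ = replicate_consistency_filter(evidence, noisy_ds.design)
        twice, tr = replicate_consistency_filter(once, noisy_ds.design)
        assert twice == once and tr.peptides_removed == 0
        prod = [noisy_ds.product_records[0].sequence]
        once, _ = product_similarity_filter(evidence, prod)
        twice, tr = product_similarity_filter(once, prod)
        assert twice == once and tr.peptides_removed == 0

    def test_monotone_and_trace_reconciliation(self, noisy_ds):
        pid = noisy_ds.product_records[0].accession
        evidence = [
            e
            for e in noisy_ds.evidence
            if e.product_id == pid and noisy_ds.design.hi3_accession not in e.accessions
        ]
        prod_seq = noisy_ds.product_records[0].sequence
        out, traces = run_cascade(
            evidence,
            contaminant_db=noisy_ds.contaminant_records,
            product_seqs=[prod_seq],
            design=noisy_ds.design,
            description_lookup={r.accession: r.description for r in noisy_ds.host_records},
        )
        n = len(evidence)
        for trace in traces:
            assert trace.peptides_in == n
            assert trace.peptides_out == n - trace.peptides_removed
            n = trace.peptides_out
        assert n == len(out)
        assert sum(t.peptides_removed for t in traces) + len(out) == len(evidence)


class TestValidateIdentifications:
    def _evidence(self, n_peptides, acc="A"):
        peps = ["AAAGGGK", "CCCDDDK", "EEEFFFK"][:n_peptides]
        return [e for p in peps for e in everywhere(p, (acc,))]

    @pytest.mark.parametrize(
        "n,identified,quantifiable", [(3, True, True), (2, True, False), (1, False, False)]
    )
    def test_peptide_count_rules(self, n, identified, quantifiable):
        (prot,) = validate_identifications(self._evidence(n), design=DESIGN)
        assert prot.identified is identified
        assert prot.quantifiable is quantifiable

    def test_same_digest_pair_rule(self):
        # two peptides, each passing replicate rule in a *different* digest
        evidence = (
            [ev("AAAGGGK", digest=1, injection=i) for i in (1, 2)]
            + [ev("CCCDDDK", digest=2, injection=i) for i in (1, 2)]
        )
        cfg_loose = FilterConfig(require_same_digest_pair=False)
        cfg_strict = FilterConfig(require_same_digest_pair=True)
        (loose,) = validate_identifications(evidence, cfg_loose, DESIGN)
        (strict,) = validate_identifications(evidence, cfg_strict, DESIGN)
        assert loose.identified and not strict.identified

    def test_excluded_accessions_not_called(self):
        out = validate_identifications(
            self._evidence(3, acc="HI3STD"), design=DESIGN, exclude_accessions={"HI3STD"}
        )
        assert out == []


class TestAnnotationExclusion:
    RECORDS = {
        "D1": ProteinRecord(accession="D1", description="Desmoplakin",
                            annotation_terms=frozenset({"GO:0030057"})),
        "I1": ProteinRecord(accession="I1", description="Titin"),
        "K1": ProteinRecord(accession="K1", description="Ig-like domain protein"),
        "N1": ProteinRecord(accession="N1", description="Enolase"),
    }

    def _identified(self, acc):
        from hcpquant.filtering import IdentifiedProtein

        return IdentifiedProtein(
            product_id="P1",
            accession=acc,
            unique_peptides=frozenset({"AAAGGGK", "CCCDDDK"}),
            identified=True,
            quantifiable=False,
        )

    def test_term_list_keyword_and_kept(self):
        cfg = FilterConfig(
            annotation_exclusion_terms=("GO:0030057",),
            iglike_exclusion_accessions=("I1",),
        )
        prots = [self._identified(a) for a in ("D1", "I1", "K1", "N1")]
        kept, trace = annotation_exclusion_filter(prots, self.RECORDS, cfg)
        assert [p.accession for p in kept] == ["N1"]
        assert dict(trace.removed_records) == {
            "D1": "annotation-term",
            "I1": "iglike-list",
            "K1": "iglike-keyword",
        }
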