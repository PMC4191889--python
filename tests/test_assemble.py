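"""Peptide-protein assembly, spectral counting, NSAF, emPAI, digestion."""
import numpy as np
import pytest

from hpcensus.assemble import (
    coverage,
    empai,
    map_peptides,
    nsaf,
    peptide_mass,
    quantify,
    spectral_counts,
    tryptic_digest,
)
from hpcensus.records import ProteinRecord, PSMRecord


def _psm(i, peptide, sample="sperm"):
    return PSMRecord(
        spectrum_id=f"s{i}",
        sample=sample,
        peptide=peptide,
        protein_ids=(),
        charge_class="2",
        tryptic_status="full",
        xcorr=3.0,
        deltacn=0.2,
        delta_mass_ppm=0.0,
    )


# distinct tryptic-looking sequences with controlled shared/unique peptides
PROT_A = ProteinRecord("protA", "MAAAWIDENTVHGGGSHAREDWEEKHHH")
PROT_B = ProteinRecord("protB", "MCCCYVNIGGEFFFSHAREDWEEKGGG")
UNIQUE_A = "WIDENTVHG"
UNIQUE_B = "YVNIGGEFF"
SHARED = "SHAREDWEEK"


def _random_protein(seed: int, length: int = 100) -> ProteinRecord:
    rng = np.random.default_rng(seed)
    letters = rng.choice(list("ACDEFGHIKLNPQRSTVWY"), size=length - 1)
    return ProteinRecord("p", "M" + "".join(letters))


class TestMapPeptides:
    def test_unique_and_shared_classification(self):
        psms = [_psm(0, UNIQUE_A), _psm(1, SHARED)]
        pmap = map_peptides(psms, [PROT_A, PROT_B])
        assert pmap.is_unique(UNIQUE_A)
        assert not pmap.is_unique(SHARED)
        assert pmap.peptide_loci[SHARED] == ("protA", "protB")

    def test_identical_proteins_collapse_to_one_cluster(self):
        twin = ProteinRecord("protZ", PROT_A.sequence)
        psms = [_psm(0, UNIQUE_A)]
        pmap = map_peptides(psms, [PROT_A, twin])
        assert set(pmap.clusters) == {"protA"}
        assert pmap.clusters["protA"].member_ids == ("protA", "protZ")
        # a peptide hitting only the merged cluster counts as unique
        assert pmap.is_unique(UNIQUE_A)

    def test_cluster_naming_is_order_independent(self):
        twin = ProteinRecord("protZ", PROT_A.sequence)
        psms = [_psm(0, UNIQUE_A)]
        forward = map_peptides(psms, [PROT_A, twin])
        backward = map_peptides(psms, [twin, PROT_A])
        assert set(forward.clusters) == set(backward.clusters)

    def test_unmatched_peptide_flagged_unmapped(self):
        pmap = map_peptides([_psm(0, "QQQQQQQ")], [PROT_A, PROT_B])
        assert pmap.unmapped == ["QQQQQQQ"]
        assert "QQQQQQQ" not in pmap.matches

    def test_match_positions_are_exact(self):
        pmap = map_peptides([_psm(0, UNIQUE_A)], [PROT_A])
        start = pmap.matches[UNIQUE_A]["protA"]
        assert PROT_A.sequence[start - 1 : start - 1 + len(UNIQUE_A)] == UNIQUE_A


class TestSpectralCounts:
    def test_shared_spectra_split_proportional_to_unique_evidence(self):
        psms = (
            [_psm(i, UNIQUE_A) for i in range(9)]
            + [_psm(9, UNIQUE_B)]
            + [_psm(10 + i, SHARED) for i in range(10)]
        )
        pmap = map_peptides(psms, [PROT_A, PROT_B])
        counts = spectral_counts(pmap, psms)
        assert counts["protA"] == pytest.approx(9 + 9.0)
        assert counts["protB"] == pytest.approx(1 + 1.0)

    def test_equal_split_without_unique_evidence(self):
        # three loci distinguished only by different shared-peptide sets,
        # so none has unique-peptide evidence: spectra split equally
        s1, s2, s3 = "SHAREDWEEK", "MIDDLEPART", "THIRDPIECE"
        prot_a = ProteinRecord("a", "M" + s1 + "GGG" + s3)
        prot_b = ProteinRecord("b", "M" + s1 + "AAA" + s2)
        prot_c = ProteinRecord("c", "M" + s2 + "CCC" + s3)
        psms = [_psm(i, s1) for i in range(10)] + [_psm(10, s2), _psm(11, s3)]
        pmap = map_peptides(psms, [prot_a, prot_b, prot_c])
        counts = spectral_counts(pmap, psms)
        assert counts["a"] == pytest.approx(5.0 + 0.5)
        assert counts["b"] == pytest.approx(5.0 + 0.5)
        assert counts["c"] == pytest.approx(1.0)

    def test_no_sharing_gives_raw_tallies(self):
        psms = [_psm(i, UNIQUE_A) for i in range(4)]
        pmap = map_peptides(psms, [PROT_A, PROT_B])
        counts = spectral_counts(pmap, psms)
        assert counts["protA"] == 4.0

    def test_conservation_under_splitting(self, passing_psms, targets):
        pmap = map_peptides(passing_psms, targets)
        counts = spectral_counts(pmap, passing_psms)
        n_mapped = sum(
            1 for p in passing_psms if p.peptide in pmap.peptide_loci
        )
        assert sum(counts.values()) == pytest.approx(n_mapped, abs=1e-9)


class TestCoverage:
    def test_single_peptide_fraction(self):
        prot = _random_protein(0)
        pep = prot.sequence[10:35]  # 25 residues of a 100-residue protein
        pmap = map_peptides([_psm(0, pep)], [prot])
        assert coverage(pmap, "p") == pytest.approx(0.25)

    def test_overlapping_intervals_union(self):
        prot = _random_protein(1)
        # residues 1-30 and 21-50: union covers half the protein
        pep1, pep2 = prot.sequence[0:30], prot.sequence[20:50]
        pmap = map_peptides([_psm(0, pep1), _psm(1, pep2)], [prot])
        assert coverage(pmap, "p") == pytest.approx(0.50)


class TestNsaf:
    def test_length_normalised_shares(self):
        values = nsaf({"a": 10.0, "b": 10.0}, {"a": 100, "b": 200})
        assert values["a"] == pytest.approx(2 / 3)
        assert values["b"] == pytest.approx(1 / 3)

    def test_single_locus_is_one(self):
        assert nsaf({"a": 7.0}, {"a": 50}) == {"a": 1.0}

    def test_scale_invariance(self):
        counts = {"a": 3.0, "b": 11.0, "c": 0.5}
        lengths = {"a": 120, "b": 80, "c": 300}
        doubled = {k: 2 * v for k, v in counts.items()}
        assert nsaf(counts, lengths) == pytest.approx(nsaf(doubled, lengths))

    def test_zero_count_loci_excluded_from_normalisation(self):
        values = nsaf({"a": 10.0, "b": 0.0}, {"a": 100, "b": 100})
        assert values == {"a": 1.0, "b": 0.0}

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            nsaf({"a": 0.0}, {"a": 10})


class TestEmpai:
    @pytest.mark.parametrize(
        "observed,observable,expected",
        [(0, 10, 0.0), (10, 10, 9.0), (5, 10, 10 ** 0.5 - 1)],
    )
    def test_formula(self, observed, observable, expected):
        assert empai(observed, observable) == pytest.approx(expected)

    def test_strictly_increasing_in_observed(self):
        values = [empai(k, 20) for k in range(21)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_observed_capped_at_observable(self):
        assert empai(15, 10) == pytest.approx(9.0)

    def test_zero_observable_rejected(self):
        with pytest.raises(ValueError):
            empai(1, 0)


class TestTrypticDigest:
    def test_kr_not_before_p_rule(self):
        prot = ProteinRecord("p", "AKRPGK")
        assert tryptic_digest(prot, (0.0, 1e6)) == ["AK", "RPGK"]

    def test_no_cleavage_sites(self):
        prot = ProteinRecord("p", "AAAGGG")
        assert tryptic_digest(prot, (0.0, 1e6)) == ["AAAGGG"]

    def test_cysteine_carries_fixed_modification(self):
        # Cys residue mass 103.00919 + water 18.010565 + carbamidomethyl
        assert peptide_mass("C") == pytest.approx(
            103.00919 + 18.010565 + 57.02146, abs=1e-4
        )

    def test_mass_window_filters(self):
        prot = ProteinRecord("p", "AKRPGK")  # AK ~ 217 Da, RPGK ~ 441 Da
        assert tryptic_digest(prot, (300.0, 500.0)) == ["RPGK"]


class TestQuantify:
    def test_nsaf_sums_to_one_and_sorted(self, passing_psms, targets):
        frame = quantify(passing_psms, targets, sample="sperm")
        assert frame["nsaf"].sum() == pytest.approx(1.0, abs=1e-9)
        assert list(frame["spectral_count"]) == sorted(
            frame["spectral_count"], reverse=True
        )
        assert (frame["coverage"] <= 1.0).all()
        assert (frame["coverage"] >= 0.0).all()
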