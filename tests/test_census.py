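"""PTM annotation, site coordinates, cross-species mapping, occurrence census."""
import pytest

from hpcensus.census import (
    AmbiguousModificationError,
    CensusTable,
    MOD_DELTAS,
    UnknownModificationError,
    annotate_mod,
    count_occurrences,
    load_printed_census,
    map_cross_species,
    site_coordinates,
)
from hpcensus.io import read_fasta
from hpcensus.records import Mod, ProteinRecord, PSMRecord
from hpcensus import refdata

AC, ME1, ME2, ME3 = 42.0106, 14.0157, 28.0314, 42.0471
UB, PH = 114.042927, 79.9663


class TestAnnotateMod:
    @pytest.mark.parametrize(
        "delta,residue,expected",
        [
            (AC, "K", "ac"),
            (ME3, "K", "me3"),  # 0.0365 Da away from ac: must not collide
            (ME1, "R", "me1"),
            (28.0313, "K", "me2"),  # alternative printed me2 value
            (PH, "S", "ph"),
            (114.0429, "K", "ub"),
        ],
    )
    def test_resolves_unique_type(self, delta, residue, expected):
        assert annotate_mod(delta, residue).ptm_type == expected

    def test_ubiquitination_not_counted_in_census(self):
        assert annotate_mod(UB, "K").counted_in_census is False
        assert annotate_mod(AC, "K").counted_in_census is True

    def test_unknown_delta_rejected(self):
        with pytest.raises(UnknownModificationError):
            annotate_mod(500.0, "K")

    def test_wrong_residue_rejected(self):
        with pytest.raises(UnknownModificationError):
            annotate_mod(AC, "S")  # acetylation is K-only here

    def test_wide_tolerance_is_ambiguous(self):
        with pytest.raises(AmbiguousModificationError):
            annotate_mod(42.03, "K", tolerance=0.05)  # ac and me3 both match


class TestSiteCoordinates:
    def test_post_met_numbering(self):
        protein = ProteinRecord("h4", "MSGRGKGGKGLGK", family="H4")
        psm = _census_psm("x", "SGRGK", (Mod(5, AC),))
        sites, flagged = site_coordinates(psm, protein, match_start=2)
        assert not flagged
        ((site, ptm),) = sites
        assert (site.site_label, ptm) == ("K5", "ac")

    def test_no_met_no_adjustment(self):
        protein = ProteinRecord("p", "SGKGGK", family="H4")
        psm = _census_psm("x", "SGKGGK", (Mod(3, AC),))
        sites, _ = site_coordinates(psm, protein, match_start=1)
        assert sites[0][0].residue_index == 3

    def test_residue_conflict_flagged_not_counted(self):
        protein = ProteinRecord("p", "MSGRGK", family="H2A")
        psm = _census_psm("x", "SGRGK", (Mod(3, AC),))  # ac on R: conflict
        sites, flagged = site_coordinates(psm, protein, match_start=2)
        assert not sites
        assert flagged[0].reason == "residue_conflict"

    def test_modification_on_initiator_met_flagged(self):
        protein = ProteinRecord("p", "MSGRGK", family="H2A")
        psm = _census_psm("x", "MSGRGK", (Mod(1, AC),))
        sites, flagged = site_coordinates(psm, protein, match_start=1)
        assert not sites
        assert len(flagged) == 1  # no counted PTM can sit on the initiator Met

    def test_unknown_delta_flagged(self):
        protein = ProteinRecord("p", "MSGRGK", family="H2A")
        psm = _census_psm("x", "SGRGK", (Mod(5, 500.0),))
        sites, flagged = site_coordinates(psm, protein, match_start=2)
        assert not sites
        assert flagged[0].reason == "unknown_delta"


def _census_psm(sid, peptide, mods, sample="sperm", tryp="full",
                protein_ids=()):
    return PSMRecord(
        spectrum_id=sid,
        sample=sample,
        peptide=peptide,
        protein_ids=protein_ids,
        charge_class="2",
        tryptic_status=tryp,
        xcorr=3.0,
        deltacn=0.2,
        delta_mass_ppm=0.0,
        mods=tuple(mods),
    )


@pytest.fixture(scope="module")
def mouse():
    return {r.protein_id: r for r in read_fasta(refdata.mouse_fasta_path())}


@pytest.fixture(scope="module")
def worm():
    return {r.protein_id: r for r in read_fasta(refdata.celegans_fasta_path())}


class TestCrossSpeciesMapping:
    def test_identity_on_identical_sequences(self, worm):
        h4 = worm["his-4"]
        for idx in (1, 20, 50, len(h4.sequence) - 1):
            assert map_cross_species(h4, h4, idx) == idx

    def test_h2a_ubiquitination_site_correspondence(self, mouse, worm):
        """Mouse H2A K119 is C. elegans K120 under post-Met numbering."""
        assert map_cross_species(mouse["mmu-H2A"], worm["his-2a"], 119) == 120
        assert map_cross_species(worm["his-2a"], mouse["mmu-H2A"], 120) == 119

    def test_h2b_acetylation_site_correspondence(self, mouse, worm):
        """Mouse H2B K12 acetylation corresponds to C. elegans H2B K7."""
        assert map_cross_species(mouse["mmu-H2B"], worm["his-2b"], 12) == 7
        assert map_cross_species(worm["his-2b"], mouse["mmu-H2B"], 7) == 12

    def test_round_trip_identity_off_gaps(self, mouse, worm):
        q, r = worm["his-2a"], mouse["mmu-H2A"]
        for idx in range(1, len(q.sequence) - 1, 7):
            fwd = map_cross_species(q, r, idx)
            if fwd is not None:
                assert map_cross_species(r, q, fwd) == idx


H3 = ProteinRecord("h3", "MARTKQTARKSTGGKAPRKQLATKAARKSAPATGGVKKPH",
                   family="H3")


class TestCountOccurrences:
    def test_single_modified_spectrum(self):
        # H3 K14 acetylation: peptide KSTGGKAPR starts at raw position 11
        psm = _census_psm("a", "KSTGGKAPR", (Mod(6, AC),),
                          protein_ids=("h3",))
        table = count_occurrences([psm], [H3])
        assert table.entries == {("H3", "K14", "ac", "sperm"): 1}

    def test_multiple_ptms_on_one_spectrum_count_separately(self):
        # K23 me2 + K27 ac on one peptide -> two occurrences
        psm = _census_psm("a", "QLATKAARKSA", (Mod(5, ME2), Mod(9, AC)),
                          protein_ids=("h3",))
        table = count_occurrences([psm], [H3])
        assert table.entries == {
            ("H3", "K23", "me2", "sperm"): 1,
            ("H3", "K27", "ac", "sperm"): 1,
        }

    def test_repeated_spectra_accumulate(self):
        psms = [
            _census_psm(f"s{i}", "KSTGGKAPR", (Mod(6, AC),),
                        protein_ids=("h3",))
            for i in range(3)
        ]
        table = count_occurrences(psms, [H3])
        assert table.entries[("H3", "K14", "ac", "sperm")] == 3

    def test_ubiquitination_routed_to_flagged(self):
        psm = _census_psm("a", "KSTGGKAPR", (Mod(6, UB),),
                          protein_ids=("h3",))
        table = count_occurrences([psm], [H3])
        assert not table.entries
        assert table.flagged_excluded == [("H3", "K14", "ub", "sperm", 1)]

    def test_semi_tryptic_excluded(self):
        psm = _census_psm("a", "KSTGGKAPR", (Mod(6, AC),), tryp="half",
                          protein_ids=("h3",))
        table = count_occurrences([psm], [H3])
        assert not table.entries and not table.flagged_excluded

    def test_samples_kept_separate(self):
        psms = [
            _census_psm("a", "KSTGGKAPR", (Mod(6, AC),), sample="sperm",
                        protein_ids=("h3",)),
            _census_psm("b", "KSTGGKAPR", (Mod(6, AC),), sample="embryo",
                        protein_ids=("h3",)),
        ]
        table = count_occurrences(psms, [H3])
        assert table.distinct_marks("sperm") == 1
        assert table.distinct_marks("embryo") == 1
        assert table.total_occurrences() == 2


def _brute_force_census(psms, proteins):
    """Independent oracle: enumerate every (PSM, mod) pair with its own
    delta table and numbering arithmetic."""
    deltas = {
        "ac": (42.0106, "K"), "me1": (14.0157, "KR"), "me2": (28.0314, "KR"),
        "me3": (42.0471, "KR"), "ph": (79.9663, "STY"),
        "ub": (114.042927, "K"), "carbamidomethyl": (57.02146, "C"),
    }
    by_id = {p.protein_id: p for p in proteins}
    counted, flagged_n = {}, 0
    for psm in psms:
        if psm.tryptic_status != "full":
            continue
        hist = sorted(
            pid for pid in psm.protein_ids
            if pid in by_id and not by_id[pid].is_decoy
            and by_id[pid].family != "other"
        )
        if not hist:
            continue
        prot = by_id[hist[0]]
        start = prot.sequence.find(psm.peptide)
        met = 1 if prot.sequence[0] == "M" else 0
        for mod in psm.mods:
            raw = start + mod.offset  # 1-based position in full sequence
            letter = prot.sequence[raw - 1]
            hits = [
                name for name, (d, res) in deltas.items()
                if abs(mod.delta - d) <= 0.005 and letter in res
            ]
            idx = raw - met
            if (
                len(hits) == 1
                and idx >= 1
                and hits[0] in ("ac", "me1", "me2", "me3")
            ):
                key = (prot.family, f"{letter}{idx}", hits[0], psm.sample)
                counted[key] = counted.get(key, 0) + 1
            else:
                flagged_n += 1
    return counted, flagged_n


class TestCensusOracle:
    def test_matches_bruteforce_enumeration(self, targets, decoys):
        """On a small instance the census equals an independent loop over
        every (PSM, modification) pair."""
        from hpcensus.simulate import SimulationConfig, simulate_psms

        config = SimulationConfig(seed=77, n_psms_per_sample=100)
        psms = simulate_psms(config, targets, decoys)
        assert len(psms) <= 200
        table = count_occurrences(psms, targets)
        expected_counts, expected_flagged = _brute_force_census(psms, targets)
        assert table.entries == expected_counts
        assert len(table.flagged_excluded) == expected_flagged

    def test_conservation_of_modification_events(self, passing_psms, targets):
        """Counted + flagged occurrences equal the total modification events
        on passing full-tryptic histone PSMs."""
        table = count_occurrences(passing_psms, targets)
        histone_ids = {t.protein_id for t in targets if t.is_histone}
        total_events = sum(
            len(p.mods)
            for p in passing_psms
            if p.tryptic_status == "full"
            and any(pid in histone_ids for pid in p.protein_ids)
        )
        assert table.total_occurrences() + len(table.flagged_excluded) == (
            total_events
        )


class TestCensusTable:
    def test_round_trip_through_frame(self):
        table = CensusTable()
        table.add("H3", "K23", "me2", "sperm", 6)
        table.add("H4", "K20", "me1", "embryo", 2)
        assert CensusTable.from_frame(table.to_frame()) == table

    def test_printed_profile_distinct_marks(self):
        printed = load_printed_census()
        assert printed.distinct_marks("embryo") == 31
        assert printed.distinct_marks("sperm") == 22

    def test_empty_census(self):
        assert CensusTable().distinct_marks("sperm") == 0

    def test_rejects_uncounted_types(self):
        with pytest.raises(ValueError):
            CensusTable({("H2A", "K120", "ub", "embryo"): 1})
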