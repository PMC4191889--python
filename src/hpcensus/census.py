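"""Histone PTM assignment, site-coordinate mapping, and the occurrence census.

Modification mass deltas follow the differential-modification table used in
the upstream database search: acetylation +42.0106 (K), mono/di/tri-methylation
+14.0157/+28.0314/+42.0471 (K,R), phosphorylation +79.9663 (S,T,Y),
ubiquitination +114.042927 (K) and the fixed cysteine carbamidomethylation
+57.02146. Ubiquitination is never counted in the census because the
iodoacetamide used during sample preparation produces a lysine adduct of the
same nominal mass as the ubiquitin GG remnant; phosphorylation is likewise
tallied separately because no phospho-enrichment was applied, so its counts
are not comparable to the ac/me classes.

Residue numbering follows the histone-field convention: position 1 is the
first residue after the initiator methionine, so mouse H2A K119 corresponds
to C. elegans K120.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .records import ProteinRecord, PSMRecord

__all__ = [
    "ModificationDelta",
    "MOD_DELTAS",
    "COUNTED_PTM_TYPES",
    "annotate_mod",
    "SiteRecord",
    "site_coordinates",
    "map_cross_species",
    "CensusTable",
    "count_occurrences",
    "distinct_marks",
    "load_printed_census",
    "UnknownModificationError",
    "AmbiguousModificationError",
]


@dataclass(frozen=True)
class ModificationDelta:
    ptm_type: str
    delta: float
    residues: frozenset[str]
    counted_in_census: bool


MOD_DELTAS: tuple[ModificationDelta, ...] = (
    ModificationDelta("ac", 42.0106, frozenset("K"), True),
    ModificationDelta("me1", 14.0157, frozenset("KR"), True),
    ModificationDelta("me2", 28.0314, frozenset("KR"), True),
    ModificationDelta("me3", 42.0471, frozenset("KR"), True),
    ModificationDelta("ph", 79.9663, frozenset("STY"), True),
    ModificationDelta("ub", 114.042927, frozenset("K"), False),
    ModificationDelta("carbamidomethyl", 57.02146, frozenset("C"), False),
)

#: PTM classes counted in the Table-1-style census; ub and ph are tallied in
#: the flagged-excluded ledger instead.
COUNTED_PTM_TYPES = frozenset({"ac", "me1", "me2", "me3"})


class UnknownModificationError(ValueError):
    """No modification in the delta table matches (mass, residue)."""


class AmbiguousModificationError(ValueError):
    """More than one modification matches within the mass tolerance."""


def annotate_mod(
    delta_mass: float, residue_letter: str, tolerance: float = 0.005
) -> ModificationDelta:
    """Resolve a mass delta on a residue to a unique PTM type.

    The default 0.005 Da tolerance cleanly separates acetylation (+42.0106)
    from tri-methylation (+42.0471): their 0.0365 Da gap exceeds twice the
    tolerance.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    hits = [
        m
        for m in MOD_DELTAS
        if abs(delta_mass - m.delta) <= tolerance and residue_letter in m.residues
    ]
    if not hits:
        raise UnknownModificationError(
            f"no modification with delta {delta_mass} Da on {residue_letter!r}"
        )
    if len(hits) > 1:
        raise AmbiguousModificationError(
            f"delta {delta_mass} Da on {residue_letter!r} matches "
            f"{[m.ptm_type for m in hits]}"
        )
    return hits[0]


def _match_by_delta(delta_mass: float, tolerance: float) -> list[ModificationDelta]:
    return [m for m in MOD_DELTAS if abs(delta_mass - m.delta) <= tolerance]


@dataclass(frozen=True)
class SiteRecord:
    """A modified residue in post-initiator-Met protein coordinates."""

    histone_family: str
    protein_id: str
    residue_index: int
    residue_letter: str
    cross_species_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError("residue_index must be >= 1")

    @property
    def site_label(self) -> str:
        return f"{self.residue_letter}{self.residue_index}"


@dataclass(frozen=True)
class FlaggedSite:
    """A modification event excluded from the census, with the reason."""

    protein_id: str
    raw_position: int
    residue_letter: str
    delta: float
    reason: str  # initiator_met | residue_conflict | unknown_delta | excluded_class
    ptm_type: Optional[str] = None


def site_coordinates(
    psm: PSMRecord,
    protein: ProteinRecord,
    match_start: int,
    tolerance: float = 0.005,
) -> tuple[list[tuple[SiteRecord, str]], list[FlaggedSite]]:
    """Project a PSM's modifications onto protein residue coordinates.

    ``match_start`` is the 1-based start of the peptide in the full protein
    sequence. Returns (site, ptm_type) pairs for mass deltas that resolve to
    a known PTM on a compatible residue, plus a flagged list for events that
    cannot be counted (unknown delta, residue incompatible with the PTM's
    residue set, or a position on the initiator methionine itself).
    """
    seq = protein.sequence
    if seq[match_start - 1 : match_start - 1 + len(psm.peptide)] != psm.peptide:
        raise ValueError(
            f"{psm.spectrum_id}: peptide does not match {protein.protein_id} "
            f"at position {match_start}"
        )
    met_offset = 1 if seq.startswith("M") else 0
    sites: list[tuple[SiteRecord, str]] = []
    flagged: list[FlaggedSite] = []
    for mod in psm.mods:
        raw = match_start + mod.offset - 1  # 1-based in the full sequence
        letter = seq[raw - 1]
        candidates = _match_by_delta(mod.delta, tolerance)
        if not candidates:
            flagged.append(FlaggedSite(protein.protein_id, raw, letter, mod.delta,
                                       "unknown_delta"))
            continue
        allowed = [m for m in candidates if letter in m.residues]
        if len(allowed) > 1:
            raise AmbiguousModificationError(
                f"{psm.spectrum_id}: delta {mod.delta} on {letter!r} is ambiguous"
            )
        if not allowed:
            flagged.append(FlaggedSite(protein.protein_id, raw, letter, mod.delta,
                                       "residue_conflict",
                                       candidates[0].ptm_type))
            continue
        ptm = allowed[0]
        residue_index = raw - met_offset
        if residue_index < 1:
            flagged.append(FlaggedSite(protein.protein_id, raw, letter, mod.delta,
                                       "initiator_met", ptm.ptm_type))
            continue
        site = SiteRecord(
            histone_family=protein.family,
            protein_id=protein.protein_id,
            residue_index=residue_index,
            residue_letter=letter,
        )
        sites.append((site, ptm.ptm_type))
    return sites, flagged


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def _strip_met(seq: str) -> str:
    return seq[1:] if seq.startswith("M") else seq


def map_cross_species(
    query: ProteinRecord, reference: ProteinRecord, residue_index: int
) -> Optional[int]:
    """Map a post-Met residue number from ``query`` onto ``reference``.

    Global Needleman-Wunsch alignment (BLOSUM62, gap open 10 / extend 0.5);
    returns the reference residue number aligned to the query residue, or
    None when the query residue falls in a gap. Histone cores are
    near-identical across species, so the mapping is insensitive to the
    precise alignment parameters, which are fixed for determinism.
    """
    qseq, rseq = _strip_met(query.sequence), _strip_met(reference.sequence)
    if not qseq or not rseq:
        raise ValueError("empty sequence after initiator-Met removal")
    if not 1 <= residue_index <= len(qseq):
        raise ValueError(f"residue_index {residue_index} outside query")
    alignment = _ALIGNER.align(qseq, rseq)[0]
    q0 = residue_index - 1
    for (qs, qe), (rs, _re) in zip(*alignment.aligned):
        if qs <= q0 < qe:
            return rs + (q0 - qs) + 1
    return None


class CensusTable:
    """Occurrence counts per (histone family, site, PTM type, sample).

    ``flagged_excluded`` keeps the events that the census rules exclude
    (ubiquitination, phosphorylation, the fixed Cys carbamidomethylation, and
    residue/position conflicts) so that counted + flagged always equals the
    total number of modification events seen.
    """

    def __init__(
        self,
        entries: Optional[Mapping[tuple[str, str, str, str], int]] = None,
        flagged_excluded: Optional[Sequence[tuple]] = None,
        cross_species: Optional[Mapping[tuple[str, str], str]] = None,
    ) -> None:
        self.entries: dict[tuple[str, str, str, str], int] = dict(entries or {})
        self.flagged_excluded: list[tuple] = list(flagged_excluded or [])
        #: (family, ce_site) -> reference-species site label, where known
        self.cross_species: dict[tuple[str, str], str] = dict(cross_species or {})
        for key, count in self.entries.items():
            family, site, ptm, sample = key
            if ptm not in COUNTED_PTM_TYPES:
                raise ValueError(f"{ptm!r} is not a counted PTM type: {key}")
            if count < 0 or count != int(count):
                raise ValueError(f"counts must be nonnegative integers: {key}")

    def add(self, family: str, site: str, ptm: str, sample: str, n: int = 1) -> None:
        if ptm not in COUNTED_PTM_TYPES:
            raise ValueError(f"{ptm!r} is not a counted PTM type")
        key = (family, site, ptm, sample)
        self.entries[key] = self.entries.get(key, 0) + n

    def total_occurrences(self, sample: Optional[str] = None) -> int:
        return sum(
            n
            for (f, s, p, smp), n in self.entries.items()
            if sample is None or smp == sample
        )

    def distinct_marks(self, sample: str) -> int:
        """Distinct (family, site, PTM) triples observed in a sample."""
        return len(
            {
                (f, s, p)
                for (f, s, p, smp), n in self.entries.items()
                if smp == sample and n >= 1
            }
        )

    def samples(self) -> list[str]:
        return sorted({smp for (_f, _s, _p, smp) in self.entries})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "histone_family": f,
                "ce_site": s,
                "ref_site": self.cross_species.get((f, s), ""),
                "ptm_type": p,
                "sample": smp,
                "occurrences": n,
            }
            for (f, s, p, smp), n in sorted(self.entries.items())
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "histone_family", "ce_site", "ref_site",
                "ptm_type", "sample", "occurrences",
            ],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CensusTable":
        entries: dict[tuple[str, str, str, str], int] = {}
        cross: dict[tuple[str, str], str] = {}
        for row in frame.itertuples(index=False):
            key = (row.histone_family, row.ce_site, row.ptm_type, row.sample)
            entries[key] = entries.get(key, 0) + int(row.occurrences)
            ref = getattr(row, "ref_site", "")
            if isinstance(ref, str) and ref:
                cross[(row.histone_family, row.ce_site)] = ref
        return cls(entries, cross_species=cross)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CensusTable) and self.entries == other.entries
        )


def count_occurrences(
    psms: Iterable[PSMRecord],
    proteins: Sequence[ProteinRecord],
    tolerance: float = 0.005,
    require_full_tryptic: bool = True,
) -> CensusTable:
    """Build the occurrence census from validated (passing) PSMs.

    Mirrors the published counting rules: only full-tryptic PSMs matched to a
    histone target enter; a spectrum bearing k countable modifications
    contributes k occurrences (one per modified site); ubiquitination and
    phosphorylation events are routed to ``flagged_excluded``; per-sample
    tallies are kept separate. When a PSM matches several target proteins the
    lexicographically smallest matched id is used for coordinates, and when a
    peptide occurs at several positions in that protein the leftmost match is
    used (ambiguity is warned about once per peptide).
    """
    by_id = {p.protein_id: p for p in proteins}
    table = CensusTable()
    warned: set[str] = set()
    for psm in psms:
        if require_full_tryptic and psm.tryptic_status != "full":
            continue
        matched = sorted(
            pid
            for pid in psm.protein_ids
            if pid in by_id and not by_id[pid].is_decoy and by_id[pid].is_histone
        )
        if not matched or not psm.mods:
            continue
        protein = by_id[matched[0]]
        start = protein.sequence.find(psm.peptide)
        if start < 0:
            continue
        if (
            psm.peptide not in warned
            and protein.sequence.find(psm.peptide, start + 1) >= 0
        ):
            warnings.warn(
                f"peptide {psm.peptide} matches {protein.protein_id} at "
                f"multiple positions; using the leftmost",
                stacklevel=2,
            )
            warned.add(psm.peptide)
        sites, flagged = site_coordinates(psm, protein, start + 1, tolerance)
        for site, ptm in sites:
            if ptm in COUNTED_PTM_TYPES:
                table.add(site.histone_family, site.site_label, ptm, psm.sample)
            else:
                table.flagged_excluded.append(
                    (site.histone_family, site.site_label, ptm, psm.sample, 1)
                )
        for flag in flagged:
            table.flagged_excluded.append(
                (flag.protein_id, f"{flag.residue_letter}{flag.raw_position}",
                 flag.ptm_type or flag.reason, psm.sample, 1)
            )
    return table


def distinct_marks(census: CensusTable, sample: str) -> int:
    """Number of distinct PTM marks (family, site, type) seen in a sample."""
    return census.distinct_marks(sample)


def load_printed_census() -> CensusTable:
    """The transcribed per-site occurrence table of the profiled dataset."""
    from . import refdata

    return CensusTable.from_frame(refdata.load_site_occurrences())
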