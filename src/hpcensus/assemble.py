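"""Peptide-to-protein assembly and abundance measures.

Validated peptides are matched back to the target database by exhaustive
substring search; proteins indistinguishable by their matched-peptide sets
collapse into one cluster locus. Spectral counts distribute spectra of shared
peptides across loci proportionally to each locus's unique-peptide evidence
(equal split when no locus has unique evidence). NSAF is the length-normalised
spectral count rescaled to sum to 1 over reported loci; emPAI is
10^(observed/observable) - 1 with observable peptides taken from an in-silico
tryptic digest restricted to a fixed monoisotopic mass window.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from pyteomics import mass as _pytmass
from pyteomics import parser as _pytparser

from .records import ProteinRecord, PSMRecord

__all__ = [
    "PeptideProteinMap",
    "ProteinQuant",
    "map_peptides",
    "spectral_counts",
    "coverage",
    "nsaf",
    "empai",
    "tryptic_digest",
    "quantify",
    "DEFAULT_MASS_RANGE",
]

#: Observable-peptide monoisotopic mass window (Da) for emPAI, chosen to match
#: a survey scan of m/z 300-1800 at charge 2; fixed for reproducibility.
DEFAULT_MASS_RANGE = (600.0, 3600.0)

CARBAMIDOMETHYL_DA = 57.02146

# trypsin: cleave C-terminal to K/R, never before P
_TRYPSIN_RULE = r"(?<=[KR])(?!P)"


@dataclass
class _Cluster:
    locus: str  # lexicographically smallest member id
    member_ids: tuple[str, ...]
    peptides: frozenset[str]
    representative: ProteinRecord  # longest member (coverage denominator)


@dataclass
class PeptideProteinMap:
    """Peptide->protein matches plus identical-peptide-set clusters.

    ``matches`` maps each mapped peptide to {protein_id: 1-based leftmost
    start}; ``unmapped`` lists peptides matching no target protein (they are
    retained but excluded from counts downstream).
    """

    matches: dict[str, dict[str, int]]
    unmapped: list[str]
    clusters: dict[str, _Cluster]
    peptide_loci: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def unique_peptides(self, locus: str) -> set[str]:
        return {
            pep for pep, loci in self.peptide_loci.items() if loci == (locus,)
        }

    def is_unique(self, peptide: str) -> bool:
        return len(self.peptide_loci.get(peptide, ())) == 1


def map_peptides(
    psms: Iterable[PSMRecord], proteins: Sequence[ProteinRecord]
) -> PeptideProteinMap:
    """Exhaustive substring mapping of distinct peptides onto the database.

    Proteins sharing an identical matched-peptide set merge into one cluster
    locus named after the lexicographically smallest member id, so clustering
    is deterministic and independent of input order.
    """
    peptides = sorted({p.peptide for p in psms})
    matches: dict[str, dict[str, int]] = {}
    unmapped: list[str] = []
    per_protein: dict[str, set[str]] = {}
    for pep in peptides:
        hit: dict[str, int] = {}
        for prot in proteins:
            pos = prot.sequence.find(pep)
            if pos >= 0:
                hit[prot.protein_id] = pos + 1
                per_protein.setdefault(prot.protein_id, set()).add(pep)
        if hit:
            matches[pep] = hit
        else:
            unmapped.append(pep)

    by_id = {p.protein_id: p for p in proteins}
    groups: dict[frozenset[str], list[str]] = {}
    for pid, peps in per_protein.items():
        groups.setdefault(frozenset(peps), []).append(pid)
    clusters: dict[str, _Cluster] = {}
    for peps, pids in groups.items():
        pids = sorted(pids)
        representative = max(
            (by_id[pid] for pid in pids), key=lambda r: (len(r.sequence), r.protein_id)
        )
        clusters[pids[0]] = _Cluster(
            locus=pids[0],
            member_ids=tuple(pids),
            peptides=peps,
            representative=representative,
        )
    member_to_locus = {
        pid: c.locus for c in clusters.values() for pid in c.member_ids
    }
    peptide_loci = {
        pep: tuple(sorted({member_to_locus[pid] for pid in hit}))
        for pep, hit in matches.items()
    }
    return PeptideProteinMap(matches, unmapped, clusters, peptide_loci)


def spectral_counts(
    pmap: PeptideProteinMap, psms: Iterable[PSMRecord]
) -> dict[str, float]:
    """Per-locus spectral counts with shared-peptide distribution.

    Each mapped PSM contributes one spectrum. Spectra of peptides shared
    across clusters are split proportionally to the clusters' unique-peptide
    spectral counts; when no sharing cluster has unique evidence the spectrum
    splits equally. Total counts are conserved exactly.
    """
    counts: dict[str, float] = {locus: 0.0 for locus in pmap.clusters}
    unique_counts: dict[str, float] = {locus: 0.0 for locus in pmap.clusters}
    shared_psms: list[tuple[str, tuple[str, ...]]] = []
    for psm in psms:
        loci = pmap.peptide_loci.get(psm.peptide)
        if not loci:
            continue  # unmapped peptide: excluded from counts
        if len(loci) == 1:
            counts[loci[0]] += 1.0
            unique_counts[loci[0]] += 1.0
        else:
            shared_psms.append((psm.peptide, loci))
    for _pep, loci in shared_psms:
        weights = [unique_counts[locus] for locus in loci]
        total = sum(weights)
        if total == 0:
            share = [1.0 / len(loci)] * len(loci)
        else:
            share = [w / total for w in weights]
        for locus, frac in zip(loci, share):
            counts[locus] += frac
    return counts


def coverage(pmap: PeptideProteinMap, locus: str) -> float:
    """Fraction of the locus sequence covered by at least one peptide.

    For clusters the longest member is the denominator, and intervals come
    from that member's own match positions.
    """
    cluster = pmap.clusters[locus]
    rep = cluster.representative
    intervals = []
    for pep in cluster.peptides:
        start = pmap.matches[pep].get(rep.protein_id)
        if start is not None:
            intervals.append((start, start + len(pep) - 1))
    if not intervals:
        return 0.0
    intervals.sort()
    covered = 0
    cur_start, cur_end = intervals[0]
    for start, end in intervals[1:]:
        if start > cur_end + 1:
            covered += cur_end - cur_start + 1
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    covered += cur_end - cur_start + 1
    return covered / len(rep.sequence)


def nsaf(
    counts: Mapping[str, float], lengths: Mapping[str, int]
) -> dict[str, float]:
    """Normalised spectral abundance factor: (SpC/L) / sum_j (SpC_j/L_j).

    Zero-count loci report 0 and are excluded from the normalising sum.
    """
    for locus, length in lengths.items():
        if length <= 0:
            raise ValueError(f"{locus}: length must be positive")
    saf = {
        locus: counts[locus] / lengths[locus]
        for locus in counts
        if counts[locus] > 0
    }
    total = sum(saf.values())
    if total == 0:
        raise ValueError("all spectral counts are zero")
    return {locus: saf.get(locus, 0.0) / total for locus in counts}


def empai(observed_peptides: int, observable_peptides: int) -> float:
    """Exponentially modified protein abundance index.

    10^(observed/observable) - 1, with observed capped at observable so the
    index saturates at 9.
    """
    if observable_peptides < 1:
        raise ValueError("observable_peptides must be >= 1")
    if observed_peptides < 0:
        raise ValueError("observed_peptides must be >= 0")
    observed = min(observed_peptides, observable_peptides)
    return 10.0 ** (observed / observable_peptides) - 1.0


def peptide_mass(peptide: str) -> float:
    """Monoisotopic peptide mass with fixed Cys carbamidomethylation (Da)."""
    return float(
        _pytmass.fast_mass(peptide) + CARBAMIDOMETHYL_DA * peptide.count("C")
    )


def tryptic_digest(
    protein: ProteinRecord,
    mass_range: tuple[float, float] = DEFAULT_MASS_RANGE,
) -> list[str]:
    """Observable fully tryptic peptides of a protein.

    Cleaves C-terminal to K/R except before P, zero missed cleavages, and
    keeps peptides whose monoisotopic mass (fixed Cys +57.02146 Da) lies in
    ``mass_range``. Peptides are returned in sequence order.
    """
    lo, hi = mass_range
    pieces = _pytparser.icleave(protein.sequence, _TRYPSIN_RULE, missed_cleavages=0)
    return [pep for _pos, pep in pieces if lo <= peptide_mass(pep) <= hi]


def quantify(
    psms: Sequence[PSMRecord],
    proteins: Sequence[ProteinRecord],
    mass_range: tuple[float, float] = DEFAULT_MASS_RANGE,
    sample: Optional[str] = None,
) -> pd.DataFrame:
    """Full per-locus quantification table for one sample.

    Columns: locus, member_ids, unique_count, spectral_count, coverage, nsaf,
    empai; sorted by spectral count descending. ``sample`` restricts the PSMs
    considered.
    """
    if sample is not None:
        psms = [p for p in psms if p.sample == sample]
    pmap = map_peptides(psms, proteins)
    counts = spectral_counts(pmap, psms)
    reported = {locus: c for locus, c in counts.items() if c > 0}
    lengths = {
        locus: len(pmap.clusters[locus].representative.sequence)
        for locus in counts
    }
    nsaf_values = nsaf(counts, lengths) if reported else {}
    rows = []
    for locus, cluster in pmap.clusters.items():
        if counts[locus] == 0:
            continue
        observable = tryptic_digest(cluster.representative, mass_range)
        observed = {
            pep
            for pep in cluster.peptides
            if pep in observable
        }
        rows.append(
            {
                "locus": locus,
                "member_ids": ",".join(cluster.member_ids),
                "unique_count": len(pmap.unique_peptides(locus)),
                "spectral_count": counts[locus],
                "coverage": coverage(pmap, locus),
                "nsaf": nsaf_values.get(locus, 0.0),
                "empai": empai(len(observed), max(1, len(observable))),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "locus", "member_ids", "unique_count", "spectral_count",
            "coverage", "nsaf", "empai",
        ],
    )
    return frame.sort_values(
        ["spectral_count", "locus"], ascending=[False, True]
    ).reset_index(drop=True)
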