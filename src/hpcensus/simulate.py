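"""Synthetic PSM generator.

Emulates the statistical structure of a target-decoy database search of
shotgun-proteomics spectra against a histone reference: two score classes
(correct vs incorrect matches) over (XCorr, DeltaCN, DeltaMass), the 4x3
charge-by-tryptic-status subgroups, and per-sample modification-site emission
frequencies taken from the profiled dataset's published per-site occurrence
rates. Ground-truth labels make the validation stage's error rates directly
checkable.

The generator is deliberately stylised: peptides are uniform-length substrings
of the reference (not strict digests), the charge and tryptic tags are drawn
independently of the peptide sequence, and incorrect matches hit targets and
decoys with equal probability — the assumption under which decoy counts
estimate the false-match rate.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .records import (
    CHARGE_CLASSES,
    TRYPTIC_STATUSES,
    Mod,
    ProteinRecord,
    PSMRecord,
)
from . import refdata
from .census import MOD_DELTAS

__all__ = [
    "ScoreClassParams",
    "SimulationConfig",
    "make_reference",
    "reverse_decoys",
    "simulate_psms",
    "default_mod_site_frequencies",
]


@dataclass(frozen=True)
class ScoreClassParams:
    """Location/scale parameters for one PSM score class.

    XCorr and DeltaCN are Gaussian (DeltaCN truncated at 0). DeltaMass (ppm)
    is Gaussian around 0 for the correct class and uniform on +/-``ppm_range``
    for the incorrect class, which makes the downstream 6 ppm filter
    consequential.
    """

    xcorr_loc: float
    xcorr_scale: float
    deltacn_loc: float
    deltacn_scale: float
    ppm_scale: float = 0.0  # sd of the Gaussian ppm error (correct class)
    ppm_range: float = 0.0  # half-width of the uniform ppm error (incorrect)


DEFAULT_CORRECT = ScoreClassParams(
    xcorr_loc=3.2, xcorr_scale=0.7, deltacn_loc=0.28, deltacn_scale=0.10,
    ppm_scale=2.0,
)
DEFAULT_INCORRECT = ScoreClassParams(
    xcorr_loc=1.4, xcorr_scale=0.5, deltacn_loc=0.06, deltacn_scale=0.04,
    ppm_range=50.0,
)


def default_mod_site_frequencies() -> dict:
    """Per-site marginal emission rates derived from the profiled dataset.

    For each (histone family, site, PTM type) the value is the published
    occurrence count divided by the sample's total histone spectra (7190
    sperm / 5998 embryo), i.e. the dataset's own per-spectrum rate. The
    simulator converts these marginal rates into probabilities conditional
    on the drawn peptide actually covering the site, so the realised
    per-spectrum rates match the dataset's. The embryo-specific H2A K120
    ubiquitination signal (132 spectra; mouse K119) is included so the
    census's exclusion path is exercised.
    """
    table = refdata.load_site_occurrences()
    freqs: dict[tuple[str, str, str], dict[str, float]] = {}
    for row in table.itertuples(index=False):
        key = (row.histone_family, row.ce_site, row.ptm_type)
        per_sample = freqs.setdefault(key, {})
        per_sample[row.sample] = (
            row.occurrences / refdata.TOTAL_HISTONE_SPECTRA[row.sample]
        )
    freqs[("H2A", "K120", "ub")] = {
        sample: n / refdata.TOTAL_HISTONE_SPECTRA[sample]
        for sample, n in refdata.H2A_K119UB_SPECTRA.items()
    }
    return freqs


def _check_weights(name: str, weights: Sequence[float], n: int) -> None:
    if len(weights) != n:
        raise ValueError(f"{name} must have {n} entries")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {sum(weights)!r})")
    if any(w < 0 for w in weights):
        raise ValueError(f"{name} must be nonnegative")


@dataclass
class SimulationConfig:
    """Configuration of one simulated two-sample experiment.

    ``seed`` is mandatory; every random draw derives from it.
    """

    seed: int
    n_psms_per_sample: int = 20_000
    true_match_fraction: float = 0.7
    samples: tuple[str, ...] = ("sperm", "embryo")
    correct_params: ScoreClassParams = DEFAULT_CORRECT
    incorrect_params: ScoreClassParams = DEFAULT_INCORRECT
    charge_class_weights: tuple[float, ...] = (0.10, 0.50, 0.30, 0.10)
    tryptic_status_weights: tuple[float, ...] = (0.70, 0.20, 0.10)
    peptide_length_range: tuple[int, int] = (7, 25)
    mod_site_frequencies: Mapping[tuple[str, str, str], Mapping[str, float]] = field(
        default_factory=default_mod_site_frequencies
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        _check_weights("charge_class_weights", self.charge_class_weights, 4)
        _check_weights("tryptic_status_weights", self.tryptic_status_weights, 3)
        if not 0.0 <= self.true_match_fraction <= 1.0:
            raise ValueError("true_match_fraction must lie in [0, 1]")
        lo, hi = self.peptide_length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid peptide_length_range")


def make_reference(config: SimulationConfig | None = None) -> list[ProteinRecord]:
    """Packaged target reference: canonical C. elegans histones plus variants.

    Deterministic for a given package version; covers the four core families
    H2A/H2B/H3/H4 plus the HTAS-1 and HTZ-1 variants, a linker H1 and an
    H3-variant scaffold.
    """
    from .io import read_fasta  # local import to avoid a cycle

    records = read_fasta(refdata.celegans_fasta_path())
    assert all(not r.is_decoy for r in records)
    return records


def reverse_decoys(targets: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Character-reversed decoy counterpart for every target record."""
    for rec in targets:
        if rec.is_decoy:
            raise ValueError(
                f"reverse_decoys expects target records only; "
                f"{rec.protein_id} is a decoy"
            )
    return [rec.reversed_decoy() for rec in targets]


_MOD_DELTA_BY_TYPE = {m.ptm_type: m.delta for m in MOD_DELTAS}


def _cover_probability(
    raw: int, seq_len: int, length_range: tuple[int, int]
) -> float:
    """P(a uniformly drawn substring covers 0-based position ``raw``)."""
    lo, hi = length_range
    total = 0.0
    n_lengths = 0
    for length in range(lo, hi + 1):
        length = min(length, seq_len)
        n_starts = seq_len - length + 1
        first = max(0, raw - length + 1)
        last = min(raw, seq_len - length)
        total += max(0, last - first + 1) / n_starts
        n_lengths += 1
    return total / n_lengths


def _site_lookup(
    targets: Sequence[ProteinRecord],
    freqs: Mapping[tuple[str, str, str], Mapping[str, float]],
    length_range: tuple[int, int],
) -> dict[str, list[tuple[int, str, float, dict]]]:
    """Per-protein list of (0-based raw position, residue, delta, sample->p).

    The configured frequencies are marginal per-correct-spectrum rates; here
    they are rescaled by the number of targets and the probability that a
    drawn peptide covers the site, so the conditional emission probability
    reproduces the marginal rate across the whole simulated sample.
    """
    by_family: dict[str, list] = {}
    for (family, site, ptm), per_sample in freqs.items():
        letter, index = site[0], int(site[1:])
        delta = _MOD_DELTA_BY_TYPE[ptm]
        by_family.setdefault(family, []).append(
            (index, letter, delta, dict(per_sample))
        )
    lookup: dict[str, list] = {}
    for rec in targets:
        met = 1 if rec.sequence.startswith("M") else 0
        entries = []
        for index, letter, delta, per_sample in by_family.get(rec.family, []):
            raw = index - 1 + met  # 0-based position in the full sequence
            if raw < len(rec.sequence) and rec.sequence[raw] == letter:
                p_cover = _cover_probability(raw, len(rec.sequence), length_range)
                scale = len(targets) / max(p_cover, 1e-12)
                conditional = {
                    sample: min(1.0, p * scale)
                    for sample, p in per_sample.items()
                }
                entries.append((raw, letter, delta, conditional))
        lookup[rec.protein_id] = entries
    return lookup


def _matching_ids(peptide: str, proteins: Sequence[ProteinRecord]) -> tuple[str, ...]:
    return tuple(p.protein_id for p in proteins if peptide in p.sequence)


def simulate_psms(
    config: SimulationConfig,
    targets: Sequence[ProteinRecord],
    decoys: Sequence[ProteinRecord],
) -> list[PSMRecord]:
    """Simulate seeded PSM tables for every configured sample.

    Correct matches (truth=True) are substrings of target sequences scored
    from the correct class; incorrect matches (truth=False) are substrings of
    a protein drawn with equal probability from targets or decoys, scored
    from the incorrect class. Scores are rounded to 4 decimals so the TSV
    round trip is lossless.
    """
    if not targets or not decoys:
        raise ValueError("targets and decoys must be non-empty")
    rng = np.random.default_rng(config.seed)
    everything = list(targets) + list(decoys)
    site_lookup = _site_lookup(
        targets, config.mod_site_frequencies, config.peptide_length_range
    )
    lo, hi = config.peptide_length_range
    cp, ip = config.correct_params, config.incorrect_params

    psms: list[PSMRecord] = []
    for sample in config.samples:
        for i in range(config.n_psms_per_sample):
            is_true = bool(rng.random() < config.true_match_fraction)
            if is_true:
                src = targets[rng.integers(len(targets))]
            elif rng.random() < 0.5:
                src = targets[rng.integers(len(targets))]
            else:
                src = decoys[rng.integers(len(decoys))]
            seq = src.sequence
            length = min(int(rng.integers(lo, hi + 1)), len(seq))
            start = int(rng.integers(0, len(seq) - length + 1))
            peptide = seq[start : start + length]

            params = cp if is_true else ip
            xcorr = rng.normal(params.xcorr_loc, params.xcorr_scale)
            deltacn = max(0.0, rng.normal(params.deltacn_loc, params.deltacn_scale))
            if is_true:
                ppm = rng.normal(0.0, params.ppm_scale)
            else:
                ppm = rng.uniform(-params.ppm_range, params.ppm_range)

            mods: list[Mod] = []
            if is_true:
                for raw, _letter, delta, per_sample in site_lookup.get(
                    src.protein_id, []
                ):
                    p = per_sample.get(sample, 0.0)
                    if start <= raw < start + length and rng.random() < p:
                        mods.append(Mod(offset=raw - start + 1, delta=delta))

            psms.append(
                PSMRecord(
                    spectrum_id=f"{sample}_{i:06d}",
                    sample=sample,
                    peptide=peptide,
                    protein_ids=_matching_ids(peptide, everything),
                    charge_class=str(
                        rng.choice(CHARGE_CLASSES, p=config.charge_class_weights)
                    ),
                    tryptic_status=str(
                        rng.choice(TRYPTIC_STATUSES, p=config.tryptic_status_weights)
                    ),
                    xcorr=round(float(xcorr), 4),
                    deltacn=round(float(deltacn), 4),
                    delta_mass_ppm=round(float(ppm), 4),
                    mods=tuple(mods),
                    truth=is_true,
                )
            )
    return psms
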