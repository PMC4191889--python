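"""Two-sample comparative statistics for the sperm/embryo histone profile.

Per-sample modified-spectrum fractions, the embryo/sperm fold ratio, distinct
mark counts, and variant-enrichment flags. Percentages and ratios are rounded
half-up to one decimal, matching the precision of the published numbers; the
fold ratio is always computed on unrounded fractions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional

from .census import CensusTable

__all__ = [
    "modified_fraction",
    "fold_ratio",
    "variant_enrichment",
    "VariantFlag",
    "SampleSummary",
    "summarize_samples",
]


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def modified_fraction(ptm_spectra: int, total_spectra: int) -> float:
    """Percentage of histone spectra bearing a counted PTM, one decimal."""
    if total_spectra <= 0:
        raise ValueError("total_spectra must be positive")
    if not 0 <= ptm_spectra <= total_spectra:
        raise ValueError("ptm_spectra must lie in [0, total_spectra]")
    return _round1(100.0 * ptm_spectra / total_spectra)


def fold_ratio(frac_a: float, frac_b: float) -> float:
    """Ratio frac_a / frac_b rounded half-up to one decimal.

    Pass unrounded fractions; the published convention reports embryo over
    sperm, so a value > 1 means sperm-depleted.
    """
    if frac_b <= 0:
        raise ValueError("denominator fraction must be positive")
    return _round1(frac_a / frac_b)


@dataclass(frozen=True)
class VariantFlag:
    variant: str
    status: str  # a_specific | b_specific | absent | shared
    ratio: Optional[float] = None  # family-normalised proportion ratio (a/b)


def variant_enrichment(
    counts_a: Mapping[str, tuple[int, int]],
    counts_b: Mapping[str, tuple[int, int]],
) -> dict[str, VariantFlag]:
    """Flag sample-specific histone variants.

    Inputs map variant name -> (variant spectra, family-total spectra) per
    sample. A variant present in one sample and absent (0 spectra) in the
    other is flagged sample-specific; absent in both is flagged absent;
    otherwise the ratio of family-normalised proportions (a over b) is
    reported.
    """
    flags: dict[str, VariantFlag] = {}
    for variant in sorted(set(counts_a) | set(counts_b)):
        ca, ta = counts_a.get(variant, (0, 0))
        cb, tb = counts_b.get(variant, (0, 0))
        if ta <= 0 or tb <= 0:
            raise ValueError(f"{variant}: family totals must be positive")
        if ca == 0 and cb == 0:
            flags[variant] = VariantFlag(variant, "absent")
        elif cb == 0:
            flags[variant] = VariantFlag(variant, "a_specific")
        elif ca == 0:
            flags[variant] = VariantFlag(variant, "b_specific")
        else:
            flags[variant] = VariantFlag(
                variant, "shared", _round1((ca / ta) / (cb / tb))
            )
    return flags


@dataclass
class SampleSummary:
    """Headline numbers for one sample."""

    sample: str
    total_histone_spectra: int
    ptm_histone_spectra: int
    modified_fraction_percent: float = field(init=False)
    distinct_marks: int = 0
    variant_spectra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.modified_fraction_percent = modified_fraction(
            self.ptm_histone_spectra, self.total_histone_spectra
        )


def summarize_samples(
    census: CensusTable,
    spectra_counts: Mapping[str, tuple[int, int]],
    variant_spectra: Optional[Mapping[str, Mapping[str, tuple[int, int]]]] = None,
) -> dict[str, SampleSummary]:
    """Assemble per-sample summaries from a census and spectral totals.

    ``spectra_counts`` maps sample -> (ptm spectra, total spectra);
    ``variant_spectra`` optionally maps sample -> {variant: (count, family
    total)}.
    """
    summaries: dict[str, SampleSummary] = {}
    for sample, (ptm, total) in spectra_counts.items():
        summary = SampleSummary(
            sample=sample,
            total_histone_spectra=total,
            ptm_histone_spectra=ptm,
        )
        summary.distinct_marks = census.distinct_marks(sample)
        if variant_spectra and sample in variant_spectra:
            summary.variant_spectra = dict(variant_spectra[sample])
        summaries[sample] = summary
    return summaries
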