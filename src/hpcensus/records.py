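"""Core record types shared across the pipeline.

A :class:`ProteinRecord` is one (possibly decoy) database entry; a
:class:`PSMRecord` is one peptide-spectrum match carrying the three search
scores used for validation, the charge/tryptic subgroup attributes, and the
modification events localised on the peptide.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

CHARGE_CLASSES = ("1", "2", "3", "gt3")
TRYPTIC_STATUSES = ("full", "half", "non")

SPECIES_TAGS = ("celegans", "mouse", "synthetic")
FAMILY_TAGS = ("H2A", "H2B", "H3", "H4", "H1", "variant", "other")

#: Histone families whose PSMs enter the PTM census.
HISTONE_FAMILIES = ("H2A", "H2B", "H3", "H4", "H1", "variant")

DECOY_PREFIX = "Reverse_"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein database entry with histone-family and species annotation."""

    protein_id: str
    sequence: str
    species: str = "synthetic"
    family: str = "other"
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"{self.protein_id}: illegal residue(s) {sorted(bad)}"
            )
        if self.species not in SPECIES_TAGS:
            raise ValueError(f"unknown species tag {self.species!r}")
        if self.family not in FAMILY_TAGS:
            raise ValueError(f"unknown family tag {self.family!r}")

    @property
    def is_histone(self) -> bool:
        return self.family in HISTONE_FAMILIES

    def reversed_decoy(self) -> "ProteinRecord":
        """Character-reversed decoy counterpart of a target record."""
        if self.is_decoy:
            raise ValueError(f"{self.protein_id} is already a decoy")
        return replace(
            self,
            protein_id=DECOY_PREFIX + self.protein_id,
            sequence=self.sequence[::-1],
            is_decoy=True,
        )


@dataclass(frozen=True)
class Mod:
    """One modification event: 1-based offset in the peptide plus mass delta (Da)."""

    offset: int
    delta: float


@dataclass
class PSMRecord:
    """One peptide-spectrum match.

    ``truth`` is only populated by the simulator: True for PSMs generated as
    genuine substring matches with correct-class scores, False for noise
    matches, None for real (unlabelled) data.
    """

    spectrum_id: str
    sample: str
    peptide: str
    protein_ids: tuple[str, ...]
    charge_class: str
    tryptic_status: str
    xcorr: float
    deltacn: float
    delta_mass_ppm: float
    mods: tuple[Mod, ...] = field(default_factory=tuple)
    truth: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.charge_class not in CHARGE_CLASSES:
            raise ValueError(
                f"{self.spectrum_id}: charge class {self.charge_class!r} "
                f"not one of {CHARGE_CLASSES}"
            )
        if self.tryptic_status not in TRYPTIC_STATUSES:
            raise ValueError(
                f"{self.spectrum_id}: tryptic status {self.tryptic_status!r} "
                f"not one of {TRYPTIC_STATUSES}"
            )
        if not self.peptide or set(self.peptide) - AMINO_ACIDS:
            raise ValueError(f"{self.spectrum_id}: invalid peptide {self.peptide!r}")
        if self.deltacn < 0:
            raise ValueError(f"{self.spectrum_id}: DeltaCN must be >= 0")
        for mod in self.mods:
            if not 1 <= mod.offset <= len(self.peptide):
                raise ValueError(
                    f"{self.spectrum_id}: mod offset {mod.offset} outside "
                    f"peptide of length {len(self.peptide)}"
                )
        self.protein_ids = tuple(self.protein_ids)
        self.mods = tuple(self.mods)

    def is_decoy_match(self, decoy_prefix: str = DECOY_PREFIX) -> bool:
        """True when every matched protein is a decoy entry."""
        return bool(self.protein_ids) and all(
            pid.startswith(decoy_prefix) for pid in self.protein_ids
        )
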