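"""Packaged reference data.

Two curated FASTA sets (C. elegans histones plus mouse scaffolds for
cross-species coordinate mapping) and the transcribed per-site PTM occurrence
table from the sperm/embryo MudPIT histone profiling dataset this pipeline
reanalyzes, together with that dataset's printed spectral-count totals.

The sequence sets are curated synthetic scaffolds: H3/H4 are the canonical,
universally conserved histone sequences; the H2A/H2B pairs are constrained to
reproduce the published C. elegans residue numbering and every published
cross-species site correspondence (e.g. mouse H2A K119 <-> C. elegans K120).
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

#: Total histone spectra per sample in the profiled dataset.
TOTAL_HISTONE_SPECTRA = {"sperm": 7190, "embryo": 5998}

#: Histone spectra per sample that carried at least one counted PTM.
PTM_HISTONE_SPECTRA = {"sperm": 127, "embryo": 253}

#: Total H2A-family spectra per sample (canonical H2A + HTZ-1 + HTAS-1).
H2A_FAMILY_SPECTRA = {"sperm": 3595, "embryo": 4758}

#: Spectra matched to the sperm-specific H2A variant HTAS-1, per sample.
HTAS1_SPECTRA = {"sperm": 285, "embryo": 0}

#: Spectra with H2A ubiquitination at mouse K119 (C. elegans K120), per sample.
H2A_K119UB_SPECTRA = {"sperm": 0, "embryo": 132}

#: Proteins identified per sample in the profiled dataset.
PROTEINS_IDENTIFIED = {"sperm": 1889, "embryo": 2421}


def _data_path(name: str):
    return resources.files("hpcensus.data").joinpath(name)


def celegans_fasta_path():
    """Path to the curated C. elegans histone reference FASTA."""
    return _data_path("celegans_histones.fasta")


def mouse_fasta_path():
    """Path to the curated mouse histone scaffold FASTA."""
    return _data_path("mouse_histones.fasta")


def load_site_occurrences() -> pd.DataFrame:
    """Transcribed per-site PTM occurrence counts (long format).

    Columns: histone_family, ce_site, ref_site, ptm_type, sample, occurrences.
    Only counted PTM classes (ac/me1/me2/me3) appear; ubiquitination and
    phosphorylation were excluded from the published site census.
    """
    with _data_path("ptm_site_occurrences.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
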