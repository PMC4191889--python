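#!/usr/bin/env python
"""Build the histone PTM occurrence census from validated full-tryptic PSMs.

One occurrence per counted modification event (a spectrum with k counted
mods adds k occurrences); ubiquitination and phosphorylation events go to
the flagged-excluded ledger. Sites carry both species' residue numbers via
global alignment against the mouse scaffolds.
"""
import argparse
import warnings
from pathlib import Path

from hpcensus import refdata
from hpcensus.census import count_occurrences, map_cross_species
from hpcensus.io import read_fasta, read_validated_psms, write_census


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dir", type=Path, default=Path("results/pipeline"))
    args = parser.parse_args()

    passing = read_validated_psms(args.dir / "validated_psms.tsv")
    targets = [
        r for r in read_fasta(args.dir / "reference_with_decoys.fasta")
        if not r.is_decoy
    ]
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="peptide .* matches")
        table = count_occurrences(passing, targets)

    # annotate cross-species coordinates for the core families
    worm = {r.family: r for r in targets}
    mouse = {r.family: r for r in read_fasta(refdata.mouse_fasta_path())}
    for family, site, _ptm, _sample in list(table.entries):
        if (family, site) in table.cross_species or family not in mouse:
            continue
        idx = int(site[1:])
        ref_idx = map_cross_species(worm[family], mouse[family], idx)
        if ref_idx is not None:
            table.cross_species[(family, site)] = f"{site[0]}{ref_idx}"

    write_census(table, args.dir / "census.tsv",
                 args.dir / "census_flagged_excluded.tsv")
    for sample in table.samples():
        print(f"{sample}: {table.distinct_marks(sample)} distinct marks, "
              f"{table.total_occurrences(sample)} occurrences")
    print(f"flagged-excluded events: {len(table.flagged_excluded)} "
          f"(ubiquitination/phosphorylation and residue conflicts)")
    print(f"wrote {args.dir / 'census.tsv'}")


if __name__ == "__main__":
    main()
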