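"""End-to-end orchestration: simulate -> validate -> assemble -> census -> compare.

Every stage writes a TSV artifact; a run log records the seed, thresholds and
estimated FDR so a run can be reproduced from the log alone.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from . import assemble, census as census_mod, compare as compare_mod, io as io_mod
from . import validate as validate_mod
from .records import DECOY_PREFIX
from .simulate import SimulationConfig, make_reference, reverse_decoys, simulate_psms

__all__ = ["PipelineConfig", "run_pipeline", "StageError"]

logger = logging.getLogger("hpcensus")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Effective parameters of one pipeline run.

    Defaults reproduce the published filtering thresholds: 90% minimum
    peptide probability, 6 ppm mass filter, 0.005 Da modification-annotation
    tolerance, 600-3600 Da emPAI observability window.
    """

    out_dir: Path
    seed: int = 0
    psm_path: Optional[Path] = None  # start from an existing PSM table
    fasta_path: Optional[Path] = None  # reference override (targets only)
    p_min: float = 0.90
    ppm_max: float = 6.0
    tolerance_da: float = 0.005
    mass_window: tuple[float, float] = assemble.DEFAULT_MASS_RANGE
    n_psms_per_sample: int = 20_000
    samples: tuple[str, ...] = ("sperm", "embryo")
    decoy_prefix: str = DECOY_PREFIX

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a summary dict (also written to run.log)."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"seed={config.seed}", f"p_min={config.p_min}",
                 f"ppm_max={config.ppm_max}",
                 f"tolerance_da={config.tolerance_da}",
                 f"mass_window={config.mass_window[0]}-{config.mass_window[1]}",
                 f"n_psms_per_sample={config.n_psms_per_sample}",
                 f"samples={','.join(config.samples)}"]

    # -- reference & simulation ------------------------------------------
    @_stage("simulate")
    def _simulate():
        if config.fasta_path is not None:
            targets = [r for r in io_mod.read_fasta(config.fasta_path)
                       if not r.is_decoy]
        else:
            targets = make_reference()
        decoys = reverse_decoys(targets)
        io_mod.write_fasta(targets + decoys, out / "reference_with_decoys.fasta")
        if config.psm_path is not None:
            psms = io_mod.read_psm_table(config.psm_path)
        else:
            sim = SimulationConfig(
                seed=config.seed,
                n_psms_per_sample=config.n_psms_per_sample,
                samples=config.samples,
            )
            psms = simulate_psms(sim, targets, decoys)
            io_mod.write_psm_table(psms, out / "psms.tsv")
        return targets, psms

    targets, psms = _simulate()
    log_lines.append(f"n_psms={len(psms)}")

    # -- validation -------------------------------------------------------
    @_stage("validate")
    def _validate():
        model = validate_mod.fit_model(psms, config.decoy_prefix)
        results = validate_mod.filter_psms(
            psms, model, p_min=config.p_min, ppm_max=config.ppm_max
        )
        io_mod.write_validation_results(results, out / "validated_psms.tsv")
        fdr = validate_mod.estimate_fdr(results, config.decoy_prefix)
        return model, results, fdr

    model, results, fdr = _validate()
    passing = [r.psm for r in results if r.passed]
    log_lines.append(f"n_passing={len(passing)}")
    log_lines.append(f"estimated_fdr_percent={fdr:.4f}")

    # -- assembly ---------------------------------------------------------
    @_stage("assemble")
    def _assemble():
        frames = {}
        for sample in config.samples:
            frame = assemble.quantify(
                passing, targets, mass_range=config.mass_window, sample=sample
            )
            io_mod.write_quant_table(frame, out / f"protein_quant_{sample}.tsv")
            frames[sample] = frame
        return frames

    quant = _assemble()

    # -- census -----------------------------------------------------------
    @_stage("census")
    def _census():
        table = census_mod.count_occurrences(
            passing, targets, tolerance=config.tolerance_da
        )
        io_mod.write_census(table, out / "census.tsv",
                            out / "census_flagged_excluded.tsv")
        return table

    table = _census()

    # -- compare ----------------------------------------------------------
    @_stage("compare")
    def _compare():
        spectra_counts = {}
        histone_ids = {t.protein_id for t in targets if t.is_histone}
        for sample in config.samples:
            sample_psms = [p for p in passing if p.sample == sample
                           and set(p.protein_ids) & histone_ids]
            n_total = len(sample_psms)
            n_ptm = sum(
                1 for p in sample_psms
                if any(_is_counted(m.delta, config.tolerance_da) for m in p.mods)
            )
            spectra_counts[sample] = (n_ptm, max(n_total, 1))
        summaries = compare_mod.summarize_samples(table, spectra_counts)
        rows = ["sample\tptm_spectra\ttotal_spectra\tmodified_fraction_percent"
                "\tdistinct_marks"]
        for sample, s in summaries.items():
            rows.append(
                f"{s.sample}\t{s.ptm_histone_spectra}\t{s.total_histone_spectra}"
                f"\t{s.modified_fraction_percent}\t{s.distinct_marks}"
            )
        (out / "comparison.tsv").write_text("\n".join(rows) + "\n")
        kv = {}
        for sample, s in summaries.items():
            kv[f"{sample}.modified_fraction_percent"] = s.modified_fraction_percent
            kv[f"{sample}.distinct_marks"] = s.distinct_marks
        if len(config.samples) == 2:
            a, b = config.samples[1], config.samples[0]  # embryo over sperm
            fa = 100.0 * summaries[a].ptm_histone_spectra / summaries[a].total_histone_spectra
            fb = 100.0 * summaries[b].ptm_histone_spectra / summaries[b].total_histone_spectra
            if fb > 0:
                kv[f"fold_ratio_{a}_over_{b}"] = compare_mod.fold_ratio(fa, fb)
        io_mod.write_config(kv, out / "comparison_summary.txt")
        return summaries, kv

    summaries, kv = _compare()

    log_lines += [f"{k}={v}" for k, v in kv.items()]
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    for line in log_lines:
        logger.info(line)
    return {
        "estimated_fdr_percent": fdr,
        "n_psms": len(psms),
        "n_passing": len(passing),
        "summaries": summaries,
        "census": table,
        "quant": quant,
        "model": model,
    }


def _is_counted(delta: float, tolerance: float) -> bool:
    for m in census_mod.MOD_DELTAS:
        if abs(delta - m.delta) <= tolerance:
            return m.ptm_type in census_mod.COUNTED_PTM_TYPES
    return False
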