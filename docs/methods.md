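# Methods

## Problem setting

The package reimplements the downstream computational analysis of a MudPIT
(2-D LC-MS/MS) histone profiling experiment comparing *C. elegans* sperm and
mixed-stage embryo chromatin. Upstream of this package sits a database search
(Sequest/ProLuCID against Wormpep plus reversed decoys, 3 Da precursor
tolerance, differential modification masses) that is out of scope; the
package's inputs are its outputs — PSM tables with XCorr, ΔCn, Δmass (ppm),
charge, tryptic status and localised modification events — either simulated
or supplied by the user in the documented TSV schema.

## PSM validation

**Subgroups.** PSMs partition into 12 subgroups: charge class {1, 2, 3, >3} ×
tryptic status {full, half, non}. Score distributions differ enough between
these strata that pooling them degrades the discriminant, so each subgroup
with at least 50 direct and 50 decoy PSMs receives its own fit; smaller
subgroups fall back to the pooled all-PSM fit (flagged `fallback_used`).
The 50/class floor keeps the LDA covariance and KDE stable at small n.

**Discriminant.** A two-class linear discriminant (pooled covariance, the
classical reading of "discriminant analysis") over (XCorr, ΔCn, |Δm| ppm),
oriented so larger scores favour direct PSMs. The magnitude of the mass error
enters the discriminant — its sign carries no information — and the same
quantity is separately hard-filtered at 6 ppm.

**Posterior.** Peptide probability is the target-decoy mixture posterior

    P(correct | s) = clip(1 − π₀ · f_decoy(s) / f_direct(s), 0, 1)

where `f_direct` is a Gaussian-kernel KDE (Silverman bandwidth, 512-point
grid spanning the observed scores ± 3 bandwidths) of the *observed*
direct-PSM scores — which is itself the mixture of correct and incorrect
matches — and `π₀ = min(1, n_decoy/n_direct)` estimates the incorrect
fraction among direct PSMs under the standard assumption that an incorrect
match hits target and decoy sequences with equal probability. Using the
observed direct density as the denominator (rather than reconstructing a
two-component mixture) is what makes the formula's limits come out right:
perfectly separated classes give probability → 1 for every direct PSM, and
identical direct/decoy distributions with equal counts give probability → 0.
Raw KDE ratios wiggle where both densities are small, so isotonic regression
along the grid enforces that probability is nondecreasing in the discriminant
score; scoring interpolates on the monotonised grid and clamps at the grid
ends.

**Filtering and FDR.** A PSM passes when probability ≥ p_min (default 0.90,
boundary inclusive) and |Δm| ≤ ppm_max (default 6 ppm, only strictly greater
rejected; the probability criterion is evaluated first for the fail reason).
Estimated FDR = 100 × (passing PSMs whose every matched protein is a decoy) /
(all passing PSMs) — deliberately the plain decoy/total estimator, matching
the convention of the analysis being reproduced, not the doubled one. It
therefore under-reports the true false-match rate by up to a factor of two;
at the sub-1% rates this pipeline operates at, the bias is well under half a
percentage point, which the acceptance checks measure directly against the
simulator's ground truth.

## Protein assembly and abundance

Peptides are matched by exhaustive substring search (histone databases are
tiny; no index needed). Proteins with identical matched-peptide sets are
indistinguishable and merge into a cluster locus named by the
lexicographically smallest member — deterministic and order-independent.
Shared-peptide spectra are distributed across loci proportionally to each
locus's unique-peptide spectral counts, splitting equally when no locus has
unique evidence; total spectra are conserved exactly. Coverage is the union
of matched intervals over the longest cluster member. NSAF is
(SpC/L)/Σ(SpC/L) with zero-count loci excluded from the normalising sum;
emPAI is 10^(N_obs/N_obsbl) − 1 with observed capped at observable. The
observable set comes from an in-silico tryptic digest (cleave after K/R, not
before P, zero missed cleavages, fixed Cys +57.02146 Da) windowed to
600–3600 Da monoisotopic — chosen to match an m/z 300–1800 survey scan at
charge 2 and fixed for reproducibility; the original study does not state its
observability criteria, so emPAI values are comparable within this package,
not with the original tables.

## PTM census

The modification table is exactly the search's differential masses:
ac +42.0106 (K), me1 +14.0157 (K/R), me2 +28.0314 (K/R), me3 +42.0471 (K/R),
ph +79.9663 (S/T/Y), ub +114.042927 (K), fixed carbamidomethyl +57.02146 (C).
Annotation tolerance is ±0.005 Da: wide enough to absorb the 28.0313/28.0314
di-methylation rounding seen in different printed sources, narrow enough that
acetylation and tri-methylation (0.0365 Da apart) never collide. Residue
numbering starts at the residue after the initiator Met, the histone-field
convention. Census rules mirror the published counting: only full-tryptic
PSMs matched to a histone target contribute; a spectrum with k counted
modifications adds k occurrences; per-sample tallies stay separate.
Ubiquitination is never counted (the iodoacetamide lysine adduct has the same
nominal mass as the ubiquitin GG remnant) and phosphorylation is tallied
separately (no phospho-enrichment was applied, so its counts are not
comparable); both go to a flagged-excluded ledger, as do residue-conflicting
events, so counted + flagged always equals the total number of modification
events — an exactly tested conservation law. Localisation within the peptide
is trusted from the PSM record (no localisation scoring). When a peptide
matches several target proteins the lexicographically smallest id provides
coordinates, and repeated matches within one protein use the leftmost
position with a warning.

Cross-species site mapping is global Needleman–Wunsch (BLOSUM62, gap open 10,
extend 0.5) on Met-stripped sequences; a residue aligned to a gap maps to
none. Histone cores are near-identical between species, so the mapping is
insensitive to these parameters; they are fixed for determinism.

## Comparative statistics

Modified fraction = 100 × PTM spectra / total histone spectra, rounded
half-up to one decimal (the printed precision); the fold ratio is computed on
unrounded fractions and reported embryo/sperm, so values > 1 mean
sperm-depleted. A variant is flagged sample-specific when its spectral count
is positive in one sample and zero in the other; otherwise the ratio of
family-normalised proportions is reported. No significance testing is
performed — the analysis being reproduced performs none.

## Packaged reference data

`data/celegans_histones.fasta` / `data/mouse_histones.fasta` form a curated
synthetic reference set. H3 and H4 are the canonical, universally conserved
histone sequences. Genuine *C. elegans* H2A/H2B and mouse H2A/H2B entries
are not bundled; instead the curated scaffolds are built from the canonical
H2A/H2B cores under the constraint that every published residue numbering
and cross-species correspondence holds (C. elegans H2A K5/K8/K10/K96/
K119/K120 against mouse K5/K9/R11/K95/K118/K119; H2B K7/K10/K11/K14/K21/
K105/K113 against mouse K12/K15/K16/K20/K24/K108/K116). The HTAS-1 scaffold
ends in the variant's published C-terminal peptide (LPKKKAKEDDKENNS); HTZ-1,
H1 and an H3-variant scaffold complete the set. Coordinate-mapping results on
these scaffolds exercise the numbering convention and alignment machinery on
the published correspondences; for other sites on H2A/H2B they are not a
substitute for the organisms' true sequences.

`data/ptm_site_occurrences.tsv` transcribes the profiled dataset's per-site
occurrence table (ac/me1/me2/me3 by histone subtype, site and sample). Its
transcription reconciles with the dataset's own summary arithmetic for sperm
(22 distinct marks, 135 total occurrences) and for the distinct-mark counts
(31 embryo); the embryo occurrence total sums to 325 against a stated 330 —
the discrepancy is in the source material, so the package exposes the summed
value and asserts only the quantities that reconcile.

## Synthetic data generator

The generator emulates the statistical structure the validation and census
stages assume, not mass spectrometry itself. Per sample it draws
`n_psms_per_sample` PSMs (default 20 000, two samples): with probability
`true_match_fraction` (default 0.7) a correct match — a uniform substring
(7–25 residues, the typical tryptic range) of a target — otherwise an
incorrect match whose source is a target or a decoy with equal probability,
the assumption the FDR estimator relies on. Scores are class-conditional:
correct XCorr ~ N(3.2, 0.7), ΔCn ~ N(0.28, 0.10) truncated at 0, Δm ~
N(0, 2 ppm); incorrect XCorr ~ N(1.4, 0.5), ΔCn ~ N(0.06, 0.04), Δm ~
U(−50, 50) ppm. The classes overlap deliberately — neither separable nor
identical — so the nonparametric posterior is exercised meaningfully, and the
uniform ppm error makes the 6 ppm filter consequential (it removes 88% of
incorrect matches on its own). The original study publishes no score
distributions; these are modelling choices, not reconstructions.

Modification emission uses the profiled dataset's own per-spectrum rates:
for each (family, site, PTM) the marginal rate is the published occurrence
count divided by the sample's total histone spectra (7190 sperm, 5998
embryo), plus the embryo-specific H2A K120 ubiquitination signal
(132/5998) to exercise the exclusion path. Because a random peptide covers a
given site only occasionally, the generator rescales the marginal rate by
the number of targets and the exact coverage probability of the site under
the peptide-length distribution, so the realised per-spectrum rates match
the published ones in expectation (probabilities are capped at 1).

What the generator does **not** model: fragment spectra, retention times,
chromatography, missed cleavages, charge-dependent score shifts, real
peptide detectability, or sample-specific protein abundance (targets are
drawn uniformly, so HTAS-1 sperm-specificity is checked from the printed
counts, not the simulation). Passing tests therefore demonstrate the
correctness of the downstream statistics under these stated conditions, not
performance on real search output.

## Problem sizes and numerics

Default analyses use 20 000 PSMs per sample; the calibration study uses 20
seeded runs of 20 000 PSMs (10 000 per sample), enough for binomial standard
errors well below the half-percentage-point band being checked. KDE grids are
512 points; densities integrate to 1 within 1e-3 on their grid; NSAF
normalisation and spectral-count conservation hold to 1e-9. Scores are
written with 4 decimals (NSAF 6), which the simulator also emits, so the TSV
round trip is lossless. All randomness flows from a single mandatory seed
through `numpy.random.default_rng`.

## Known limitations

- The decoy/total FDR estimator is downward-biased by construction (see
  above); it is kept for fidelity to the convention being reproduced.
- Identical-set clustering is the only protein inference; no parsimony
  beyond it.
- emPAI observability is a fixed convention (600–3600 Da, zero missed
  cleavages), not a reconstruction of the original criteria.
- The curated H2A/H2B scaffolds guarantee the published site
  correspondences but are not the organisms' full true sequences.
- Whether the published total-histone-spectra denominators include
  semi-tryptic spectra is not stated in the source; the pipeline computes
  its denominators from all passing histone spectra and exposes the census
  (full-tryptic) counts separately.
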