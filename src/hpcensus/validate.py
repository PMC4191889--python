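"""Target-decoy PSM validation.

PSMs are grouped into 12 subgroups by charge class (1, 2, 3, >3) and tryptic
status (full, half, non). Within each subgroup a two-class linear discriminant
over (XCorr, DeltaCN, |DeltaMass ppm|) separates direct (target-matched) from
decoy PSMs, and peptide probabilities come from a nonparametric
(kernel-density) fit of the two projected score distributions:

    P(correct | s) = clip(1 - pi0 * f_decoy(s) / f_direct(s), 0, 1)

where f_direct is the density of the observed direct scores (itself the
mixture of correct and incorrect matches) and pi0 = n_decoy / n_direct
estimates the incorrect fraction among direct PSMs, under the standard
target-decoy assumption that an incorrect match is equally likely to hit a
target or a decoy sequence. Isotonic regression along the score grid enforces
the monotonicity that raw KDE ratios can violate.

Filtering accepts a PSM when its probability reaches ``p_min`` (default 0.90)
and |DeltaMass| is at most ``ppm_max`` (default 6 ppm). The estimated FDR is
the percentage of decoy PSMs among all accepted PSMs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.isotonic import IsotonicRegression

from .records import (
    CHARGE_CLASSES,
    DECOY_PREFIX,
    TRYPTIC_STATUSES,
    PSMRecord,
)

__all__ = [
    "SubgroupKey",
    "ALL_SUBGROUPS",
    "assign_subgroup",
    "ValidationModel",
    "ValidationResult",
    "fit_model",
    "score_probability",
    "filter_psms",
    "estimate_fdr",
    "NoDecoyError",
    "NoPassingPSMError",
]

N_MIN_PER_CLASS = 50
GRID_SIZE = 512


@dataclass(frozen=True)
class SubgroupKey:
    charge_class: str
    tryptic_status: str

    def __post_init__(self) -> None:
        if self.charge_class not in CHARGE_CLASSES:
            raise ValueError(f"unknown charge class {self.charge_class!r}")
        if self.tryptic_status not in TRYPTIC_STATUSES:
            raise ValueError(f"unknown tryptic status {self.tryptic_status!r}")


ALL_SUBGROUPS = tuple(
    SubgroupKey(c, t) for c in CHARGE_CLASSES for t in TRYPTIC_STATUSES
)


def assign_subgroup(psm: PSMRecord) -> SubgroupKey:
    """Deterministic subgroup key from the PSM's charge and tryptic tags."""
    return SubgroupKey(psm.charge_class, psm.tryptic_status)


class NoDecoyError(ValueError):
    """The model cannot calibrate without any decoy PSMs."""


class NoPassingPSMError(ValueError):
    """FDR is undefined when no PSM passes the filters."""


def _features(psms: Sequence[PSMRecord]) -> np.ndarray:
    return np.array(
        [[p.xcorr, p.deltacn, abs(p.delta_mass_ppm)] for p in psms], float
    )


@dataclass
class _SubgroupFit:
    """Discriminant weights plus the gridded posterior for one subgroup."""

    weights: np.ndarray  # 3-vector over (xcorr, deltacn, |ppm|)
    grid: np.ndarray
    direct_density: np.ndarray
    decoy_density: np.ndarray
    posterior: np.ndarray
    pi_incorrect: float
    fallback_used: bool = False

    def score(self, psm: PSMRecord) -> float:
        x = np.array([psm.xcorr, psm.deltacn, abs(psm.delta_mass_ppm)])
        return float(x @ self.weights)

    def probability(self, psm: PSMRecord) -> float:
        return float(
            np.interp(self.score(psm), self.grid, self.posterior)
        )


def _fit_subgroup(
    direct: np.ndarray, decoy: np.ndarray, fallback_used: bool = False
) -> _SubgroupFit:
    lda = LinearDiscriminantAnalysis()
    X = np.vstack([direct, decoy])
    y = np.concatenate([np.ones(len(direct)), np.zeros(len(decoy))])
    lda.fit(X, y)
    w = lda.coef_[0].astype(float)
    s_direct, s_decoy = direct @ w, decoy @ w
    if s_direct.mean() < s_decoy.mean():  # orient: higher score = more direct
        w = -w
        s_direct, s_decoy = -s_direct, -s_decoy

    kde_direct = gaussian_kde(s_direct, bw_method="silverman")
    kde_decoy = gaussian_kde(s_decoy, bw_method="silverman")
    bw = max(
        float(kde_direct.factor * s_direct.std(ddof=1)),
        float(kde_decoy.factor * s_decoy.std(ddof=1)),
    )
    all_s = np.concatenate([s_direct, s_decoy])
    grid = np.linspace(all_s.min() - 3 * bw, all_s.max() + 3 * bw, GRID_SIZE)
    f_direct = kde_direct(grid)
    f_decoy = kde_decoy(grid)

    pi0 = min(1.0, len(decoy) / len(direct))
    ratio = f_decoy / np.maximum(f_direct, 1e-300)
    posterior = np.clip(1.0 - pi0 * ratio, 0.0, 1.0)
    posterior = IsotonicRegression(
        y_min=0.0, y_max=1.0, increasing=True
    ).fit_transform(grid, posterior)
    return _SubgroupFit(
        weights=w,
        grid=grid,
        direct_density=f_direct,
        decoy_density=f_decoy,
        posterior=np.asarray(posterior),
        pi_incorrect=pi0,
        fallback_used=fallback_used,
    )


@dataclass
class ValidationModel:
    """Per-subgroup discriminant/density fits with a pooled fallback."""

    subgroups: dict
    pooled: _SubgroupFit
    decoy_prefix: str = DECOY_PREFIX

    def fit_for(self, key: SubgroupKey) -> _SubgroupFit:
        return self.subgroups.get(key, self.pooled)

    @property
    def n_subgroup_fits(self) -> int:
        return len(self.subgroups)


def fit_model(
    psms: Sequence[PSMRecord], decoy_prefix: str = DECOY_PREFIX
) -> ValidationModel:
    """Fit the per-subgroup validation model.

    Subgroups with at least ``N_MIN_PER_CLASS`` direct and decoy members get
    their own discriminant + KDE fit; the rest fall back to the pooled
    (all-subgroup) fit, marked ``fallback_used``.
    """
    direct = [p for p in psms if not p.is_decoy_match(decoy_prefix)]
    decoy = [p for p in psms if p.is_decoy_match(decoy_prefix)]
    if not decoy:
        raise NoDecoyError(
            "no decoy PSMs: the target-decoy model cannot calibrate"
        )
    if not direct:
        raise ValueError("no direct PSMs to validate")
    pooled = _fit_subgroup(_features(direct), _features(decoy), fallback_used=True)

    subgroup_fits: dict[SubgroupKey, _SubgroupFit] = {}
    for key in ALL_SUBGROUPS:
        sub_direct = [p for p in direct if assign_subgroup(p) == key]
        sub_decoy = [p for p in decoy if assign_subgroup(p) == key]
        if len(sub_direct) >= N_MIN_PER_CLASS and len(sub_decoy) >= N_MIN_PER_CLASS:
            subgroup_fits[key] = _fit_subgroup(
                _features(sub_direct), _features(sub_decoy)
            )
    return ValidationModel(
        subgroups=subgroup_fits, pooled=pooled, decoy_prefix=decoy_prefix
    )


def score_probability(model: ValidationModel, psm: PSMRecord) -> float:
    """Peptide probability of one PSM under the fitted model (in [0, 1])."""
    return model.fit_for(assign_subgroup(psm)).probability(psm)


@dataclass
class ValidationResult:
    psm: PSMRecord
    probability: float
    passed: bool
    fail_reason: str  # below_probability | ppm_exceeded | none

    def __post_init__(self) -> None:
        assert self.passed == (self.fail_reason == "none")


def filter_psms(
    psms: Iterable[PSMRecord],
    model: ValidationModel,
    p_min: float = 0.90,
    ppm_max: float = 6.0,
) -> list[ValidationResult]:
    """Apply the probability threshold and the hard |DeltaMass| ppm filter.

    Order-preserving; every input PSM appears exactly once. The probability
    boundary is inclusive (probability == p_min passes), as is the ppm
    boundary (|ppm| == ppm_max passes; only strictly greater is rejected).
    """
    results = []
    for psm in psms:
        prob = score_probability(model, psm)
        if prob < p_min:
            passed, reason = False, "below_probability"
        elif abs(psm.delta_mass_ppm) > ppm_max:
            passed, reason = False, "ppm_exceeded"
        else:
            passed, reason = True, "none"
        results.append(ValidationResult(psm, prob, passed, reason))
    return results


def estimate_fdr(
    results: Iterable[ValidationResult], decoy_prefix: str = DECOY_PREFIX
) -> float:
    """Decoy-based FDR estimate, as a percentage of accepted PSMs.

    100 x (accepted PSMs whose every matched protein is a decoy) / (all
    accepted PSMs). This is the plain decoy/total estimator, not the doubled
    one.
    """
    passing = [r for r in results if r.passed]
    if not passing:
        raise NoPassingPSMError("no PSM passed the filters; FDR undefined")
    n_decoy = sum(r.psm.is_decoy_match(decoy_prefix) for r in passing)
    return 100.0 * n_decoy / len(passing)
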