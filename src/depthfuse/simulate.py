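"""Synthetic cohorts with a target AI operating point and correlated raters.

Real endoscopic images and per-case expert reads are not publicly
deposited for this problem, so the generator emulates the *statistical*
structure the analysis pipeline assumes:

* a balanced (or arbitrary) mix of intramucosal (M) and submucosal (SM)
  cases;
* an AI probability built from a binormal latent score — the score is
  N(0, 1) for M cases and N(delta, 1) for SM cases, and thresholding at
  ``t`` yields exactly the requested (sensitivity, specificity) in
  expectation, with ``t = Phi^-1(spec)`` and
  ``delta = Phi^-1(spec) + Phi^-1(sens)``;
* one binary vote per rater from a one-factor latent Gaussian model:
  each case draws a shared factor ``c ~ N(0,1)`` and rater r's latent is
  ``sqrt(rho) * c + sqrt(1 - rho) * e_r``; per-class thresholds pin every
  rater's marginal (sensitivity, specificity) exactly for any
  correlation ``rho``, while ``rho`` alone controls how often raters
  agree beyond chance.

Presets reproduce the published study design: a 250/250 training-like
cohort with four expert raters at their printed operating points, and a
100/100 test-like cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .metrics import NEGATIVE, POSITIVE
from .records import CaseRecord

__all__ = [
    "BinormalCalibration",
    "CohortConfig",
    "calibrate_binormal",
    "generate_cohort",
    "paper_preset",
    "PRESET_NAMES",
]

#: median tumour diameter ~18 mm with a long right tail, typical of
#: depressed-type early gastric cancer series
_DIAMETER_LOG_MEAN = float(np.log(18.0))
_DIAMETER_LOG_SD = 0.45
_P_UNDIFFERENTIATED = 0.30
_LARGE_DIAMETER_MM = 30.0


@dataclass(frozen=True)
class BinormalCalibration:
    """Latent-scale class separation and decision threshold."""

    delta: float
    t: float

    @property
    def sensitivity(self) -> float:
        return float(norm.cdf(self.delta - self.t))

    @property
    def specificity(self) -> float:
        return float(norm.cdf(self.t))


def calibrate_binormal(sens: float, spec: float) -> BinormalCalibration:
    """Threshold and class separation hitting an operating point exactly.

    With the M latent ~ N(0, 1), SM latent ~ N(delta, 1) and the SM call
    made when the latent exceeds ``t``, the choices ``t = Phi^-1(spec)``
    and ``delta = t + Phi^-1(sens)`` give sensitivity ``Phi(delta - t)``
    and specificity ``Phi(t)`` equal to the targets. Boundary values 0
    and 1 have no finite calibration and are rejected.
    """
    if not (0.0 < sens < 1.0 and 0.0 < spec < 1.0):
        raise ValueError("sensitivity and specificity must lie strictly in (0, 1)")
    t = float(norm.ppf(spec))
    delta = t + float(norm.ppf(sens))
    return BinormalCalibration(delta=delta, t=t)


@dataclass(frozen=True)
class CohortConfig:
    """Everything that determines a synthetic cohort, including the seed."""

    n_pos: int
    n_neg: int
    ai_sens: float
    ai_spec: float
    rater_ops: Mapping[str, Tuple[float, float]] = field(default_factory=dict)
    rho: float = 0.5
    covariate_effect: float = 0.0
    sm1_fraction: float = 0.38
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("both class sizes must be >= 1")
        for name, value in (("ai_sens", self.ai_sens), ("ai_spec", self.ai_spec)):
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1), got {value}")
        for rater, (s, sp) in self.rater_ops.items():
            if not (0.0 < s < 1.0 and 0.0 < sp < 1.0):
                raise ValueError(
                    f"rater {rater!r} operating point must lie strictly in (0, 1)^2"
                )
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if not 0.0 <= self.sm1_fraction <= 1.0:
            raise ValueError("sm1_fraction must lie in [0, 1]")


def generate_cohort(config: CohortConfig) -> List[CaseRecord]:
    """Draw a deterministic synthetic cohort from *config*.

    The AI probability is a logistic transform of the shifted latent
    score, ``p_sm = expit(delta * (s - t))``, i.e. the equal-prior
    binormal posterior recentred so that the p = 0.5 boundary coincides
    with the calibrated threshold ``t`` — so thresholding the published
    probability at 0.5 reproduces the target operating point. When
    ``covariate_effect > 0``, truth-M lesions that are large (> 30 mm) or
    undifferentiated have their AI latent shifted toward SM, emulating
    the classifier's documented failure mode on such lesions.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_pos + config.n_neg
    is_sm = np.zeros(n, dtype=bool)
    is_sm[: config.n_pos] = True
    is_sm = is_sm[rng.permutation(n)]

    diameter = rng.lognormal(_DIAMETER_LOG_MEAN, _DIAMETER_LOG_SD, size=n)
    undiff = rng.random(n) < _P_UNDIFFERENTIATED

    cal = calibrate_binormal(config.ai_sens, config.ai_spec)
    s = np.where(is_sm, cal.delta, 0.0) + rng.standard_normal(n)
    if config.covariate_effect != 0.0:
        hard_m = ~is_sm & ((diameter > _LARGE_DIAMETER_MM) | undiff)
        s = s + config.covariate_effect * hard_m
    # below-chance targets give delta <= 0; keep p monotone in s with the
    # 0.5 cut still at t (a plain logistic link instead of the posterior)
    slope = cal.delta if cal.delta > 0 else 1.0
    p_sm = expit(slope * (s - cal.t))

    raters = list(config.rater_ops)
    votes = np.zeros((n, len(raters)), dtype=bool)
    if raters:
        c = rng.standard_normal(n)
        e = rng.standard_normal((n, len(raters)))
        u = np.sqrt(config.rho) * c[:, None] + np.sqrt(1.0 - config.rho) * e
        for j, rater in enumerate(raters):
            sens_r, spec_r = config.rater_ops[rater]
            # P(vote SM | SM) = sens_r ; P(vote SM | M) = 1 - spec_r
            thresh = np.where(is_sm, norm.isf(sens_r), norm.ppf(spec_r))
            votes[:, j] = u[:, j] > thresh

    sm1 = rng.random(n) < config.sm1_fraction

    width = max(4, len(str(n)))
    cohort: List[CaseRecord] = []
    for i in range(n):
        truth = POSITIVE if is_sm[i] else NEGATIVE
        cohort.append(
            CaseRecord(
                case_id=f"case-{i + 1:0{width}d}",
                truth=truth,
                p_sm=float(p_sm[i]),
                votes={r: (POSITIVE if votes[i, j] else NEGATIVE) for j, r in enumerate(raters)},
                sm_stage=("SM1" if sm1[i] else "SM2") if is_sm[i] else None,
                diameter_mm=float(diameter[i]),
                histology="undifferentiated" if undiff[i] else "differentiated",
            )
        )
    return cohort


#: printed per-rater operating points of the four expert endoscopists
#: (sensitivity, specificity) on the 250/250 training cohort
EXPERT_OPERATING_POINTS: Dict[str, Tuple[float, float]] = {
    "A": (0.616, 0.760),
    "B": (0.544, 0.892),
    "C": (0.432, 0.900),
    "D": (0.600, 0.696),
}

PRESET_NAMES = ("training_like", "test_like")


def paper_preset(name: str, seed: int = 0, rho: float = 0.5) -> CohortConfig:
    """Cohort configurations mirroring the published study design.

    ``training_like``: 250 M / 250 SM cases, AI operating point
    (0.76, 0.78), four expert raters A-D at their printed operating
    points, SM1 fraction 95/250.

    ``test_like``: 100 M / 100 SM cases from the external-validation
    design, AI operating point (0.74, 0.71), three raters at the
    panel-level operating point (0.52, 0.88), SM1 fraction 26/100.
    """
    if name == "training_like":
        return CohortConfig(
            n_pos=250,
            n_neg=250,
            ai_sens=0.76,
            ai_spec=0.78,
            rater_ops=dict(EXPERT_OPERATING_POINTS),
            rho=rho,
            sm1_fraction=95 / 250,
            seed=seed,
        )
    if name == "test_like":
        return CohortConfig(
            n_pos=100,
            n_neg=100,
            ai_sens=0.74,
            ai_spec=0.71,
            rater_ops={"A": (0.52, 0.88), "B": (0.52, 0.88), "C": (0.52, 0.88)},
            rho=rho,
            sm1_fraction=26 / 100,
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}: expected one of {PRESET_NAMES}")
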