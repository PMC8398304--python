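"""Fixed-effects inverse-variance meta-analysis with heterogeneity statistics.

Independent per-allele estimates of the same disease are combined under the
common-effect model: weights w_i = 1/se_i², combined effect
Σw_i·b_i / Σw_i, combined standard error (Σw_i)^(-1/2). Between-study
heterogeneity is quantified by Cochran's Q = Σ w_i (b_i − b̄)², its
chi-square upper-tail p at k−1 degrees of freedom, and
I² = max(0, (Q − df)/Q)·100%.

Only the fixed-effects model is provided — no random-effects fallback is
attempted when I² > 0; the heterogeneity statistics are reported so the
reader can judge the common-effect assumption.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, norm

from .mr_core import RatioEstimate, _two_sided_p

__all__ = ["MetaResult", "fixed_effects_meta", "heterogeneity"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetaResult:
    """Combined estimate for one disease with its heterogeneity statistics."""

    disease_label: str
    member_labels: tuple[str, ...]
    beta_combined: float
    se_combined: float
    or_point: float
    ci_low: float
    ci_high: float
    p: float
    q_stat: float
    q_df: int
    p_het: float
    i2_percent: float
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if self.se_combined <= 0:
            raise ValueError("se_combined must be positive")
        if self.q_stat < 0:
            raise ValueError("q_stat must be non-negative")
        if not 0.0 <= self.i2_percent <= 100.0:
            raise ValueError("i2_percent must lie in [0, 100]")

    @property
    def k(self) -> int:
        return len(self.member_labels)

    def as_dict(self) -> dict[str, object]:
        return {
            "disease_label": self.disease_label,
            "member_labels": list(self.member_labels),
            "beta": self.beta_combined,
            "se": self.se_combined,
            "or": self.or_point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "q_stat": self.q_stat,
            "q_df": self.q_df,
            "p_het": self.p_het,
            "i2_percent": self.i2_percent,
            "confidence": self.confidence,
        }


def heterogeneity(
    estimates: list[RatioEstimate], beta_combined: float
) -> tuple[float, int, float, float]:
    """Cochran's Q, its df, chi-square p and I² for a set of estimates.

    With fewer than two estimates heterogeneity is undefined; the function
    warns and returns the degenerate (0, 0, 1, 0).
    """
    k = len(estimates)
    if k < 2:
        warnings.warn("heterogeneity undefined for fewer than 2 estimates", UserWarning, stacklevel=2)
        return 0.0, 0, 1.0, 0.0
    w = np.array([e.weight for e in estimates])
    b = np.array([e.beta for e in estimates])
    q = float(np.sum(w * (b - beta_combined) ** 2))
    df = k - 1
    p_het = float(chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return q, df, p_het, i2


def fixed_effects_meta(estimates: list[RatioEstimate], disease_label: str) -> MetaResult:
    """Combine estimates of one disease under the common-effect model.

    All members must be on the same scale (all per-allele or all per the
    same exposure unit). A single estimate passes through unchanged with
    q_df = 0. Raises ``ValueError`` on an empty list or mixed scales.
    """
    if not estimates:
        raise ValueError("fixed_effects_meta requires at least one estimate")
    scales = {e.scale for e in estimates}
    if len(scales) > 1:
        raise ValueError(f"cannot combine estimates on mixed scales: {sorted(scales)}")
    confidences = {e.confidence for e in estimates}
    if len(confidences) > 1:
        raise ValueError("members use different confidence levels")
    confidence = confidences.pop()

    w = np.array([e.weight for e in estimates])
    b = np.array([e.beta for e in estimates])
    beta_combined = float(np.sum(w * b) / np.sum(w))
    se_combined = float(np.sum(w)) ** -0.5
    if len(estimates) >= 2:
        q, df, p_het, i2 = heterogeneity(estimates, beta_combined)
    else:
        q, df, p_het, i2 = 0.0, 0, 1.0, 0.0

    z = float(norm.ppf(0.5 + confidence / 2.0))
    p = _two_sided_p(beta_combined / se_combined)
    result = MetaResult(
        disease_label=disease_label,
        member_labels=tuple(e.label for e in estimates),
        beta_combined=beta_combined,
        se_combined=se_combined,
        or_point=math.exp(beta_combined),
        ci_low=math.exp(beta_combined - z * se_combined),
        ci_high=math.exp(beta_combined + z * se_combined),
        p=p,
        q_stat=q,
        q_df=df,
        p_het=p_het,
        i2_percent=i2,
        confidence=confidence,
    )
    logger.info(
        "%s: combined OR %.4f (%.4f-%.4f) from %d estimate(s), I2=%.1f%%",
        disease_label,
        result.or_point,
        result.ci_low,
        result.ci_high,
        result.k,
        result.i2_percent,
    )
    return result
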