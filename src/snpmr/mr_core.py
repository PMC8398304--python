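"""Wald-ratio causal estimation for a single genetic instrument.

The causal effect of an exposure X on an outcome Y, instrumented by one
variant G, is estimated by the ratio of regression coefficients

    beta_IV = beta_GY / beta_GX,

the Wald (ratio) estimator. When the outcome beta is a log-odds per allele,
``exp(beta_GY)`` is itself the per-allele odds ratio; dividing by the
variant–exposure coefficient rescales it to the exposure's units.

Two standard errors are offered for the ratio:

* ``first_order``:  se(beta_GY) / |beta_GX| — ignores uncertainty in the
  denominator; exact for per-allele reporting, where the published odds
  ratios carry only the outcome standard error.
* ``second_order``: delta-method expansion including the exposure
  uncertainty, sqrt(se_GY²/beta_GX² + beta_GY²·se_GX²/beta_GX⁴).

Confidence intervals and p-values use the standard normal reference
throughout (two-sided), as is conventional for GWAS-scale sample sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .summary_io import GwasAssociation

__all__ = [
    "InstrumentRecord",
    "RatioEstimate",
    "per_allele_estimate",
    "wald_ratio",
    "rescale_estimate",
]

PER_ALLELE = "per_allele"
PER_EXPOSURE_UNIT = "per_exposure_unit"


@dataclass(frozen=True)
class InstrumentRecord:
    """Variant–exposure association defining the genetic instrument.

    ``beta_exposure`` is the exposure change per copy of ``effect_allele``
    in ``units`` (e.g. 17.1 g/day of milk per rs4988235 T allele).
    ``r2`` (variance explained) and ``n_exposure`` are optional metadata
    used by instrument-strength diagnostics.
    """

    variant_id: str
    effect_allele: str
    beta_exposure: float
    se_exposure: float
    units: str
    other_allele: str | None = None
    r2: float | None = None
    n_exposure: int | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.se_exposure) and self.se_exposure > 0):
            raise ValueError(f"se_exposure must be positive, got {self.se_exposure!r}")
        if self.r2 is not None and not 0.0 <= self.r2 <= 1.0:
            raise ValueError(f"r2 must lie in [0, 1], got {self.r2!r}")


@dataclass(frozen=True)
class RatioEstimate:
    """A causal (or per-allele) effect on the log-odds scale with its OR form.

    ``scale`` records whether ``beta`` is per effect allele or per exposure
    unit (``units`` then names the unit). ``weight`` is the inverse-variance
    weight 1/se² used by the meta-analysis.
    """

    label: str
    beta: float
    se: float
    or_point: float
    ci_low: float
    ci_high: float
    p: float
    scale: str
    confidence: float = 0.95
    units: str | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValueError(f"se must be positive, got {self.se!r}")
        if not math.isclose(self.or_point, math.exp(self.beta), rel_tol=1e-12):
            raise ValueError("or_point must equal exp(beta)")
        if not self.ci_low < self.or_point < self.ci_high:
            raise ValueError("confidence interval must bracket the point estimate")
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"p must lie in (0, 1], got {self.p!r}")

    @property
    def weight(self) -> float:
        """Inverse-variance weight 1/se²."""
        return 1.0 / (self.se * self.se)

    def as_dict(self) -> dict[str, object]:
        return {
            "label": self.label,
            "beta": self.beta,
            "se": self.se,
            "or": self.or_point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "scale": self.scale,
            "confidence": self.confidence,
            "units": self.units,
        }


def _z_quantile(confidence: float) -> float:
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must lie in (0, 1), got {confidence!r}")
    return float(norm.ppf(0.5 + confidence / 2.0))


def _two_sided_p(z_obs: float) -> float:
    # normal tail underflows to 0 around |z| ~ 39; keep p inside (0, 1]
    p = 2.0 * float(norm.sf(abs(z_obs)))
    return min(max(p, 5e-324), 1.0)


def _estimate(label: str, beta: float, se: float, confidence: float, scale: str, units: str | None) -> RatioEstimate:
    z = _z_quantile(confidence)
    p = _two_sided_p(beta / se)
    return RatioEstimate(
        label=label,
        beta=beta,
        se=se,
        or_point=math.exp(beta),
        ci_low=math.exp(beta - z * se),
        ci_high=math.exp(beta + z * se),
        p=p,
        scale=scale,
        confidence=confidence,
        units=units,
    )


def per_allele_estimate(assoc: GwasAssociation, confidence: float = 0.95) -> RatioEstimate:
    """Per-allele odds ratio with its confidence interval and p-value.

    The association's beta (log-odds per effect allele) is exponentiated;
    the interval is ``exp(beta ± z·se)`` with z the standard-normal quantile
    for the requested two-sided ``confidence``; p is the two-sided normal
    tail probability of ``|beta|/se``.
    """
    return _estimate(assoc.study_label, assoc.beta, assoc.se, confidence, PER_ALLELE, None)


def wald_ratio(
    assoc: GwasAssociation,
    instrument: InstrumentRecord,
    se_method: str = "first_order",
    confidence: float = 0.95,
) -> RatioEstimate:
    """Wald-ratio causal estimate per unit of the instrumented exposure.

    Divides the variant–outcome coefficient by the variant–exposure
    coefficient. ``se_method`` selects the first-order standard error
    (outcome uncertainty only) or the second-order delta-method form that
    also propagates the exposure standard error; the second-order se is
    never smaller than the first-order one.

    Raises
    ------
    ZeroDivisionError
        If the instrument's exposure beta is zero (degenerate instrument).
    """
    bx, sx = instrument.beta_exposure, instrument.se_exposure
    if bx == 0:
        raise ZeroDivisionError("degenerate instrument: beta_exposure is zero, ratio undefined")
    beta = assoc.beta / bx
    if se_method == "first_order":
        se = assoc.se / abs(bx)
    elif se_method == "second_order":
        se = math.sqrt(assoc.se**2 / bx**2 + assoc.beta**2 * sx**2 / bx**4)
    else:
        raise ValueError(f"se_method must be 'first_order' or 'second_order', got {se_method!r}")
    return _estimate(assoc.study_label, beta, se, confidence, PER_EXPOSURE_UNIT, instrument.units)


def rescale_estimate(est: RatioEstimate, factor: float, new_units: str | None = None) -> RatioEstimate:
    """Re-express an estimate per ``factor`` exposure units.

    Multiplies beta and se by ``factor`` (e.g. 100 to report per 100 g/day
    instead of per g/day) and recomputes the OR, interval and p; since
    beta/se is unchanged, p is invariant up to floating-point error.
    """
    if not (math.isfinite(factor) and factor > 0):
        raise ValueError(f"factor must be a positive real, got {factor!r}")
    return _estimate(est.label, est.beta * factor, est.se * factor, est.confidence, est.scale, new_units or est.units)
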