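"""Instrument-strength diagnostics for a single-variant instrument.

For a diallelic variant in Hardy-Weinberg equilibrium with effect-allele
frequency p, the allele count G has variance 2p(1-p), so a per-allele
effect b on an exposure with total standard deviation sigma explains

    R² = 2 p (1-p) b² / sigma²

of the exposure variance. The first-stage F statistic for k instruments in
a sample of n is F = R²(n-k-1) / (k(1-R²)); F > 10 is the conventional
rule of thumb for a non-weak instrument.

A :class:`StrengthReport` can also carry externally *reported* R²/F values
verbatim (source="reported"); the module never forces the two printed
numbers to be mutually consistent, since published R² and F frequently come
from different underlying regressions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = ["StrengthReport", "variance_explained", "f_statistic", "r2_from_f"]


@dataclass(frozen=True)
class StrengthReport:
    r2: float
    f_stat: float
    n: int | None
    source: str = "computed"  # "reported" | "computed"

    def __post_init__(self) -> None:
        if not 0.0 < self.r2 < 1.0:
            raise ValueError(f"r2 must lie in (0, 1), got {self.r2!r}")
        if self.f_stat <= 0:
            raise ValueError(f"f_stat must be positive, got {self.f_stat!r}")
        if self.source not in ("reported", "computed"):
            raise ValueError(f"source must be 'reported' or 'computed', got {self.source!r}")

    def as_dict(self) -> dict[str, object]:
        return {"r2": self.r2, "f_stat": self.f_stat, "n": self.n, "source": self.source}


def variance_explained(beta_exposure: float, eaf: float, exposure_sd: float) -> float:
    """Share of exposure variance explained by the variant under HWE.

    ``exposure_sd`` is the *total* standard deviation of the exposure in
    the population. Values ≥ 1 are clipped to 1 with a warning (they signal
    an exposure_sd smaller than the genetic contribution alone).
    """
    if not 0.0 < eaf < 1.0:
        raise ValueError(f"degenerate variant: eaf must lie strictly in (0, 1), got {eaf!r}")
    if exposure_sd <= 0:
        raise ValueError(f"exposure_sd must be positive, got {exposure_sd!r}")
    r2 = 2.0 * eaf * (1.0 - eaf) * beta_exposure**2 / exposure_sd**2
    if r2 >= 1.0:
        warnings.warn(
            f"computed R2 = {r2:.3g} >= 1; exposure_sd is smaller than the genetic "
            "contribution implies, clipping to 1",
            UserWarning,
            stacklevel=2,
        )
        return 1.0
    return r2


def f_statistic(r2: float, n: int, k: int = 1) -> float:
    """First-stage F for variance explained ``r2`` with ``k`` instruments."""
    if not 0.0 <= r2 < 1.0:
        raise ValueError(f"r2 must lie in [0, 1), got {r2!r}")
    if n <= k + 1:
        raise ValueError(f"need n > k + 1, got n={n}, k={k}")
    return r2 * (n - k - 1) / (k * (1.0 - r2))


def r2_from_f(f_stat: float, n: int, k: int = 1) -> float:
    """Invert :func:`f_statistic`: the R² implying ``f_stat`` at sample size ``n``."""
    if f_stat < 0:
        raise ValueError(f"f_stat must be non-negative, got {f_stat!r}")
    if n <= k + 1:
        raise ValueError(f"need n > k + 1, got n={n}, k={k}")
    kf = k * f_stat
    return kf / (n - k - 1 + kf)
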