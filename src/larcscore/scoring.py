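"""Immunoscore and neoadjuvant rectal (NAR) score computation.

The immunoscore (IS) of a patient is the arithmetic mean of four density
percentiles -- CD3+ and CD8+ T-cell densities in the tumor core (CT) and
at the invasive margin (IM) -- dichotomized at 62 (high: mean >= 62).
Percentiles are taken against the analysis cohort itself, per
marker-region, using the Hazen plotting position 100*(rank - 0.5)/n with
mid-ranks for ties: symmetric, bounded away from 0 and 100, and standard
for small cohorts.

The NAR score is a surrogate endpoint for survival after neoadjuvant
treatment of rectal cancer:

    NAR = (5*pN - 3*(cT - pT) + 12)^2 / 9.61

with integer-encoded stages (baseline clinical T, post-treatment
pathologic T and N).  The radiologic variant substitutes post-treatment
MRI stages for the pathologic ones.  Scores are categorized low (<8),
intermediate (8-16, inclusive) and high (>16); over the encoded stage
domain the inner term is a nonnegative integer, so the attainable values
k^2/9.61 never hit a boundary exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "IS_CUTOFF",
    "ImmunoscoreResult",
    "NarResult",
    "percentile_ranks",
    "immunoscore",
    "categorize_nar",
    "nar_pathologic",
    "nar_radiologic",
    "combined_stratum",
]

IS_CUTOFF = 62.0
NAR_DENOMINATOR = 9.61
NAR_LOW_UPPER = 8.0
NAR_HIGH_LOWER = 16.0


@dataclass(frozen=True)
class ImmunoscoreResult:
    """Four marker-region percentiles, their mean, and the high/low class."""

    p_cd3_ct: float
    p_cd3_im: float
    p_cd8_ct: float
    p_cd8_im: float
    mean_percentile: float
    is_class: str  # "high" | "low"


@dataclass(frozen=True)
class NarResult:
    """NAR value plus its low/intermediate/high category."""

    value: float
    category: str  # "low" | "intermediate" | "high"
    variant: str   # "pathologic" | "radiologic"


def percentile_ranks(densities: Sequence[float]) -> List[float]:
    """Hazen percentile ranks of one marker-region across the cohort.

    percentile(x) = 100 * (rank(x) - 0.5) / n, mid-ranks for ties;
    output order matches input order.
    """
    arr = np.asarray(densities, dtype=float)
    if arr.size == 0:
        raise ValueError("percentile_ranks requires a nonempty list")
    if not np.all(np.isfinite(arr)):
        raise ValueError("densities must be finite")
    if np.any(arr < 0):
        raise ValueError("densities must be nonnegative")
    ranks = rankdata(arr, method="average")
    return list(100.0 * (ranks - 0.5) / arr.size)


def immunoscore(
    p_cd3_ct: float,
    p_cd3_im: float,
    p_cd8_ct: float,
    p_cd8_im: float,
    cutoff: float = IS_CUTOFF,
) -> ImmunoscoreResult:
    """Mean of the four marker-region percentiles, classed high iff >= cutoff."""
    ps = (p_cd3_ct, p_cd3_im, p_cd8_ct, p_cd8_im)
    for p in ps:
        if not (0.0 <= p <= 100.0):
            raise ValueError(f"percentile out of [0, 100]: {p!r}")
    mean = sum(ps) / 4.0
    return ImmunoscoreResult(*ps, mean_percentile=mean,
                             is_class="high" if mean >= cutoff else "low")


def categorize_nar(value: float) -> str:
    """low (<8) / intermediate (8-16) / high (>16)."""
    if value < 0:
        raise ValueError(f"NAR value must be nonnegative, got {value!r}")
    if value < NAR_LOW_UPPER:
        return "low"
    if value <= NAR_HIGH_LOWER:
        return "intermediate"
    return "high"


def _check_stage(value: int, hi: int, name: str) -> int:
    if not isinstance(value, (int, np.integer)) or not (0 <= value <= hi):
        raise ValueError(f"{name} must be an integer in 0..{hi}, got {value!r}")
    return int(value)


def _nar(ct: int, t_post: int, n_post: int, variant: str) -> NarResult:
    ct = _check_stage(ct, 4, "cT")
    t_post = _check_stage(t_post, 4, "post-treatment T")
    n_post = _check_stage(n_post, 2, "post-treatment N")
    inner = 5 * n_post - 3 * (ct - t_post) + 12
    # inner >= 5*0 - 3*(4-0) + 12 = 0 over the encoded domain
    value = inner * inner / NAR_DENOMINATOR
    return NarResult(value=value, category=categorize_nar(value), variant=variant)


def nar_pathologic(ct: int, ypt: int, ypn: int) -> NarResult:
    """Pathologic NAR from encoded baseline cT and pathologic ypT/ypN."""
    return _nar(ct, ypt, ypn, "pathologic")


def nar_radiologic(ct_pre: int, ct_post: int, cn_post: int) -> NarResult:
    """Radiologic NAR from encoded pre-treatment cT and post-treatment MRI T/N."""
    return _nar(ct_pre, ct_post, cn_post, "radiologic")


def combined_stratum(is_class: Optional[str], mrtrg: Optional[int]) -> Optional[str]:
    """Combined immunoscore x mrTRG stratum.

    "is_high_and_trg1" iff is_class == "high" and mrTRG == 1, else "other";
    missing input -> None.
    """
    if is_class is None or mrtrg is None:
        return None
    if is_class not in ("high", "low"):
        raise ValueError(f"is_class must be 'high' or 'low', got {is_class!r}")
    if mrtrg not in (1, 2, 3, 4, 5):
        raise ValueError(f"mrTRG must be in 1..5, got {mrtrg!r}")
    return "is_high_and_trg1" if (is_class == "high" and mrtrg == 1) else "other"
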