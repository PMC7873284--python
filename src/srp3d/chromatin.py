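"""Heterochromatin condensation ratios from retained projected function values.

For one nucleus, the per-patch pooled global-function values feed an
intensity ratio and the pooled radial+angular difference values feed an
aggregation ratio.  In both cases the heterochromatin threshold is the
minimum non-zero per-patch maximum; values strictly above it count as
heterochromatin (HC) and the ratio is ``sum(HC) / (sum(all) - sum(HC))``.

The +/-1 projection makes roughly half the raw function values negative
while the ratio is a fraction of a non-negative total, so all values enter
in magnitude: thresholds come from per-patch maxima of ``|f|`` and the
sums are of ``|f|``.  This keeps both sums non-negative and the ratio
well defined and scale-invariant.  Phenotype groups of per-nucleus ratios
are compared with the two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "HCECResult",
    "GroupComparison",
    "hc_threshold",
    "hc_ec_intensity",
    "hc_ec_aggregation",
    "measure_volume",
    "compare_groups",
]


@dataclass(frozen=True)
class HCECResult:
    """Per-nucleus condensation ratios and the thresholds that produced them."""

    ratio_intensity: float
    ratio_aggregation: float
    threshold_G: float
    threshold_RA: float
    patch_count: int
    valid: bool = True


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of two ratio cohorts."""

    p_value: float
    z_statistic: float
    direction: str  # "A>B", "A<B" or "A=B" by median shift
    n_a: int
    n_b: int
    alpha: float
    reject: bool


def hc_threshold(per_patch_maxima: Sequence[float]) -> float:
    """Minimum strictly non-zero entry of the per-patch maxima."""
    m = np.asarray(per_patch_maxima, dtype=float)
    nz = m[m != 0]
    if nz.size == 0:
        raise ValueError("all per-patch maxima are zero (degenerate volume)")
    return float(nz.min())


def _hc_ec_ratio(values_per_patch: List[np.ndarray]) -> tuple[float, float, bool]:
    """Shared mechanics of both ratios, on the value magnitudes.

    Returns ``(ratio, threshold, valid)``.  HC membership is strict
    (values equal to the threshold count as euchromatin), so an all-equal
    volume yields ratio 0.  A non-positive euchromatin denominator (all
    mass above the threshold) is flagged invalid and reported as an
    infinite sentinel.
    """
    mags = [np.abs(np.asarray(v, dtype=float)).ravel() for v in values_per_patch]
    maxima = [float(np.max(v)) for v in mags]
    thr = hc_threshold(maxima)
    pooled = np.concatenate(mags)
    hc_sum = float(pooled[pooled > thr].sum())
    total = float(pooled.sum())
    denom = total - hc_sum
    if denom <= 0:
        warnings.warn(
            f"euchromatin denominator {denom} <= 0; ratio is undefined",
            stacklevel=3,
        )
        return float("inf"), thr, False
    return hc_sum / denom, thr, True


def hc_ec_intensity(descriptor_set) -> float:
    """HC/EC intensity ratio from the pooled global-function values.

    Scale-invariant: multiplying every voxel by ``c > 0`` scales values and
    threshold alike and leaves the ratio unchanged.
    """
    vals = [d.raw_fG for d in descriptor_set.descriptors]
    if not vals:
        raise ValueError("descriptor set is empty")
    ratio, _, _ = _hc_ec_ratio(vals)
    return ratio


def hc_ec_aggregation(descriptor_set) -> float:
    """HC/EC aggregation ratio from the pooled radial+angular difference values."""
    vals = [d.raw_fRA for d in descriptor_set.descriptors]
    if not vals:
        raise ValueError("descriptor set is empty")
    ratio, _, _ = _hc_ec_ratio(vals)
    return ratio


def measure_volume(descriptor_set) -> HCECResult:
    """Both condensation ratios of one nucleus, with thresholds."""
    g_vals = [d.raw_fG for d in descriptor_set.descriptors]
    ra_vals = [d.raw_fRA for d in descriptor_set.descriptors]
    if not g_vals:
        raise ValueError("descriptor set is empty")
    r_int, thr_g, ok_g = _hc_ec_ratio(g_vals)
    r_agg, thr_ra, ok_ra = _hc_ec_ratio(ra_vals)
    return HCECResult(
        ratio_intensity=r_int,
        ratio_aggregation=r_agg,
        threshold_G=thr_g,
        threshold_RA=thr_ra,
        patch_count=len(g_vals),
        valid=ok_g and ok_ra,
    )


def compare_groups(
    ratios_a: Sequence[float],
    ratios_b: Sequence[float],
    alpha: float = 0.01,
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test between two cohorts of ratios."""
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    z, p = stats.ranksums(a, b)
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if med_a > med_b:
        direction = "A>B"
    elif med_a < med_b:
        direction = "A<B"
    else:
        direction = "A=B"
    return GroupComparison(
        p_value=float(p),
        z_statistic=float(z),
        direction=direction,
        n_a=a.size,
        n_b=b.size,
        alpha=alpha,
        reject=bool(p < alpha),
    )
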