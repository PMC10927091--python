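"""Signed, thresholded, normalized mutual information (nI) between a
structural feature and binary assembly membership.

The statistic is plug-in mutual information between the feature (discretized
into equal-width bins between two percentiles) and the binary membership
indicator, divided by the membership entropy so it lies in [0, 1]. Values
not exceeding a permutation threshold (mean + 1 std of shuffled-membership
controls) are set to zero; surviving values receive the sign of the trend of
membership probability versus feature value (count-weighted least-squares
slope). The conditional variant conditions both the information and the
entropy on a third (binned) feature and permutes membership within strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .structure import FeatureVector


@dataclass
class BinnedFeature:
    codes: np.ndarray  # bin index per neuron
    edges: np.ndarray
    degenerate: bool = False  # constant feature: single occupied bin


@dataclass
class NIResult:
    ni: float  # signed, thresholded, in [-1, 1]
    raw_mi: float  # bits
    entropy: float  # H(Y) (or H(Y|Z)) in bits
    threshold: float  # permutation threshold on raw MI
    slope: float  # fitted membership-curve slope (sign source)
    significant: bool
    edges: np.ndarray = field(default=None)
    notes: list = field(default_factory=list)


def bin_feature(
    values, n_bins: int = 21, pct_lo: float = 1.0, pct_hi: float = 99.0
) -> BinnedFeature:
    """Equal-width discretization between two percentiles; out-of-range
    values are clipped into the end bins."""
    if isinstance(values, FeatureVector):
        values = values.values
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if not finite.any():
        raise ValueError("all-missing feature")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if not pct_lo < pct_hi:
        raise ValueError("pct_lo must be < pct_hi")
    lo, hi = np.percentile(x[finite], [pct_lo, pct_hi])
    if hi <= lo:  # (near-)constant feature
        codes = np.zeros(x.size, dtype=np.int64)
        return BinnedFeature(codes, np.array([lo, lo]), degenerate=True)
    edges = np.linspace(lo, hi, n_bins + 1)
    codes = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1).astype(np.int64)
    return BinnedFeature(codes, edges)


def membership_curve(xb: BinnedFeature, y):
    """Per occupied bin: (bin index, P(Y=1 | bin), sample count)."""
    y = np.asarray(y, dtype=np.int64)
    if y.size != xb.codes.size:
        raise ValueError("misaligned feature and membership")
    bins = np.unique(xb.codes)
    probs = np.array([y[xb.codes == b].mean() for b in bins])
    counts = np.array([(xb.codes == b).sum() for b in bins])
    return bins, probs, counts


def _plugin_mi_bits(codes: np.ndarray, y: np.ndarray, n_codes: int) -> float:
    """Plug-in I(X;Y) in bits from the joint histogram."""
    joint = np.zeros((n_codes, 2))
    np.add.at(joint, (codes, y), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (px * py))
    return float(np.nansum(terms))


def _entropy_bits(y: np.ndarray) -> float:
    p = np.bincount(y, minlength=2).astype(float)
    p /= p.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _weighted_slope(xb: BinnedFeature, y: np.ndarray) -> float:
    bins, probs, counts = membership_curve(xb, y)
    if bins.size < 2:
        return 0.0
    centers = (
        0.5 * (xb.edges[:-1] + xb.edges[1:])[bins]
        if xb.edges.size > bins.max() + 1
        else bins.astype(float)
    )
    w = counts.astype(float)
    xm = np.average(centers, weights=w)
    ym = np.average(probs, weights=w)
    denom = np.sum(w * (centers - xm) ** 2)
    if denom == 0:
        return 0.0
    return float(np.sum(w * (centers - xm) * (probs - ym)) / denom)


def normalized_mi(
    x,
    y,
    n_bins: int = 21,
    n_controls: int = 100,
    seed: int = 0,
    pct_lo: float = 1.0,
    pct_hi: float = 99.0,
    xb: Optional[BinnedFeature] = None,
) -> NIResult:
    """nI(Y; X): signed, thresholded, entropy-normalized mutual information.

    Significance: the raw MI must exceed mean + 1 std of the MI values
    obtained after permuting the membership vector ``n_controls`` times
    (permuting Y preserves the feature marginal exactly).
    """
    y = np.asarray(y, dtype=np.int64)
    if np.unique(y).size < 2:
        raise ValueError("membership vector must contain both classes")
    if xb is None:
        xb = bin_feature(x, n_bins, pct_lo, pct_hi)
    n_codes = int(xb.codes.max()) + 1
    H = _entropy_bits(y)
    raw = _plugin_mi_bits(xb.codes, y, n_codes)
    notes = []
    if xb.degenerate:
        notes.append("degenerate feature: single occupied bin")
        return NIResult(0.0, raw, H, np.inf, 0.0, False, xb.edges, notes)

    rng = np.random.default_rng(seed)
    controls = np.empty(n_controls)
    for c in range(n_controls):
        controls[c] = _plugin_mi_bits(xb.codes, rng.permutation(y), n_codes)
    threshold = float(controls.mean() + controls.std(ddof=0))
    if raw <= threshold:
        return NIResult(0.0, raw, H, threshold, 0.0, False, xb.edges, notes)
    slope = _weighted_slope(xb, y)
    sign = -1.0 if slope < 0 else 1.0
    return NIResult(sign * raw / H, raw, H, threshold, slope, True, xb.edges, notes)


def conditional_normalized_mi(
    x,
    y,
    z,
    n_bins: int = 21,
    n_controls: int = 100,
    seed: int = 0,
    pct_lo: float = 1.0,
    pct_hi: float = 99.0,
) -> NIResult:
    """Conditional nI: I(X;Y|Z) / H(Y|Z), with Z binned like X.

    Permutation controls shuffle membership within Z-strata (preserving the
    Y–Z relation); the sign comes from the count-weighted average of
    within-stratum membership-curve slopes. Strata containing a single
    membership class contribute zero information and are logged.
    """
    y = np.asarray(y, dtype=np.int64)
    if np.unique(y).size < 2:
        raise ValueError("membership vector must contain both classes")
    xb = bin_feature(x, n_bins, pct_lo, pct_hi)
    zb = bin_feature(z, n_bins, pct_lo, pct_hi)
    n_codes = int(xb.codes.max()) + 1
    strata = np.unique(zb.codes)
    n = y.size
    notes = []

    def cond_mi(yv: np.ndarray) -> float:
        total = 0.0
        for s in strata:
            m = zb.codes == s
            ys = yv[m]
            if np.unique(ys).size < 2:
                continue
            total += m.sum() / n * _plugin_mi_bits(xb.codes[m], ys, n_codes)
        return total

    H = 0.0
    slopes, weights = [], []
    for s in strata:
        m = zb.codes == s
        ys = y[m]
        if np.unique(ys).size < 2:
            notes.append(f"stratum {int(s)}: single membership class")
        H += m.sum() / n * _entropy_bits(ys)
        sub = BinnedFeature(xb.codes[m], xb.edges, xb.degenerate)
        slopes.append(_weighted_slope(sub, ys))
        weights.append(m.sum())
    raw = cond_mi(y)
    if H == 0:
        warnings.warn("H(Y|Z) = 0: conditional nI undefined, returning 0")
        return NIResult(0.0, raw, 0.0, np.inf, 0.0, False, xb.edges, notes)

    rng = np.random.default_rng(seed)
    controls = np.empty(n_controls)
    for c in range(n_controls):
        yp = y.copy()
        for s in strata:
            m = np.where(zb.codes == s)[0]
            yp[m] = yp[m[rng.permutation(m.size)]]
        controls[c] = cond_mi(yp)
    threshold = float(controls.mean() + controls.std(ddof=0))
    if raw <= threshold:
        return NIResult(0.0, raw, H, threshold, 0.0, False, xb.edges, notes)
    slope = float(np.average(slopes, weights=weights)) if slopes else 0.0
    sign = -1.0 if slope < 0 else 1.0
    return NIResult(sign * raw / H, raw, H, threshold, slope, True, xb.edges, notes)
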