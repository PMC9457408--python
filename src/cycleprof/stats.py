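"""Bimodality detection for per-bin intensity distributions.

The default detector is Hartigan's dip statistic: twice the dip is the
minimal sup-norm distance between the empirical CDF and the closest
unimodal CDF. The statistic is computed with the classical iterative
greatest-convex-minorant / least-concave-majorant construction; its null
distribution is calibrated by seeded Monte Carlo on the uniform law (the
asymptotically least-favourable unimodal null, as in standard dip-test
practice), using the n^(-1/2) scaling of the null dip to share one
reference simulation across sample sizes.

A two-component Gaussian-mixture BIC comparison is available as an
alternative detector.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError

__all__ = ["dip_statistic", "dip_test", "gmm_bic_bimodal", "is_bimodal"]


def _lower_hull(x: np.ndarray, idx: np.ndarray) -> list[int]:
    """Indices (subset of idx) of the greatest convex minorant of (x_i, i)."""
    hull: list[int] = []
    for i in idx:
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            if (x[b] - x[a]) * (i - a) - (b - a) * (x[i] - x[a]) <= 0:
                hull.pop()
            else:
                break
        hull.append(int(i))
    return hull


def _upper_hull(x: np.ndarray, idx: np.ndarray) -> list[int]:
    """Indices of the least concave majorant of (x_i, i)."""
    hull: list[int] = []
    for i in idx:
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            if (x[b] - x[a]) * (i - a) - (b - a) * (x[i] - x[a]) >= 0:
                hull.pop()
            else:
                break
        hull.append(int(i))
    return hull


def _interp_counts(xq: np.ndarray, x: np.ndarray, hull: list[int]) -> np.ndarray:
    return np.interp(xq, x[hull], np.asarray(hull, dtype=float))


def _ecdf_hull_deviation(x: np.ndarray, hull: list[int], lo: int, hi: int) -> float:
    """Max deviation (in counts) between the ECDF and the hull fit on [lo, hi]."""
    j = np.arange(lo, hi + 1)
    fit = _interp_counts(x[j], x, hull)
    return float(np.maximum(np.abs(fit - j), np.abs(fit - j - 1)).max())


def dip_statistic(values: np.ndarray) -> float:
    """Hartigan-style dip statistic of a 1D sample.

    Returns ~1/(2n) for perfectly unimodal (e.g. equally spaced) data and
    approaches 0.25 for two well-separated point masses.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 4 or x[0] == x[-1]:
        return 0.0
    low, high = 0, n - 1
    dip = 1.0 / (2.0 * n)
    for _ in range(100):
        idx = np.arange(low, high + 1)
        gcm = _lower_hull(x, idx)
        lcm = _upper_hull(x, idx)

        # largest gap between the two hull curves, and where it occurs
        gaps = []
        for v in gcm:
            gaps.append((_interp_counts(np.array([x[v]]), x, lcm)[0] - v, v, "g"))
        for v in lcm:
            gaps.append((v - _interp_counts(np.array([x[v]]), x, gcm)[0], v, "l"))
        d, v_star, side = max(gaps, key=lambda t: t[0])
        # the best unimodal fit splits any hull deviation in half
        d /= 2.0 * n
        if d <= dip:
            break
        if side == "g":
            ig = v_star
            ih = next((u for u in lcm if u >= v_star), high)
        else:
            ih = v_star
            ig = next((u for u in reversed(gcm) if u <= v_star), low)
        dip_l = _ecdf_hull_deviation(x, gcm, low, ig) / (2.0 * n)
        dip_u = _ecdf_hull_deviation(x, lcm, ih, high) / (2.0 * n)
        dip = max(dip, dip_l, dip_u)
        if ig <= low and ih >= high:
            break
        low, high = max(low, ig), min(high, ih)
        if high - low < 2:
            break
    return float(dip)


# Null-quantile cache: {(alpha, n_ref, n_boot, seed): sqrt(n_ref) * q_alpha}
_NULL_CACHE: dict[tuple, float] = {}


def _null_scaled_quantile(alpha: float, n_ref: int = 1024, n_boot: int = 499,
                          seed: int = 12345) -> float:
    key = (alpha, n_ref, n_boot, seed)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(seed)
        dips = np.array([dip_statistic(rng.uniform(size=n_ref))
                         for _ in range(n_boot)])
        _NULL_CACHE[key] = float(np.quantile(dips, 1.0 - alpha) * np.sqrt(n_ref))
    return _NULL_CACHE[key]


def dip_test(values: np.ndarray, alpha: float = 0.05,
             exact_boot: int | None = None, seed: int = 12345):
    """Test a sample for multimodality with the dip statistic.

    Returns ``(dip, critical_value, reject)``. By default the critical
    value is the uniform-null quantile simulated once at a reference size
    and rescaled by n^(-1/2); pass ``exact_boot`` to simulate the null at
    the sample's own size instead.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 4:
        raise ValidationError("dip test requires at least 4 observations")
    d = dip_statistic(values)
    if exact_boot:
        rng = np.random.default_rng(seed)
        dips = np.array([dip_statistic(rng.uniform(size=n))
                         for _ in range(exact_boot)])
        crit = float(np.quantile(dips, 1.0 - alpha))
    else:
        crit = _null_scaled_quantile(alpha) / np.sqrt(n)
    return d, crit, bool(d > crit)


def gmm_bic_bimodal(values: np.ndarray, min_weight: float = 0.1,
                    seed: int = 0) -> bool:
    """Two- vs one-component Gaussian-mixture BIC comparison.

    Bimodal iff the 2-component fit wins on BIC, both weights exceed
    ``min_weight`` and the components are separated (Ashman D > 2).
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(values, dtype=float).reshape(-1, 1)
    g1 = GaussianMixture(1, random_state=seed).fit(x)
    g2 = GaussianMixture(2, random_state=seed).fit(x)
    if g2.bic(x) >= g1.bic(x):
        return False
    w = g2.weights_
    if w.min() < min_weight:
        return False
    mu = g2.means_.ravel()
    var = g2.covariances_.ravel()
    ashman_d = abs(mu[0] - mu[1]) * np.sqrt(2.0 / (var[0] + var[1]))
    return bool(ashman_d > 2.0)


def is_bimodal(values: np.ndarray, method: str = "dip", alpha: float = 0.05,
               seed: int = 12345) -> bool:
    """Dispatch to the configured bimodality detector."""
    if method == "dip":
        return dip_test(values, alpha=alpha, seed=seed)[2]
    if method == "gmm":
        return gmm_bic_bimodal(values, seed=seed)
    raise ValidationError(f"unknown bimodality method {method!r}")
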