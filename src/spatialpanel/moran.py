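"""Global Moran's I and Moran-scatterplot quadrant classification.

The global statistic for observations x_1..x_n with weights w_ij is

    I = [sum_i sum_j w_ij (x_i - xbar)(x_j - xbar)] / [S^2 * sum_i sum_j w_ij]

with S^2 the 1/n-divisor sample variance.  Under the null of no spatial
association E[I] = -1/(n-1).  Inference is either the normal
approximation under the randomization assumption (the exact mean and
variance of I over the n! relabelings, with a kurtosis correction) or a
Monte-Carlo permutation test.

The quadrant classification standardizes the observations (population
standard deviation, matching S^2), takes the spatial lag of the
standardized values, and labels each region by the sign pair:
HH (both positive), LH (value low, lag high), LL (both non-positive),
HL (value high, lag low).  Exact zeros fall on the "low" side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .weights import SpatialWeights

__all__ = [
    "MoranResult",
    "QuadrantClassification",
    "DegenerateInputError",
    "spatial_lag",
    "global_morans_i",
    "moran_inference",
    "quadrant_classify",
    "moran_by_year",
]


class DegenerateInputError(ValueError):
    """Constant input vector: Moran's I is undefined when S^2 = 0."""


@dataclass
class MoranResult:
    statistic: float
    n: int
    sample_mean: float
    sample_variance: float
    expected_null: float
    variance_null: float | None = None
    z_score: float | None = None
    p_value: float | None = None
    inference_method: str | None = None


@dataclass
class QuadrantClassification:
    labels: dict[int, str]
    counts: dict[str, int]
    standardized_values: dict[int, float]
    spatial_lags: dict[int, float]


def _as_vector(x, n: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (n,):
        raise ValueError(f"expected a length-{n} vector, got shape {x.shape}")
    return x


def spatial_lag(W: SpatialWeights, x) -> np.ndarray:
    """Weighted average (or sum, for binary style) of neighbours' values."""
    x = _as_vector(x, W.n)
    return W.matrix @ x


def global_morans_i(x, W: SpatialWeights) -> MoranResult:
    """The global Moran's I statistic (no inference fields filled)."""
    x = _as_vector(x, W.n)
    n = W.n
    if n < 3:
        raise ValueError("Moran's I needs at least 3 regions")
    if np.any(W.matrix < 0):
        raise ValueError("negative spatial weights are not allowed")
    xbar = x.mean()
    z = x - xbar
    s2 = float(z @ z) / n
    if s2 <= 0:
        raise DegenerateInputError("constant vector: sample variance is zero")
    s0 = W.matrix.sum()
    num = float(z @ W.matrix @ z)
    stat = num / (s2 * s0)
    return MoranResult(
        statistic=stat,
        n=n,
        sample_mean=float(xbar),
        sample_variance=s2,
        expected_null=-1.0 / (n - 1),
    )


def _randomization_variance(z: np.ndarray, W: np.ndarray) -> float:
    # Exact variance of I over the n! permutations of the observations
    # (the "randomization assumption"), with the sample-kurtosis term.
    n = len(z)
    s0 = W.sum()
    s1 = 0.5 * ((W + W.T) ** 2).sum()
    s2 = ((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum()
    m2 = (z ** 2).sum() / n
    m4 = (z ** 4).sum() / n
    b2 = m4 / m2 ** 2
    a = n * ((n ** 2 - 3 * n + 3) * s1 - n * s2 + 3 * s0 ** 2)
    b = b2 * ((n ** 2 - n) * s1 - 2 * n * s2 + 6 * s0 ** 2)
    ei = -1.0 / (n - 1)
    return (a - b) / ((n - 1) * (n - 2) * (n - 3) * s0 ** 2) - ei ** 2


def moran_inference(
    x,
    W: SpatialWeights,
    method: str = "normal_randomization",
    n_permutations: int = 999,
    seed: int | None = None,
) -> MoranResult:
    """Moran's I with a null-hypothesis test.

    ``normal_randomization`` compares z = (I - E[I]) / sd_rand(I) against
    the standard normal, where the variance is the exact permutation
    variance of I (kurtosis-corrected).  ``permutation`` reports the
    two-sided pseudo p-value (#{|I_perm - E| >= |I_obs - E|} + 1) /
    (n_permutations + 1).
    """
    res = global_morans_i(x, W)
    x = _as_vector(x, W.n)
    z = x - x.mean()
    if method == "normal_randomization":
        if W.n < 4:
            raise ValueError("randomization variance needs n >= 4")
        var = _randomization_variance(z, W.matrix)
        if var <= 0:
            raise ArithmeticError("non-positive null variance")
        zscore = (res.statistic - res.expected_null) / np.sqrt(var)
        res.variance_null = float(var)
        res.z_score = float(zscore)
        res.p_value = float(2 * stats.norm.sf(abs(zscore)))
        res.inference_method = "normal_randomization"
    elif method == "permutation":
        if n_permutations < 99:
            raise ValueError("use at least 99 permutations")
        if seed is None:
            raise ValueError("permutation inference requires a seed")
        rng = np.random.default_rng(seed)
        s0 = W.matrix.sum()
        s2 = res.sample_variance
        obs_dev = abs(res.statistic - res.expected_null)
        count = 0
        for _ in range(n_permutations):
            zp = rng.permutation(z)
            ip = float(zp @ W.matrix @ zp) / (s2 * s0)
            if abs(ip - res.expected_null) >= obs_dev - 1e-14:
                count += 1
        res.p_value = (count + 1) / (n_permutations + 1)
        res.inference_method = "permutation"
    else:
        raise ValueError(f"unknown inference method {method!r}")
    return res


def quadrant_classify(x, W: SpatialWeights) -> QuadrantClassification:
    """Moran-scatterplot quadrant labels (HH / LH / LL / HL) per region."""
    if W.style != "row_standardized":
        raise ValueError("quadrant classification expects row-standardized weights")
    x = _as_vector(x, W.n)
    sd = x.std()  # population (1/n) standard deviation, matching S^2
    if sd <= 0:
        raise DegenerateInputError("constant vector")
    zs = (x - x.mean()) / sd
    lag = W.matrix @ zs
    labels: dict[int, str] = {}
    counts = {"HH": 0, "LH": 0, "LL": 0, "HL": 0}
    for k, region in enumerate(W.region_order):
        hi_val = zs[k] > 0
        hi_lag = lag[k] > 0
        lab = ("HH" if hi_lag else "HL") if hi_val else ("LH" if hi_lag else "LL")
        labels[region] = lab
        counts[lab] += 1
    return QuadrantClassification(
        labels=labels,
        counts=counts,
        standardized_values=dict(zip(W.region_order, zs.tolist())),
        spatial_lags=dict(zip(W.region_order, lag.tolist())),
    )


def moran_by_year(
    panel: pd.DataFrame,
    variable: str,
    W: SpatialWeights,
    method: str = "normal_randomization",
    n_permutations: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-year global Moran's I for one panel variable.

    ``panel`` is a balanced long-format table with ``region_id`` and
    ``year`` columns; rows within each year are aligned to the weight
    matrix's region order.  Returns one row per year with columns
    ``year``, ``moran_i``, ``z``, ``p``.
    """
    rows = []
    for t, (year, grp) in enumerate(panel.groupby("year", sort=True)):
        grp = grp.set_index("region_id").reindex(W.region_order)
        if grp[variable].isna().any():
            missing = grp.index[grp[variable].isna()].tolist()
            raise ValueError(f"unbalanced panel: year {year} missing regions {missing}")
        perm_seed = None if seed is None else seed + t
        res = moran_inference(
            grp[variable].to_numpy(), W, method=method,
            n_permutations=n_permutations, seed=perm_seed,
        )
        rows.append({"year": year, "moran_i": res.statistic,
                     "z": res.z_score, "p": res.p_value})
    return pd.DataFrame(rows)
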