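"""Robust univariate outlier detection: medcouple and adjusted boxplot fences.

The medcouple mc is a robust measure of skewness defined over all pairs
(x_i <= q2 <= x_j) of a sample as the median of the kernel

    h(x_i, x_j) = ((x_j - q2) - (q2 - x_i)) / (x_j - x_i),   x_i != x_j,

with a special sign kernel for observations tied at the median: for k ties,
h over the tied pairs enumerates sign(i + j - 1 - k) for i, j = 1..k.  mc is
0 for symmetric samples, positive for right-skewed and negative for
left-skewed ones, and always lies in [-1, 1].

The adjusted fences (after Dovoedo) asymmetrize the boxplot arms around the
median using mc:

    lower = q2 - 4 e^(-1.93 mc) (q2 - q1)
    upper = q2 + 4 e^( 2.18 mc) (q3 - q2)

For a normal sample the probability of falling outside the fences is about
0.007.  Quartiles use linear interpolation of the empirical CDF (the "type
7" convention of mainstream numeric stacks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OutlierFences",
    "medcouple",
    "adjusted_fences",
    "tukey_fences",
    "left_outliers",
]


@dataclass(frozen=True)
class OutlierFences:
    """Sample quartiles, medcouple and the resulting outlier fences."""

    q1: float
    q2: float
    q3: float
    mc: float
    lower: float
    upper: float

    def is_outlier(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x < self.lower) | (x > self.upper)


def medcouple(x) -> float:
    """Medcouple of a sample (O(n^2) definition).

    Requires at least 3 observations.  An all-tied sample has mc = 0 by
    convention.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 3:
        raise ValueError(f"medcouple needs a sample of size >= 3, got {n}")
    q2 = float(np.median(x))
    lower = x[x <= q2]
    upper = x[x >= q2]
    if lower[0] == upper[-1]:  # all values identical
        return 0.0
    zl = lower - q2  # <= 0
    zu = upper - q2  # >= 0
    # kernel over the (lower, upper) grid; both-at-median pairs fixed below
    denom = zu[None, :] - zl[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        h = (zu[None, :] + zl[:, None]) / denom
    ties = int(np.count_nonzero(x == q2))
    if ties:
        # replace the ties x ties block with the balanced sign multiset
        # sign(i + j - 1 - k), i, j = 1..k
        tie_rows = zl == 0.0
        tie_cols = zu == 0.0
        i = np.arange(1, ties + 1)
        block = np.sign(i[:, None] + i[None, :] - 1 - ties).astype(float)
        h[np.ix_(tie_rows, tie_cols)] = block
    return float(np.median(h))


def _quartiles(x: np.ndarray) -> tuple[float, float, float]:
    q1, q2, q3 = np.percentile(x, [25.0, 50.0, 75.0])
    return float(q1), float(q2), float(q3)


def adjusted_fences(x) -> OutlierFences:
    """Medcouple-adjusted boxplot fences centered on the median.

    Degenerate samples (q1 == q3) collapse both fences to q2, so every
    off-median point is an outlier; a warning is emitted in that case.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError(f"adjusted fences need a sample of size >= 4, got {x.size}")
    q1, q2, q3 = _quartiles(x)
    mc = medcouple(x)
    lower = q2 - 4.0 * np.exp(-1.93 * mc) * (q2 - q1)
    upper = q2 + 4.0 * np.exp(2.18 * mc) * (q3 - q2)
    if q1 == q3 and not np.all(x == q2):
        import warnings

        warnings.warn(
            "degenerate sample (q1 == q3): fences collapse to the median", stacklevel=2
        )
    return OutlierFences(q1=q1, q2=q2, q3=q3, mc=mc, lower=float(lower), upper=float(upper))


def tukey_fences(x) -> OutlierFences:
    """Classic Tukey boxplot fences [q1 - 1.5 IQR, q3 + 1.5 IQR]."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError(f"Tukey fences need a sample of size >= 4, got {x.size}")
    q1, q2, q3 = _quartiles(x)
    iqr = q3 - q1
    return OutlierFences(
        q1=q1,
        q2=q2,
        q3=q3,
        mc=0.0,
        lower=q1 - 1.5 * iqr,
        upper=q3 + 1.5 * iqr,
    )


def left_outliers(x) -> np.ndarray:
    """Values strictly below the adjusted lower fence of the sample."""
    x = np.asarray(x, dtype=float)
    fences = adjusted_fences(x)
    return x[x < fences.lower]
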