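"""Moran's I spatial autocorrelation for per-lake values.

Uses the raw binary MST-threshold connectivity as the weight matrix
(no row standardization). Under the null of no spatial structure
E[I] = −1/(n−1); the variance is the classical normality-assumption
variance, and the test is two-sided normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spatial import ConnectivityMatrix

__all__ = ["MoranResult", "morans_i"]


@dataclass
class MoranResult:
    species: str
    observed: float
    expected: float
    sd: float
    p_value: float
    n: int


def morans_i(x: np.ndarray, w: ConnectivityMatrix | np.ndarray, species: str = "",
             row_standardize: bool = False) -> MoranResult:
    """Moran's I with expectation, normality variance, two-sided p.

    I = (n/S0) Σ_ij w_ij (x_i−x̄)(x_j−x̄) / Σ_i (x_i−x̄)²  with
    S0 = Σ w_ij. Var under normality uses S1 = ½Σ(w_ij+w_ji)² and
    S2 = Σ_i (w_i· + w_·i)². Weights are used as given (raw binary) by
    default; ``row_standardize=True`` divides each row by its sum
    first, the convention of some implementations. Constant ``x`` or
    an all-zero weight matrix is rejected (the statistic is undefined).
    """
    wm = w.w if isinstance(w, ConnectivityMatrix) else np.asarray(w, dtype=float)
    if row_standardize:
        rs = wm.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        wm = wm / rs
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least three observations")
    if wm.shape != (n, n):
        raise ValueError("weight matrix shape mismatch")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("constant input: Moran's I undefined")
    s0 = float(wm.sum())
    if s0 == 0:
        raise ValueError("zero-weight matrix")
    num = float(z @ wm @ z)
    obs = (n / s0) * num / denom
    expected = -1.0 / (n - 1)
    s1 = 0.5 * float(((wm + wm.T) ** 2).sum())
    s2 = float(((wm.sum(axis=1) + wm.sum(axis=0)) ** 2).sum())
    var = (n * n * s1 - n * s2 + 3 * s0 * s0) / (s0 * s0 * (n * n - 1)) - expected**2
    sd = float(np.sqrt(max(var, 0.0)))
    if sd == 0.0:  # degenerate weights (e.g. complete graph): I is forced
        p = float("nan")
    else:
        zscore = (obs - expected) / sd
        p = float(2 * stats.norm.sf(abs(zscore)))
    return MoranResult(species=species, observed=float(obs), expected=expected, sd=sd, p_value=p, n=n)
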