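"""Small shared statistical helpers.

Kept dependency-light: the episode-level analyses call :func:`ols` inside
permutation/bootstrap loops where statsmodels' model-building overhead is
noticeable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class EffectEstimate:
    """A single regression (or correlation) coefficient with inference.

    ``p_value`` is always two-sided unless the producing routine says
    otherwise.
    """

    term: str
    beta: float
    se: float
    p_value: float
    model: str = ""
    n: int = 0


def ols(X: np.ndarray, y: np.ndarray, names: list[str], model: str = "ols") -> dict[str, EffectEstimate]:
    """Ordinary least squares with conventional t-based inference.

    Parameters
    ----------
    X : (n, k) design matrix (include the intercept column yourself).
    y : (n,) response.
    names : labels for the columns of ``X``; estimates are keyed by these.

    Returns one :class:`EffectEstimate` per named column. Degrees of freedom
    use the numerical rank of ``X`` so redundant dummy columns do not distort
    the standard errors.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if len(names) != k:
        raise ValueError(f"{k} columns but {len(names)} names")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - rank
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    out: dict[str, EffectEstimate] = {}
    for j, name in enumerate(names):
        if se[j] > 0:
            t = beta[j] / se[j]
            p = 2.0 * stats.t.sf(abs(t), dof)
        else:
            p = float("nan")
        out[name] = EffectEstimate(term=name, beta=float(beta[j]), se=float(se[j]),
                                   p_value=float(p), model=model, n=n)
    return out


def sd_outlier_mask(values: np.ndarray, threshold_sd: float = 3.0) -> np.ndarray:
    """Flag entries more than ``threshold_sd`` SDs from their column mean.

    ``values`` is (observations, variables); NaNs are ignored when computing
    the column mean/SD and are never flagged. A constant column (SD 0) flags
    nothing. Single pass: the mean/SD are computed once, on all values.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
        squeeze = True
    else:
        squeeze = False
    mean = np.nanmean(values, axis=0)
    sd = np.nanstd(values, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs(values - mean) / sd
    mask = np.where(np.isfinite(z), z > threshold_sd, False)
    return mask[:, 0] if squeeze else mask


def safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r that returns 0.0 when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])
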