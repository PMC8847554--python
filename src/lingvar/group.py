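"""Between-subject analyses: severity scores, feature associations, pools.

These operations relate 12-month feature summaries and network centralities
to a cross-sectional severity score. All association tests are two-sided
and uncorrected by design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import EffectEstimate, ols, sd_outlier_mask

log = logging.getLogger(__name__)


def combine_severity(scores: pd.DataFrame) -> pd.Series:
    """Pool severity scores from several scales onto one z-scale.

    ``scores`` has columns user_id, scale, score. Each scale is standardised
    by its own mean and SD, then the scales are concatenated into a single
    severity column. A scale with a single user has no SD and is an error.
    """
    required = {"user_id", "scale", "score"}
    if not required.issubset(scores.columns):
        raise ValueError(f"scores must have columns {sorted(required)}")
    if scores["user_id"].duplicated().any():
        raise ValueError("each user may contribute one score")
    pieces = []
    for scale, grp in scores.groupby("scale"):
        if len(grp) < 2:
            raise ValueError(f"scale {scale!r} has fewer than 2 users")
        z = (grp["score"] - grp["score"].mean()) / grp["score"].std(ddof=1)
        pieces.append(pd.Series(z.to_numpy(), index=grp["user_id"].to_numpy()))
    return pd.concat(pieces).rename("severity_z").rename_axis("user_id")


def mean_feature_outliers(feature_means: pd.DataFrame, threshold_sd: float = 3.0) -> pd.DataFrame:
    """Flag per-user 12-month feature means > 3 SD from the group mean.

    Returns a boolean DataFrame (True = excluded) aligned with the input
    (users x features).
    """
    mask = sd_outlier_mask(feature_means.to_numpy(dtype=float), threshold_sd)
    return pd.DataFrame(mask, index=feature_means.index, columns=feature_means.columns)


def feature_severity_association(feature_means: pd.DataFrame, severity: pd.Series,
                                 mask: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-feature association with severity: Pearson r and standardised beta.

    The regression is severity ~ z(feature mean), so with both sides
    standardised beta equals r; both are reported with two-sided,
    uncorrected p-values. Masked entries are excluded pairwise. Constant
    features get NaN estimates and a warning.
    """
    severity = severity.loc[feature_means.index]
    rows = []
    for feat in feature_means.columns:
        x = feature_means[feat].to_numpy(dtype=float)
        y = severity.to_numpy(dtype=float)
        keep = np.isfinite(x) & np.isfinite(y)
        if mask is not None:
            keep &= ~mask[feat].to_numpy()
        x, y = x[keep], y[keep]
        if len(x) < 3 or np.std(x) == 0:
            log.warning("feature %s is constant/degenerate; no association computed", feat)
            rows.append({"feature": feat, "n": len(x), "r": np.nan, "r_p": np.nan,
                         "beta": np.nan, "se": np.nan, "p": np.nan})
            continue
        r, r_p = stats.pearsonr(x, y)
        xz = (x - x.mean()) / x.std(ddof=1)
        X = np.column_stack([np.ones_like(xz), xz])
        est = ols(X, y, ["intercept", feat], model="severity~feature")[feat]
        rows.append({"feature": feat, "n": len(x), "r": float(r), "r_p": float(r_p),
                     "beta": est.beta, "se": est.se, "p": est.p_value})
    return pd.DataFrame(rows).set_index("feature")


def severity_strength_regression(strengths: pd.DataFrame, severity: pd.Series,
                                 covariates: str = "none",
                                 mask: pd.DataFrame | None = None) -> dict[str, EffectEstimate]:
    """Regress each strength column on severity (optionally + day count).

    ``strengths`` has one row per user; a ``global`` column plus per-node
    columns, and an ``n_days`` column when ``covariates='n_days'``. Returns
    the severity EffectEstimate per outcome column.
    """
    if covariates not in ("none", "n_days"):
        raise ValueError(f"unknown covariates {covariates!r}")
    sev = severity.loc[strengths.index].to_numpy(dtype=float)
    if np.std(sev) == 0:
        raise ValueError("severity is constant; coefficient undefined")
    out: dict[str, EffectEstimate] = {}
    outcome_cols = [c for c in strengths.columns if c != "n_days"]
    for col in outcome_cols:
        y = strengths[col].to_numpy(dtype=float)
        keep = np.isfinite(y)
        if mask is not None and col in mask.columns:
            keep &= ~mask[col].to_numpy()
        cols = [np.ones(keep.sum()), sev[keep]]
        names = ["intercept", "severity"]
        if covariates == "n_days":
            cols.append(strengths["n_days"].to_numpy(dtype=float)[keep])
            names.append("n_days")
        est = ols(np.column_stack(cols), y[keep], names,
                  model=f"{col}~severity" + ("+n_days" if covariates == "n_days" else ""))
        out[col] = est["severity"]
    return out


@dataclass
class SplitHalfResult:
    r: float
    p: float
    n_edges: int
    r_excluding_strongest: float
    p_excluding_strongest: float


def split_half_edge_reliability(networks: list[np.ndarray], seed: int = 0) -> SplitHalfResult:
    """Split users in two random halves; correlate the halves' mean edges.

    The correlation runs over the p(p-1)/2 unique off-diagonal entries of
    the two half-sample mean networks, and once more with the strongest
    full-sample edge removed.
    """
    if len(networks) < 4:
        raise ValueError("need at least 4 users for a split-half check")
    arr = np.stack([np.asarray(o, dtype=float) for o in networks])
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(arr))
    half = len(arr) // 2
    m1 = arr[order[:half]].mean(axis=0)
    m2 = arr[order[half: 2 * half]].mean(axis=0)
    iu = np.triu_indices(arr.shape[1], k=1)
    e1, e2 = m1[iu], m2[iu]
    r, p = stats.pearsonr(e1, e2)
    strongest = int(np.argmax(np.abs(arr.mean(axis=0)[iu])))
    keep = np.arange(len(e1)) != strongest
    r2, p2 = stats.pearsonr(e1[keep], e2[keep])
    return SplitHalfResult(r=float(r), p=float(p), n_edges=len(e1),
                           r_excluding_strongest=float(r2), p_excluding_strongest=float(p2))


@dataclass
class FeaturePools:
    """Depression-relevant vs irrelevant feature pools at threshold alpha."""

    table: pd.DataFrame  # index feature; columns r, p, pool
    alpha: float = 0.05

    @property
    def relevant(self) -> list[str]:
        return list(self.table.index[self.table["pool"] == "relevant"])

    @property
    def irrelevant(self) -> list[str]:
        return list(self.table.index[self.table["pool"] == "irrelevant"])


def build_feature_pools(feature_means: pd.DataFrame, severity: pd.Series,
                        alpha: float = 0.05, mask: pd.DataFrame | None = None) -> FeaturePools:
    """Partition features by bivariate severity association at p < alpha.

    Constant or degenerate features are forced into the irrelevant pool
    with a warning (their p is NaN).
    """
    assoc = feature_severity_association(feature_means, severity, mask=mask)
    pool = np.where(np.nan_to_num(assoc["r_p"].to_numpy(), nan=1.0) < alpha,
                    "relevant", "irrelevant")
    table = assoc[["r", "r_p"]].rename(columns={"r_p": "p"}).assign(pool=pool)
    return FeaturePools(table=table, alpha=alpha)
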