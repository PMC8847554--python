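"""Within-subject episode contrasts on personalised networks.

Each eligible user (>= 15 observed days both within and outside an episode)
contributes two fitted networks. The episode effect is the coefficient on a
within-episode indicator in a linear model with per-user fixed intercepts
on the two-rows-per-user stacked table; with no covariates that coefficient
is exactly the mean paired difference.

Because networks fit on fewer days have systematically inflated strength
estimates, naive contrasts are confounded by the within/outside day-count
imbalance. :func:`permutation_null` reproduces and controls for that bias
by re-estimating both networks under label shuffles that preserve each
user's day counts exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import EffectEstimate, ols
from .centrality import global_strength, node_strength
from .episodes import check_eligibility
from .gvar import FitConfig, GvarFit, estimate_network

log = logging.getLogger(__name__)


@dataclass
class PairedNetworks:
    user_id: str
    within_fit: GvarFit
    outside_fit: GvarFit
    n_days_within: int
    n_days_outside: int

    def __post_init__(self) -> None:
        if self.within_fit.node_names != self.outside_fit.node_names:
            raise ValueError("within/outside fits have different node sets")


def fit_paired_networks(matrix, labels: np.ndarray, config: FitConfig = FitConfig(),
                        nodes: list[str] | None = None, min_days: int = 15) -> PairedNetworks:
    """Fit separate within- and outside-episode networks for one user.

    Lag pairs are built inside each day subset, so a within-day is never
    regressed on an outside-day (or vice versa).
    """
    labels = np.asarray(labels, dtype=bool)
    elig = check_eligibility(matrix, labels, mode="paired", min_days_paired=min_days)
    if not elig.eligible:
        raise ValueError(
            f"user {matrix.user_id} ineligible: {elig.n_within} within / {elig.n_outside} outside days")
    within_fit = estimate_network(matrix.select_days(labels), nodes=nodes, config=config)
    outside_fit = estimate_network(matrix.select_days(~labels), nodes=nodes, config=config)
    return PairedNetworks(user_id=matrix.user_id, within_fit=within_fit,
                          outside_fit=outside_fit,
                          n_days_within=elig.n_within, n_days_outside=elig.n_outside)


def stack_paired_table(pairs: list[PairedNetworks]) -> pd.DataFrame:
    """Two rows per user: period (1=within), strengths, day counts."""
    rows = []
    for pn in pairs:
        for fit, period, nd in ((pn.within_fit, 1, pn.n_days_within),
                                (pn.outside_fit, 0, pn.n_days_outside)):
            s = node_strength(fit.pcc)
            row = {"user_id": pn.user_id, "period": period,
                   "global_strength": global_strength(s), "n_days": nd}
            row.update({name: s[i] for i, name in enumerate(fit.node_names)})
            rows.append(row)
    return pd.DataFrame(rows)


def episode_effect(table: pd.DataFrame, outcome: str = "global_strength",
                   covariates: str = "none") -> EffectEstimate:
    """Episode coefficient from the stacked two-rows-per-user table.

    ``covariates`` is one of ``none``, ``n_days``, ``n_days_plus_interaction``.
    Per-user fixed intercepts make the contrast exactly paired; with
    ``none`` the coefficient equals the mean within-minus-outside
    difference.
    """
    if covariates not in ("none", "n_days", "n_days_plus_interaction"):
        raise ValueError(f"unknown covariates {covariates!r}")
    users = table["user_id"].to_numpy()
    uniq, inv = np.unique(users, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 users with pairs")
    y = table[outcome].to_numpy(dtype=float)
    episode = table["period"].to_numpy(dtype=float)
    dummies = np.eye(len(uniq))[inv]
    cols = [episode[:, None], dummies]
    names = ["episode"] + [f"u:{u}" for u in uniq]
    if covariates in ("n_days", "n_days_plus_interaction"):
        n_days = table["n_days"].to_numpy(dtype=float)
        cols.insert(1, n_days[:, None])
        names.insert(1, "n_days")
    if covariates == "n_days_plus_interaction":
        cols.insert(2, (episode * table["n_days"].to_numpy(dtype=float))[:, None])
        names.insert(2, "episode:n_days")
    X = np.hstack(cols)
    return ols(X, y, names, model=f"{outcome}~episode({covariates})+user")["episode"]


def episode_interaction(table: pd.DataFrame, outcome: str = "global_strength") -> EffectEstimate:
    """Coefficient of the episode x day-count interaction."""
    users = table["user_id"].to_numpy()
    uniq, inv = np.unique(users, return_inverse=True)
    y = table[outcome].to_numpy(dtype=float)
    episode = table["period"].to_numpy(dtype=float)
    n_days = table["n_days"].to_numpy(dtype=float)
    X = np.hstack([episode[:, None], n_days[:, None], (episode * n_days)[:, None],
                   np.eye(len(uniq))[inv]])
    names = ["episode", "n_days", "episode:n_days"] + [f"u:{u}" for u in uniq]
    return ols(X, y, names, model=f"{outcome}~episode*n_days+user")["episode:n_days"]


def wilcoxon_paired(within: np.ndarray, outside: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired global strengths.

    Returns (V, p) with V the sum of positive-difference ranks (zero
    differences dropped first). All-zero differences give (0, 1) with a
    warning.
    """
    d = np.asarray(within, dtype=float) - np.asarray(outside, dtype=float)
    nz = d[d != 0]
    if nz.size == 0:
        log.warning("all paired differences are zero; signed-rank test degenerate")
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(nz))
    v = float(ranks[nz > 0].sum())
    res = stats.wilcoxon(nz, alternative="two-sided")
    return v, float(res.pvalue)


@dataclass
class BootstrapResult:
    betas: np.ndarray
    mean: float
    se: float
    p_one_sided: float  # exceedance of 0 by the subsample distribution
    fraction: float
    n_boot: int


def bootstrap_effect(table: pd.DataFrame, fraction: float = 0.8, n_boot: int = 1000,
                     seed: int = 0, outcome: str = "global_strength",
                     covariates: str = "none") -> BootstrapResult:
    """Subsample ceil(fraction * n) users without replacement, n_boot times.

    The episode coefficient is recomputed on each user subsample from the
    precomputed strength table; the summary reports the distribution's
    mean, SD, and the one-sided exceedance of zero (1 + #{beta <= 0}) /
    (n_boot + 1).
    """
    uniq = table["user_id"].unique()
    if len(uniq) < 5:
        raise ValueError("need at least 5 users to subsample")
    rng = np.random.default_rng(seed)
    m = int(np.ceil(fraction * len(uniq)))
    betas = np.empty(n_boot)
    for b in range(n_boot):
        chosen = rng.choice(uniq, size=m, replace=False)
        sub = table[table["user_id"].isin(chosen)]
        betas[b] = episode_effect(sub, outcome=outcome, covariates=covariates).beta
    p = (1.0 + float(np.sum(betas <= 0))) / (n_boot + 1.0)
    return BootstrapResult(betas=betas, mean=float(betas.mean()),
                           se=float(betas.std(ddof=1)), p_one_sided=p,
                           fraction=fraction, n_boot=n_boot)


@dataclass
class PermutationResult:
    observed_beta: float
    null_betas: np.ndarray = field(repr=False)
    null_mean: float = float("nan")
    null_se: float = float("nan")
    empirical_p: float = float("nan")

    def __post_init__(self) -> None:
        self.null_betas = np.asarray(self.null_betas, dtype=float)
        B = len(self.null_betas)
        if B:
            self.null_mean = float(self.null_betas.mean())
            self.null_se = float(self.null_betas.std(ddof=1)) if B > 1 else float("nan")
            self.empirical_p = (1.0 + float(np.sum(self.null_betas >= self.observed_beta))) / (B + 1.0)


def permutation_null(users: list[tuple], config: FitConfig = FitConfig(),
                     n_perm: int = 200, seed: int = 0, covariates: str = "none",
                     min_days: int = 15, max_retries: int = 5) -> PermutationResult:
    """Day-label permutation null for the episode effect.

    ``users`` is a list of (DailyFeatureMatrix, within-labels). Per
    permutation and per user, a uniformly random subset of the user's
    observed days — of exactly the user's true within-day count — is
    relabelled fake-within and both networks are re-estimated, which is
    what exposes the day-count bias: fake-within periods are as short as
    real ones, so the null mean coefficient is itself shifted. Failing
    draws (degenerate subsets) are redrawn with a log entry.
    """
    observed_pairs = [fit_paired_networks(m, lab, config=config, min_days=min_days)
                      for m, lab in users]
    observed = episode_effect(stack_paired_table(observed_pairs), covariates=covariates).beta

    rng = np.random.default_rng(seed)
    null_betas = np.empty(n_perm)
    for b in range(n_perm):
        pairs = []
        for matrix, labels in users:
            labels = np.asarray(labels, dtype=bool)
            n, k = len(labels), int(labels.sum())
            pn = None
            for attempt in range(max_retries):
                fake = np.zeros(n, dtype=bool)
                fake[rng.choice(n, size=k, replace=False)] = True
                try:
                    pn = fit_paired_networks(matrix, fake, config=config, min_days=min_days)
                    break
                except (ValueError, np.linalg.LinAlgError) as exc:
                    log.debug("permutation draw failed for %s (try %d): %s",
                              matrix.user_id, attempt + 1, exc)
            if pn is None:
                raise RuntimeError(f"could not draw a valid permutation for {matrix.user_id}")
            pairs.append(pn)
        null_betas[b] = episode_effect(stack_paired_table(pairs), covariates=covariates).beta
    return PermutationResult(observed_beta=float(observed), null_betas=null_betas)
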