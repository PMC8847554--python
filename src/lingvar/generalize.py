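"""Random-network generalisation: does the episode effect extend beyond the
a priori node set?

Sets of 9 features are sampled from a severity-relevant and a
severity-irrelevant pool; the full paired episode analysis (with a
day-count covariate) runs per set, and a linear model on the per-set
coefficients compares the pools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import EffectEstimate, ols
from .episode_effects import episode_effect, fit_paired_networks, stack_paired_table
from .gvar import FitConfig

log = logging.getLogger(__name__)


def sample_feature_sets(pool: list[str], k: int = 9, n_sets: int = 1000,
                        seed: int = 0) -> list[tuple[str, ...]]:
    """Sample ``n_sets`` sets of ``k`` distinct features from a pool.

    Features are distinct within a set; sets may repeat across draws.
    """
    if len(pool) < k:
        raise ValueError(f"pool has {len(pool)} features; need at least {k}")
    rng = np.random.default_rng(seed)
    pool = list(pool)
    return [tuple(rng.choice(pool, size=k, replace=False)) for _ in range(n_sets)]


@dataclass
class NetworkSampleResult:
    set_id: str
    features: tuple[str, ...]
    pool: str
    effect: EffectEstimate


def episode_effect_per_set(sets: list[tuple[str, ...]], users: list[tuple],
                           pool_label: str, config: FitConfig = FitConfig(),
                           covariates: str = "n_days",
                           min_days: int = 15) -> list[NetworkSampleResult]:
    """Run the paired episode analysis once per sampled feature set.

    ``users`` is a list of (DailyFeatureMatrix, within-labels) for the
    paired-eligible sample. Per-set failures are logged and excluded.
    """
    results: list[NetworkSampleResult] = []
    for s, feats in enumerate(sets):
        set_id = f"{pool_label}-{s:04d}"
        try:
            pairs = [fit_paired_networks(m, lab, config=config, nodes=list(feats),
                                         min_days=min_days)
                     for m, lab in users]
            est = episode_effect(stack_paired_table(pairs), covariates=covariates)
        except (ValueError, np.linalg.LinAlgError) as exc:
            log.warning("set %s excluded: %s", set_id, exc)
            continue
        results.append(NetworkSampleResult(set_id=set_id, features=feats,
                                           pool=pool_label, effect=est))
    return results


def compare_pools(results: list[NetworkSampleResult]) -> EffectEstimate:
    """Linear model of per-set episode coefficients on a pool indicator.

    The coefficient is the relevant-minus-irrelevant difference in mean
    episode effect across the sampled networks.
    """
    pools = {r.pool for r in results}
    if len(pools) < 2:
        raise ValueError(f"need both pools represented; got {sorted(pools)}")
    betas = np.array([r.effect.beta for r in results])
    indicator = np.array([1.0 if r.pool == "relevant" else 0.0 for r in results])
    X = np.column_stack([np.ones_like(betas), indicator])
    return ols(X, betas, ["intercept", "pool"], model="set_beta~pool")["pool"]


def top_network_report(results: list[NetworkSampleResult], top_n: int = 100,
                       pool: str = "relevant") -> dict:
    """Rank sets by episode coefficient; report inclusion frequencies.

    Returns the ranked top sets and, for each feature, the fraction of the
    top ``top_n`` sets containing it.
    """
    pool_results = [r for r in results if r.pool == pool]
    if len(pool_results) < top_n:
        raise ValueError(f"only {len(pool_results)} {pool}-pool results; need {top_n}")
    ranked = sorted(pool_results, key=lambda r: r.effect.beta, reverse=True)[:top_n]
    counts: dict[str, int] = {}
    for r in ranked:
        for f in r.features:
            counts[f] = counts.get(f, 0) + 1
    freq = {f: c / top_n for f, c in sorted(counts.items(), key=lambda kv: -kv[1])}
    return {
        "top_sets": [{"set_id": r.set_id, "features": list(r.features),
                      "beta": r.effect.beta, "p": r.effect.p_value} for r in ranked],
        "inclusion_frequency": freq,
    }


def results_to_frame(results: list[NetworkSampleResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"set_id": r.set_id, "pool": r.pool, "features": "|".join(r.features),
         "beta": r.effect.beta, "se": r.effect.se, "p": r.effect.p_value}
        for r in results
    ])
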