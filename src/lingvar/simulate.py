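"""Synthetic cohorts with known latent network dynamics.

Each user's daily feature series follows a lag-1 VAR whose innovation
precision switches between an "outside" matrix and a within-episode version
with off-diagonals scaled by a connectivity multiplier. Episode schedules,
missing days, severity scores tied to connectivity and feature means, and
(optionally) raw token streams are all generated from one seed, so every
downstream stage of the pipeline can be tested against ground truth.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centrality import global_strength, node_strength
from .episodes import EpisodeCalendar, recode_episodes
from .gvar import pcc_from_precision
from .text import CategoryDictionary, DailyFeatureMatrix

log = logging.getLogger(__name__)

#: calendar anchor for day index 1
DEFAULT_START_DATE = dt.date(2020, 1, 6)


def _check_stationary(B: np.ndarray) -> None:
    rho = float(np.max(np.abs(np.linalg.eigvals(B))))
    if rho >= 1.0:
        raise ValueError(f"temporal matrix is non-stationary: spectral radius {rho:.3f} >= 1")


def _check_pd(K: np.ndarray, name: str) -> None:
    K = np.asarray(K, dtype=float)
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if float(np.min(np.linalg.eigvalsh(K))) <= 0:
        raise ValueError(f"{name} must be positive definite")


def scale_precision(K: np.ndarray, multiplier: float) -> np.ndarray:
    """Scale the off-diagonals of a precision matrix by ``multiplier``."""
    K2 = np.array(K, dtype=float, copy=True)
    off = ~np.eye(K2.shape[0], dtype=bool)
    K2[off] *= multiplier
    return K2


@dataclass
class GeneratorConfig:
    """Everything needed to draw a reproducible synthetic cohort."""

    n_users: int
    temporal_matrix: np.ndarray
    precision_outside: np.ndarray
    n_days: int = 365
    connectivity_multiplier: float = 1.0
    episode_rate: float = 1.56
    episode_duration_mean_days: float = 104.0
    episode_duration_sd_days: float = 97.0
    missing_day_prob: float = 0.0
    severity_noise_sd: float = 0.5
    severity_feature_slopes: np.ndarray | None = None
    severity_connectivity_slope: float = 1.0
    latent_center: float = 0.0
    latent_scale: float = 1.0
    tokens_per_day: int = 0
    burn_in: int = 200
    start_date: dt.date = DEFAULT_START_DATE
    seed: int = 0

    def __post_init__(self) -> None:
        self.temporal_matrix = np.asarray(self.temporal_matrix, dtype=float)
        self.precision_outside = np.asarray(self.precision_outside, dtype=float)
        _check_stationary(self.temporal_matrix)
        _check_pd(self.precision_outside, "precision_outside")
        if self.connectivity_multiplier < 0:
            raise ValueError("connectivity_multiplier must be >= 0")
        _check_pd(scale_precision(self.precision_outside, self.connectivity_multiplier),
                  "within-episode precision")
        if not (0 <= self.missing_day_prob < 1):
            raise ValueError("missing_day_prob must lie in [0, 1)")
        if self.severity_feature_slopes is None:
            self.severity_feature_slopes = np.zeros(self.n_features)
        self.severity_feature_slopes = np.asarray(self.severity_feature_slopes, dtype=float)
        if self.severity_feature_slopes.shape != (self.n_features,):
            raise ValueError("severity_feature_slopes must have one entry per feature")

    @property
    def n_features(self) -> int:
        return self.temporal_matrix.shape[0]

    @property
    def precision_within(self) -> np.ndarray:
        return scale_precision(self.precision_outside, self.connectivity_multiplier)


def default_temporal_matrix(p: int, diag: float = 0.3) -> np.ndarray:
    """A simple stationary temporal matrix: autoregression on the diagonal."""
    return diag * np.eye(p)


def chain_precision(p: int, omega: float = 0.3) -> np.ndarray:
    """Unit-diagonal precision whose chain edges have partial correlation ``omega``."""
    K = np.eye(p)
    for i in range(p - 1):
        K[i, i + 1] = K[i + 1, i] = -omega
    _check_pd(K, "chain precision")
    return K


def dense_precision(p: int, omega: float = 0.2) -> np.ndarray:
    """Unit-diagonal precision with all pairwise partial correlations ``omega``."""
    K = np.full((p, p), -omega)
    np.fill_diagonal(K, 1.0)
    _check_pd(K, "dense precision")
    return K


def simulate_gvar_series(temporal_matrix: np.ndarray, precision: np.ndarray,
                         n_days: int, burn_in: int = 200,
                         seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw a stationary series y_t = B y_{t-1} + eps_t, eps ~ N(0, K^{-1}).

    The first ``burn_in`` samples are discarded so the returned draw is
    effectively from the stationary distribution.
    """
    B = np.asarray(temporal_matrix, dtype=float)
    _check_stationary(B)
    _check_pd(precision, "precision")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = B.shape[0]
    innov_chol = np.linalg.cholesky(np.linalg.inv(precision))
    eps = rng.standard_normal((burn_in + n_days, p)) @ innov_chol.T
    y = np.zeros(p)
    out = np.empty((burn_in + n_days, p))
    for t in range(burn_in + n_days):
        y = B @ y + eps[t]
        out[t] = y
    return out[burn_in:]


def _switching_series(B: np.ndarray, K_out: np.ndarray, K_in: np.ndarray,
                      within: np.ndarray, burn_in: int, rng: np.random.Generator) -> np.ndarray:
    p = B.shape[0]
    chol_out = np.linalg.cholesky(np.linalg.inv(K_out))
    chol_in = np.linalg.cholesky(np.linalg.inv(K_in))
    n = len(within)
    out = np.empty((n, p))
    y = np.zeros(p)
    for _ in range(burn_in):
        y = B @ y + chol_out @ rng.standard_normal(p)
    for t in range(n):
        chol = chol_in if within[t] else chol_out
        y = B @ y + chol @ rng.standard_normal(p)
        out[t] = y
    return out


def latent_to_percentage(latent: np.ndarray, center: float = 0.0, scale: float = 1.0) -> np.ndarray:
    """Logistic map of latent values onto the (0, 100) percentage scale."""
    return 100.0 / (1.0 + np.exp(-(latent - center) / scale))


def _draw_schedule(cfg: GeneratorConfig, rng: np.random.Generator, user_id: str) -> EpisodeCalendar:
    n_ep = int(rng.poisson(cfg.episode_rate))
    mean, sd = cfg.episode_duration_mean_days, cfg.episode_duration_sd_days
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    raw = []
    for _ in range(n_ep):
        dur = max(1, int(round(float(rng.lognormal(mu, np.sqrt(sigma2))))))
        start = int(rng.integers(1, cfg.n_days + 1))
        end = start + dur - 1
        if end > cfg.n_days:
            log.debug("user %s: episode truncated at day %d", user_id, cfg.n_days)
            end = cfg.n_days
        d0 = cfg.start_date + dt.timedelta(days=start - 1)
        d1 = cfg.start_date + dt.timedelta(days=end - 1)
        raw.append((d0, d1))
    return recode_episodes(raw, user_id=user_id)


@dataclass
class SyntheticUser:
    user_id: str
    latent: np.ndarray
    matrix: DailyFeatureMatrix
    calendar: EpisodeCalendar
    within_mask_full: np.ndarray  # over all n_days, before missingness
    severity: float = float("nan")
    documents: list[tuple[dt.date, str]] = field(default_factory=list)


@dataclass
class SyntheticCohort:
    users: list[SyntheticUser]
    config: GeneratorConfig
    omega_outside: np.ndarray
    omega_within: np.ndarray
    connectivity_truth: np.ndarray  # per-user mean daily true global strength

    @property
    def severity(self) -> pd.Series:
        return pd.Series({u.user_id: u.severity for u in self.users}, name="severity_z")


def simulate_cohort(config: GeneratorConfig,
                    dictionary: CategoryDictionary | None = None) -> SyntheticCohort:
    """Generate a full cohort; all randomness derives from ``config.seed``."""
    p = config.n_features
    if dictionary is not None and dictionary.n_categories != p:
        raise ValueError(f"dictionary has {dictionary.n_categories} categories "
                         f"but the generator has {p} features")
    seq = np.random.SeedSequence(config.seed)
    user_seeds = seq.spawn(config.n_users + 1)
    master = np.random.default_rng(user_seeds[-1])

    omega_out = pcc_from_precision(config.precision_outside)
    omega_in = pcc_from_precision(config.precision_within)
    g_out = global_strength(node_strength(omega_out))
    g_in = global_strength(node_strength(omega_in))

    users: list[SyntheticUser] = []
    conn = np.empty(config.n_users)
    feat_means = np.empty((config.n_users, p))
    for u in range(config.n_users):
        rng = np.random.default_rng(user_seeds[u])
        uid = f"u{u:04d}"
        calendar = _draw_schedule(config, rng, uid)
        days = [config.start_date + dt.timedelta(days=i) for i in range(config.n_days)]
        within = np.array([calendar.contains(d) for d in days], dtype=bool)
        latent = _switching_series(config.temporal_matrix, config.precision_outside,
                                  config.precision_within, within, config.burn_in, rng)
        values = latent_to_percentage(latent, config.latent_center, config.latent_scale)
        keep = rng.random(config.n_days) >= config.missing_day_prob
        matrix = DailyFeatureMatrix(
            user_id=uid,
            dates=[d for d, k in zip(days, keep) if k],
            feature_names=[f"f{j}" for j in range(p)] if dictionary is None
            else dictionary.category_names,
            values=values[keep],
            survey_date=config.start_date + dt.timedelta(days=config.n_days - 1),
        )
        conn[u] = np.mean(np.where(within, g_in, g_out))
        feat_means[u] = values.mean(axis=0)
        documents: list[tuple[dt.date, str]] = []
        if config.tokens_per_day > 0 and dictionary is not None:
            docs, _ = render_documents(latent[keep], dictionary, config.tokens_per_day,
                                       seed=rng, center=config.latent_center,
                                       scale=config.latent_scale)
            documents = [(matrix.dates[i], text) for i, text in docs]
        users.append(SyntheticUser(user_id=uid, latent=latent, matrix=matrix,
                                   calendar=calendar, within_mask_full=within,
                                   documents=documents))

    # severity: standardised blend of true connectivity, feature means, and noise
    raw = (config.severity_connectivity_slope * conn
           + feat_means @ config.severity_feature_slopes
           + config.severity_noise_sd * master.standard_normal(config.n_users))
    sd = raw.std(ddof=1) if config.n_users > 1 else 0.0
    z = (raw - raw.mean()) / sd if sd > 0 else raw - raw.mean()
    for u, user in enumerate(users):
        user.severity = float(z[u])

    return SyntheticCohort(users=users, config=config, omega_outside=omega_out,
                           omega_within=omega_in, connectivity_truth=conn)


def render_documents(series: np.ndarray, dictionary: CategoryDictionary,
                     tokens_per_day: int, seed: int | np.random.Generator = 0,
                     center: float = 0.0, scale: float = 1.0):
    """Emit one synthetic document per day from latent category propensities.

    Each latent value maps through a logistic onto (0, 1) and is divided by
    the number of categories, so daily category probabilities sum to < 1;
    the remainder goes to out-of-dictionary filler tokens. Tokens are drawn
    i.i.d. from that mixture, with uniform word choice within a category.

    Returns (documents, probabilities) where documents is a list of
    (day_index, text) — days with ``tokens_per_day`` = 0 are absent — and
    probabilities is the (T, n_categories) generating matrix.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    series = np.asarray(series, dtype=float)
    n_cat = dictionary.n_categories
    probs = 1.0 / (1.0 + np.exp(-(series - center) / scale)) / n_cat

    words_by_cat: list[list[str]] = []
    redistributed = np.ones(n_cat, dtype=bool)
    for i, (cid, name) in enumerate(dictionary.categories):
        words = [p.rstrip("*") for p, cids in dictionary.entries if cid in cids]
        words = [w for w in words if w]
        if not words:
            log.warning("category %s has no usable entries; probability sent to filler", name)
            redistributed[i] = False
        words_by_cat.append(words)
    filler = [f"zz{k}x" for k in range(20)]

    documents: list[tuple[int, str]] = []
    if tokens_per_day <= 0:
        return documents, probs
    for t in range(series.shape[0]):
        pvec = np.where(redistributed, probs[t], 0.0)
        mixture = np.append(pvec, max(0.0, 1.0 - pvec.sum()))
        counts = rng.multinomial(tokens_per_day, mixture / mixture.sum())
        tokens: list[str] = []
        for c in range(n_cat):
            if counts[c]:
                tokens.extend(rng.choice(words_by_cat[c], size=counts[c]).tolist())
        if counts[-1]:
            tokens.extend(rng.choice(filler, size=counts[-1]).tolist())
        rng.shuffle(tokens)
        documents.append((t, " ".join(tokens)))
    return documents, probs


# ---------------------------------------------------------------------------
# cohort serialisation (text formats only)


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    from pathlib import Path

    from .episodes import write_calendar_csv
    from .text import write_features_csv

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_features_csv([u.matrix for u in cohort.users], out / "features.csv")
    write_calendar_csv([u.calendar for u in cohort.users], out / "episodes.csv")
    cohort.severity.rename_axis("user_id").reset_index().to_csv(out / "severity.csv", index=False)
    cfg = cohort.config
    truth = {
        "temporal_matrix": cfg.temporal_matrix.tolist(),
        "precision_outside": cfg.precision_outside.tolist(),
        "connectivity_multiplier": cfg.connectivity_multiplier,
        "omega_outside": cohort.omega_outside.tolist(),
        "omega_within": cohort.omega_within.tolist(),
        "connectivity_truth": {u.user_id: float(c)
                               for u, c in zip(cohort.users, cohort.connectivity_truth)},
        "seed": cfg.seed,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    if any(u.documents for u in cohort.users):
        with open(out / "documents.jsonl", "w", encoding="utf-8") as fh:
            for u in cohort.users:
                for day, text in u.documents:
                    fh.write(json.dumps({"user_id": u.user_id, "date": day.isoformat(),
                                         "text": text}) + "\n")
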