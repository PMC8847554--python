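"""Document cleaning, dictionary-based category scoring, and daily matrices.

The scoring pipeline turns a stream of timestamped raw documents into one
row per user-day of word-category percentages: documents are cleaned,
aggregated into daily bins, and scored against a word/stem dictionary. Days
without documents produce no row, and only days inside the 12 months before
the user's survey date are retained.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: punctuation retained by cleaning, as standalone tokens
RETAINED_PUNCT = {".", "!", "?"}

_URL_RE = re.compile(r"(?:https?://|www\.)\S+")
_MENTION_RE = re.compile(r"@\w+")
_PUNCT_PAD_RE = re.compile(r"([.!?])")
_NON_TOKEN_RE = re.compile(r"[^a-z0-9.!?\s]")


def clean_text(raw_text: str, keep_hashtag_word: bool = True) -> list[str]:
    """Clean one document into lowercase tokens.

    URLs and @-mentions are removed whole; the ``#`` symbol is stripped (the
    word after it is kept by default); ``.``, ``!`` and ``?`` survive as
    separate tokens; every other non-alphanumeric character (emoji,
    ellipses, commas, ...) becomes a token boundary.
    """
    text = raw_text.lower()
    text = _URL_RE.sub(" ", text)
    text = _MENTION_RE.sub(" ", text)
    if keep_hashtag_word:
        text = text.replace("#", "")
    else:
        text = re.sub(r"#\w+", " ", text)
    text = _PUNCT_PAD_RE.sub(r" \1 ", text)
    text = _NON_TOKEN_RE.sub(" ", text)
    return text.split()


@dataclass(frozen=True)
class CategoryDictionary:
    """A word-category dictionary: literal words plus ``stem*`` prefixes.

    ``categories`` is an ordered list of (id, name); ``entries`` maps each
    pattern to the set of category ids it scores. The trailing asterisk
    marks a stem: ``happ*`` matches any token beginning with ``happ``.
    """

    categories: tuple[tuple[int, str], ...]
    entries: tuple[tuple[str, frozenset[int]], ...]

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.categories]
        names = [name for _, name in self.categories]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate category id")
        if len(set(names)) != len(names):
            raise ValueError("duplicate category name")
        known = set(ids)
        for pattern, cids in self.entries:
            bad = set(cids) - known
            if bad:
                raise ValueError(f"entry {pattern!r} references unknown category id(s) {sorted(bad)}")

    @property
    def category_names(self) -> list[str]:
        return [name for _, name in self.categories]

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def exact_lookup(self) -> dict[str, frozenset[int]]:
        out: dict[str, set[int]] = {}
        for pattern, cids in self.entries:
            if not pattern.endswith("*"):
                out.setdefault(pattern, set()).update(cids)
        return {w: frozenset(s) for w, s in out.items()}

    def stem_lookup(self) -> list[tuple[str, frozenset[int]]]:
        return [(p[:-1], cids) for p, cids in self.entries if p.endswith("*")]


def load_dictionary(path) -> CategoryDictionary:
    """Parse the ``%``-delimited dictionary dialect.

    Layout: a line ``%``, then ``id<TAB>name`` category lines, then ``%``,
    then ``pattern<TAB>id[<TAB>id...]`` entry lines. Unknown or duplicate
    category ids are hard errors reported with their line number.
    """
    categories: list[tuple[int, str]] = []
    entries: list[tuple[str, frozenset[int]]] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    section = 0
    seen_ids: set[int] = set()
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped == "%":
            section += 1
            continue
        parts = stripped.split("\t")
        if section == 1:
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: malformed category line {line!r}")
            cid = int(parts[0])
            if cid in seen_ids:
                raise ValueError(f"line {lineno}: duplicate category id {cid}")
            seen_ids.add(cid)
            categories.append((cid, parts[1]))
        elif section == 2:
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: malformed entry line {line!r}")
            cids = frozenset(int(p) for p in parts[1:])
            bad = cids - seen_ids
            if bad:
                raise ValueError(f"line {lineno}: entry {parts[0]!r} references unknown id(s) {sorted(bad)}")
            entries.append((parts[0], cids))
        else:
            raise ValueError(f"line {lineno}: content before the first '%' delimiter")
    return CategoryDictionary(categories=tuple(categories), entries=tuple(entries))


def write_dictionary(dictionary: CategoryDictionary, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("%\n")
        for cid, name in dictionary.categories:
            fh.write(f"{cid}\t{name}\n")
        fh.write("%\n")
        for pattern, cids in dictionary.entries:
            fh.write(pattern + "\t" + "\t".join(str(c) for c in sorted(cids)) + "\n")


def make_toy_dictionary(category_names: list[str] | None = None,
                        words_per_category: int = 8,
                        stem_fraction: float = 0.25) -> CategoryDictionary:
    """A small synthetic dictionary for end-to-end testing.

    Vocabulary is deterministic: category ``k`` gets words ``w<k>a0`` ...;
    a leading fraction of the entries are stems.
    """
    if category_names is None:
        category_names = ["negemo", "posemo", "selfref", "weref", "youref",
                          "thirdref", "swear", "article", "negate"]
    categories = tuple((i + 1, name) for i, name in enumerate(category_names))
    entries = []
    n_stems = int(round(stem_fraction * words_per_category))
    for i, _name in enumerate(categories):
        cid = i + 1
        for j in range(words_per_category):
            word = f"w{cid}a{j}"
            if j < n_stems:
                word += "*"
            entries.append((word, frozenset({cid})))
    return CategoryDictionary(categories=categories, entries=tuple(entries))


def score_tokens(tokens: list[str], dictionary: CategoryDictionary,
                 stem_policy: str = "shadow") -> tuple[np.ndarray, int]:
    """Score cleaned tokens against the dictionary.

    Returns (percentages aligned with ``dictionary.categories``, word count).
    The word count excludes retained punctuation tokens. A token may score
    several categories at once. Under the default ``shadow`` policy an exact
    entry for a token suppresses stem matches; under ``union`` both apply.
    Zero countable words -> word count 0 and an all-NaN vector (the caller
    skips the day).
    """
    if stem_policy not in ("shadow", "union"):
        raise ValueError(f"unknown stem_policy {stem_policy!r}")
    words = [t for t in tokens if t not in RETAINED_PUNCT]
    wc = len(words)
    p = dictionary.n_categories
    if wc == 0:
        return np.full(p, np.nan), 0
    exact = dictionary.exact_lookup()
    stems = dictionary.stem_lookup()
    col = {cid: i for i, (cid, _) in enumerate(dictionary.categories)}
    counts = np.zeros(p)
    for w in words:
        hit = exact.get(w)
        cats: set[int] = set(hit) if hit is not None else set()
        if hit is None or stem_policy == "union":
            for stem, cids in stems:
                if w.startswith(stem):
                    cats.update(cids)
        for cid in cats:
            counts[col[cid]] += 1
    return 100.0 * counts / wc, wc


@dataclass(frozen=True)
class DocumentRecord:
    """One raw document assigned to a calendar day (UTC)."""

    user_id: str
    date: dt.date
    raw_text: str
    tokens: tuple[str, ...] | None = None

    def cleaned(self) -> list[str]:
        return list(self.tokens) if self.tokens is not None else clean_text(self.raw_text)


@dataclass
class DailyFeatureMatrix:
    """Per-user daily rows of category percentages.

    Only days with at least one (non-empty) document appear; rows are in
    strictly increasing date order and all values lie in [0, 100].
    """

    user_id: str
    dates: list[dt.date]
    feature_names: list[str]
    values: np.ndarray
    word_count: np.ndarray | None = None
    survey_date: dt.date | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (len(self.dates), len(self.feature_names)):
            raise ValueError("values shape does not match dates x features")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ValueError("dates must be strictly increasing")
        if self.values.size and (np.nanmin(self.values) < -1e-9 or np.nanmax(self.values) > 100 + 1e-9):
            raise ValueError("feature values must lie in [0, 100]")
        if self.survey_date is not None:
            for d in self.dates:
                if not (self.survey_date - dt.timedelta(days=365) <= d <= self.survey_date):
                    raise ValueError(f"day {d} outside the 12 months before {self.survey_date}")

    @property
    def n_days(self) -> int:
        return len(self.dates)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def select_days(self, mask: np.ndarray) -> "DailyFeatureMatrix":
        mask = np.asarray(mask, dtype=bool)
        return DailyFeatureMatrix(
            user_id=self.user_id,
            dates=[d for d, m in zip(self.dates, mask) if m],
            feature_names=list(self.feature_names),
            values=self.values[mask],
            word_count=None if self.word_count is None else np.asarray(self.word_count)[mask],
            survey_date=self.survey_date,
        )

    def select_features(self, names: list[str]) -> "DailyFeatureMatrix":
        missing = [n for n in names if n not in self.feature_names]
        if missing:
            raise KeyError(f"unknown feature(s) {missing}")
        idx = [self.feature_names.index(n) for n in names]
        return DailyFeatureMatrix(
            user_id=self.user_id, dates=list(self.dates), feature_names=list(names),
            values=self.values[:, idx], word_count=self.word_count, survey_date=self.survey_date,
        )

    def feature_means(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names,
                          index=pd.Index(self.dates, name="date"))
        if self.word_count is not None:
            df["word_count"] = self.word_count
        df.insert(0, "user_id", self.user_id)
        return df


def build_daily_matrix(documents, dictionary: CategoryDictionary,
                       survey_date: dt.date, window_days: int = 365,
                       stem_policy: str = "shadow") -> DailyFeatureMatrix:
    """Aggregate one user's documents into daily bins and score each day.

    Documents may arrive in any order; all documents of a user-day are
    concatenated before scoring. Days more than ``window_days`` before the
    survey date (or after it) are dropped, as are days whose concatenated
    text has no countable words.
    """
    docs = list(documents)
    users = {d.user_id for d in docs}
    if len(users) > 1:
        raise ValueError(f"documents span multiple users: {sorted(users)}")
    user_id = docs[0].user_id if docs else ""
    earliest = survey_date - dt.timedelta(days=window_days)

    by_day: dict[dt.date, list[str]] = {}
    for doc in docs:
        if not (earliest <= doc.date <= survey_date):
            continue
        by_day.setdefault(doc.date, []).extend(doc.cleaned())

    dates, rows, wcs = [], [], []
    for day in sorted(by_day):
        perc, wc = score_tokens(by_day[day], dictionary, stem_policy=stem_policy)
        if wc == 0:
            continue
        dates.append(day)
        rows.append(perc)
        wcs.append(wc)
    if not dates:
        log.warning("user %s has no in-window days with countable words", user_id)
    values = np.array(rows) if rows else np.empty((0, dictionary.n_categories))
    return DailyFeatureMatrix(user_id=user_id, dates=dates,
                              feature_names=dictionary.category_names,
                              values=values, word_count=np.array(wcs, dtype=int),
                              survey_date=survey_date)


# ---------------------------------------------------------------------------
# I/O


def read_documents_jsonl(path) -> list[DocumentRecord]:
    """Read documents from JSONL with keys user_id, date (ISO), text."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            day = dt.datetime.fromisoformat(rec["date"]).date() if "T" in rec["date"] \
                else dt.date.fromisoformat(rec["date"])
            out.append(DocumentRecord(user_id=str(rec["user_id"]), date=day, raw_text=rec["text"]))
    return out


def read_documents_csv(path) -> list[DocumentRecord]:
    df = pd.read_csv(path, dtype={"user_id": str})
    ts = pd.to_datetime(df["timestamp"], utc=True)
    return [DocumentRecord(user_id=str(u), date=t.date(), raw_text=str(x))
            for u, t, x in zip(df["user_id"], ts, df["text"])]


def write_features_csv(matrices: list[DailyFeatureMatrix], path) -> None:
    """Long CSV: user_id, date, feature, value (+ word_count rows)."""
    rows = []
    for m in matrices:
        for i, day in enumerate(m.dates):
            for j, feat in enumerate(m.feature_names):
                rows.append((m.user_id, day.isoformat(), feat, m.values[i, j]))
            if m.word_count is not None:
                rows.append((m.user_id, day.isoformat(), "word_count", int(m.word_count[i])))
    pd.DataFrame(rows, columns=["user_id", "date", "feature", "value"]).to_csv(path, index=False)


def read_features_csv(path) -> list[DailyFeatureMatrix]:
    df = pd.read_csv(path, dtype={"user_id": str})
    matrices = []
    for uid, grp in df.groupby("user_id", sort=True):
        wide = grp.pivot_table(index="date", columns="feature", values="value", sort=True)
        wc = None
        if "word_count" in wide.columns:
            wc = wide.pop("word_count").to_numpy().astype(int)
        feats = [c for c in wide.columns]
        matrices.append(DailyFeatureMatrix(
            user_id=str(uid),
            dates=[dt.date.fromisoformat(d) for d in wide.index],
            feature_names=feats,
            values=wide.to_numpy(),
            word_count=wc,
        ))
    return matrices
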