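"""Transitive growth-pattern mining and evaluation.

If organisms A and B are documented together on medium m1, B and C together
on m2, and C on a third medium m3 (all distinct), transitivity of "shares a
medium" predicts that A grows on m3. This module mines such patterns from a
positive-only growth database, scores how often the implied pairing is
already documented against a random-organism control (binomial test), and
emits the implied new pairings.

Media hosting fewer than 3 or more than 100 organisms are excluded before
mining: singleton media carry no sharing signal and very popular media
would make everything look transitive.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from ._stats import binomial_upper_tail as _binomial_upper_tail
from .core import GrowthDatabase, MediarecError

logger = logging.getLogger(__name__)

MIN_MEDIA_ORGANISMS = 3
MAX_MEDIA_ORGANISMS = 100


@dataclass(frozen=True)
class TransitivePattern:
    """Witnesses AB|m1, BC|m2, C|m3 with all organisms and media distinct."""

    organisms: tuple[str, str, str]  # (A, B, C)
    media: tuple[str, str, str]  # (m1, m2, m3)


@dataclass(frozen=True)
class TransitivityEvaluation:
    n_tests: int
    positives_test: int  # patterns whose implied pairing (A, m3) is documented
    positives_control: int  # (X, m3) documented for a random organism X
    null_rate: float
    p_value: float
    log10_p: float
    seed: int | None


@dataclass(frozen=True)
class TransitivePrediction:
    organism: str
    medium: str
    witnesses: int  # number of distinct patterns implying the pairing


def binomial_upper_tail(k: int, n: int, p: float) -> tuple[float, float]:
    """Exact log-space upper tail P(X >= k | n, p); see :mod:`mediarec._stats`."""
    return _binomial_upper_tail(k, n, p)


# ---------------------------------------------------------------------------
# Exact-uniform pattern sampling
# ---------------------------------------------------------------------------
class _PatternSpace:
    """Counts and samples uniformly over all valid transitive patterns.

    A pattern is determined by a bridge (B, m1, m2) — organism B documented
    on both media — plus choices of C on m2 (with a third medium), A on m1,
    and m3. For every bridge the number of completions is computed exactly,
    so sampling bridge ∝ completions, then C ∝ its completions, then A and
    m3 uniformly, is exactly uniform over pattern tuples.
    """

    def __init__(self, db: GrowthDatabase):
        self.db = db
        self.orgs_of = {m: sorted(db.organisms_of(m)) for m in db.media}
        self.media_of = {o: sorted(db.media_of(o)) for o in db.organisms}
        self._orgs_set = {m: frozenset(v) for m, v in self.orgs_of.items()}
        self._media_set = {o: frozenset(v) for o, v in self.media_of.items()}
        bridges: list[tuple[str, str, str]] = []
        weights: list[int] = []
        for b in sorted(db.organisms):
            bmedia = self.media_of[b]
            if len(bmedia) < 2:
                continue
            for m1 in bmedia:
                k1 = len(self.orgs_of[m1])
                for m2 in bmedia:
                    if m2 == m1:
                        continue
                    w = 0
                    for c in self.orgs_of[m2]:
                        if c == b:
                            continue
                        w += self._t(c, m1, m2) * self._a(c, m1, k1)
                    if w > 0:
                        bridges.append((b, m1, m2))
                        weights.append(w)
        self.bridges = bridges
        self.weights = np.asarray(weights, dtype=float)
        self.total = int(sum(weights))

    def _t(self, c: str, m1: str, m2: str) -> int:
        return len(self.media_of[c]) - (m1 in self._media_set[c]) - 1  # m2 counted

    def _a(self, c: str, m1: str, k1: int) -> int:
        return k1 - 1 - (c in self._orgs_set[m1])

    def sample(self, rng: np.random.Generator) -> TransitivePattern:
        i = rng.choice(len(self.bridges), p=self.weights / self.weights.sum())
        b, m1, m2 = self.bridges[i]
        k1 = len(self.orgs_of[m1])
        cands = [c for c in self.orgs_of[m2] if c != b]
        cw = np.array(
            [self._t(c, m1, m2) * self._a(c, m1, k1) for c in cands], dtype=float
        )
        c = cands[rng.choice(len(cands), p=cw / cw.sum())]
        a_cands = [a for a in self.orgs_of[m1] if a not in (b, c)]
        a = a_cands[rng.integers(len(a_cands))]
        m3_cands = [m for m in self.media_of[c] if m not in (m1, m2)]
        m3 = m3_cands[rng.integers(len(m3_cands))]
        return TransitivePattern((a, b, c), (m1, m2, m3))

    def enumerate(self) -> Iterator[TransitivePattern]:
        for b, m1, m2 in self.bridges:
            for c in self.orgs_of[m2]:
                if c == b:
                    continue
                m3s = [m for m in self.media_of[c] if m not in (m1, m2)]
                if not m3s:
                    continue
                for a in self.orgs_of[m1]:
                    if a in (b, c):
                        continue
                    for m3 in m3s:
                        yield TransitivePattern((a, b, c), (m1, m2, m3))


def _filtered(db: GrowthDatabase) -> GrowthDatabase:
    return db.filter_media(MIN_MEDIA_ORGANISMS, MAX_MEDIA_ORGANISMS)


def mine_patterns(
    db: GrowthDatabase, n: int, seed: int | None = None
) -> list[TransitivePattern]:
    """Sample ``n`` distinct transitive patterns uniformly at random.

    Media outside the [3, 100]-organism band never appear. If fewer than
    ``n`` distinct patterns exist, all of them are returned with a warning.
    Reproducible under ``seed``.
    """
    if n < 0:
        raise MediarecError("n must be non-negative")
    return _mine_from_space(_PatternSpace(_filtered(db)), n, seed)


def evaluate_transitivity(
    db: GrowthDatabase,
    n: int,
    seed: int | None = None,
    null_rate: float | None = None,
) -> TransitivityEvaluation:
    """Score mined patterns against a random-organism control.

    For each pattern the test succeeds when the implied pairing (A, m3) is
    documented; the control replaces A with an organism X drawn uniformly
    from the database excluding A, B and C. The binomial upper tail of the
    test successes is computed under a null rate estimated from the control
    as max(control successes, 1) / n — conservative when the control shows
    zero successes — unless ``null_rate`` is given explicitly.
    """
    if n <= 0:
        raise MediarecError("n must be positive")
    patterns = mine_patterns(db, n, seed=seed)
    if not patterns:
        raise MediarecError("no patterns to evaluate")
    rng = np.random.default_rng(None if seed is None else seed + 1)
    organisms = sorted(db.organisms)
    pos_test = pos_ctrl = 0
    for pat in patterns:
        a, b, c = pat.organisms
        m3 = pat.media[2]
        if db.has_pairing(a, m3):
            pos_test += 1
        cands = [o for o in organisms if o not in (a, b, c)]
        x = cands[rng.integers(len(cands))]
        if db.has_pairing(x, m3):
            pos_ctrl += 1
    n_eff = len(patterns)
    p_hat = null_rate if null_rate is not None else max(pos_ctrl, 1) / n_eff
    if p_hat >= 1.0:  # saturated control: keep the test well defined
        p_hat = 1.0 - 0.5 / n_eff
    p_value, log10_p = binomial_upper_tail(pos_test, n_eff, p_hat)
    return TransitivityEvaluation(
        n_tests=n_eff,
        positives_test=pos_test,
        positives_control=pos_ctrl,
        null_rate=p_hat,
        p_value=p_value,
        log10_p=log10_p,
        seed=seed,
    )


def predict_transitive(db: GrowthDatabase) -> list[TransitivePrediction]:
    """All new pairings implied by some transitive pattern, deduplicated.

    Each prediction carries the number of distinct patterns
    (B, C, m1, m2, m3 combinations) witnessing it. Pairings already in the
    database are never emitted. Cost grows with the cube of the co-growth
    neighborhood size; intended for databases up to a few thousand
    pairings.
    """
    fdb = _filtered(db)
    media_of = {o: fdb.media_of(o) for o in fdb.organisms}
    co: dict[str, set[str]] = {o: set() for o in fdb.organisms}
    for m in fdb.media:
        orgs = fdb.organisms_of(m)
        for o in orgs:
            co[o].update(orgs)
    counts: dict[tuple[str, str], int] = {}
    for a in sorted(fdb.organisms):
        media_a = media_of[a]
        for b in co[a]:
            if b == a:
                continue
            s1 = media_a & media_of[b]
            if not s1:
                continue
            for c in co[b]:
                if c in (a, b):
                    continue
                s2 = media_of[b] & media_of[c]
                if not s2:
                    continue
                s12 = s1 & s2
                for m3 in media_of[c]:
                    n1 = len(s1) - (m3 in s1)
                    n2 = len(s2) - (m3 in s2)
                    n12 = len(s12) - (m3 in s12)
                    n_patterns = n1 * n2 - n12
                    if n_patterns > 0 and not fdb.has_pairing(a, m3):
                        counts[(a, m3)] = counts.get((a, m3), 0) + n_patterns
    return [
        TransitivePrediction(org, med, w)
        for (org, med), w in sorted(counts.items())
    ]


class TransitivityPredictor(BaseEstimator):
    """Estimator wrapper around transitive mining and prediction.

    Parameters
    ----------
    min_media_organisms, max_media_organisms : int
        Media outside this organism-count band are excluded before mining.
    """

    def __init__(
        self,
        min_media_organisms: int = MIN_MEDIA_ORGANISMS,
        max_media_organisms: int = MAX_MEDIA_ORGANISMS,
    ):
        self.min_media_organisms = min_media_organisms
        self.max_media_organisms = max_media_organisms

    def fit(self, db: GrowthDatabase, y=None) -> "TransitivityPredictor":
        self.db_ = db
        self.filtered_db_ = db.filter_media(
            self.min_media_organisms, self.max_media_organisms
        )
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "db_"):
            raise MediarecError("estimator is not fitted; call fit(db) first")

    def mine(self, n: int, random_state: int | None = None) -> list[TransitivePattern]:
        self._check_fitted()
        space = _PatternSpace(self.filtered_db_)
        # reuse module function but respect custom band
        return _mine_from_space(space, n, random_state)

    def evaluate(
        self, n: int, random_state: int | None = None, null_rate: float | None = None
    ) -> TransitivityEvaluation:
        self._check_fitted()
        return evaluate_transitivity(
            self.db_, n, seed=random_state, null_rate=null_rate
        )

    def predict(self) -> list[TransitivePrediction]:
        self._check_fitted()
        return predict_transitive(self.db_)


def _mine_from_space(
    space: _PatternSpace, n: int, seed: int | None
) -> list[TransitivePattern]:
    rng = np.random.default_rng(seed)
    if space.total == 0:
        warnings.warn("no transitive patterns exist in the database")
        return []
    if space.total <= n:
        if space.total < n:
            warnings.warn(f"only {space.total} distinct patterns exist; returning all")
        patterns = list(space.enumerate())
        rng.shuffle(patterns)
        return patterns
    if n > space.total / 2:
        patterns = list(space.enumerate())
        idx = rng.choice(space.total, size=n, replace=False)
        return [patterns[i] for i in idx]
    out: list[TransitivePattern] = []
    seen: set[TransitivePattern] = set()
    attempts, cap = 0, 50 * n + 1000
    while len(out) < n and attempts < cap:
        attempts += 1
        p = space.sample(rng)
        if p not in seen:
            seen.add(p)
            out.append(p)
    return out
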