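"""Collaborative-filtering medium recommendation.

The recommender scores a (test organism, medium) pair by the weighted
number of phylogenetic neighbors of the test organism documented to grow on
that medium. Neighbors are organisms within a normalized subtree distance
cutoff (default 0.04); each neighbor at distance d votes with weight
cutoff / d, so nearer relatives count more. In ecological mode neighbors
are organisms within a Jaccard co-occurrence distance of 0.15 and votes are
unweighted. The test organism's own pairings never contribute, so scoring
an organism already in the database is an honest leave-one-out test.

Also here: the popularity-weighted null predictor used as a baseline,
score-binned true-positive evaluation with (partial) Spearman statistics,
and the oxygen / salt organism classifiers and prediction filters.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from ._stats import partial_spearman, spearman
from .core import (
    EnvironmentTable,
    GrowthDatabase,
    MediarecError,
    MediumVariant,
    TaxonomyTree,
    organisms_in_tree,
)
from .similarity import eco_similarity

logger = logging.getLogger(__name__)

PHYLO_CUTOFF_DEFAULT = 0.04
ECO_CUTOFF_DEFAULT = 0.15
NACL_MOLAR_MASS = 58.44  # g/mol
SALTY_NACL_G_PER_L = 15.0


@dataclass(frozen=True)
class CollabPrediction:
    """A scored (organism, medium) recommendation."""

    organism: str
    medium: str
    score: float
    neighbor_count: int
    is_known: bool
    passed_filters: bool | None = None
    filter_flags: tuple[tuple[str, bool], ...] = ()


@dataclass(frozen=True)
class OrganismProfile:
    oxygen_class: str = "unknown"  # aerobic | anaerobic | facultative | unknown
    salt_class: str = "unknown"  # high | low | unknown


class MediumRecommender(BaseEstimator):
    """Phylogeny- or ecology-based collaborative filtering recommender.

    Parameters
    ----------
    mode : {"phylogenetic", "ecological"}
        Distance source: normalized subtree distance on a taxonomy, or
        Jaccard distance over environment co-occurrence.
    cutoff : float or None
        Neighbor distance cutoff; defaults to 0.04 (phylogenetic) or
        0.15 (ecological) when None.
    weighting : {"cutoff_over_distance", "uniform"} or None
        Neighbor vote weight; defaults to cutoff/distance for phylogenetic
        mode and uniform for ecological mode.
    min_distance_floor : float or None
        Distances are floored at this value inside the weight so a single
        near-identical strain cannot dominate; defaults to 1/total_leaves.
    """

    def __init__(
        self,
        mode: str = "phylogenetic",
        cutoff: float | None = None,
        weighting: str | None = None,
        min_distance_floor: float | None = None,
    ):
        self.mode = mode
        self.cutoff = cutoff
        self.weighting = weighting
        self.min_distance_floor = min_distance_floor

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        db: GrowthDatabase,
        tree: TaxonomyTree | None = None,
        environments: EnvironmentTable | None = None,
    ) -> "MediumRecommender":
        if self.mode not in ("phylogenetic", "ecological"):
            raise MediarecError(f"unknown mode {self.mode!r}")
        if self.mode == "phylogenetic":
            if tree is None:
                raise MediarecError("phylogenetic mode requires a taxonomy tree")
            self.tree_ = tree
            self.environments_ = None
            self.cutoff_ = self.cutoff if self.cutoff is not None else PHYLO_CUTOFF_DEFAULT
            self.weighting_ = self.weighting or "cutoff_over_distance"
            self.floor_ = (
                self.min_distance_floor
                if self.min_distance_floor is not None
                else 1.0 / tree.total_leaves
            )
            self.organisms_ = sorted(organisms_in_tree(db, tree))
        else:
            if environments is None:
                raise MediarecError("ecological mode requires an environment table")
            self.tree_ = None
            self.environments_ = environments
            self.cutoff_ = self.cutoff if self.cutoff is not None else ECO_CUTOFF_DEFAULT
            self.weighting_ = self.weighting or "uniform"
            self.floor_ = self.min_distance_floor or 1e-9
            self.organisms_ = sorted(o for o in db.organisms if o in environments)
        if not 0.0 < self.cutoff_ <= 1.0:
            raise MediarecError(f"cutoff must be in (0, 1], got {self.cutoff_}")
        if self.floor_ >= self.cutoff_:
            raise MediarecError("min_distance_floor must be below the cutoff")
        self.db_ = db
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "db_"):
            raise MediarecError("estimator is not fitted; call fit(db, ...) first")

    # -- distances and neighbors ------------------------------------------
    def _distance(self, a: str, b: str) -> float:
        if self.mode == "phylogenetic":
            return self.tree_.subtree_distance(a, b)
        return 1.0 - eco_similarity(a, b, self.environments_)

    def neighbors(self, organism: str) -> list[tuple[str, float]]:
        """Database organisms within the cutoff, with their distances."""
        self._check_fitted()
        if self.mode == "phylogenetic" and organism not in self.tree_:
            raise MediarecError(f"organism {organism!r} not in the taxonomy tree")
        if self.mode == "ecological" and organism not in self.environments_:
            raise MediarecError(f"organism {organism!r} not in the environment table")
        out = []
        for other in self.organisms_:
            if other == organism:
                continue
            d = self._distance(organism, other)
            if d <= self.cutoff_:
                out.append((other, d))
        return out

    def _weight(self, d: float) -> float:
        if self.weighting_ == "uniform":
            return 1.0
        return self.cutoff_ / max(d, self.floor_)

    # -- scoring -----------------------------------------------------------
    def score_pair(self, organism: str, medium: str) -> float:
        """Collaborative score of one (organism, medium) pair.

        Sum over neighbors documented on the medium of cutoff/d (or 1 in
        uniform weighting). The organism's own pairings are excluded, so
        this is leave-one-out by construction.
        """
        self._check_fitted()
        return sum(
            self._weight(d)
            for o, d in self.neighbors(organism)
            if self.db_.has_pairing(o, medium)
        )

    def predict_media(self, organism: str) -> list[CollabPrediction]:
        """All media with positive score, ranked by score (ties by medium ID)."""
        self._check_fitted()
        scores: dict[str, float] = {}
        counts: dict[str, int] = {}
        for o, d in self.neighbors(organism):
            w = self._weight(d)
            for medium in self.db_.media_of(o):
                scores[medium] = scores.get(medium, 0.0) + w
                counts[medium] = counts.get(medium, 0) + 1
        preds = [
            CollabPrediction(
                organism=organism,
                medium=m,
                score=s,
                neighbor_count=counts[m],
                is_known=self.db_.has_pairing(organism, m),
            )
            for m, s in scores.items()
        ]
        preds.sort(key=lambda p: (-p.score, p.medium))
        return preds

    def predict(self, organisms: Iterable[str] | None = None) -> list[CollabPrediction]:
        """Leave-one-out predictions for many organisms (default: all fitted)."""
        self._check_fitted()
        targets = list(organisms) if organisms is not None else self.organisms_
        out: list[CollabPrediction] = []
        for org in targets:
            out.extend(self.predict_media(org))
        return out


class PopularityNullRecommender(BaseEstimator):
    """Null predictor pairing organisms with media by popularity alone.

    Organisms and media are sampled independently, each with probability
    proportional to its number of known pairings; organisms can be
    restricted to those present in the phylogenetic (or ecological) set so
    the null matches the collaborative predictor's universe.
    """

    def fit(
        self, db: GrowthDatabase, organisms: Iterable[str] | None = None
    ) -> "PopularityNullRecommender":
        self.db_ = db
        orgs = sorted(organisms) if organisms is not None else sorted(db.organisms)
        self.organisms_ = [o for o in orgs if len(db.media_of(o)) > 0]
        self.media_ = [m for m in sorted(db.media) if len(db.organisms_of(m)) > 0]
        if not self.organisms_ or not self.media_:
            raise MediarecError("database has no pairings to weight by")
        ow = np.array([len(db.media_of(o)) for o in self.organisms_], dtype=float)
        mw = np.array([len(db.organisms_of(m)) for m in self.media_], dtype=float)
        self.organism_p_ = ow / ow.sum()
        self.media_p_ = mw / mw.sum()
        return self

    def sample(
        self, n_predictions: int, random_state: int | None = None
    ) -> list[tuple[str, str]]:
        if not hasattr(self, "db_"):
            raise MediarecError("estimator is not fitted; call fit(db) first")
        if n_predictions <= 0:
            raise MediarecError("n_predictions must be positive")
        rng = np.random.default_rng(random_state)
        oi = rng.choice(len(self.organisms_), size=n_predictions, p=self.organism_p_)
        mi = rng.choice(len(self.media_), size=n_predictions, p=self.media_p_)
        return [(self.organisms_[i], self.media_[j]) for i, j in zip(oi, mi)]


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------
def collab_score(
    test_org: str,
    medium: str,
    db: GrowthDatabase,
    tree: TaxonomyTree,
    cutoff: float = PHYLO_CUTOFF_DEFAULT,
    weighting: str = "cutoff_over_distance",
    min_distance_floor: float | None = None,
) -> float:
    rec = MediumRecommender(
        cutoff=cutoff, weighting=weighting, min_distance_floor=min_distance_floor
    ).fit(db, tree=tree)
    return rec.score_pair(test_org, medium)


def predict_media(
    test_org: str,
    db: GrowthDatabase,
    tree: TaxonomyTree,
    cutoff: float = PHYLO_CUTOFF_DEFAULT,
    weighting: str = "cutoff_over_distance",
    min_distance_floor: float | None = None,
) -> list[CollabPrediction]:
    rec = MediumRecommender(
        cutoff=cutoff, weighting=weighting, min_distance_floor=min_distance_floor
    ).fit(db, tree=tree)
    return rec.predict_media(test_org)


def null_predict(
    db: GrowthDatabase,
    n_predictions: int,
    seed: int | None = None,
    organisms: Iterable[str] | None = None,
) -> list[tuple[str, str]]:
    return (
        PopularityNullRecommender()
        .fit(db, organisms=organisms)
        .sample(n_predictions, random_state=seed)
    )


# ---------------------------------------------------------------------------
# Score-binned evaluation
# ---------------------------------------------------------------------------
@dataclass
class ScoreBinTable:
    """True-positive fraction per collaborative-score bin."""

    bin_edges: np.ndarray
    counts: np.ndarray
    tp_fractions: np.ndarray
    mean_scores: np.ndarray
    mean_popularity: np.ndarray
    rho: float
    p_value: float
    partial_rho: float
    partial_p: float


def evaluate_by_score_bin(
    predictions: Sequence[CollabPrediction],
    db: GrowthDatabase,
    n_bins: int = 10,
    bin_scale: str = "log",
) -> ScoreBinTable:
    """Bin predictions by score; per-bin TP fraction and rank correlations.

    A prediction is a true positive when its pairing is already documented.
    Scores are heavy-tailed, so bins are logarithmic by default. Reports
    Spearman of bin score vs TP fraction and the partial Spearman
    controlling for mean medium popularity per bin.
    """
    if not predictions:
        raise MediarecError("no predictions to evaluate")
    scores = np.array([p.score for p in predictions])
    tp = np.array(
        [db.has_pairing(p.organism, p.medium) for p in predictions], dtype=float
    )
    pop = np.array([len(db.organisms_of(p.medium)) for p in predictions], dtype=float)
    if np.any(scores <= 0):
        raise MediarecError("all prediction scores must be positive")
    lo, hi = scores.min(), scores.max()
    if bin_scale == "log":
        edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    elif bin_scale == "linear":
        edges = np.linspace(lo, hi, n_bins + 1)
    else:
        raise MediarecError(f"unknown bin_scale {bin_scale!r}")
    edges[-1] = np.nextafter(edges[-1], np.inf)
    idx = np.clip(np.digitize(scores, edges) - 1, 0, n_bins - 1)

    counts = np.bincount(idx, minlength=n_bins)
    tp_frac = np.full(n_bins, np.nan)
    mean_score = np.full(n_bins, np.nan)
    mean_pop = np.full(n_bins, np.nan)
    for i in range(n_bins):
        mask = idx == i
        if mask.any():
            tp_frac[i] = tp[mask].mean()
            mean_score[i] = scores[mask].mean()
            mean_pop[i] = pop[mask].mean()
    occ = counts > 0
    if occ.sum() < 3:
        raise MediarecError("fewer than 3 occupied score bins; cannot correlate")
    rho, p = spearman(mean_score[occ], tp_frac[occ])
    if occ.sum() >= 4:
        prho, pp = partial_spearman(mean_score[occ], tp_frac[occ], mean_pop[occ])
    else:
        prho, pp = float("nan"), float("nan")
    return ScoreBinTable(
        bin_edges=edges,
        counts=counts,
        tp_fractions=tp_frac,
        mean_scores=mean_score,
        mean_popularity=mean_pop,
        rho=rho,
        p_value=p,
        partial_rho=prho,
        partial_p=pp,
    )


def permutation_enrichment(
    predictions: Sequence[CollabPrediction],
    db: GrowthDatabase,
    organisms: Iterable[str] | None = None,
    n_permutations: int = 1000,
    random_state: int | None = None,
) -> dict:
    """Empirical permutation test of TP enrichment over the popularity null.

    Draws ``n_permutations`` null prediction sets of matched size from the
    popularity-weighted null and compares their true-positive counts with
    the observed one: p = (1 + #{null TP >= observed}) / (K + 1).
    """
    if not predictions:
        raise MediarecError("no predictions to test")
    observed = sum(db.has_pairing(p.organism, p.medium) for p in predictions)
    null = PopularityNullRecommender().fit(db, organisms=organisms)
    rng = np.random.default_rng(random_state)
    m = len(predictions)
    null_tp = np.empty(n_permutations, dtype=int)
    for k in range(n_permutations):
        pairs = null.sample(m, random_state=int(rng.integers(2**31)))
        null_tp[k] = sum(db.has_pairing(o, med) for o, med in pairs)
    p = (1 + int(np.sum(null_tp >= observed))) / (n_permutations + 1)
    mean_null = float(null_tp.mean())
    return {
        "observed_tp": int(observed),
        "n_predictions": m,
        "null_tp_mean": mean_null,
        "enrichment_ratio": observed / mean_null if mean_null > 0 else float("inf"),
        "p_value": p,
        "null_tp": null_tp,
    }


# ---------------------------------------------------------------------------
# Oxygen and salt classification, prediction filters
# ---------------------------------------------------------------------------
def classify_oxygen(
    org: str, db: GrowthDatabase, media_oxygen: Mapping[str, str]
) -> str:
    """aerobic / anaerobic when unanimous over annotated media; facultative
    when mixed; unknown with no annotated pairings."""
    statuses = {
        media_oxygen.get(m, "unknown") for m in db.media_of(org)
    } - {"unknown"}
    if not statuses:
        return "unknown"
    if statuses == {"aerobic"}:
        return "aerobic"
    if statuses == {"anaerobic"}:
        return "anaerobic"
    return "facultative"


def nacl_equivalent_g_per_l(medium: MediumVariant) -> float:
    """NaCl g/l reconstructed from the compiled composition.

    Full dissociation is assumed, so the NaCl equivalent is
    min(mol Na+, mol Cl-) x 58.44, plus any complex 'sea-salts' g/l. An
    approximation: other sodium or chloride salts contribute their ions.
    """
    na = medium.amount_of("Na+") or 0.0
    cl = medium.amount_of("Cl-") or 0.0
    g = min(na, cl) * NACL_MOLAR_MASS
    sea = medium.amount_of("sea-salts")
    if sea:
        g += sea
    return g


def classify_salt(medium: MediumVariant) -> str:
    """'salty' when NaCl-equivalent >= 15 g/l or the name contains 'sea'."""
    if "sea" in medium.name.lower():
        return "salty"
    return "salty" if nacl_equivalent_g_per_l(medium) >= SALTY_NACL_G_PER_L else "not_salty"


def classify_salt_org(
    org: str, db: GrowthDatabase, media_salt: Mapping[str, str]
) -> str:
    """high when all the organism's media are salty, low when none, else unknown."""
    statuses = {media_salt.get(m, "unknown") for m in db.media_of(org)}
    statuses -= {"unknown"}
    if not statuses:
        return "unknown"
    if statuses == {"salty"}:
        return "high"
    if statuses == {"not_salty"}:
        return "low"
    return "unknown"


def build_profiles(
    db: GrowthDatabase,
    media_oxygen: Mapping[str, str] | None = None,
    media_salt: Mapping[str, str] | None = None,
) -> dict[str, OrganismProfile]:
    """Oxygen/salt profile for every organism, from its observed pairings."""
    profiles = {}
    for org in db.organisms:
        profiles[org] = OrganismProfile(
            oxygen_class=classify_oxygen(org, db, media_oxygen or {}),
            salt_class=classify_salt_org(org, db, media_salt or {}),
        )
    return profiles


def media_salt_statuses(
    media: Mapping[str, MediumVariant]
) -> dict[str, str]:
    return {mid: classify_salt(m) for mid, m in media.items()}


def _passes_oxygen(org_class: str, medium_status: str) -> bool:
    if org_class in ("facultative", "unknown") or medium_status == "unknown":
        return True
    return org_class == medium_status  # aerobic-aerobic / anaerobic-anaerobic


def _passes_salt(org_class: str, medium_status: str) -> bool:
    if org_class == "unknown" or medium_status == "unknown":
        return True
    if org_class == "high":
        return medium_status == "salty"
    return medium_status == "not_salty"  # low-salt organisms


def apply_filters(
    predictions: Sequence[CollabPrediction],
    profiles: Mapping[str, OrganismProfile],
    media_oxygen: Mapping[str, str] | None = None,
    media_salt: Mapping[str, str] | None = None,
) -> list[CollabPrediction]:
    """Annotate predictions with oxygen/salt filter flags.

    Mismatched oxygen pairs are excluded in both directions (anaerobic
    organism x aerobic medium and vice versa); facultative and unknown
    organisms pass. High-salt organisms keep only salty media, low-salt
    organisms only non-salty ones; unknowns pass. The returned predictions
    carry per-filter flags and ``passed_filters``; use
    :func:`filter_predictions` to drop the failures.
    """
    media_oxygen = media_oxygen or {}
    media_salt = media_salt or {}
    out = []
    for p in predictions:
        profile = profiles.get(p.organism, OrganismProfile())
        ox_ok = _passes_oxygen(
            profile.oxygen_class, media_oxygen.get(p.medium, "unknown")
        )
        salt_ok = _passes_salt(
            profile.salt_class, media_salt.get(p.medium, "unknown")
        )
        out.append(
            replace(
                p,
                passed_filters=ox_ok and salt_ok,
                filter_flags=(("oxygen", ox_ok), ("salt", salt_ok)),
            )
        )
    return out


def filter_predictions(
    predictions: Sequence[CollabPrediction],
    profiles: Mapping[str, OrganismProfile],
    media_oxygen: Mapping[str, str] | None = None,
    media_salt: Mapping[str, str] | None = None,
) -> list[CollabPrediction]:
    """Predictions surviving the oxygen and salt filters."""
    return [
        p
        for p in apply_filters(predictions, profiles, media_oxygen, media_salt)
        if p.passed_filters
    ]
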