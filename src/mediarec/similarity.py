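"""Organism and media similarity, and distance-binned media sharing.

Phylogenetic proximity is measured by the normalized subtree distance: the
number of leaves beneath the lowest common ancestor of two organisms over
the total number of leaves. Ecological proximity is the Jaccard index of
the environments two organisms co-occur in. The central descriptive
analysis bins organism pairs by distance and asks what fraction of pairs in
each bin share at least one medium (or pass a partial composition match),
then correlates similarity with that fraction across bins.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._stats import spearman
from .core import (
    EnvironmentTable,
    GrowthDatabase,
    MediarecError,
    MediumVariant,
    TaxonomyTree,
)

logger = logging.getLogger(__name__)

PAIR_MATCH_MODES = ("exact", "union", "best_match")
MEDIA_METRICS = ("jaccard", "component_count")

#: partial matching by raw component counts only compares media with at
#: least this many components, and thresholds may not exceed it
MIN_COMPONENTS_FOR_COUNT = 15


def phylo_distance(a: str, b: str, tree: TaxonomyTree) -> float:
    """Normalized subtree distance in (0, 1]; 1/total_leaves for a == b."""
    return tree.subtree_distance(a, b)


def eco_similarity(a: str, b: str, envs: EnvironmentTable) -> float:
    """Jaccard index of shared environments; error when both sets are empty."""
    ea, eb = envs.environments_of(a), envs.environments_of(b)
    union = ea | eb
    if not union:
        raise MediarecError(
            f"ecological similarity of {a!r} and {b!r} is undefined: "
            "both environment sets are empty"
        )
    return len(ea & eb) / len(union)


def media_similarity(
    m_a: MediumVariant, m_b: MediumVariant, metric: str = "jaccard"
) -> float:
    """Similarity of two compiled media at the constituent-component level.

    ``jaccard``: |shared| / |union| of component identifiers;
    ``component_count``: |shared|. Component identity is post-compilation,
    so different raw spellings of one compound always match, and complex
    components match by category tag.
    """
    if metric not in MEDIA_METRICS:
        raise MediarecError(f"metric must be one of {MEDIA_METRICS}")
    ca, cb = m_a.component_ids(), m_b.component_ids()
    shared = len(ca & cb)
    if metric == "component_count":
        return float(shared)
    union = len(ca | cb)
    if union == 0:
        raise MediarecError(
            f"jaccard similarity of empty media {m_a.medium_id!r} and "
            f"{m_b.medium_id!r} is undefined"
        )
    return shared / union


def _component_sets(
    org: str,
    db: GrowthDatabase,
    media: Mapping[str, MediumVariant],
    metric: str,
) -> list[frozenset[str]]:
    sets = []
    for mid in sorted(db.media_of(org)):
        medium = media[mid]
        ids = medium.component_ids()
        if metric == "component_count" and len(ids) < MIN_COMPONENTS_FOR_COUNT:
            continue
        sets.append(ids)
    return sets


def pair_match(
    org_a: str,
    org_b: str,
    db: GrowthDatabase,
    media: Mapping[str, MediumVariant] | None = None,
    mode: str = "exact",
    metric: str = "jaccard",
    threshold: float | None = None,
) -> bool:
    """Do two organisms share (exactly or partially) a lab medium?

    ``exact`` — share at least one identical medium ID. ``union`` — the
    similarity of the unions of their media's component sets reaches
    ``threshold``. ``best_match`` — the best-matching pair of their media
    reaches ``threshold``. Organisms without media cannot be evaluated and
    raise an error (callers exclude and report them).
    """
    if mode not in PAIR_MATCH_MODES:
        raise MediarecError(f"mode must be one of {PAIR_MATCH_MODES}")
    media_a, media_b = db.media_of(org_a), db.media_of(org_b)
    if not media_a or not media_b:
        missing = org_a if not media_a else org_b
        raise MediarecError(f"organism {missing!r} has no media in the database")
    if mode == "exact":
        return bool(media_a & media_b)
    if media is None:
        raise MediarecError(f"mode {mode!r} requires compiled media")
    if threshold is None:
        raise MediarecError(f"mode {mode!r} requires a threshold")
    if metric == "component_count" and threshold > MIN_COMPONENTS_FOR_COUNT:
        raise MediarecError(
            f"component_count thresholds above {MIN_COMPONENTS_FOR_COUNT} "
            "are not comparable across media"
        )
    sets_a = _component_sets(org_a, db, media, metric)
    sets_b = _component_sets(org_b, db, media, metric)
    if not sets_a or not sets_b:
        return False

    def similarity(ca: frozenset[str], cb: frozenset[str]) -> float:
        shared = len(ca & cb)
        if metric == "component_count":
            return float(shared)
        union = len(ca | cb)
        return shared / union if union else 0.0

    if mode == "union":
        ua = frozenset().union(*sets_a)
        ub = frozenset().union(*sets_b)
        return similarity(ua, ub) >= threshold
    best = max(similarity(ca, cb) for ca in sets_a for cb in sets_b)
    return best >= threshold


@dataclass
class DistanceBinSummary:
    """Binned association of organism distance with media sharing."""

    bin_edges: np.ndarray
    pair_counts: np.ndarray
    sharing_fractions: np.ndarray  # NaN for empty bins
    rho: float  # Spearman of similarity (1 - distance) vs sharing fraction
    p_value: float
    n_pairs: int
    n_excluded_organisms: int
    degenerate: bool = False

    def occupied(self) -> np.ndarray:
        return self.pair_counts > 0


def binned_association(
    db: GrowthDatabase,
    tree: TaxonomyTree | None = None,
    envs: EnvironmentTable | None = None,
    media: Mapping[str, MediumVariant] | None = None,
    n_bins: int = 10,
    mode: str = "exact",
    metric: str = "jaccard",
    threshold: float | None = None,
    bin_strategy: str = "width",
) -> DistanceBinSummary:
    """Bin organism pairs by distance; fraction sharing a medium per bin.

    Exactly one of ``tree`` (phylogenetic subtree distance) or ``envs``
    (ecological Jaccard distance, 1 - similarity) must be given. Organism
    pairs where either organism has no media are excluded and counted.
    The summary's rho is the Spearman correlation, across occupied bins,
    of bin similarity (1 - distance) with the sharing fraction, so a
    positive rho means closer organisms share media more often.
    """
    if (tree is None) == (envs is None):
        raise MediarecError("provide exactly one of tree or envs")
    if n_bins < 2:
        raise MediarecError("need at least 2 bins")

    universe = sorted(
        o
        for o in db.organisms
        if db.media_of(o) and (o in tree if tree is not None else o in envs)
    )
    n_excluded = len(db.organisms) - len(universe)
    if len(universe) < 2:
        raise MediarecError("fewer than two organisms usable for binning")

    distances, shares = [], []
    for a, b in itertools.combinations(universe, 2):
        if tree is not None:
            d = tree.subtree_distance(a, b)
        else:
            d = 1.0 - eco_similarity(a, b, envs)
        distances.append(d)
        shares.append(
            pair_match(a, b, db, media=media, mode=mode, metric=metric,
                       threshold=threshold)
        )
    distances = np.asarray(distances)
    shares = np.asarray(shares, dtype=float)

    if bin_strategy == "width":
        edges = np.linspace(0.0, 1.0, n_bins + 1)
    elif bin_strategy == "count":
        edges = np.unique(np.quantile(distances, np.linspace(0, 1, n_bins + 1)))
        edges[0], edges[-1] = 0.0, 1.0
    else:
        raise MediarecError(f"unknown bin_strategy {bin_strategy!r}")

    idx = np.clip(np.digitize(distances, edges[1:-1], right=True), 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    fractions = np.full(len(edges) - 1, np.nan)
    for i in range(len(edges) - 1):
        if counts[i]:
            fractions[i] = shares[idx == i].mean()

    occupied = counts > 0
    if occupied.sum() < 2:
        raise MediarecError("all organism pairs fall into a single bin")
    centers = (edges[:-1] + edges[1:]) / 2.0
    similarity = 1.0 - centers[occupied]
    frac = fractions[occupied]
    degenerate = bool(np.all(frac == frac[0]))
    if degenerate:
        rho, p = float("nan"), float("nan")
        logger.warning("sharing fraction is constant across bins; rho undefined")
    else:
        rho, p = spearman(similarity, frac)
    return DistanceBinSummary(
        bin_edges=edges,
        pair_counts=counts,
        sharing_fractions=fractions,
        rho=rho,
        p_value=p,
        n_pairs=int(len(distances)),
        n_excluded_organisms=n_excluded,
        degenerate=degenerate,
    )
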