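"""Medium richness scoring and organism richness-preference prediction.

Richness is a weighted g/l sum of a medium's complex components plus a
configurable list of "rich" defined carbon compounds — a proxy for the
total nutritional carbon available. Media fall into low (<= 5 g/l),
medium (<= 15 g/l) and high (> 15 g/l) classes; an organism's preferred
class is the one whose predicted media accumulate the largest summed
collaborative score.

Default category weights are 1.0 per g/l and the rich defined-compound
list covers the common sugars; both are configuration, not canon — real
deployments should supply their own weight table.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._stats import rank_sum_test
from .core import GrowthDatabase, MediarecError, MediumVariant
from .recommend import CollabPrediction

RICHNESS_CLASSES = ("low", "medium", "high")

#: molar masses (g/mol) of defined compounds counted toward richness
DEFAULT_RICH_DEFINED: dict[str, float] = {
    "glucose": 180.16,
    "sucrose": 342.30,
    "lactose": 342.30,
    "xylose": 150.13,
    "glycerol": 92.09,
}


@dataclass(frozen=True)
class RichnessConfig:
    """Weights and cutoffs for the richness score.

    ``weights`` maps a complex category or rich defined compound to its g/l
    multiplier (default 1.0); ``low_cutoff`` / ``high_cutoff`` are the
    class boundaries in g/l, with a boundary score assigned to the lower
    class; ``rich_defined`` maps defined compound IDs counted toward
    richness to their molar mass so mol/l converts to g/l.
    """

    weights: Mapping[str, float] = field(default_factory=dict)
    default_weight: float = 1.0
    low_cutoff: float = 5.0
    high_cutoff: float = 15.0
    rich_defined: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RICH_DEFINED)
    )

    def __post_init__(self) -> None:
        if not 0 < self.low_cutoff < self.high_cutoff:
            raise MediarecError("cutoffs must be positive and ordered")

    def weight(self, component_id: str) -> float:
        return self.weights.get(component_id, self.default_weight)


@dataclass(frozen=True)
class RichnessClass:
    label: str
    score: float  # weighted g/l sum

    def __post_init__(self) -> None:
        if self.label not in RICHNESS_CLASSES:
            raise MediarecError(f"label must be one of {RICHNESS_CLASSES}")


def medium_richness(
    medium: MediumVariant, cfg: RichnessConfig | None = None
) -> RichnessClass:
    """Weighted rich-component g/l sum and the class it falls into."""
    cfg = cfg or RichnessConfig()
    score = 0.0
    for c in medium.components:
        if c.kind == "complex":
            score += cfg.weight(c.component_id) * c.amount
        elif c.kind == "defined" and c.component_id in cfg.rich_defined:
            g_per_l = c.amount * cfg.rich_defined[c.component_id]
            score += cfg.weight(c.component_id) * g_per_l
    if score <= cfg.low_cutoff:
        label = "low"
    elif score <= cfg.high_cutoff:
        label = "medium"
    else:
        label = "high"
    return RichnessClass(label=label, score=score)


def classify_media(
    media: Mapping[str, MediumVariant], cfg: RichnessConfig | None = None
) -> dict[str, RichnessClass]:
    return {mid: medium_richness(m, cfg) for mid, m in media.items()}


def organism_richness_preference(
    org: str,
    predictions: Sequence[CollabPrediction],
    media_classes: Mapping[str, RichnessClass | str],
) -> str:
    """Richness class with the highest summed collaborative score.

    ``predictions`` should already be salt/oxygen-filtered and, being
    collaborative predictions, never use the organism's own pairings.
    Ties break toward the lower richness class (conservative toward
    minimal media); an organism with no predictions returns "unknown".
    """
    sums = {c: 0.0 for c in RICHNESS_CLASSES}
    any_pred = False
    for p in predictions:
        if p.organism != org:
            continue
        cls = media_classes.get(p.medium)
        if cls is None:
            continue
        label = cls.label if isinstance(cls, RichnessClass) else cls
        sums[label] += p.score
        any_pred = True
    if not any_pred:
        return "unknown"
    return max(RICHNESS_CLASSES, key=lambda c: (sums[c], -RICHNESS_CLASSES.index(c)))


def gold_standard_preferences(
    db: GrowthDatabase, media_classes: Mapping[str, RichnessClass | str]
) -> dict[str, str]:
    """Organisms whose every known medium shares one richness class.

    Organisms with mixed classes, no pairings, or unclassified media are
    omitted — a partial gold standard, exactly as strict as the data.
    """
    out: dict[str, str] = {}
    for org in db.organisms:
        media = db.media_of(org)
        labels = set()
        for m in media:
            cls = media_classes.get(m)
            if cls is None:
                labels = set()
                break
            labels.add(cls.label if isinstance(cls, RichnessClass) else cls)
        if len(labels) == 1:
            out[org] = next(iter(labels))
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    statistic: float
    p_value: float
    direction: str  # "higher_with" | "higher_without" | "none"
    n_with: int
    n_without: int


def category_enrichment(
    media_scores: Mapping[str, float],
    media_categories: Mapping[str, Iterable[str]],
    category: str,
) -> EnrichmentResult:
    """Rank-sum test of collaborative scores, media containing vs lacking a
    component category.

    Two-sided Wilcoxon rank-sum on the scores of media whose component set
    includes the category against those whose does not; the direction
    reports which group scored higher. Either group empty is an error.
    """
    with_cat, without = [], []
    for mid, score in media_scores.items():
        cats = set(media_categories.get(mid, ()))
        (with_cat if category in cats else without).append(score)
    if not with_cat or not without:
        raise MediarecError(
            f"category {category!r}: both groups must be non-empty "
            f"(n_with={len(with_cat)}, n_without={len(without)})"
        )
    stat, p = rank_sum_test(with_cat, without)
    mean_with = sum(with_cat) / len(with_cat)
    mean_without = sum(without) / len(without)
    if mean_with > mean_without:
        direction = "higher_with"
    elif mean_with < mean_without:
        direction = "higher_without"
    else:
        direction = "none"
    return EnrichmentResult(
        statistic=stat,
        p_value=p,
        direction=direction,
        n_with=len(with_cat),
        n_without=len(without),
    )


def media_component_categories(
    media: Mapping[str, MediumVariant],
    category_map: Mapping[str, str] | None = None,
) -> dict[str, frozenset[str]]:
    """Component categories present in each medium.

    Complex components contribute their category tag directly; defined
    components map through ``category_map`` (compound ID -> category) when
    given.
    """
    category_map = category_map or {}
    out = {}
    for mid, m in media.items():
        cats = set()
        for c in m.components:
            if c.kind == "complex":
                cats.add(c.component_id)
            else:
                cat = category_map.get(c.component_id)
                if cat:
                    cats.add(cat)
        out[mid] = frozenset(cats)
    return out
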