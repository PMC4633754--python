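"""Core domain types shared across the package.

The objects here model a positive-only culture collection: media with
standardized compositions, an organism-by-medium growth relation in which
only confirmed growth is recorded (absence of a pairing carries no negative
evidence), a rooted taxonomy over the organisms, and an optional
organism-by-environment co-occurrence table.
"""
from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

COMPOUND_CLASSES = ("defined", "complex", "other")
OXYGEN_STATUSES = ("aerobic", "anaerobic", "unknown")
VOLUME_MODES = ("fill", "scale")

#: kinds a compiled medium component can have
COMPONENT_KINDS = ("defined", "complex", "trace", "gas_substrate")


class MediarecError(ValueError):
    """Base class for domain errors raised by this package."""


class UnknownEntityError(MediarecError, KeyError):
    """An organism or medium ID was used without being registered."""


@dataclass(frozen=True)
class CompoundRecord:
    """Maps a raw ingredient name to its constituent compounds.

    Parameters
    ----------
    raw_name : str
        Ingredient name as it appears in recipes (e.g. ``"CaCl2 x 2 H2O"``).
    semi_unique_name : str
        Normalized name shared by all spellings/hydrates of the compound.
    constituents : tuple of (str, int)
        Constituent compound IDs with their molar ratios. One mole of the
        raw compound contributes ``ratio`` moles of each constituent.
        Empty for complex (undefined) components.
    n_waters : int
        Hydrate waters attached to the raw form.
    molecular_weight : float or None
        g/mol of the raw form *including* hydrate waters; required for any
        compound that must be converted from grams to moles.
    compound_class : {"defined", "complex", "other"}
        ``complex`` components (peptone, extracts, ...) have no constituents
        and carry a ``category`` tag instead.
    category : str or None
        Complex-component category (e.g. ``"complex-meat"``).
    """

    raw_name: str
    semi_unique_name: str
    constituents: tuple[tuple[str, int], ...] = ()
    n_waters: int = 0
    molecular_weight: float | None = None
    compound_class: str = "defined"
    category: str | None = None

    def __post_init__(self) -> None:
        if self.compound_class not in COMPOUND_CLASSES:
            raise MediarecError(
                f"compound_class must be one of {COMPOUND_CLASSES}, "
                f"got {self.compound_class!r}"
            )
        if self.compound_class == "complex":
            if self.constituents:
                raise MediarecError(
                    f"complex compound {self.raw_name!r} cannot have constituents"
                )
            if not self.category:
                raise MediarecError(
                    f"complex compound {self.raw_name!r} requires a category tag"
                )
        else:
            if not 1 <= len(self.constituents) <= 3:
                raise MediarecError(
                    f"compound {self.raw_name!r} must map to 1-3 constituents, "
                    f"got {len(self.constituents)}"
                )
            if any(r <= 0 for _, r in self.constituents):
                raise MediarecError(
                    f"compound {self.raw_name!r} has a non-positive molar ratio"
                )
        if self.n_waters < 0:
            raise MediarecError("n_waters must be non-negative")
        if self.molecular_weight is not None and self.molecular_weight <= 0:
            raise MediarecError("molecular_weight must be positive")


@dataclass(frozen=True)
class CompiledComponent:
    """One component of a compiled medium, at the constituent level.

    ``defined`` components carry mol/l, ``complex`` ones g/l under their
    category tag, and ``trace`` / ``gas_substrate`` entries are flags with
    no numeric concentration.
    """

    component_id: str
    kind: str
    amount: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in COMPONENT_KINDS:
            raise MediarecError(f"unknown component kind {self.kind!r}")
        if self.kind in ("trace", "gas_substrate"):
            if self.amount is not None:
                raise MediarecError(
                    f"{self.kind} component {self.component_id!r} "
                    "must not carry a concentration"
                )
        else:
            if self.amount is None or self.amount < 0:
                raise MediarecError(
                    f"component {self.component_id!r} needs a non-negative amount"
                )


@dataclass
class MediumVariant:
    """A medium identity with resolved per-component concentrations."""

    medium_id: str
    name: str = ""
    components: list[CompiledComponent] = field(default_factory=list)
    ph: float | None = None
    volume_mode: str = "fill"
    oxygen_status: str = "unknown"

    def __post_init__(self) -> None:
        if self.ph is not None and not 0.0 <= self.ph <= 14.0:
            raise MediarecError(f"pH {self.ph} outside [0, 14]")
        if self.volume_mode not in VOLUME_MODES:
            raise MediarecError(f"volume_mode must be one of {VOLUME_MODES}")
        if self.oxygen_status not in OXYGEN_STATUSES:
            raise MediarecError(f"oxygen_status must be one of {OXYGEN_STATUSES}")

    @property
    def is_defined(self) -> bool:
        """True when the medium has no complex-class component."""
        return all(c.kind != "complex" for c in self.components)

    def component_ids(self) -> frozenset[str]:
        """Identifiers of all components (constituents, categories, flags)."""
        return frozenset(c.component_id for c in self.components)

    def amount_of(self, component_id: str) -> float | None:
        for c in self.components:
            if c.component_id == component_id:
                return c.amount
        return None


class GrowthDatabase:
    """Sparse positive-only organism x media growth relation.

    Only confirmed growth pairings are stored; a missing pairing means
    "untested", never "no growth".
    """

    def __init__(
        self,
        organisms: Iterable[str] = (),
        media: Iterable[str] = (),
        pairings: Iterable[tuple[str, str]] = (),
    ) -> None:
        self._org_media: dict[str, set[str]] = {o: set() for o in organisms}
        self._med_orgs: dict[str, set[str]] = {m: set() for m in media}
        for org, med in pairings:
            self.add_pairing(org, med)

    # -- registration ------------------------------------------------------
    def add_organism(self, organism: str) -> "GrowthDatabase":
        self._org_media.setdefault(organism, set())
        return self

    def add_medium(self, medium: str) -> "GrowthDatabase":
        self._med_orgs.setdefault(medium, set())
        return self

    def add_pairing(self, organism: str, medium: str) -> "GrowthDatabase":
        """Record a positive growth pairing. Idempotent.

        Both IDs must already be registered (``add_organism`` /
        ``add_medium``); an unknown ID raises :class:`UnknownEntityError`
        naming the missing entity.
        """
        if organism not in self._org_media:
            raise UnknownEntityError(f"unknown organism {organism!r}")
        if medium not in self._med_orgs:
            raise UnknownEntityError(f"unknown medium {medium!r}")
        self._org_media[organism].add(medium)
        self._med_orgs[medium].add(organism)
        return self

    # -- accessors ---------------------------------------------------------
    @property
    def organisms(self) -> frozenset[str]:
        return frozenset(self._org_media)

    @property
    def media(self) -> frozenset[str]:
        return frozenset(self._med_orgs)

    @property
    def pairings(self) -> frozenset[tuple[str, str]]:
        return frozenset(
            (o, m) for o, ms in self._org_media.items() for m in ms
        )

    @property
    def n_pairings(self) -> int:
        return sum(len(ms) for ms in self._org_media.values())

    def has_pairing(self, organism: str, medium: str) -> bool:
        return medium in self._org_media.get(organism, ())

    def media_of(self, organism: str) -> frozenset[str]:
        if organism not in self._org_media:
            raise UnknownEntityError(f"unknown organism {organism!r}")
        return frozenset(self._org_media[organism])

    def organisms_of(self, medium: str) -> frozenset[str]:
        if medium not in self._med_orgs:
            raise UnknownEntityError(f"unknown medium {medium!r}")
        return frozenset(self._med_orgs[medium])

    def popularity(self, entity: str) -> int:
        """Number of pairings touching ``entity`` (an organism or a medium).

        An ID registered both as organism and medium is ambiguous and
        rejected; use :meth:`media_of` / :meth:`organisms_of` instead.
        """
        is_org = entity in self._org_media
        is_med = entity in self._med_orgs
        if is_org and is_med:
            raise MediarecError(
                f"{entity!r} is both an organism and a medium; "
                "query media_of/organisms_of explicitly"
            )
        if is_org:
            return len(self._org_media[entity])
        if is_med:
            return len(self._med_orgs[entity])
        raise UnknownEntityError(f"unknown entity {entity!r}")

    def filter_media(self, min_organisms: int, max_organisms: int) -> "GrowthDatabase":
        """Restrict to media hosting between min and max organisms (inclusive).

        All organisms stay registered; only pairings through retained media
        survive.
        """
        keep = {
            m for m, orgs in self._med_orgs.items()
            if min_organisms <= len(orgs) <= max_organisms
        }
        out = GrowthDatabase(organisms=self._org_media, media=keep)
        for m in keep:
            for o in self._med_orgs[m]:
                out.add_pairing(o, m)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GrowthDatabase):
            return NotImplemented
        return (
            self.organisms == other.organisms
            and self.media == other.media
            and self.pairings == other.pairings
        )

    def __repr__(self) -> str:
        return (
            f"GrowthDatabase({len(self._org_media)} organisms, "
            f"{len(self._med_orgs)} media, {self.n_pairings} pairings)"
        )

    # -- IO ----------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write the relation as two-column TSV (organism_id, medium_id).

        Entities without pairings are kept via sentinel rows with an empty
        partner column so the relation round-trips losslessly.
        """
        rows = sorted(self.pairings)
        lonely_orgs = sorted(o for o, ms in self._org_media.items() if not ms)
        lonely_media = sorted(m for m, os_ in self._med_orgs.items() if not os_)
        df = pd.DataFrame(
            rows + [(o, "") for o in lonely_orgs] + [("", m) for m in lonely_media],
            columns=["organism_id", "medium_id"],
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GrowthDatabase":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if list(df.columns[:2]) != ["organism_id", "medium_id"]:
            raise MediarecError(
                "growth table must have header columns organism_id, medium_id"
            )
        db = cls()
        for org, med in zip(df["organism_id"], df["medium_id"]):
            if org:
                db.add_organism(org)
            if med:
                db.add_medium(med)
            if org and med:
                db.add_pairing(org, med)
        return db


class TaxonomyTree:
    """Rooted taxonomy whose leaves are organism IDs.

    Supports the subtree distance used throughout the package: the number
    of leaves beneath the lowest common ancestor of two organisms divided
    by the total number of leaves, a value in (0, 1].
    """

    def __init__(self, paths: Mapping[str, tuple[int, ...]], leaf_counts: Sequence[int]):
        self._paths = dict(paths)
        self._leaf_counts = list(leaf_counts)
        self.total_leaves = len(self._paths)
        if self.total_leaves == 0:
            raise MediarecError("taxonomy tree has no leaves")

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, source: str | Path) -> "TaxonomyTree":
        """Build from a Newick string or file path (leaf labels = organism IDs)."""
        import skbio

        if isinstance(source, Path) or (
            isinstance(source, str) and "(" not in source
        ):
            tree = skbio.TreeNode.read(str(source))
        else:
            tree = skbio.TreeNode.read(io.StringIO(source))
        return cls._from_skbio(tree)

    @classmethod
    def _from_skbio(cls, root) -> "TaxonomyTree":
        paths: dict[str, tuple[int, ...]] = {}
        leaf_counts: list[int] = []

        def walk(node, prefix: tuple[int, ...]) -> int:
            idx = len(leaf_counts)
            leaf_counts.append(0)
            path = prefix + (idx,)
            if node.is_tip():
                name = str(node.name)
                if name in paths:
                    raise MediarecError(f"duplicate leaf label {name!r}")
                paths[name] = path
                leaf_counts[idx] = 1
                return 1
            n = sum(walk(c, path) for c in node.children)
            leaf_counts[idx] = n
            return n

        walk(root, ())
        return cls(paths, leaf_counts)

    @classmethod
    def from_parent_child(cls, table: Iterable[tuple[str, str]]) -> "TaxonomyTree":
        """Build from (parent, child) rows; the root is the parent never a child."""
        children: dict[str, list[str]] = {}
        seen_child: set[str] = set()
        nodes: set[str] = set()
        for parent, child in table:
            children.setdefault(parent, []).append(child)
            seen_child.add(child)
            nodes.update((parent, child))
        roots = [n for n in nodes if n not in seen_child]
        if len(roots) != 1:
            raise MediarecError(f"expected exactly one root, found {sorted(roots)}")

        paths: dict[str, tuple[int, ...]] = {}
        leaf_counts: list[int] = []

        def walk(name: str, prefix: tuple[int, ...]) -> int:
            idx = len(leaf_counts)
            leaf_counts.append(0)
            path = prefix + (idx,)
            kids = children.get(name, [])
            if not kids:
                if name in paths:
                    raise MediarecError(f"duplicate leaf label {name!r}")
                paths[name] = path
                leaf_counts[idx] = 1
                return 1
            n = sum(walk(k, path) for k in kids)
            leaf_counts[idx] = n
            return n

        walk(roots[0], ())
        return cls(paths, leaf_counts)

    # -- queries -----------------------------------------------------------
    @property
    def leaves(self) -> frozenset[str]:
        return frozenset(self._paths)

    def __contains__(self, organism: str) -> bool:
        return organism in self._paths

    def lca_leaf_count(self, a: str, b: str) -> int:
        """Leaves beneath the lowest common ancestor of ``a`` and ``b``."""
        try:
            pa, pb = self._paths[a], self._paths[b]
        except KeyError as exc:
            raise UnknownEntityError(f"organism {exc.args[0]!r} not in tree") from None
        lca = pa[0]
        for x, y in zip(pa, pb):
            if x != y:
                break
            lca = x
        return self._leaf_counts[lca]

    def subtree_distance(self, a: str, b: str) -> float:
        """Normalized subtree distance in (0, 1]; symmetric; 1/total for a==b."""
        return self.lca_leaf_count(a, b) / self.total_leaves


class EnvironmentTable:
    """Mapping organism ID -> set of environment IDs (possibly empty)."""

    def __init__(self, mapping: Mapping[str, Iterable[str]] | None = None):
        self._envs: dict[str, frozenset[str]] = {
            o: frozenset(es) for o, es in (mapping or {}).items()
        }

    def environments_of(self, organism: str) -> frozenset[str]:
        if organism not in self._envs:
            raise UnknownEntityError(f"organism {organism!r} not in environment table")
        return self._envs[organism]

    def __contains__(self, organism: str) -> bool:
        return organism in self._envs

    @property
    def organisms(self) -> frozenset[str]:
        return frozenset(self._envs)

    def to_tsv(self, path: str | Path) -> None:
        rows = sorted(
            (o, e) for o, es in self._envs.items() for e in es
        ) + [(o, "") for o, es in sorted(self._envs.items()) if not es]
        pd.DataFrame(rows, columns=["organism_id", "environment_id"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EnvironmentTable":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        mapping: dict[str, set[str]] = {}
        for org, env in zip(df["organism_id"], df["environment_id"]):
            mapping.setdefault(org, set())
            if env:
                mapping[org].add(env)
        return cls(mapping)


def organisms_in_tree(db: GrowthDatabase, tree: TaxonomyTree) -> frozenset[str]:
    """Database organisms mapped to tree leaves; the rest are logged and excluded.

    Organisms in the growth database but absent from the taxonomy stay in
    the database, but phylogeny-based operations ignore them.
    """
    present = frozenset(o for o in db.organisms if o in tree)
    missing = db.organisms - present
    if missing:
        logger.warning(
            "%d organism(s) absent from the taxonomy are excluded from "
            "phylogeny-based operations: %s",
            len(missing),
            ", ".join(sorted(missing)[:5]) + ("..." if len(missing) > 5 else ""),
        )
    return present
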