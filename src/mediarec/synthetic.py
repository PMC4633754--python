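"""Synthetic study systems: taxonomy, media, growth relations, environments.

Every predictor in this package is exercised against generated data with
controlled structure: a balanced taxonomy whose clades hold planted media
preferences, media whose compositions realize planted salt / oxygen /
richness classes, and a positive-only growth relation in which each
pairing is inherited from the organism's clade preference with probability
``signal`` and drawn uniformly from all media otherwise. At signal 1 every
pairing follows the clade preference (so organism salt/oxygen classes are
consistent with their media by construction); at signal 0 pairings are
independent of the taxonomy. A ground-truth ledger records everything
planted, so recovery tests need no hidden state.

A separate constructor plants transitive structure with an exactly known
positive fraction, from two block types whose pattern sets are fully
enumerable: 3-organism x 3-media cliques (every transitive pattern
positive) and 7-organism chains (exactly 4 patterns, all negative).
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CompiledComponent,
    EnvironmentTable,
    GrowthDatabase,
    MediarecError,
    MediumVariant,
    TaxonomyTree,
)
from .recipes import write_media_table

NACL_MOLAR_MASS = 58.44
GLUCOSE_MOLAR_MASS = 180.16

_TRACE_POOL = ("Fe2+", "Zn2+", "Mn2+", "Co2+", "Cu2+", "MoO4^2-")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the generator.

    ``signal`` is the probability that a pairing is inherited from the
    organism's clade-level media preference rather than drawn uniformly
    from all media.
    """

    n_organisms: int = 128
    n_media: int = 64
    clade_size: int = 8
    media_per_clade: int = 4
    pairings_per_organism: int = 3
    signal: float = 0.75
    fraction_anaerobic: float = 0.3
    fraction_salty: float = 0.25
    richness_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    n_environments: int = 24
    envs_per_clade: int = 3
    env_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.signal <= 1.0:
            raise MediarecError("signal must be in [0, 1]")
        for name in ("fraction_anaerobic", "fraction_salty", "env_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise MediarecError(f"{name} must be in [0, 1]")
        if self.n_organisms < 2 * self.clade_size:
            raise MediarecError("need at least two clades of organisms")
        if self.pairings_per_organism < 1:
            raise MediarecError("each organism needs at least one pairing")
        if abs(sum(self.richness_mix) - 1.0) > 1e-9:
            raise MediarecError("richness_mix must sum to 1")


@dataclass
class SyntheticDataset:
    tree: TaxonomyTree
    newick: str
    media: dict[str, MediumVariant]
    media_oxygen: dict[str, str]
    db: GrowthDatabase
    environments: EnvironmentTable
    truth: dict


def _balanced_newick(leaves: list[str]) -> str:
    if len(leaves) == 1:
        return leaves[0]
    mid = (len(leaves) + 1) // 2
    return f"({_balanced_newick(leaves[:mid])},{_balanced_newick(leaves[mid:])})"


def _make_medium(
    mid: str,
    rng: np.random.Generator,
    salty: bool,
    oxygen: str,
    richness: str,
    sea_name: bool = False,
) -> MediumVariant:
    components: list[CompiledComponent] = []
    nacl = 25.0 if salty else 2.0
    mol = nacl / NACL_MOLAR_MASS
    components.append(CompiledComponent("Na+", "defined", mol))
    components.append(CompiledComponent("Cl-", "defined", mol))
    components.append(CompiledComponent("K+", "defined", 0.01))
    components.append(CompiledComponent("HPO4^2-", "defined", 0.01))
    if richness == "low":
        components.append(
            CompiledComponent("glucose", "defined", 2.0 / GLUCOSE_MOLAR_MASS)
        )
    elif richness == "medium":
        components.append(CompiledComponent("complex-meat", "complex", 8.0))
        components.append(
            CompiledComponent("glucose", "defined", 2.0 / GLUCOSE_MOLAR_MASS)
        )
    else:
        components.append(CompiledComponent("complex-yeast", "complex", 18.0))
        components.append(CompiledComponent("complex-meat", "complex", 4.0))
    for t in rng.choice(len(_TRACE_POOL), size=2, replace=False):
        components.append(CompiledComponent(_TRACE_POOL[t], "defined", 1e-5))
    name = f"synthetic sea water {mid}" if sea_name else f"synthetic medium {mid}"
    return MediumVariant(
        medium_id=mid,
        name=name,
        components=components,
        ph=round(float(rng.uniform(6.0, 8.0)), 2),
        oxygen_status=oxygen,
    )


def generate(cfg: SynthConfig) -> SyntheticDataset:
    """Generate a full synthetic study system. Reproducible under cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    width = max(4, len(str(cfg.n_organisms)))
    organisms = [f"org{str(i).zfill(width)}" for i in range(cfg.n_organisms)]
    newick = _balanced_newick(organisms) + ";"
    tree = TaxonomyTree.from_newick(newick)

    n_clades = cfg.n_organisms // cfg.clade_size
    clades = [
        organisms[i * cfg.clade_size : (i + 1) * cfg.clade_size]
        for i in range(n_clades)
    ]
    leftover = organisms[n_clades * cfg.clade_size :]
    if leftover:  # tail organisms join the last clade
        clades[-1] = clades[-1] + leftover

    if cfg.n_media < n_clades * cfg.media_per_clade:
        raise MediarecError(
            f"infeasible config: {cfg.n_media} media cannot give "
            f"{n_clades} clades {cfg.media_per_clade} preferred media each"
        )

    # clade-level planted attributes
    clade_profile = []
    labels = ("low", "medium", "high")
    for i in range(n_clades):
        clade_profile.append(
            {
                "oxygen": "anaerobic"
                if rng.random() < cfg.fraction_anaerobic
                else "aerobic",
                "salt": "high" if rng.random() < cfg.fraction_salty else "low",
                "richness": labels[
                    int(rng.choice(3, p=np.asarray(cfg.richness_mix)))
                ],
            }
        )

    # media: preferred sets realize the owning clade's profile; the rest
    # are background with random profiles
    media: dict[str, MediumVariant] = {}
    media_oxygen: dict[str, str] = {}
    media_class: dict[str, str] = {}
    clade_media: dict[int, list[str]] = {}
    mwidth = max(3, len(str(cfg.n_media)))
    counter = 0
    n_salty_named = 0

    def new_medium(salty: bool, oxygen: str, richness: str) -> str:
        nonlocal counter, n_salty_named
        mid = f"m{str(counter).zfill(mwidth)}"
        counter += 1
        sea_name = salty and (n_salty_named % 3 == 0)
        if salty:
            n_salty_named += 1
        medium = _make_medium(mid, rng, salty, oxygen, richness, sea_name)
        media[mid] = medium
        media_oxygen[mid] = oxygen
        media_class[mid] = richness
        return mid

    for i, profile in enumerate(clade_profile):
        clade_media[i] = [
            new_medium(profile["salt"] == "high", profile["oxygen"], profile["richness"])
            for _ in range(cfg.media_per_clade)
        ]
    while counter < cfg.n_media:
        new_medium(
            bool(rng.random() < cfg.fraction_salty),
            "anaerobic" if rng.random() < cfg.fraction_anaerobic else "aerobic",
            labels[int(rng.choice(3, p=np.asarray(cfg.richness_mix)))],
        )
    all_media = sorted(media)

    # growth relation
    db = GrowthDatabase(organisms=organisms, media=all_media)
    clade_of: dict[str, int] = {}
    for ci, clade in enumerate(clades):
        for org in clade:
            clade_of[org] = ci
            drawn: set[str] = set()
            while len(drawn) < cfg.pairings_per_organism:
                if rng.random() < cfg.signal:
                    mid = clade_media[ci][rng.integers(len(clade_media[ci]))]
                else:
                    mid = all_media[rng.integers(len(all_media))]
                drawn.add(mid)
            for mid in sorted(drawn):
                db.add_pairing(org, mid)

    # environments: clade-level habitats plus noise
    env_ids = [f"env{str(i).zfill(2)}" for i in range(cfg.n_environments)]
    clade_envs = {
        i: sorted(
            env_ids[j]
            for j in rng.choice(
                cfg.n_environments, size=cfg.envs_per_clade, replace=False
            )
        )
        for i in range(n_clades)
    }
    env_map: dict[str, set[str]] = {}
    for org in organisms:
        envs = set(clade_envs[clade_of[org]])
        if rng.random() < cfg.env_noise:
            envs.add(env_ids[rng.integers(cfg.n_environments)])
        env_map[org] = envs
    environments = EnvironmentTable(env_map)

    truth = {
        "config": asdict(cfg),
        "clade_of": clade_of,
        "clades": [list(c) for c in clades],
        "clade_profile": clade_profile,
        "clade_media": {str(k): v for k, v in clade_media.items()},
        "media_class": media_class,
        "media_oxygen": media_oxygen,
        "clade_envs": {str(k): v for k, v in clade_envs.items()},
    }
    return SyntheticDataset(
        tree=tree,
        newick=newick,
        media=media,
        media_oxygen=media_oxygen,
        db=db,
        environments=environments,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write all artifacts as plain-text files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": outdir / "tree.nwk",
        "growth": outdir / "growth.tsv",
        "media": outdir / "media.tsv",
        "media_meta": outdir / "media_meta.tsv",
        "environments": outdir / "environments.tsv",
        "truth": outdir / "truth.json",
    }
    paths["tree"].write_text(dataset.newick + "\n")
    dataset.db.to_tsv(paths["growth"])
    write_media_table(
        [dataset.media[m] for m in sorted(dataset.media)], paths["media"]
    )
    pd.DataFrame(
        [
            (m, dataset.media_oxygen[m], dataset.media[m].name)
            for m in sorted(dataset.media)
        ],
        columns=["medium_id", "oxygen_status", "name"],
    ).to_csv(paths["media_meta"], sep="\t", index=False)
    dataset.environments.to_tsv(paths["environments"])
    paths["truth"].write_text(json.dumps(dataset.truth, indent=1, sort_keys=True))
    return paths


# ---------------------------------------------------------------------------
# Planted transitivity
# ---------------------------------------------------------------------------
def plant_transitivity(
    f: float, min_patterns: int = 1200, seed: int | None = None
) -> tuple[GrowthDatabase, dict]:
    """Growth database whose transitive patterns are positive with exact
    fraction ``f``.

    Built from disjoint blocks: cliques of 3 organisms x 3 media (all 36
    patterns per block positive, since every organism is documented on
    every block medium) and 7-organism chains contributing exactly 4
    patterns each, all negative. With Nc cliques and Nn chains the positive
    fraction of the pattern universe is 36 Nc / (36 Nc + 4 Nn); block
    counts are chosen from the rational approximation of ``f`` so the
    planted fraction is exact, and scaled until at least ``min_patterns``
    patterns exist. Any uniform pattern miner then recovers ``f`` within
    sampling error. The returned ledger records the realized fraction and
    pattern counts.
    """
    if not 0.0 <= f <= 1.0:
        raise MediarecError("planted fraction must be in [0, 1]")
    fr = Fraction(f).limit_denominator(1000)
    p, q = fr.numerator, fr.denominator
    n_clique_unit, n_chain_unit = p, 9 * (q - p)
    per_set = 36 * p + 4 * n_chain_unit  # = 36 q patterns per unit set
    m = max(1, math.ceil(min_patterns / per_set))
    n_cliques, n_chains = m * n_clique_unit, m * n_chain_unit

    db = GrowthDatabase()
    org_counter = med_counter = 0

    def new_org() -> str:
        nonlocal org_counter
        oid = f"torg{org_counter:05d}"
        org_counter += 1
        db.add_organism(oid)
        return oid

    def new_med() -> str:
        nonlocal med_counter
        mid = f"tm{med_counter:05d}"
        med_counter += 1
        db.add_medium(mid)
        return mid

    for _ in range(n_cliques):
        orgs = [new_org() for _ in range(3)]
        meds = [new_med() for _ in range(3)]
        for o in orgs:
            for md in meds:
                db.add_pairing(o, md)
    for _ in range(n_chains):
        a, a2, b, c, qq, r, s = (new_org() for _ in range(7))
        m1, m2, m3 = (new_med() for _ in range(3))
        for o in (a, a2, b):
            db.add_pairing(o, m1)
        for o in (b, c, qq):
            db.add_pairing(o, m2)
        for o in (c, r, s):
            db.add_pairing(o, m3)

    n_pos = 36 * n_cliques
    n_total = n_pos + 4 * n_chains
    truth = {
        "requested_fraction": f,
        "planted_fraction": n_pos / n_total if n_total else float("nan"),
        "n_patterns": n_total,
        "n_positive_patterns": n_pos,
        "n_cliques": n_cliques,
        "n_chains": n_chains,
        "seed": seed,
    }
    return db, truth
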