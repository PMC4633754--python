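"""Recipe compiler: tagged recipe text -> standardized molar compositions.

Culture-media recipes arrive as semi-structured text: ingredient lines with
heterogeneous units, pH and strain-variant instructions as ``/tag/`` lines,
declared (or undeclared) final volumes, and cross-references to submedia
such as trace-element solutions that must be recursively unpacked. The
compiler turns one recipe (plus its referenced recipes and a compound
table) into a :class:`~mediarec.core.MediumVariant` whose defined
components are in mol/l, complex components in g/l, and trace / gas
entries flagged without a concentration.

Dialect
-------
One statement per line; ``#`` starts a comment::

    /ph/ 7.2
    NaCl @ 5 g
    /notag/ CaCl2 x 2 H2O @ 10 mg
    ref: M2 @ 100 ml
    volume: 0.5 l
    /rm/ NaCl                  # variant instruction: remove a compound
    /conc/ glucose @ 10 g      # variant instruction: reset a concentration
    /replace/ NaCl => KCl      # variant instruction: swap compounds

The ``/rm/``, ``/conc/`` and ``/replace/`` tags are captured during parsing
and can be expanded into medium variants (one variant per instruction, IDs
suffixed ``base.1``, ``base.2``, ...), mirroring how strain-specific
instructions in a culture catalogue nearly double the number of distinct
media.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import (
    CompiledComponent,
    CompoundRecord,
    MediarecError,
    MediumVariant,
)

KNOWN_TAGS = ("ph", "replace", "conc", "rm", "notag")


class RecipeError(MediarecError):
    """Raised for unparseable or inconsistent recipe input."""


# ---------------------------------------------------------------------------
# Units
# ---------------------------------------------------------------------------
# kind semantics (value after multiplying by the factor):
#   mass      -> grams          volume   -> litres (of an individual compound)
#   mole      -> moles          conc_g   -> g per litre
#   conc_mol  -> mol per litre  conc_l   -> litre per litre
#   trace / gas_substrate       -> flags, no numeric value
DEFAULT_UNIT_MAP: dict[str, tuple[str, float]] = {
    "ng": ("mass", 1e-9),
    "ug": ("mass", 1e-6),
    "µg": ("mass", 1e-6),
    "mg": ("mass", 1e-3),
    "g": ("mass", 1.0),
    "kg": ("mass", 1e3),
    "ul": ("volume", 1e-6),
    "µl": ("volume", 1e-6),
    "ml": ("volume", 1e-3),
    "l": ("volume", 1.0),
    "nmol": ("mole", 1e-9),
    "umol": ("mole", 1e-6),
    "µmol": ("mole", 1e-6),
    "mmol": ("mole", 1e-3),
    "mol": ("mole", 1.0),
    "nM": ("conc_mol", 1e-9),
    "uM": ("conc_mol", 1e-6),
    "µM": ("conc_mol", 1e-6),
    "mM": ("conc_mol", 1e-3),
    "M": ("conc_mol", 1.0),
    "mol/l": ("conc_mol", 1.0),
    "mmol/l": ("conc_mol", 1e-3),
    "ug/l": ("conc_g", 1e-6),
    "mg/l": ("conc_g", 1e-3),
    "g/l": ("conc_g", 1.0),
    "mg/ml": ("conc_g", 1.0),
    "g/100ml": ("conc_g", 10.0),
    "%": ("conc_g", 10.0),  # mass/volume percent: 1% = 10 g/l
    "ml/l": ("conc_l", 1e-3),
    "ul/l": ("conc_l", 1e-6),
    "l/l": ("conc_l", 1.0),
    "trace": ("trace", 1.0),
    "gas": ("gas_substrate", 1.0),
    "gas_substrate": ("gas_substrate", 1.0),
}

#: grams per litre of compound volume under the 1 g = 1 ml density convention
GRAMS_PER_LITRE = 1000.0


# ---------------------------------------------------------------------------
# Parsed representation
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class IngredientLine:
    raw_name: str
    amount: float
    raw_unit: str


@dataclass
class RawRecipe:
    """A parsed, still-unconverted recipe."""

    medium_id: str
    lines: list[IngredientLine] = field(default_factory=list)
    tags: list[tuple[str, str]] = field(default_factory=list)
    referenced_media: list[tuple[str, float, str]] = field(default_factory=list)
    declared_volume: tuple[float, str] | None = None

    @property
    def ph(self) -> float | None:
        for tag, payload in self.tags:
            if tag == "ph":
                return float(payload)
        return None


@dataclass(frozen=True)
class VariantInstruction:
    """An ordered list of edits deriving one variant from a base recipe.

    Edits are tuples: ``("replace", old, new)``,
    ``("set_concentration", name, amount, unit)``, ``("remove", name)``,
    ``("set_ph", value)``, ``("add", name, amount, unit)``.
    """

    label: str
    edits: tuple[tuple, ...]


@dataclass(frozen=True)
class VolumeResolution:
    """fill: ignore the declared volume; scale: rescale composition to 1 l."""

    mode: str
    multiplier: float


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------
_INGREDIENT_RE = re.compile(r"^(?P<name>.+?)\s*@\s*(?P<amount>\S+)(?:\s+(?P<unit>\S+))?$")


def _parse_amount(text: str, lineno: int) -> float:
    try:
        value = float(text)
    except ValueError:
        raise RecipeError(f"line {lineno}: malformed amount {text!r}") from None
    if value < 0:
        raise RecipeError(f"line {lineno}: negative amount {text!r}")
    return value


def parse_recipe(text: str, medium_id: str = "M") -> RawRecipe:
    """Parse tagged recipe text into a :class:`RawRecipe`.

    The parse is total: every non-empty line is either captured or raises a
    :class:`RecipeError` naming the offending line; nothing is silently
    dropped.
    """
    recipe = RawRecipe(medium_id=medium_id)
    for lineno, raw_line in enumerate(text.splitlines(), start=1):
        line = raw_line.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("/"):
            m = re.match(r"^/([a-zA-Z_]+)/\s*(.*)$", line)
            if not m:
                raise RecipeError(f"line {lineno}: malformed tag line {line!r}")
            tag, payload = m.group(1).lower(), m.group(2).strip()
            if tag not in KNOWN_TAGS:
                raise RecipeError(f"line {lineno}: unknown tag /{tag}/")
            if tag == "notag":
                # a /notag/ prefix marks a plain ingredient line
                recipe.lines.append(_parse_ingredient(payload, lineno))
            elif tag == "ph":
                _parse_amount(payload, lineno)
                recipe.tags.append((tag, payload))
            else:
                recipe.tags.append((tag, payload))
            continue
        if line.lower().startswith("ref:"):
            body = line[4:].strip()
            m = _INGREDIENT_RE.match(body)
            if not m or not m.group("unit"):
                raise RecipeError(
                    f"line {lineno}: malformed reference {line!r} "
                    "(expected 'ref: <medium_id> @ <amount> <unit>')"
                )
            recipe.referenced_media.append(
                (
                    m.group("name"),
                    _parse_amount(m.group("amount"), lineno),
                    m.group("unit"),
                )
            )
            continue
        if line.lower().startswith("volume:"):
            body = line[7:].strip()
            parts = body.split()
            if len(parts) != 2:
                raise RecipeError(
                    f"line {lineno}: malformed volume declaration {line!r}"
                )
            recipe.declared_volume = (_parse_amount(parts[0], lineno), parts[1])
            continue
        recipe.lines.append(_parse_ingredient(line, lineno))
    return recipe


def _parse_ingredient(line: str, lineno: int) -> IngredientLine:
    m = _INGREDIENT_RE.match(line)
    if not m:
        raise RecipeError(
            f"line {lineno}: unparseable ingredient line {line!r} "
            "(expected 'name @ amount unit')"
        )
    unit = m.group("unit")
    if unit is None:
        raise RecipeError(f"line {lineno}: missing unit in {line!r}")
    return IngredientLine(
        raw_name=m.group("name"),
        amount=_parse_amount(m.group("amount"), lineno),
        raw_unit=unit,
    )


def variant_instructions_from_tags(recipe: RawRecipe) -> list[VariantInstruction]:
    """Turn captured /replace/ /conc/ /rm/ tag lines into variant instructions.

    Each tag line yields one single-edit variant, matching the catalogue
    convention of one strain-specific instruction per base medium.
    """
    instructions: list[VariantInstruction] = []
    for i, (tag, payload) in enumerate(
        t for t in recipe.tags if t[0] in ("replace", "conc", "rm")
    ):
        n = len(instructions) + 1
        if tag == "rm":
            edits: tuple[tuple, ...] = (("remove", payload.strip()),)
        elif tag == "replace":
            if "=>" not in payload:
                raise RecipeError(f"malformed /replace/ payload {payload!r}")
            old, new = (s.strip() for s in payload.split("=>", 1))
            edits = (("replace", old, new),)
        else:  # conc
            m = _INGREDIENT_RE.match(payload)
            if not m or not m.group("unit"):
                raise RecipeError(f"malformed /conc/ payload {payload!r}")
            edits = (
                (
                    "set_concentration",
                    m.group("name"),
                    float(m.group("amount")),
                    m.group("unit"),
                ),
            )
        instructions.append(VariantInstruction(label=str(n), edits=edits))
    return instructions


# ---------------------------------------------------------------------------
# Variant expansion
# ---------------------------------------------------------------------------
def expand_variants(
    base: RawRecipe, instructions: Sequence[VariantInstruction]
) -> list[RawRecipe]:
    """Apply each instruction to the base, returning [base, variant1, ...].

    Variant IDs are ``<base>.<1-based counter>``. Edits referencing a
    compound absent from the base raise :class:`RecipeError` naming it.
    """
    out = [base]
    for i, instr in enumerate(instructions, start=1):
        lines = list(base.lines)
        tags = list(base.tags)
        for edit in instr.edits:
            op = edit[0]
            if op == "remove":
                _, name = edit
                idx = _find_line(lines, name)
                if idx is None:
                    raise RecipeError(
                        f"variant {instr.label}: cannot remove absent compound {name!r}"
                    )
                del lines[idx]
            elif op == "replace":
                _, old, new = edit
                idx = _find_line(lines, old)
                if idx is None:
                    raise RecipeError(
                        f"variant {instr.label}: cannot replace absent compound {old!r}"
                    )
                prev = lines[idx]
                lines[idx] = IngredientLine(new, prev.amount, prev.raw_unit)
            elif op == "set_concentration":
                _, name, amount, unit = edit
                idx = _find_line(lines, name)
                if idx is None:
                    raise RecipeError(
                        f"variant {instr.label}: cannot set concentration of "
                        f"absent compound {name!r}"
                    )
                lines[idx] = IngredientLine(name, amount, unit)
            elif op == "add":
                _, name, amount, unit = edit
                lines.append(IngredientLine(name, amount, unit))
            elif op == "set_ph":
                _, value = edit
                tags = [(t, p) for t, p in tags if t != "ph"]
                tags.append(("ph", str(value)))
            else:
                raise RecipeError(f"unknown edit {op!r}")
        out.append(
            RawRecipe(
                medium_id=f"{base.medium_id}.{i}",
                lines=lines,
                tags=tags,
                referenced_media=list(base.referenced_media),
                declared_volume=base.declared_volume,
            )
        )
    return out


def _find_line(lines: list[IngredientLine], name: str) -> int | None:
    for i, line in enumerate(lines):
        if line.raw_name == name:
            return i
    return None


# ---------------------------------------------------------------------------
# Volume resolution
# ---------------------------------------------------------------------------
def resolve_volume(
    recipe: RawRecipe,
    overrides: Mapping[str, str] | None = None,
    unit_map: Mapping[str, tuple[str, float]] | None = None,
    tolerance: float = 0.01,
) -> VolumeResolution:
    """Decide fill vs scale and the multiplier bringing the recipe to 1 l.

    General rule: ``fill`` (multiplier 1, declared volume ignored) when no
    volume is declared or the declared volume is 1 l within ``tolerance``;
    ``scale`` (multiplier = 1 l / declared volume) otherwise. A per-medium
    override table is authoritative.
    """
    unit_map = unit_map or DEFAULT_UNIT_MAP
    override = (overrides or {}).get(recipe.medium_id)
    if override is not None and override not in ("fill", "scale"):
        raise RecipeError(
            f"override for {recipe.medium_id!r} must be 'fill' or 'scale'"
        )

    volume_l: float | None = None
    if recipe.declared_volume is not None:
        amount, unit = recipe.declared_volume
        kind, factor = _lookup_unit(unit, unit_map)
        if kind != "volume":
            raise RecipeError(
                f"declared volume of {recipe.medium_id!r} has non-volume unit {unit!r}"
            )
        volume_l = amount * factor

    if override == "fill":
        return VolumeResolution("fill", 1.0)
    if override == "scale":
        if not volume_l:
            raise RecipeError(
                f"{recipe.medium_id!r}: scale mode requires a positive declared volume"
            )
        return VolumeResolution("scale", 1.0 / volume_l)
    if volume_l is None or abs(volume_l - 1.0) <= tolerance:
        return VolumeResolution("fill", 1.0)
    if volume_l == 0:
        raise RecipeError(f"{recipe.medium_id!r}: declared volume is zero")
    return VolumeResolution("scale", 1.0 / volume_l)


# ---------------------------------------------------------------------------
# Reference unpacking
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class FlatEntry:
    """A raw component with its per-litre contribution to the final medium."""

    raw_name: str
    kind: str  # g_per_l | mol_per_l | trace | gas_substrate
    amount: float | None


def _lookup_unit(
    unit: str, unit_map: Mapping[str, tuple[str, float]]
) -> tuple[str, float]:
    if unit in unit_map:
        return unit_map[unit]
    lowered = unit.lower()
    if lowered in unit_map:
        return unit_map[lowered]
    raise RecipeError(f"unknown unit {unit!r}")


def _normalize_line(
    line: IngredientLine, unit_map: Mapping[str, tuple[str, float]]
) -> FlatEntry:
    """Convert a single ingredient line to per-litre grams/moles or a flag.

    Amounts without an explicit per-litre unit are read as quantities for
    one litre of the declaring recipe (the microbiology rule of thumb);
    compound volumes become grams via the 1 g = 1 ml density convention.
    """
    kind, factor = _lookup_unit(line.raw_unit, unit_map)
    if kind in ("trace", "gas_substrate"):
        return FlatEntry(line.raw_name, kind, None)
    value = line.amount * factor
    if kind == "mass":
        return FlatEntry(line.raw_name, "g_per_l", value)
    if kind == "volume":
        return FlatEntry(line.raw_name, "g_per_l", value * GRAMS_PER_LITRE)
    if kind == "mole":
        return FlatEntry(line.raw_name, "mol_per_l", value)
    if kind == "conc_g":
        return FlatEntry(line.raw_name, "g_per_l", value)
    if kind == "conc_mol":
        return FlatEntry(line.raw_name, "mol_per_l", value)
    if kind == "conc_l":
        # volume of an individual compound per litre: density rule applies
        return FlatEntry(line.raw_name, "g_per_l", value * GRAMS_PER_LITRE)
    raise RecipeError(f"unhandled unit kind {kind!r}")


def unpack_references(
    recipe: RawRecipe,
    recipe_set: Mapping[str, RawRecipe],
    unit_map: Mapping[str, tuple[str, float]] | None = None,
    overrides: Mapping[str, str] | None = None,
) -> list[FlatEntry]:
    """Flatten nested submedium references into per-litre contributions.

    Nested volume factors multiply through (100 ml of a submedium listing a
    compound at 5 g/l contributes 0.5 g/l); the 1 g = 1 ml density rule
    applies to volumes of individual compounds, never to volumes of
    submedia. Identical components met at several nesting levels are
    summed. Cyclic references raise an error listing the cycle.
    """
    unit_map = unit_map or DEFAULT_UNIT_MAP
    totals: dict[tuple[str, str], float] = {}
    flags: dict[tuple[str, str], FlatEntry] = {}

    def visit(mid: str, factor: float, stack: tuple[str, ...]) -> None:
        if mid in stack:
            cycle = " -> ".join(stack[stack.index(mid):] + (mid,))
            raise RecipeError(f"cyclic medium reference: {cycle}")
        if mid not in recipe_set:
            raise RecipeError(f"reference to missing medium {mid!r}")
        rec = recipe_set[mid]
        mult = resolve_volume(rec, overrides, unit_map).multiplier * factor
        for line in rec.lines:
            entry = _normalize_line(line, unit_map)
            key = (entry.raw_name, entry.kind)
            if entry.amount is None:
                flags.setdefault(key, entry)
            else:
                totals[key] = totals.get(key, 0.0) + entry.amount * mult
        for ref_id, amount, unit in rec.referenced_media:
            kind, ufactor = _lookup_unit(unit, unit_map)
            if kind == "volume":
                ref_l = amount * ufactor
            elif kind == "conc_l":
                ref_l = amount * ufactor
            else:
                raise RecipeError(
                    f"{mid!r}: reference to {ref_id!r} must carry a volume unit, "
                    f"got {unit!r}"
                )
            visit(ref_id, mult * ref_l, stack + (mid,))

    if recipe.medium_id not in recipe_set:
        recipe_set = {**recipe_set, recipe.medium_id: recipe}
    visit(recipe.medium_id, 1.0, ())
    out = [
        FlatEntry(name, kind, amount)
        for (name, kind), amount in sorted(totals.items())
    ]
    out.extend(flags[k] for k in sorted(flags))
    return out


# ---------------------------------------------------------------------------
# Standard-unit conversion
# ---------------------------------------------------------------------------
def to_standard_units(
    entries: Iterable[FlatEntry],
    compounds: Mapping[str, CompoundRecord],
) -> list[CompiledComponent]:
    """Convert flattened entries to constituent-level standard components.

    Defined compounds listed in grams become moles via their molecular
    weight (which includes hydrate waters); each constituent contributes
    ``moles x molar_ratio``. Complex components stay in g/l under their
    category tag. Entries resolving to the same constituent are summed.
    """
    mol: dict[str, float] = {}
    gl: dict[str, float] = {}
    flags: dict[str, str] = {}
    for entry in entries:
        rec = compounds.get(entry.raw_name)
        if rec is None:
            raise RecipeError(f"compound {entry.raw_name!r} not in compound table")
        if entry.kind in ("trace", "gas_substrate"):
            flags[rec.semi_unique_name] = entry.kind
            continue
        if rec.compound_class == "complex":
            if entry.kind != "g_per_l":
                raise RecipeError(
                    f"complex compound {entry.raw_name!r} must be quantified "
                    f"by mass, got {entry.kind}"
                )
            assert rec.category is not None
            gl[rec.category] = gl.get(rec.category, 0.0) + entry.amount
            continue
        # defined / other: convert to moles of the raw form
        if entry.kind == "g_per_l":
            if rec.molecular_weight is None:
                raise RecipeError(
                    f"no molecular weight for gram-quantified compound "
                    f"{entry.raw_name!r}"
                )
            moles = entry.amount / rec.molecular_weight
        else:  # mol_per_l
            moles = entry.amount
        for cid, ratio in rec.constituents:
            mol[cid] = mol.get(cid, 0.0) + moles * ratio

    out = [
        CompiledComponent(cid, "defined", amount) for cid, amount in sorted(mol.items())
    ]
    out += [
        CompiledComponent(cat, "complex", amount) for cat, amount in sorted(gl.items())
    ]
    out += [CompiledComponent(cid, kind) for cid, kind in sorted(flags.items())]
    return out


def compile_medium(
    recipe_id: str,
    recipe_set: Mapping[str, RawRecipe],
    compounds: Mapping[str, CompoundRecord],
    unit_map: Mapping[str, tuple[str, float]] | None = None,
    overrides: Mapping[str, str] | None = None,
    name: str = "",
    oxygen_status: str = "unknown",
) -> MediumVariant:
    """Compile one recipe (with its references) into a MediumVariant."""
    if recipe_id not in recipe_set:
        raise RecipeError(f"unknown recipe {recipe_id!r}")
    recipe = recipe_set[recipe_id]
    resolution = resolve_volume(recipe, overrides, unit_map or DEFAULT_UNIT_MAP)
    flat = unpack_references(recipe, recipe_set, unit_map, overrides)
    components = to_standard_units(flat, compounds)
    return MediumVariant(
        medium_id=recipe_id,
        name=name or recipe_id,
        components=components,
        ph=recipe.ph,
        volume_mode=resolution.mode,
        oxygen_status=oxygen_status,
    )


# ---------------------------------------------------------------------------
# Compound table and media matrix IO
# ---------------------------------------------------------------------------
def read_compound_table(path: str | Path) -> dict[str, CompoundRecord]:
    """Read a TSV compound table keyed by raw ingredient name.

    Columns: raw_name, semi_unique_name, constituents (``id:ratio;...``),
    n_waters, molecular_weight (empty allowed), compound_class, category.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    table: dict[str, CompoundRecord] = {}
    for row in df.itertuples(index=False):
        constituents: tuple[tuple[str, int], ...] = ()
        if row.constituents:
            constituents = tuple(
                (part.split(":")[0], int(part.split(":")[1]))
                for part in row.constituents.split(";")
            )
        table[row.raw_name] = CompoundRecord(
            raw_name=row.raw_name,
            semi_unique_name=row.semi_unique_name or row.raw_name,
            constituents=constituents,
            n_waters=int(row.n_waters or 0),
            molecular_weight=float(row.molecular_weight)
            if row.molecular_weight
            else None,
            compound_class=row.compound_class or "defined",
            category=row.category or None,
        )
    return table


def default_compound_table() -> dict[str, CompoundRecord]:
    """The compound table shipped with the package (common media ingredients)."""
    with resources.as_file(
        resources.files("mediarec").joinpath("data/compounds.tsv")
    ) as path:
        return read_compound_table(path)


def write_media_table(
    media: Iterable[MediumVariant], path: str | Path
) -> None:
    """Write compiled media as a wide media-by-component TSV matrix.

    Defined components appear as ``cpd:<id>`` columns in mol/l, complex
    categories as ``complex:<category>`` in g/l, trace and gas flags as
    ``trace:<id>`` / ``gas:<id>`` booleans, plus metadata columns.
    """
    media = list(media)
    rows = []
    for m in media:
        row: dict[str, object] = {
            "medium_id": m.medium_id,
            "name": m.name,
            "ph": "" if m.ph is None else m.ph,
            "volume_mode": m.volume_mode,
            "oxygen_status": m.oxygen_status,
            "is_defined": int(m.is_defined),
        }
        for c in m.components:
            if c.kind == "defined":
                row[f"cpd:{c.component_id}"] = c.amount
            elif c.kind == "complex":
                row[f"complex:{c.component_id}"] = c.amount
            elif c.kind == "trace":
                row[f"trace:{c.component_id}"] = 1
            else:
                row[f"gas:{c.component_id}"] = 1
        rows.append(row)
    df = pd.DataFrame(rows)
    meta = ["medium_id", "name", "ph", "volume_mode", "oxygen_status", "is_defined"]
    comp_cols = sorted(c for c in df.columns if c not in meta)
    df = df[meta + comp_cols]
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_media_table(path: str | Path) -> dict[str, MediumVariant]:
    """Read back a media matrix written by :func:`write_media_table`."""
    df = pd.read_csv(
        path, sep="\t", keep_default_na=False, float_precision="round_trip"
    )
    media: dict[str, MediumVariant] = {}
    comp_cols = [
        c
        for c in df.columns
        if c.split(":", 1)[0] in ("cpd", "complex", "trace", "gas")
    ]
    for row in df.itertuples(index=False):
        components: list[CompiledComponent] = []
        # positional access keeps odd column names (with ':') intact
        values = dict(zip(df.columns, row))
        for col in comp_cols:
            value = values[col]
            if value == "" or (isinstance(value, float) and pd.isna(value)):
                continue
            prefix, cid = col.split(":", 1)
            if prefix == "cpd":
                components.append(CompiledComponent(cid, "defined", float(value)))
            elif prefix == "complex":
                components.append(CompiledComponent(cid, "complex", float(value)))
            elif prefix == "trace":
                if float(value):
                    components.append(CompiledComponent(cid, "trace"))
            else:
                if float(value):
                    components.append(CompiledComponent(cid, "gas_substrate"))
        ph = values["ph"]
        medium = MediumVariant(
            medium_id=str(values["medium_id"]),
            name=str(values["name"]),
            components=components,
            ph=float(ph) if ph != "" else None,
            volume_mode=str(values["volume_mode"]),
            oxygen_status=str(values["oxygen_status"]),
        )
        media[medium.medium_id] = medium
    return media
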