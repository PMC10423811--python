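"""Gene-set registry: GMT I/O, recipe-based construction, validation.

The analysis scores seven programmed-cell-death (PCD) signatures and eight
ferroptosis-related metabolic pathways. Each list is built from source sets
by one of three rules: ``extract`` (copy a single source), ``intersect``
(set intersection of two or more sources), or ``literature`` (a curated
list passed through unchanged). Published list sizes are carried as
``expected_size`` and checked — a mismatch warns rather than fails, because
source-database versions drift.

The bundled fixture sources (``data/synthetic_sources.gmt``) are synthetic
stand-ins sized so every recipe reproduces its published count; real MSigDB
GMT files are a drop-in replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "GeneSet",
    "GeneSetRecipe",
    "Registry",
    "GeneSetSizeWarning",
    "read_gmt",
    "write_gmt",
    "load_recipes",
    "build_geneset",
    "build_registry",
    "default_registry",
    "validate_registry",
    "ValidationReport",
]

VALID_RULES = ("extract", "intersect", "literature")
CATEGORIES = ("pcd", "metabolic")


class GeneSetSizeWarning(UserWarning):
    """A built set's size differs from its published expected size."""


def _normalize(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique, uppercase gene symbols.

    Genes are stored in alphabetical canonical order so serialization is
    reproducible.
    """

    name: str
    genes: tuple[str, ...]
    provenance: str = ""
    expected_size: int | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        genes = tuple(sorted({_normalize(g) for g in self.genes if g.strip()}))
        if any(not g for g in genes):
            raise ValueError(f"gene set {self.name!r} contains empty symbols")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return _normalize(symbol) in set(self.genes)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclass(frozen=True)
class GeneSetRecipe:
    """How a target gene list is constructed from source sets."""

    target_name: str
    rule: str
    sources: tuple[str, ...]
    expected_size: int | None = None
    category: str | None = None

    def __post_init__(self) -> None:
        if self.rule not in VALID_RULES:
            raise ValueError(f"unknown rule {self.rule!r}; expected one of {VALID_RULES}")
        object.__setattr__(self, "sources", tuple(self.sources))
        if self.rule == "intersect" and len(self.sources) < 2:
            raise ValueError(f"recipe {self.target_name!r}: intersect needs >=2 sources")
        if self.rule in ("extract", "literature") and len(self.sources) != 1:
            raise ValueError(f"recipe {self.target_name!r}: {self.rule} needs exactly 1 source")
        if self.category is not None and self.category not in CATEGORIES:
            raise ValueError(f"recipe {self.target_name!r}: unknown category {self.category!r}")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, genes...).

    Symbols are uppercased and whitespace-stripped; duplicates within a
    line are collapsed; empty tokens are dropped. A line with no non-empty
    gene token, or fewer than three fields, is a parse error.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
            name, description = fields[0].strip(), fields[1]
            genes = [g for g in (t.strip() for t in fields[2:]) if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            seen.add(name)
            sets.append(GeneSet(name=name, genes=tuple(genes), provenance=description))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    """Write gene sets in GMT format, genes in canonical order."""
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.provenance or "."] + list(gs.genes)) + "\n")


def load_recipes(path: str | Path) -> list[GeneSetRecipe]:
    """Load construction recipes from a YAML list."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValueError(f"{path}: recipe file must contain a YAML list")
    return [
        GeneSetRecipe(
            target_name=entry["target_name"],
            rule=entry["rule"],
            sources=tuple(entry["sources"]),
            expected_size=entry.get("expected_size"),
            category=entry.get("category"),
        )
        for entry in raw
    ]


def build_geneset(recipe: GeneSetRecipe, sources: Mapping[str, GeneSet]) -> GeneSet:
    """Construct a gene set from its recipe.

    ``extract``/``literature`` copy the single source; ``intersect`` takes
    the set intersection of all sources (order-independent). If the result
    size differs from ``expected_size`` a :class:`GeneSetSizeWarning` is
    emitted and both sizes are recorded in the provenance.
    """
    missing = [s for s in recipe.sources if s not in sources]
    if missing:
        raise KeyError(f"recipe {recipe.target_name!r}: missing source set(s) {missing}")

    if recipe.rule in ("extract", "literature"):
        genes: frozenset[str] = sources[recipe.sources[0]].as_set()
    else:
        genes = frozenset.intersection(*(sources[s].as_set() for s in recipe.sources))
        if not genes:
            warnings.warn(
                f"recipe {recipe.target_name!r}: empty intersection of {recipe.sources}",
                GeneSetSizeWarning,
                stacklevel=2,
            )

    provenance = f"{recipe.rule}({', '.join(recipe.sources)})"
    if recipe.expected_size is not None and len(genes) != recipe.expected_size:
        warnings.warn(
            f"gene set {recipe.target_name!r}: built size {len(genes)} != "
            f"expected {recipe.expected_size}",
            GeneSetSizeWarning,
            stacklevel=2,
        )
        provenance += f" [size {len(genes)}, expected {recipe.expected_size}]"
    return GeneSet(
        name=recipe.target_name,
        genes=tuple(genes),
        provenance=provenance,
        expected_size=recipe.expected_size,
    )


@dataclass
class Registry:
    """Mapping of set name -> GeneSet with a category (pcd/metabolic) per set."""

    _sets: dict[str, GeneSet] = field(default_factory=dict)
    _categories: dict[str, str] = field(default_factory=dict)

    def add(self, geneset: GeneSet, category: str) -> None:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        if geneset.name in self._sets:
            raise ValueError(f"duplicate gene set name {geneset.name!r}")
        self._sets[geneset.name] = geneset
        self._categories[geneset.name] = category

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __iter__(self):
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def category(self, name: str) -> str:
        return self._categories[name]

    def by_category(self, category: str) -> list[GeneSet]:
        return [gs for gs in self if self._categories[gs.name] == category]

    def metabolic_union(self) -> GeneSet:
        """Union of all metabolic sets — the 'metabolism-related genes' universe."""
        metabolic = self.by_category("metabolic")
        if not metabolic:
            raise ValueError("registry has no metabolic sets")
        genes = frozenset().union(*(gs.as_set() for gs in metabolic))
        return GeneSet(
            name="metabolic_union",
            genes=tuple(genes),
            provenance="union(" + ", ".join(gs.name for gs in metabolic) + ")",
        )

    def sets_containing(self, symbol: str) -> list[str]:
        return [gs.name for gs in self if symbol in gs]


def build_registry(
    source_sets: Iterable[GeneSet], recipes: Iterable[GeneSetRecipe]
) -> Registry:
    """Build all recipe targets against the given sources."""
    sources = {gs.name: gs for gs in source_sets}
    registry = Registry()
    for recipe in recipes:
        registry.add(build_geneset(recipe, sources), category=recipe.category or "pcd")
    return registry


def default_registry() -> Registry:
    """The bundled 15-set registry built from the synthetic fixture sources."""
    data = resources.files("nephrosig") / "data"
    with resources.as_file(data / "synthetic_sources.gmt") as gmt_path:
        sources = read_gmt(gmt_path)
    with resources.as_file(data / "recipes.yaml") as recipe_path:
        recipes = load_recipes(recipe_path)
    return build_registry(sources, recipes)


@dataclass(frozen=True)
class ValidationReport:
    rows: tuple[dict, ...]
    n_match: int
    n_total: int
    overall_pass: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [
            f"{r['name']:28s} size={r['size']:4d} expected={r['expected']!s:>4} "
            f"{'ok' if r['match'] else 'MISMATCH'}"
            for r in self.rows
        ]
        lines.append(f"{self.n_match}/{self.n_total} match; overall_pass={self.overall_pass}")
        return "\n".join(lines)


def validate_registry(registry: Registry) -> ValidationReport:
    """Report actual vs expected sizes per set; overall pass iff all non-empty."""
    rows = []
    for gs in registry:
        match = gs.expected_size is None or len(gs) == gs.expected_size
        rows.append(
            {
                "name": gs.name,
                "category": registry.category(gs.name),
                "size": len(gs),
                "expected": gs.expected_size,
                "match": match,
            }
        )
    n_match = sum(r["match"] for r in rows)
    overall = all(r["size"] > 0 for r in rows)
    return ValidationReport(
        rows=tuple(rows), n_match=n_match, n_total=len(rows), overall_pass=overall
    )
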