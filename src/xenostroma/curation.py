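"""Ortholog harmonization, the combined two-model stroma transcriptome, and
the sequential signature-subtraction ("curation") procedure.

The combined bone-metastasis stroma transcriptome (the union of the per-model
differentially expressed gene lists) is partitioned by subtracting, in order,
(1) inflammatory/wound-healing/desmoplastic response signatures, (2) stroma
signatures of cancers that rarely metastasize to bone, and (3) stroma
signatures of osteotropic primary cancers.  The remainder is the "Core"
bone-specific signature; the three removed layers are the inflammatory-shared,
universal, and osteotropic components.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ORDER = ("inflammatory", "non-osteotropic-cancer", "osteotropic-primary")
COMPONENT_NAMES = {
    "inflammatory": "inflammatory-shared",
    "non-osteotropic-cancer": "universal",
    "osteotropic-primary": "osteotropic",
}

SIGNATURE_CATEGORIES = frozenset(
    {
        "inflammatory",
        "wound",
        "desmoplastic",
        "non-osteotropic-cancer",
        "osteotropic-primary",
        "niche-HSC",
        "niche-UGM",
        "stromal-cell-type",
    }
)


@dataclass
class GeneSignature:
    """A published-style gene set with species and curation category."""

    name: str
    species: str
    category: str
    symbols: tuple[str, ...]
    directions: dict[str, str] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError(f"signature {self.name} has no symbols")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError(f"duplicate symbols in signature {self.name}")

    @property
    def symbol_set(self) -> frozenset[str]:
        return frozenset(self.symbols)


@dataclass
class OrthologMap:
    """One-to-one symbol pairs between two species.

    ``pairs`` maps species-A symbols to species-B symbols; lookups work in
    both directions.  Collisions (many-to-one) must be resolved before
    construction; :func:`case_convention_map` resolves them to the first
    canonical pair and logs the rest.
    """

    species_a: str
    species_b: str
    pairs: dict[str, str]
    unmapped_policy: str = "drop"

    def __post_init__(self) -> None:
        values = list(self.pairs.values())
        if len(set(values)) != len(values):
            raise ValueError("ortholog map is not one-to-one after collision resolution")
        self._reverse = {v: k for k, v in self.pairs.items()}

    def translate(self, symbol: str, target_species: str) -> str | None:
        if target_species == self.species_b:
            return self.pairs.get(symbol)
        if target_species == self.species_a:
            return self._reverse.get(symbol)
        raise KeyError(f"species {target_species!r} not covered by this map")

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            sorted(self.pairs.items()), columns=[self.species_a, self.species_b]
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthologMap":
        df = pd.read_csv(path, sep="\t", comment="#")
        a, b = df.columns[:2]
        return cls(str(a), str(b), dict(zip(df[a].astype(str), df[b].astype(str))))


def case_convention_map(
    mouse_symbols: Iterable[str], overrides: Mapping[str, str] | None = None
) -> OrthologMap:
    """Default mouse<->human map by casing convention (Postn <-> POSTN),
    with optional explicit overrides; collisions resolved to the first pair."""
    pairs: dict[str, str] = {}
    used: set[str] = set()
    collisions: list[str] = []
    for sym in mouse_symbols:
        human = (overrides or {}).get(sym, sym.upper())
        if human in used:
            collisions.append(sym)
            continue
        pairs[sym] = human
        used.add(human)
    m = OrthologMap("mouse", "human", pairs)
    m.collisions = collisions  # type: ignore[attr-defined]
    return m


@dataclass
class HarmonizationLog:
    unmapped: list[str]
    collapsed: list[str]


def harmonize_symbols(
    sig: GeneSignature, ortholog_map: OrthologMap, target_species: str
) -> tuple[GeneSignature, HarmonizationLog]:
    """Translate a signature into ``target_species`` symbols.

    Unmapped symbols are dropped and logged; duplicates arising from the
    translation are collapsed and logged.
    """
    if target_species not in (ortholog_map.species_a, ortholog_map.species_b):
        raise KeyError(f"target species {target_species!r} absent from ortholog map")
    if sig.species == target_species:
        return sig, HarmonizationLog([], [])
    translated: list[str] = []
    unmapped: list[str] = []
    collapsed: list[str] = []
    seen: set[str] = set()
    for sym in sig.symbols:
        t = ortholog_map.translate(sym, target_species)
        if t is None:
            unmapped.append(sym)
        elif t in seen:
            collapsed.append(sym)
        else:
            translated.append(t)
            seen.add(t)
    directions = {}
    for sym, d in sig.directions.items():
        t = ortholog_map.translate(sym, target_species)
        if t is not None:
            directions[t] = d
    out = GeneSignature(
        name=sig.name,
        species=target_species,
        category=sig.category,
        symbols=tuple(translated),
        directions=directions,
        provenance=sig.provenance,
    )
    return out, HarmonizationLog(unmapped, collapsed)


# ---------------------------------------------------------------------------
# combined stroma transcriptome


@dataclass
class ConcordanceResult:
    r_squared: float
    slope_sign: int  # +1 concordant, -1 discordant

    @property
    def discordant(self) -> bool:
        return self.slope_sign < 0


def concordance_r2(fc_pairs: Sequence[tuple[float, float]]) -> ConcordanceResult:
    """Squared Pearson correlation of per-gene log2FC pairs, with the sign of
    the relationship reported separately (R^2 alone hides discordance)."""
    if len(fc_pairs) < 3:
        raise ValueError("need >= 3 fold-change pairs")
    x = np.array([a for a, _ in fc_pairs], dtype=np.float64)
    y = np.array([b for _, b in fc_pairs], dtype=np.float64)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        # correlation undefined for a constant margin
        return ConcordanceResult(r_squared=float("nan"), slope_sign=1)
    r = stats.pearsonr(x, y).statistic
    return ConcordanceResult(r_squared=float(r * r), slope_sign=1 if r >= 0 else -1)


@dataclass
class OBBMST:
    """Union of the two per-model DE gene lists, with the common/unique
    partition and cross-model fold-change concordance."""

    model_a: str
    model_b: str
    lfc_a: dict[str, float]
    lfc_b: dict[str, float]
    common: frozenset[str]
    unique_a: frozenset[str]
    unique_b: frozenset[str]
    discordant: frozenset[str]
    concordance: ConcordanceResult | None

    @property
    def all_genes(self) -> frozenset[str]:
        return self.common | self.unique_a | self.unique_b

    def direction(self, gene: str) -> str:
        lfc = self.lfc_a.get(gene, self.lfc_b.get(gene, 0.0))
        return "up" if lfc > 0 else "down"


def build_obbmst(
    de_a: pd.DataFrame, de_b: pd.DataFrame, model_a: str = "A", model_b: str = "B"
) -> OBBMST:
    """Combine two direction-annotated DE tables (gene-indexed, with a
    ``log2FC`` column) into the union transcriptome.

    A gene is *common* iff present in both lists regardless of direction;
    direction disagreements are flagged as discordant, not removed.
    """
    lfc_a = {str(g): float(v) for g, v in de_a["log2FC"].items()}
    lfc_b = {str(g): float(v) for g, v in de_b["log2FC"].items()}
    set_a, set_b = set(lfc_a), set(lfc_b)
    common = frozenset(set_a & set_b)
    discordant = frozenset(g for g in common if lfc_a[g] * lfc_b[g] < 0)
    pairs = [(lfc_a[g], lfc_b[g]) for g in sorted(common)]
    concordance = concordance_r2(pairs) if len(pairs) >= 3 else None
    return OBBMST(
        model_a=model_a,
        model_b=model_b,
        lfc_a=lfc_a,
        lfc_b=lfc_b,
        common=common,
        unique_a=frozenset(set_a - set_b),
        unique_b=frozenset(set_b - set_a),
        discordant=discordant,
        concordance=concordance,
    )


# ---------------------------------------------------------------------------
# curation ledger


@dataclass
class CurationStage:
    category: str
    signatures: tuple[str, ...]
    removed: frozenset[str]
    remainder: frozenset[str]


@dataclass
class CurationLedger:
    """Ordered record of the signature subtractions and the final partition.

    Invariant: the stage-removed sets are pairwise disjoint and, together
    with the core, reconstitute the starting set exactly.
    """

    starting: frozenset[str]
    stages: list[CurationStage]
    components: dict[str, frozenset[str]]  # core / inflammatory-shared / universal / osteotropic

    @property
    def core(self) -> frozenset[str]:
        return self.components["core"]

    def fractions(self) -> dict[str, float]:
        n = len(self.starting)
        return {name: len(genes) / n for name, genes in self.components.items()}

    def check_conservation(self) -> None:
        union: set[str] = set(self.core)
        total = len(self.core)
        for stage in self.stages:
            union |= stage.removed
            total += len(stage.removed)
        if union != set(self.starting) or total != len(self.starting):
            raise AssertionError("curation ledger does not conserve the starting set")

    def to_dict(self) -> dict:
        return {
            "starting": sorted(self.starting),
            "stages": [
                {
                    "category": s.category,
                    "signatures": list(s.signatures),
                    "removed": sorted(s.removed),
                    "n_removed": len(s.removed),
                    "remainder": sorted(s.remainder),
                }
                for s in self.stages
            ],
            "components": {k: sorted(v) for k, v in self.components.items()},
            "fractions": {k: round(f, 9) for k, f in self.fractions().items()},
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True, indent=2)
            fh.write("\n")


def curate(
    genes: Iterable[str] | OBBMST,
    registry: Sequence[GeneSignature],
    order: Sequence[str] = DEFAULT_ORDER,
) -> CurationLedger:
    """Sequentially subtract category signature unions from the gene set.

    ``order`` must be a permutation of the three subtraction categories.
    Matching is by symbol only, ignoring direction (the emulated procedure
    subtracts gene identities, not signed responses).
    """
    if sorted(order) != sorted(DEFAULT_ORDER):
        raise ValueError(f"order must be a permutation of {DEFAULT_ORDER}, got {tuple(order)}")
    start = frozenset(genes.all_genes if isinstance(genes, OBBMST) else genes)
    remainder = set(start)
    stages: list[CurationStage] = []
    components: dict[str, frozenset[str]] = {}
    by_category: dict[str, list[GeneSignature]] = {}
    for sig in registry:
        by_category.setdefault(sig.category, []).append(sig)
    for category in order:
        sigs = by_category.get(category, [])
        union: set[str] = set()
        for sig in sigs:
            union |= sig.symbol_set
        removed = frozenset(remainder & union)
        remainder -= removed
        stages.append(
            CurationStage(
                category=category,
                signatures=tuple(s.name for s in sigs),
                removed=removed,
                remainder=frozenset(remainder),
            )
        )
        components[COMPONENT_NAMES[category]] = removed
    components["core"] = frozenset(remainder)
    ledger = CurationLedger(starting=start, stages=stages, components=components)
    ledger.check_conservation()
    return ledger


def venn_partition(sets: Mapping[str, Iterable[str]]) -> dict[tuple[str, ...], int]:
    """Counts of every non-empty region of the inclusion-exclusion lattice of
    2-4 named sets; region keys are the sorted tuples of member set names."""
    names = list(sets)
    if not 2 <= len(names) <= 4:
        raise ValueError("venn_partition takes 2-4 sets")
    materialized = {name: set(s) for name, s in sets.items()}
    universe = set().union(*materialized.values())
    counts: dict[tuple[str, ...], int] = {}
    for element in universe:
        key = tuple(sorted(n for n in names if element in materialized[n]))
        counts[key] = counts.get(key, 0) + 1
    return counts
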