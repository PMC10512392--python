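"""Drug–gene interaction calling on heterozygote fitness tables.

A fitness table holds relative growth (1.0 ≈ wild-type) of heterozygous
deletion mutants across drug treatments. A cell is a *negative* drug–gene
interaction when the mutant's fitness drops below a defect cutoff (≥10%
defect ⇔ fitness ≤ 0.90; the stringent variant uses >30% ⇔ fitness < 0.70,
strict). Negatives split into *expected* interactions — the mutant is the
drug's known target — and *novel* ones, and the overlap between a predicted
interaction set and the sensitive set is assessed with an upper-tail
hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TargetMap",
    "InteractionCallSet",
    "load_fitness_table",
    "load_target_map",
    "flag_baseline_defect",
    "call_negative",
    "partition_expected",
    "hypergeom_enrichment",
]


@dataclass(frozen=True)
class TargetMap:
    """Drug → primary target gene mapping (one target per drug)."""

    targets: dict[str, str]
    methods: dict[str, str]

    def target(self, drug: str) -> str | None:
        return self.targets.get(drug)


@dataclass(frozen=True)
class InteractionCallSet:
    """Negative drug–gene interaction calls at one fitness cutoff."""

    negatives: frozenset[tuple[str, str]]  # (mutant, drug)
    cutoff: float
    strict: bool
    expected: frozenset[tuple[str, str]] = frozenset()
    novel: frozenset[tuple[str, str]] = frozenset()


def load_fitness_table(path=None) -> pd.DataFrame:
    """Read a mutants × drugs fitness TSV (default: the packaged 10×11 table).

    Rows are heterozygous deletion mutants, columns are drugs, values are
    relative fitness (1.0 = wild-type-like growth).
    """
    if path is None:
        path = resources.files("synscreen.data") / "het_fitness.tsv"
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.isna().any().any():
        raise ValueError("fitness table has missing cells")
    if (table.values < 0).any():
        raise ValueError("fitness values must be >= 0")
    return table


def load_target_map(path=None) -> TargetMap:
    """Read a drug→target TSV (default: the packaged known-target map)."""
    if path is None:
        path = resources.files("synscreen.data") / "known_targets.tsv"
    df = pd.read_csv(path, sep="\t")
    if df["drug"].duplicated().any():
        raise ValueError("each drug must map to exactly one primary target")
    return TargetMap(
        targets=dict(zip(df["drug"], df["gene"])),
        methods=dict(zip(df["drug"], df.get("method", ""))),
    )


def flag_baseline_defect(
    no_drug_fitness: pd.Series, tolerance: float = 0.2
) -> list[str]:
    """Mutants whose untreated fitness deviates from 1 by more than ``tolerance``.

    Such rows (e.g. a constitutively sick heterozygote) should be excluded
    before interaction calling, since their drug rows conflate the drug
    response with the constitutive defect.
    """
    dev = (no_drug_fitness - 1.0).abs()
    return sorted(no_drug_fitness.index[dev > tolerance])


def call_negative(
    table: pd.DataFrame, cutoff: float = 0.90, strict: bool = False
) -> InteractionCallSet:
    """All (mutant, drug) cells at or below a fitness-defect cutoff.

    ``strict=False`` uses ``fitness <= cutoff`` (a ≥10% defect is cutoff
    0.90); ``strict=True`` uses ``fitness < cutoff`` (a >30% defect is
    cutoff 0.70).
    """
    if not 0 < cutoff <= 1.2:
        raise ValueError("cutoff must be in (0, 1.2]")
    mask = table.lt(cutoff) if strict else table.le(cutoff)
    negatives = frozenset(
        (mutant, drug)
        for mutant in table.index
        for drug in table.columns
        if mask.at[mutant, drug]
    )
    return InteractionCallSet(negatives=negatives, cutoff=cutoff, strict=strict)


def partition_expected(
    calls: InteractionCallSet, target_map: TargetMap
) -> InteractionCallSet:
    """Split negatives into expected (mutant is the drug's target) and novel."""
    expected = frozenset(
        (mutant, drug)
        for mutant, drug in calls.negatives
        if target_map.target(drug) == mutant
    )
    return InteractionCallSet(
        negatives=calls.negatives,
        cutoff=calls.cutoff,
        strict=calls.strict,
        expected=expected,
        novel=calls.negatives - expected,
    )


def hypergeom_enrichment(
    overlap: int, predicted: int, sensitive: int, universe: int
) -> float:
    """Upper-tail hypergeometric P(X >= overlap).

    ``predicted`` cells are drawn without replacement from a ``universe`` of
    tested cells containing ``sensitive`` sensitive ones; the p-value is the
    probability of seeing at least the observed overlap by chance.
    """
    if not (0 <= overlap <= min(predicted, sensitive) <= universe):
        raise ValueError("inconsistent counts for hypergeometric test")
    if max(predicted, sensitive) > universe:
        raise ValueError("counts exceed the universe")
    return float(stats.hypergeom.sf(overlap - 1, universe, sensitive, predicted))


def call_report(
    table: pd.DataFrame, calls: InteractionCallSet
) -> pd.DataFrame:
    """Long-format report: one row per cell with its fitness, call and class."""
    rows = []
    for mutant in table.index:
        for drug in table.columns:
            cell = (mutant, drug)
            if cell in calls.expected:
                klass = "expected"
            elif cell in calls.novel:
                klass = "novel"
            else:
                klass = ""
            rows.append(
                {
                    "mutant": mutant,
                    "drug": drug,
                    "fitness": table.at[mutant, drug],
                    "call": cell in calls.negatives,
                    "class": klass,
                }
            )
    return pd.DataFrame(rows)
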