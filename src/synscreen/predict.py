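"""Synergy prediction from single-agent chemogenomic profiles.

The prediction rule: if drug A's chemogenomic profile shows the heterozygous
deletion of gene *g* to be sensitive, and *g* is the known target of drug B
(but not of A itself), then A inhibits something that buffers *g* — so A+B
is predicted synergistic. Enrichment of confirmed synergies among the
predicted pairs is quantified against a background rate from random pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .druggene import TargetMap

__all__ = [
    "ChemogenomicProfile",
    "SynergyPrediction",
    "predict_pairs",
    "pair_count",
    "fold_enrichment",
]


@dataclass(frozen=True)
class ChemogenomicProfile:
    """Per-gene sensitivity scores from a single-agent genome-wide screen.

    ``scores`` maps gene → sensitivity (log2 control/treatment ratio, or a
    robust Z when ``scored_as="z"``); genes scoring at or above ``threshold``
    form the sensitive set. Defaults: log2 ratio ≥ 1, or Z ≥ 2.
    """

    drug: str
    scores: dict[str, float]
    scored_as: str = "log2_ratio"
    threshold: float | None = None

    @property
    def effective_threshold(self) -> float:
        if self.threshold is not None:
            return self.threshold
        return 2.0 if self.scored_as == "z" else 1.0

    @property
    def sensitive_set(self) -> set[str]:
        thr = self.effective_threshold
        return {g for g, s in self.scores.items() if s >= thr}


@dataclass(frozen=True)
class SynergyPrediction:
    """A predicted synergistic pair, with the gene mediating the prediction."""

    drug_a: str
    drug_b: str
    via_gene: str
    rationale: float  # score of via_gene in drug_a's profile


def predict_pairs(
    profiles: list[ChemogenomicProfile],
    target_map: TargetMap,
    threshold: float | None = None,
) -> list[SynergyPrediction]:
    """Predict synergistic pairs from single-agent profiles and a target map.

    For profile A and every other mapped drug B: predict A+B iff target(B)
    is in A's sensitive set and target(B) differs from A's own target.
    Unordered duplicates keep the direction with the stronger rationale
    score (ties: lexicographically smaller drug_a). Drugs whose target gene
    is absent from the profiles' gene universe are skipped.
    """
    universe: set[str] = set()
    for p in profiles:
        universe |= set(p.scores)
    best: dict[frozenset[str], SynergyPrediction] = {}
    for prof in profiles:
        if threshold is not None:
            prof = ChemogenomicProfile(
                prof.drug, prof.scores, prof.scored_as, threshold
            )
        sensitive = prof.sensitive_set
        for drug_b, target_b in target_map.targets.items():
            if drug_b == prof.drug:
                continue
            if target_b not in universe:
                continue  # target not scored anywhere: cannot evaluate
            if target_b == target_map.target(prof.drug):
                continue  # would just re-predict A's own target
            if target_b not in sensitive:
                continue
            pred = SynergyPrediction(
                drug_a=prof.drug,
                drug_b=drug_b,
                via_gene=target_b,
                rationale=prof.scores[target_b],
            )
            key = frozenset((prof.drug, drug_b))
            prev = best.get(key)
            if (
                prev is None
                or pred.rationale > prev.rationale
                or (pred.rationale == prev.rationale and pred.drug_a < prev.drug_a)
            ):
                best[key] = pred
    return sorted(best.values(), key=lambda p: (p.drug_a, p.drug_b))


def pair_count(n: int) -> int:
    """Number of unordered pairs of n compounds: (n² − n)/2."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return (n * n - n) // 2


def fold_enrichment(hits: int, tested: int, bg_hits: int, bg_tested: int) -> float:
    """Hit-rate ratio (hits/tested) / (bg_hits/bg_tested)."""
    if tested <= 0 or bg_tested <= 0:
        raise ValueError("tested counts must be positive")
    if bg_hits <= 0:
        raise ValueError("background hit rate is zero: enrichment undefined")
    return (hits / tested) / (bg_hits / bg_tested)


def predictions_frame(preds: list[SynergyPrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "drug_a": p.drug_a,
                "drug_b": p.drug_b,
                "via_gene": p.via_gene,
                "rationale_score": p.rationale,
            }
            for p in preds
        ],
        columns=["drug_a", "drug_b", "via_gene", "rationale_score"],
    )
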