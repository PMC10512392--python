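"""Preranked gene-set enrichment on combination sensitivity scores.

Genes are ranked by their combination sensitivity ε (or Z); GO-style gene
sets (GMT collections, filtered to 6–199 members inside the scored
universe) are scored with the weighted Kolmogorov–Smirnov running-sum
enrichment statistic, and significance comes from gene-label permutations.
Per-combination enrichment vectors are assembled into a combinations ×
terms matrix and clustered with the same Pearson-distance linkage used for
strain profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hiphop import cluster_profiles

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "filter_sets",
    "gsea_preranked",
    "random_set_es",
    "enrichment_table",
    "enrichment_matrix",
]

MIN_SET_SIZE = 5  # strict: kept sets have size > 5
MAX_SET_SIZE = 200  # strict: kept sets have size < 200


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets with free-text descriptions (GMT semantics)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str]

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment of one gene set in one ranked list."""

    name: str
    size: int
    es: float
    nes: float
    p: float
    direction: str  # "top" (high scores) or "bottom"


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: per line, name, description, then member genes."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, desc, *genes = fields
            sets[name] = frozenset(g for g in genes if g)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            genes = sorted(collection.sets[name])
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def filter_sets(
    collection: GeneSetCollection, universe: set[str]
) -> GeneSetCollection:
    """Intersect sets with the scored universe; keep sizes in (5, 200)."""
    kept: dict[str, frozenset[str]] = {}
    for name, genes in collection.sets.items():
        inside = genes & universe
        if MIN_SET_SIZE < len(inside) < MAX_SET_SIZE:
            kept[name] = frozenset(inside)
    return GeneSetCollection(
        sets=kept,
        descriptions={n: collection.descriptions.get(n, "") for n in kept},
    )


def _ranked(scores: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Genes and scores sorted by descending score, gene name on ties."""
    s = pd.Series(scores, dtype=float)
    order = sorted(s.index, key=lambda g: (-s[g], str(g)))
    return np.asarray(order, dtype=object), s.loc[order].to_numpy()


def _running_es(
    weights: np.ndarray, hit_mask: np.ndarray, miss_step: float
) -> float:
    """Signed maximum deviation of the weighted KS running sum."""
    nr = weights[hit_mask].sum()
    if nr == 0:  # all-zero scores inside the set: fall back to equal weights
        steps = np.where(hit_mask, 1.0 / hit_mask.sum(), -miss_step)
    else:
        steps = np.full(len(weights), -miss_step)
        steps[hit_mask] = weights[hit_mask] / nr
    run = np.cumsum(steps)
    i = int(np.argmax(np.abs(run)))
    return float(run[i])


def _random_set_es(
    weights: np.ndarray, set_size: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """ES values of ``n_draws`` uniformly random same-size gene sets."""
    n = len(weights)
    miss_step = 1.0 / (n - set_size)
    # random subsets via argpartition of uniform draws
    hit_idx = np.argpartition(rng.random((n_draws, n)), set_size - 1, axis=1)
    out = np.empty(n_draws)
    mask = np.zeros(n, dtype=bool)
    for k in range(n_draws):
        mask[:] = False
        mask[hit_idx[k, :set_size]] = True
        out[k] = _running_es(weights, mask, miss_step)
    return out


def random_set_es(
    scores: pd.Series | dict,
    set_size: int,
    n_draws: int,
    seed: int = 0,
    weight: float = 1.0,
) -> np.ndarray:
    """Null ES distribution: enrichment scores of random same-size gene sets.

    Used to study the permutation null (e.g. p-value calibration) on a given
    ranked list without running the full per-set machinery repeatedly.
    """
    s = pd.Series(scores, dtype=float)
    _, vals = _ranked(s)
    if not 0 < set_size < len(vals):
        raise ValueError("set_size must be within the universe")
    weights = np.abs(vals) ** weight
    return _random_set_es(weights, set_size, n_draws, np.random.default_rng(seed))


def gsea_preranked(
    scores: pd.Series | dict,
    gene_set,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    name: str = "",
) -> EnrichmentResult:
    """Weighted-KS enrichment of one gene set in a preranked gene list.

    Genes are ranked by descending score; walking the list, hitting a set
    member increments the running sum proportionally to |score|^weight and
    a miss decrements it by 1/(N − |S|); ES is the signed maximum deviation.
    The p-value is the fraction of random same-size gene sets (out of
    ``n_perm``, conditioned on sharing the observed ES sign) whose ES is at
    least as extreme, with the +1 small-sample correction; NES divides ES
    by the mean |permuted ES| of the same sign. Deterministic for a fixed
    ``seed``.
    """
    s = pd.Series(scores, dtype=float)
    if len(s) < 8:
        raise ValueError("need scores for at least 8 genes")
    genes, vals = _ranked(s)
    members = frozenset(gene_set) & set(s.index)
    m = len(members)
    n = len(genes)
    if m == 0:
        raise ValueError(f"gene set {name!r} has no scored members")
    if m == n:
        raise ValueError(f"gene set {name!r} covers the whole universe")
    hit_mask = np.isin(genes, sorted(members))
    weights = np.abs(vals) ** weight
    miss_step = 1.0 / (n - m)
    es = _running_es(weights, hit_mask, miss_step)

    perm_es = _random_set_es(weights, m, n_perm, np.random.default_rng(seed))
    if es >= 0:
        same = perm_es[perm_es >= 0]
        extreme = int(np.sum(same >= es))
    else:
        same = perm_es[perm_es < 0]
        extreme = int(np.sum(same <= es))
    # conditional on the observed sign, as in standard GSEA: this keeps the
    # null p-values uniform on (0, 1]
    p = (1 + extreme) / (1 + len(same))
    denom = float(np.mean(np.abs(same))) if len(same) else np.nan
    nes = es / denom if denom and np.isfinite(denom) else np.nan
    return EnrichmentResult(
        name=name,
        size=m,
        es=es,
        nes=float(nes),
        p=float(p),
        direction="top" if es >= 0 else "bottom",
    )


def enrichment_table(
    scores: pd.Series | dict,
    collection: GeneSetCollection,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run every set of a (pre-filtered) collection; BH-adjust the p-values."""
    rows = []
    for i, (set_name, genes) in enumerate(sorted(collection.sets.items())):
        res = gsea_preranked(
            scores, genes, weight=weight, n_perm=n_perm,
            seed=seed + i, name=set_name,
        )
        rows.append(
            {
                "set": res.name,
                "size": res.size,
                "es": res.es,
                "nes": res.nes,
                "p": res.p,
                "direction": res.direction,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = stats.false_discovery_control(df["p"], method="bh")
    return df


def enrichment_matrix(
    results: dict[str, pd.DataFrame],
    annotations: dict[str, bool] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Combinations × gene-set NES matrix, clustered on both axes.

    ``results`` maps a combination label to its enrichment table;
    ``annotations`` optionally flags which combinations were synergistic
    (carried through for plotting). Returns the reordered matrix and a dict
    with the linkages/leaf orders; a single combination is returned as a
    1×K matrix with no clustering.
    """
    mat = pd.DataFrame(
        {combo: df.set_index("set")["nes"] for combo, df in results.items()}
    ).T.sort_index()
    meta: dict = {"synergistic": annotations or {}}
    if len(mat) >= 2 and mat.shape[1] >= 2:
        row_link, row_labels = cluster_profiles(mat, axis="rows")
        col_link, col_labels = cluster_profiles(mat, axis="columns")
        from scipy.cluster import hierarchy

        row_order = [row_labels[i] for i in hierarchy.leaves_list(row_link)]
        col_order = [col_labels[i] for i in hierarchy.leaves_list(col_link)]
        mat = mat.loc[row_order, col_order]
        meta.update(
            row_linkage=row_link, row_order=row_order,
            col_linkage=col_link, col_order=col_order,
        )
    return mat, meta
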