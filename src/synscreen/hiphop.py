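"""Barcode-screen (HIP–HOP) intensity processing and combination calling.

A pooled deletion collection is grown under a chemical treatment; each
strain's abundance is read out by hybridising its up/down barcodes to an
array (2 tags × 5 replicate features = 10 signals per strain per array).
The processing chain, applied in this fixed order, is::

    saturation_correct -> quantile_normalize -> log2 -> snm_normalize
        -> select_tag -> robust_z

yielding one robust-Z fitness-defect profile per treatment (positive Z =
strain depleted). A combination assay comprises five screens — A+B plus
each single agent at its IC20 and at its combination dose — from which
*combination-specific* sensitive strains (combo Z ≥ 2, every single-agent
Z < 2) and the per-strain combination sensitivity ε are derived, and
profiles are clustered on Pearson-correlation distance.

The intensity table is a long-format DataFrame with columns
``strain, tag, replicate, intensity, array, batch, treatment, essentiality,
is_control``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "ScreenProfile",
    "CombinationResult",
    "quantile_normalize",
    "saturation_correct",
    "snm_normalize",
    "select_tag",
    "robust_z",
    "combination_specific",
    "sensitivity_epsilon",
    "cluster_profiles",
    "linkage_to_newick",
]

REQUIRED_COLUMNS = [
    "strain",
    "tag",
    "replicate",
    "intensity",
    "array",
    "batch",
    "treatment",
    "essentiality",
    "is_control",
]

#: Normal-consistency factor: 1.4826·MAD estimates a Gaussian σ.
MAD_SCALE = 1.4826


class DegenerateScaleError(ValueError):
    """The control distribution has zero spread; Z-scores are undefined."""


@dataclass(frozen=True)
class ScreenProfile:
    """Robust-Z fitness-defect profile for one treatment.

    ``z`` is indexed by strain (positive = depleted); ``tag_used`` records
    which barcode was kept per strain; ``essentiality`` carries the panel
    (het-essential → HIP, hom-nonessential → HOP).
    """

    treatment: str
    z: pd.Series
    tag_used: pd.Series
    essentiality: pd.Series


@dataclass(frozen=True)
class CombinationResult:
    """The five screens of one combination assay.

    ``a_ic20``/``b_ic20`` are the single agents at their own IC20;
    ``a_combo_dose``/``b_combo_dose`` at the (lower) doses used in the
    combination.
    """

    combo: ScreenProfile
    a_ic20: ScreenProfile
    a_combo_dose: ScreenProfile
    b_ic20: ScreenProfile
    b_combo_dose: ScreenProfile

    @property
    def singles(self) -> tuple[ScreenProfile, ...]:
        return (self.a_ic20, self.a_combo_dose, self.b_ic20, self.b_combo_dose)

    @property
    def strains(self) -> pd.Index:
        idx = self.combo.z.index
        for s in self.singles:
            idx = idx.intersection(s.z.index)
        return idx


def _check_table(t: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"intensity table lacks columns: {missing}")
    if (t["intensity"] < 0).any():
        raise ValueError("intensities must be >= 0")


def quantile_normalize(t: pd.DataFrame) -> pd.DataFrame:
    """Force every array's intensity distribution onto the common one.

    Each array's values are replaced, rank for rank, by the mean order
    statistic across arrays; within-array ranks are preserved. All arrays
    must carry the same number of probes.
    """
    _check_table(t)
    arrays = t["array"].unique()
    if len(arrays) < 2:
        raise ValueError("quantile normalization needs >= 2 arrays")
    counts = t.groupby("array").size()
    if counts.nunique() != 1:
        raise ValueError("arrays have unequal probe counts")
    out = t.copy()
    out["intensity"] = out["intensity"].astype(float)
    n = int(counts.iloc[0])
    sorted_stack = np.empty((len(arrays), n))
    for k, a in enumerate(arrays):
        sorted_stack[k] = np.sort(t.loc[t["array"] == a, "intensity"].to_numpy())
    reference = sorted_stack.mean(axis=0)
    for a in arrays:
        idx = t.index[t["array"] == a]
        vals = t.loc[idx, "intensity"].to_numpy()
        ranks = np.argsort(np.argsort(vals, kind="stable"), kind="stable")
        out.loc[idx, "intensity"] = reference[ranks]
    return out


def saturation_correct(t: pd.DataFrame, ceiling: float | None = None) -> pd.DataFrame:
    """Undo hybridisation-feature saturation.

    Measured signal is modelled as ``y = c·x/(c + x)`` (hyperbolic approach
    to the scanner ceiling ``c``); inverting gives ``x = y·c/(c − y)``.
    Values at or above ``0.95·c`` are winsorised to the corrected value at
    that point and flagged in a ``saturated`` column. The default ceiling is
    0.95 × the maximum observed feature intensity.
    """
    _check_table(t)
    if ceiling is None:
        ceiling = 0.95 * float(t["intensity"].max())
    if ceiling <= 0:
        raise ValueError("ceiling must be positive")
    y = t["intensity"].to_numpy(dtype=float)
    cap = 0.95 * ceiling
    saturated = y >= cap
    y_w = np.minimum(y, cap)
    corrected = y_w * ceiling / (ceiling - y_w)
    out = t.copy()
    out["intensity"] = corrected
    out["saturated"] = saturated
    return out


def _probe_key(t: pd.DataFrame) -> pd.Series:
    return (
        t["strain"].astype(str)
        + "|"
        + t["tag"].astype(str)
        + "|"
        + t["replicate"].astype(str)
    )


def snm_normalize(t: pd.DataFrame) -> pd.DataFrame:
    """Supervised removal of batch (chip-date) effects from logged intensities.

    Per probe, intensities across arrays are modelled additively as
    treatment effect + batch effect; the fitted batch component (sum-to-zero
    coded, so treatment contrasts are untouched) is subtracted. Requires
    each batch to contain more than one treatment level, otherwise batch
    and treatment are confounded and the fit is refused. A single batch is
    a no-op.

    Input intensities must already be on the log scale.
    """
    _check_table(t)
    array_meta = (
        t[["array", "treatment", "batch"]].drop_duplicates().set_index("array")
    )
    if array_meta.index.has_duplicates:
        raise ValueError("an array maps to multiple treatment/batch labels")
    batches = array_meta["batch"].unique()
    if len(batches) == 1:
        return t.copy()
    per_batch = array_meta.groupby("batch")["treatment"].nunique()
    if (per_batch == 1).any():
        bad = list(per_batch.index[per_batch == 1])
        raise ValueError(
            f"batch(es) {bad} contain a single treatment level: "
            "batch and treatment effects are confounded"
        )
    wide = t.assign(_probe=_probe_key(t)).pivot(
        index="_probe", columns="array", values="intensity"
    )
    if wide.isna().any().any():
        raise ValueError("every probe must appear once on every array")
    arrays = wide.columns
    treat = pd.get_dummies(array_meta.loc[arrays, "treatment"]).to_numpy(float)
    batch_d = pd.get_dummies(array_meta.loc[arrays, "batch"]).to_numpy(float)
    batch_c = batch_d[:, :-1] - batch_d[:, -1:]  # sum-to-zero contrasts
    design = np.hstack([treat, batch_c])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("treatment + batch design is rank deficient")
    coef, *_ = np.linalg.lstsq(design, wide.to_numpy().T, rcond=None)
    batch_part = batch_c @ coef[treat.shape[1]:, :]
    corrected = wide.to_numpy() - batch_part.T
    fixed = pd.DataFrame(corrected, index=wide.index, columns=arrays)
    out = t.copy()
    probe = _probe_key(t)
    out["intensity"] = [
        fixed.at[p, a] for p, a in zip(probe, t["array"])
    ]
    return out


def select_tag(t: pd.DataFrame) -> pd.Series:
    """Choose the quieter barcode (up or down) per strain.

    For each strain and tag, the coefficient of variation (sd/mean over the
    5 replicate features) is computed within each array and averaged across
    arrays; the tag with the lower CV wins, ties go to the uptag. A tag with
    non-positive mean signal anywhere is disqualified; if both are
    disqualified the uptag is kept.
    """
    _check_table(t)
    strains = t.loc[~t["is_control"]]

    def _cv(g: pd.DataFrame) -> float:
        per_array = g.groupby("array")["intensity"].agg(["std", "mean"])
        if (per_array["mean"] <= 0).any() or per_array["mean"].isna().any():
            return np.inf
        return float((per_array["std"] / per_array["mean"]).mean())

    cvs = (
        strains.groupby(["strain", "tag"])[["array", "intensity"]]
        .apply(_cv)
        .unstack("tag")
    )
    chosen = {}
    for strain, row in cvs.iterrows():
        up = row.get("up", np.inf)
        down = row.get("down", np.inf)
        chosen[strain] = "down" if down < up else "up"
    return pd.Series(chosen, name="tag_used").sort_index()


def robust_z(
    t: pd.DataFrame,
    profile_for: str,
    tag_used: pd.Series | None = None,
) -> ScreenProfile:
    """Robust-Z fitness-defect profile for one treatment.

    Per strain, the selected tag's replicate features on the treatment's
    arrays are averaged into one abundance value x. The Z-score is computed
    against the control distribution (flagged control probes when present,
    otherwise all strains of the table) as::

        z = (median(controls) − x) / (1.4826 · MAD(controls))

    so depleted (sensitive) strains score positive.
    """
    _check_table(t)
    sub = t.loc[t["treatment"] == profile_for]
    if sub.empty:
        raise ValueError(f"no rows for treatment {profile_for!r}")
    if tag_used is None:
        tag_used = select_tag(t)
    strains = sub.loc[~sub["is_control"]].copy()
    strains["keep"] = strains["tag"].eq(
        strains["strain"].map(tag_used).fillna("up")
    )
    x = (
        strains.loc[strains["keep"]]
        .groupby("strain")["intensity"]
        .mean()
        .sort_index()
    )
    controls = sub.loc[sub["is_control"]]
    if len(controls) >= 3:
        ctrl_vals = controls.groupby("strain")["intensity"].mean().to_numpy()
    else:
        ctrl_vals = x.to_numpy()
    center = float(np.median(ctrl_vals))
    mad = float(np.median(np.abs(ctrl_vals - center)))
    if mad == 0:
        raise DegenerateScaleError("control MAD is zero")
    z = (center - x) / (MAD_SCALE * mad)
    ess = (
        sub.loc[~sub["is_control"]]
        .drop_duplicates("strain")
        .set_index("strain")["essentiality"]
        .reindex(z.index)
    )
    return ScreenProfile(
        treatment=profile_for,
        z=z.rename("z"),
        tag_used=tag_used.reindex(z.index),
        essentiality=ess,
    )


def combination_specific(
    r: CombinationResult, threshold: float = 2.0
) -> dict[str, set[str]]:
    """Combination-specific sensitive strains, split by panel.

    A strain qualifies when its fitness defect in the combination screen is
    ``>= threshold`` while in *each* of the four single-agent screens it
    stays strictly below the threshold. Returned keyed by panel
    (``het-essential`` → HIP, ``hom-nonessential`` → HOP).
    """
    strains = r.strains
    combo_z = r.combo.z.loc[strains]
    ok = combo_z >= threshold
    for s in r.singles:
        ok &= s.z.loc[strains] < threshold
    hits = strains[ok]
    panels: dict[str, set[str]] = {}
    for strain in hits:
        panel = str(r.combo.essentiality.get(strain, "unknown"))
        panels.setdefault(panel, set()).add(strain)
    return panels


def specific_set(r: CombinationResult, threshold: float = 2.0) -> set[str]:
    """All combination-specific strains, panels pooled."""
    out: set[str] = set()
    for strains in combination_specific(r, threshold).values():
        out |= strains
    return out


def sensitivity_epsilon(r: CombinationResult, mode: str = "product") -> pd.Series:
    """Per-strain combination sensitivity ε.

    ``mode="product"``: ε = z_AB − z_A·z_B; ``mode="sum"``:
    ε = z_AB − (z_A + z_B). Single-agent Z-scores come from the combo-dose
    screens (the doses actually present in the combination).
    """
    strains = r.strains
    z_ab = r.combo.z.loc[strains]
    z_a = r.a_combo_dose.z.loc[strains]
    z_b = r.b_combo_dose.z.loc[strains]
    if mode == "product":
        eps = z_ab - z_a * z_b
    elif mode == "sum":
        eps = z_ab - (z_a + z_b)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return eps.rename("eps")


def _correlation_distance(mat: np.ndarray) -> np.ndarray:
    """1 − Pearson r between rows; rows with zero variance get r = 0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    dist = np.clip((dist + dist.T) / 2, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    return dist


def cluster_profiles(profiles: pd.DataFrame, axis: str = "rows"):
    """Average-linkage clustering on Pearson-correlation distance.

    ``profiles`` is a strains × treatments matrix (Z-scores or ε values);
    ``axis="rows"`` clusters strains, ``axis="columns"`` treatments. Labels
    are sorted first so the leaf order is deterministic under relabelling.
    Returns ``(linkage_matrix, labels)``.
    """
    mat = profiles.sort_index(axis=0).sort_index(axis=1)
    if axis == "columns":
        mat = mat.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    labels = list(mat.index)
    if len(labels) < 2:
        raise ValueError("need at least two profiles to cluster")
    dist = _correlation_distance(mat.to_numpy(dtype=float))
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return link, labels


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree string."""
    n = len(labels)

    def height(i: int) -> float:
        return 0.0 if i < n else float(link[i - n][2])

    def render(i: int, parent_h: float) -> str:
        branch = max(parent_h - height(i), 0.0)
        if i < n:
            return f"{labels[i]}:{branch:.6g}"
        left, right = int(link[i - n][0]), int(link[i - n][1])
        h = height(i)
        return f"({render(left, h)},{render(right, h)}):{branch:.6g}"

    root = 2 * n - 2
    h = height(root)
    left, right = int(link[-1][0]), int(link[-1][1])
    return f"({render(left, h)},{render(right, h)});"
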