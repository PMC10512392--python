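"""Synthetic data with known ground truth for every analysis stage.

Three generators emulate the study designs the analysis modules consume:

* :func:`gen_dose_matrix` — checkerboard growth curves. Single-agent
  relative growth follows a Hill dose-response; the combination's relative
  growth is the Bliss product plus a planted interaction δ, realised as an
  amplitude-scaled logistic OD curve per well, so the growth→AUC pipeline
  recovers the planted interaction exactly in the noise-free limit.
* :func:`gen_combination_screens` — five-screen barcode intensity tables
  (combination + four single-agent screens) with lognormal strain
  abundances, replicate features, batch (chip-date) shifts, control probes,
  feature saturation, and a spiked set of combination-specific sensitive
  strains.
* :func:`gen_prediction_world` — single-agent chemogenomic profiles with a
  target map in which true synergistic pairs are planted exactly where drug
  A's profile sensitises drug B's target, plus configurable decoys.

All generators are deterministic given ``cfg.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import GrowthCurve
from .synergy import DoseMatrix, W_MAX
from .druggene import TargetMap
from .predict import ChemogenomicProfile

__all__ = [
    "SynthConfig",
    "HillParams",
    "hill_growth",
    "dose_ladder",
    "gen_dose_matrix",
    "measured_dose_matrix",
    "sham_dose_matrix",
    "true_w_grid",
    "gen_combination_screens",
    "gen_prediction_world",
]

#: Inhibition levels (percent) of the 6-point checkerboard dose ladder.
IC_LEVELS_6 = (0.0, 2.0, 5.0, 10.0, 20.0, 50.0)
#: Inhibition levels of the 4-point random/prediction-screen ladder.
IC_LEVELS_4 = (0.0, 10.0, 20.0, 50.0)

SCREEN_ROLES = ("combo", "a_ic20", "a_combo_dose", "b_ic20", "b_combo_dose")


@dataclass(frozen=True)
class HillParams:
    """Single-agent Hill dose-response: W(d) = 1 / (1 + (d/ic50)^slope)."""

    ic50: float
    slope: float = 2.0


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth parameters for all generators.

    Growth-curve block: 96 timepoints at 15-min spacing over 24 h; logistic
    kinetics with a ~90-min doubling time and a 0.0625 OD inoculum (typical
    plate-reader yeast runs). ``delta`` is the planted Bliss interaction on
    the relative-growth scale; ``od_noise_sd`` is additive OD read noise.

    Screen block: 200 strains (half HIP, half HOP panel), 2 tags × 5
    replicate features, two chip-date batches with a 0.5 log2 shift,
    control probes spanning a σ=1 log2 ladder (the robust-Z scale), strain
    abundance spread σ=0.25 log2, feature noise σ=0.1 log2, and spikes
    depleted by ``spike_z`` × the control scale in the combination screen
    only.
    """

    seed: int = 0
    # growth curves
    n_timepoints: int = 96
    dt_min: float = 15.0
    od_start: float = 0.0625
    od_max: float = 1.0
    growth_rate: float = 0.0077  # 1/min; ln2/r ≈ 90 min doubling
    hill_a: HillParams = HillParams(ic50=1.0, slope=2.0)
    hill_b: HillParams = HillParams(ic50=10.0, slope=2.0)
    delta: float = 0.0
    od_noise_sd: float = 0.0
    # barcode screens
    n_strains: int = 200
    n_spikes: int = 20
    spike_z: float = 4.0
    baseline_log2: float = 10.0
    strain_sd: float = 0.25
    control_sd: float = 1.0
    feature_sd: float = 0.1
    n_replicate_features: int = 5
    batch_shifts: tuple[float, ...] = (0.0, 0.5)
    control_fraction: float = 0.1
    saturation_ceiling: float = 65536.0
    spikes_in_single: int = 0
    n_single_sensitive: int | None = None  # default: n_spikes per single screen
    # prediction world
    n_drugs: int = 8
    n_extra_genes: int = 40
    n_true_pairs: int = 6
    decoy_rate: float = 0.0
    score_noise_sd: float = 0.0
    sensitivity_score: float = 3.0


def hill_growth(dose: float, hill: HillParams) -> float:
    """Relative growth of a single agent at ``dose``."""
    if dose <= 0:
        return 1.0
    return 1.0 / (1.0 + (dose / hill.ic50) ** hill.slope)


def dose_ladder(hill: HillParams, ic_levels=IC_LEVELS_6) -> np.ndarray:
    """Doses producing the requested inhibition percentages (IC levels)."""
    doses = []
    for level in ic_levels:
        if level <= 0:
            doses.append(0.0)
        else:
            frac = level / 100.0
            doses.append(hill.ic50 * (frac / (1.0 - frac)) ** (1.0 / hill.slope))
    return np.asarray(doses)


def _logistic_od(cfg: SynthConfig, times: np.ndarray) -> np.ndarray:
    x0, k, r = cfg.od_start, cfg.od_max, cfg.growth_rate
    return k / (1.0 + ((k - x0) / x0) * np.exp(-r * times))


def true_w_grid(cfg: SynthConfig, doses_a: np.ndarray, doses_b: np.ndarray) -> np.ndarray:
    """Planted relative-growth grid: Bliss product + δ on dual-drug cells."""
    wa = np.array([hill_growth(d, cfg.hill_a) for d in doses_a])
    wb = np.array([hill_growth(d, cfg.hill_b) for d in doses_b])
    grid = np.outer(wa, wb)
    grid[1:, 1:] += cfg.delta
    return np.clip(grid, 0.0, W_MAX)


def gen_dose_matrix(
    cfg: SynthConfig,
    drug_a: str = "drugA",
    drug_b: str = "drugB",
    ic_levels=IC_LEVELS_6,
):
    """Checkerboard of raw growth curves with a planted interaction.

    Per well, the OD rise is the control logistic's rise scaled by the
    planted relative growth W (an amplitude-scaled logistic: same rate,
    scaled plateau), plus optional additive Gaussian read noise. Returns
    ``(curves, doses_a, doses_b, truth)`` where ``curves[(i, j)]`` is the
    well at dose indices (i, j) and ``truth`` is the planted δ.
    """
    rng = np.random.default_rng(cfg.seed)
    times = np.arange(cfg.n_timepoints) * cfg.dt_min
    ctrl = _logistic_od(cfg, times)
    doses_a = dose_ladder(cfg.hill_a, ic_levels)
    doses_b = dose_ladder(cfg.hill_b, ic_levels)
    grid = true_w_grid(cfg, doses_a, doses_b)
    curves: dict[tuple[int, int], GrowthCurve] = {}
    for i in range(len(doses_a)):
        for j in range(len(doses_b)):
            od = cfg.od_start + grid[i, j] * (ctrl - cfg.od_start)
            if cfg.od_noise_sd > 0:
                od = od + rng.normal(0.0, cfg.od_noise_sd, size=od.shape)
            cond = (
                "control"
                if i == 0 and j == 0
                else f"{drug_a}:{doses_a[i]:g}+{drug_b}:{doses_b[j]:g}"
            )
            curves[(i, j)] = GrowthCurve(
                times=times,
                ods=np.maximum(od, 0.0),
                well_id=f"r{i}c{j}",
                condition=cond,
            )
    return curves, doses_a, doses_b, cfg.delta


def measured_dose_matrix(
    cfg: SynthConfig,
    drug_a: str = "drugA",
    drug_b: str = "drugB",
    ic_levels=IC_LEVELS_6,
    smooth_window: int = 5,
) -> tuple[DoseMatrix, float]:
    """Run the generated checkerboard through the growth pipeline.

    Convenience wrapper: generates curves, smooths them, computes the
    inhibition ratio of every well against the no-drug well, and assembles
    the DoseMatrix. Returns ``(matrix, truth δ)``.
    """
    from .growth import inhibition_ratio, smooth_curve

    curves, doses_a, doses_b, truth = gen_dose_matrix(
        cfg, drug_a, drug_b, ic_levels
    )
    smoothed = {k: smooth_curve(c, smooth_window) for k, c in curves.items()}
    control = smoothed[(0, 0)]
    w = np.zeros((len(doses_a), len(doses_b)))
    for (i, j), curve in smoothed.items():
        w[i, j] = inhibition_ratio(curve, control).w
    return (
        DoseMatrix(
            drug_a=drug_a, drug_b=drug_b, doses_a=doses_a, doses_b=doses_b, w=w
        ),
        truth,
    )


def sham_dose_matrix(
    cfg: SynthConfig, ic_levels=IC_LEVELS_6, drug: str = "drugA"
) -> DoseMatrix:
    """Self-by-self checkerboard from one Hill curve (additive control).

    Cell (i, j) receives the total dose d_i + d_j of the same drug, so the
    matrix is Loewe-additive by construction and must not be called
    synergistic.
    """
    doses = dose_ladder(cfg.hill_a, ic_levels)
    w = np.array(
        [[hill_growth(di + dj, cfg.hill_a) for dj in doses] for di in doses]
    )
    return DoseMatrix(
        drug_a=drug, drug_b=drug + "_sham", doses_a=doses, doses_b=doses, w=w
    )


def _saturate(x: np.ndarray, ceiling: float) -> np.ndarray:
    return ceiling * x / (ceiling + x)


def gen_combination_screens(cfg: SynthConfig):
    """Five-screen barcode intensity tables with spiked specific strains.

    Strains get a lognormal baseline abundance (log2 scale, σ =
    ``strain_sd``); each of the five screens is hybridised to one array per
    batch (two chip-date batches with additive log2 shifts); every array
    carries 2 tags × ``n_replicate_features`` features per strain plus
    control probes drawn from a σ = ``control_sd`` ladder. Spiked strains
    are depleted by ``spike_z × control_sd`` log2 units in the combination
    screen only (optionally also in one single-agent screen, to exercise
    the gating rule). Intensities pass through the feature-saturation
    transfer, so the analysis pipeline's correction step is exercised.

    Returns ``(table, spikes)``: the long-format intensity DataFrame and
    the planted spike strain set.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_strains
    strains = [f"strain_{i:04d}" for i in range(n)]
    essentiality = [
        "het-essential" if i < n // 2 else "hom-nonessential" for i in range(n)
    ]
    n_ctrl = max(3, int(round(cfg.control_fraction * n)))
    controls = [f"ctrl_{i:03d}" for i in range(n_ctrl)]

    base_strain = cfg.baseline_log2 + rng.normal(0.0, cfg.strain_sd, size=n)
    base_ctrl = cfg.baseline_log2 + rng.normal(0.0, cfg.control_sd, size=n_ctrl)
    tag_offset = rng.normal(0.0, 0.05, size=(n, 2))  # up/down hybridisation bias

    # Each screen depletes its own sensitive strains: the combination screen
    # the planted combination-specific spikes, and every single-agent screen
    # (run at a bioactive dose) a disjoint decoy set of the same size. This
    # mirrors real screens — each treatment has its own hit list — and keeps
    # the per-array intensity distributions exchangeable, which is what
    # quantile normalization assumes.
    n_single = (
        cfg.n_spikes if cfg.n_single_sensitive is None else cfg.n_single_sensitive
    )
    need = cfg.n_spikes + 4 * n_single
    if need > n:
        raise ValueError("not enough strains for spikes + single-agent hits")
    picked = rng.choice(n, size=need, replace=False)
    spike_idx = picked[: cfg.n_spikes]
    spikes = {strains[i] for i in spike_idx}
    single_sensitive = {
        role: set(picked[cfg.n_spikes + k * n_single:
                         cfg.n_spikes + (k + 1) * n_single])
        for k, role in enumerate(SCREEN_ROLES[1:])
    }
    single_leak_idx = set(spike_idx[: cfg.spikes_in_single])
    depletion = cfg.spike_z * cfg.control_sd

    batches = [f"chip{k + 1}" for k in range(len(cfg.batch_shifts))]
    rows: list[dict] = []
    for role in SCREEN_ROLES:
        for b_idx, batch in enumerate(batches):
            array_id = f"{role}@{batch}"
            shift = cfg.batch_shifts[b_idx]
            for s_idx, strain in enumerate(strains):
                effect = 0.0
                if strain in spikes and role == "combo":
                    effect = -depletion
                elif s_idx in single_leak_idx and role == "a_ic20":
                    effect = -depletion
                elif role != "combo" and s_idx in single_sensitive[role]:
                    effect = -depletion
                for t_idx, tag in enumerate(("up", "down")):
                    mu = base_strain[s_idx] + tag_offset[s_idx, t_idx] + shift + effect
                    logs = mu + rng.normal(
                        0.0, cfg.feature_sd, size=cfg.n_replicate_features
                    )
                    for rep, lv in enumerate(logs, start=1):
                        rows.append(
                            {
                                "strain": strain,
                                "tag": tag,
                                "replicate": rep,
                                "intensity": 2.0 ** lv,
                                "array": array_id,
                                "batch": batch,
                                "treatment": role,
                                "essentiality": essentiality[s_idx],
                                "is_control": False,
                            }
                        )
            for c_idx, ctrl in enumerate(controls):
                mu = base_ctrl[c_idx] + shift
                logs = mu + rng.normal(
                    0.0, cfg.feature_sd, size=cfg.n_replicate_features
                )
                for rep, lv in enumerate(logs, start=1):
                    rows.append(
                        {
                            "strain": ctrl,
                            "tag": "up",
                            "replicate": rep,
                            "intensity": 2.0 ** lv,
                            "array": array_id,
                            "batch": batch,
                            "treatment": role,
                            "essentiality": "control",
                            "is_control": True,
                        }
                    )
    table = pd.DataFrame(rows)
    table["intensity"] = _saturate(
        table["intensity"].to_numpy(), cfg.saturation_ceiling
    )
    return table, spikes


def gen_prediction_world(cfg: SynthConfig):
    """Chemogenomic profiles with planted predictive structure.

    ``n_drugs`` drugs each target one distinct gene; the gene universe adds
    ``n_extra_genes`` bystanders. For each planted true pair (A, B), drug
    B's target is made sensitive in A's profile (score =
    ``sensitivity_score``); decoy sensitivities are added on non-true pairs
    at ``decoy_rate``. Gaussian score noise is optional. Returns
    ``(profiles, target_map, true_pairs)`` with true pairs as frozensets of
    two drug names.
    """
    rng = np.random.default_rng(cfg.seed)
    drugs = [f"drug_{i:02d}" for i in range(cfg.n_drugs)]
    targets = {d: f"target_{i:02d}" for i, d in enumerate(drugs)}
    genes = sorted(targets.values()) + [
        f"gene_{i:03d}" for i in range(cfg.n_extra_genes)
    ]
    all_pairs = [
        (a, b) for i, a in enumerate(drugs) for b in drugs[i + 1:]
    ]
    if cfg.n_true_pairs > len(all_pairs):
        raise ValueError("more true pairs requested than pairs exist")
    chosen = rng.choice(len(all_pairs), size=cfg.n_true_pairs, replace=False)
    true_pairs = {frozenset(all_pairs[i]) for i in chosen}

    scores = {d: {g: 0.0 for g in genes} for d in drugs}
    for a, b in all_pairs:
        planted = frozenset((a, b)) in true_pairs
        for x, y in ((a, b), (b, a)):
            if targets[y] == targets[x]:
                continue
            if planted or rng.random() < cfg.decoy_rate:
                scores[x][targets[y]] = cfg.sensitivity_score
    profiles = []
    for d in drugs:
        s = dict(scores[d])
        if cfg.score_noise_sd > 0:
            for g in s:
                s[g] += rng.normal(0.0, cfg.score_noise_sd)
        profiles.append(
            ChemogenomicProfile(drug=d, scores=s, scored_as="log2_ratio")
        )
    tmap = TargetMap(targets=targets, methods={d: "synthetic" for d in drugs})
    return profiles, tmap, true_pairs
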