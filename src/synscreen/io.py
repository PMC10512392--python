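"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats: plate-reader OD tables (long ``well,time_min,od600`` or wide with a
time column), plate maps binding wells to drug doses, dose-matrix TSVs
(dose headers + W grid), ε heatmap TSVs, per-pair call JSON records,
barcode intensity TSVs, screen-profile and combination-report TSVs, and
Newick dendrograms.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .growth import GrowthCurve
from .hiphop import REQUIRED_COLUMNS, CombinationResult, ScreenProfile
from .synergy import DoseMatrix, EpsilonMatrix, SynergyCall

__all__ = [
    "read_plate_long",
    "read_plate_wide",
    "read_plate_map",
    "read_dose_matrix",
    "write_dose_matrix",
    "write_epsilon_matrix",
    "write_call_record",
    "read_intensity_table",
    "write_intensity_table",
    "write_screen_profile",
    "write_combination_report",
]


def read_plate_long(path) -> dict[str, GrowthCurve]:
    """Long plate CSV (columns well, time_min, od600) → curves by well."""
    df = pd.read_csv(path)
    needed = {"well", "time_min", "od600"}
    if not needed.issubset(df.columns):
        raise ValueError(f"plate CSV must have columns {sorted(needed)}")
    curves = {}
    for well, g in df.groupby("well", sort=True):
        g = g.sort_values("time_min")
        curves[str(well)] = GrowthCurve(
            times=g["time_min"].to_numpy(float),
            ods=g["od600"].to_numpy(float),
            well_id=str(well),
        )
    return curves


def read_plate_wide(path, time_column: str = "time_min") -> dict[str, GrowthCurve]:
    """Wide plate CSV (a time column, one column per well) → curves."""
    df = pd.read_csv(path)
    if time_column not in df.columns:
        raise ValueError(f"wide plate CSV lacks time column {time_column!r}")
    df = df.sort_values(time_column)
    t = df[time_column].to_numpy(float)
    return {
        well: GrowthCurve(times=t, ods=df[well].to_numpy(float), well_id=well)
        for well in df.columns
        if well != time_column
    }


def read_plate_map(path) -> pd.DataFrame:
    """Plate-map TSV: well, drug_a, dose_a, drug_b, dose_b."""
    df = pd.read_csv(path, sep="\t")
    needed = ["well", "drug_a", "dose_a", "drug_b", "dose_b"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"plate map lacks columns {missing}")
    for col in ("dose_a", "dose_b"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.loc[bad].iloc[0]
            raise ValueError(
                f"plate map row for well {row['well']!r}: non-numeric {col}"
            )
        df[col] = pd.to_numeric(df[col])
    return df


def assemble_dose_matrix(
    curves: dict[str, GrowthCurve],
    plate_map: pd.DataFrame,
    smooth_window: int = 5,
) -> DoseMatrix:
    """Build a checkerboard from per-well curves and a plate map.

    The map must describe a full factorial of the dose ladders of one drug
    pair, including the shared no-drug well at (0, 0).
    """
    from .growth import inhibition_ratio, smooth_curve

    drugs_a = sorted(set(plate_map["drug_a"]))
    drugs_b = sorted(set(plate_map["drug_b"]))
    if len(drugs_a) != 1 or len(drugs_b) != 1:
        raise ValueError("plate map must describe exactly one drug pair")
    doses_a = np.sort(plate_map["dose_a"].unique())
    doses_b = np.sort(plate_map["dose_b"].unique())
    lookup = {
        (row.dose_a, row.dose_b): row.well for row in plate_map.itertuples()
    }
    missing = [w for w in plate_map["well"] if w not in curves]
    if missing:
        raise ValueError(f"plate map wells missing from plate data: {missing}")
    smoothed = {w: smooth_curve(curves[w], smooth_window) for w in plate_map["well"]}
    try:
        ctrl_well = lookup[(doses_a[0], doses_b[0])]
    except KeyError:
        raise ValueError("plate map lacks the no-drug (0, 0) well") from None
    control = smoothed[ctrl_well]
    w = np.zeros((len(doses_a), len(doses_b)))
    for i, da in enumerate(doses_a):
        for j, db in enumerate(doses_b):
            well = lookup.get((da, db))
            if well is None:
                raise ValueError(f"plate map misses dose cell ({da:g}, {db:g})")
            w[i, j] = inhibition_ratio(smoothed[well], control).w
    return DoseMatrix(
        drug_a=drugs_a[0], drug_b=drugs_b[0],
        doses_a=doses_a, doses_b=doses_b, w=w,
    )


def write_dose_matrix(m: DoseMatrix, path) -> None:
    """Dose-matrix TSV: W grid with dose ladders as row/column headers."""
    df = pd.DataFrame(m.w, index=m.doses_a, columns=m.doses_b)
    df.index.name = f"{m.drug_a}|{m.drug_b}"
    df.to_csv(path, sep="\t")


def read_dose_matrix(path) -> DoseMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    name = df.index.name or "drugA|drugB"
    drug_a, _, drug_b = name.partition("|")
    return DoseMatrix(
        drug_a=drug_a,
        drug_b=drug_b or "drugB",
        doses_a=df.index.to_numpy(float),
        doses_b=np.asarray([float(c) for c in df.columns]),
        w=df.to_numpy(float),
    )


def write_epsilon_matrix(e: EpsilonMatrix, doses_a, doses_b, path) -> None:
    """ε heatmap TSV aligned to the dose matrix (margins are empty cells)."""
    df = pd.DataFrame(e.eps, index=doses_a, columns=doses_b)
    df.index.name = f"{e.drug_a}|{e.drug_b}"
    df.to_csv(path, sep="\t")


def write_call_record(call: SynergyCall, path) -> None:
    """Per-pair JSON record of the four model calls and the consensus."""
    record = {
        "drug_a": call.drug_a,
        "drug_b": call.drug_b,
        "bliss": call.bliss,
        "loewe": call.loewe,
        "hsa": call.hsa,
        "potentiation": call.potentiation,
        "consensus": call.consensus,
        "avg_s": call.avg_s,
        "min_eps": call.min_eps,
    }
    Path(path).write_text(json.dumps(record, indent=2) + "\n")


def read_intensity_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"intensity table lacks columns {missing}")
    if df["is_control"].dtype != bool:
        df["is_control"] = df["is_control"].astype(str).str.lower().isin(
            ("true", "1", "yes")
        )
    return df


def write_intensity_table(t: pd.DataFrame, path) -> None:
    t.to_csv(path, sep="\t", index=False)


def write_screen_profile(p: ScreenProfile, path) -> None:
    pd.DataFrame(
        {"strain": p.z.index, "z": p.z.to_numpy(), "tag_used": p.tag_used.to_numpy()}
    ).to_csv(path, sep="\t", index=False)


def write_combination_report(
    r: CombinationResult,
    eps: pd.Series,
    specific: set[str],
    path,
) -> None:
    """Combination report TSV: per strain, panel, the five Z's, ε, and flag."""
    strains = r.strains
    pd.DataFrame(
        {
            "strain": strains,
            "panel": r.combo.essentiality.loc[strains].to_numpy(),
            "z_combo": r.combo.z.loc[strains].to_numpy(),
            "z_a_ic20": r.a_ic20.z.loc[strains].to_numpy(),
            "z_a_combo_dose": r.a_combo_dose.z.loc[strains].to_numpy(),
            "z_b_ic20": r.b_ic20.z.loc[strains].to_numpy(),
            "z_b_combo_dose": r.b_combo_dose.z.loc[strains].to_numpy(),
            "eps": eps.loc[strains].to_numpy(),
            "combination_specific": [s in specific for s in strains],
        }
    ).to_csv(path, sep="\t", index=False)
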