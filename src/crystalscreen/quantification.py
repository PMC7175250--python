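"""Dose-response quantification of crystallization inhibition.

Per-crystal class labels and calibrated areas are aggregated into per-
condition totals (a condition is one compound concentration within one
experiment, imaged as 2 wells x 5 fields by default).  The crystal total is
the COM + COD + n.d. area; the noise class is tracked but excluded.  Totals
are normalized to the in-experiment no-inhibitor control, never across
experiments, because absolute crystallization yield varies between
experiments.  The minimal inhibitory concentration (MIC) is the lowest
tested concentration whose across-experiment mean normalized area falls
strictly below the 5% threshold; when no concentration qualifies the
sentinel "> <max tested>" is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging_io import CLASS_NAMES

CRYSTAL_CLASSES = (0, 1, 2)   # COM, COD, n.d. count toward the crystal total
DEFAULT_THRESHOLD = 0.05      # "< 5% of control" inhibition rule

CONDITION_KEYS = ["experiment_id", "compound", "concentration_nm"]


class NormalizationError(ValueError):
    """Missing or zero-area control: normalization is undefined."""


@dataclass(frozen=True)
class InhibitionResult:
    """Minimal inhibitory concentrations for one compound.

    ``mic_complete_nm`` / ``mic_com_nm`` are concentrations in nM, or None
    when the criterion is never met on the tested grid ("not reached").
    """

    compound: str
    concentrations_nm: tuple[float, ...]
    mean_normalized_total: tuple[float, ...]   # % of control, per concentration
    mean_normalized_com: tuple[float, ...]
    mic_complete_nm: float | None
    mic_com_nm: float | None
    threshold: float = DEFAULT_THRESHOLD

    def render_mic(self, which: str = "complete") -> str:
        mic = self.mic_complete_nm if which == "complete" else self.mic_com_nm
        if mic is None:
            return f">{format_concentration(max(self.concentrations_nm))}"
        return format_concentration(mic)


def format_concentration(nm: float) -> str:
    """Human-readable concentration, e.g. 40 nm -> '40 nM', 3000 -> '3 µM'."""
    if nm >= 1e6:
        return f"{nm / 1e6:g} mM"
    if nm >= 1e3:
        return f"{nm / 1e3:g} µM"
    return f"{nm:g} nM"


def quantify_wells(crystals: pd.DataFrame,
                   keys: list[str] | None = None) -> pd.DataFrame:
    """Aggregate labeled crystals into per-condition class areas and counts.

    ``crystals`` must carry the condition key columns, ``well_id``,
    ``field_index``, ``area`` (µm²) and ``label``.  Output has one row per
    condition with total_area_<cls>, count_<cls>, mean_area_per_field_<cls>,
    n_fields and the crystal total (COM + COD + n.d.).
    """
    keys = keys or CONDITION_KEYS
    required = set(keys) | {"well_id", "field_index", "area", "label"}
    missing = required - set(crystals.columns)
    if missing:
        raise ValueError(f"crystal table missing column(s): {sorted(missing)}")
    if crystals["label"].isna().any():
        raise ValueError("unlabeled segment(s) in crystal table")
    rows = []
    for cond, grp in crystals.groupby(keys, sort=True):
        n_fields = grp.groupby(["well_id", "field_index"]).ngroups
        row = dict(zip(keys, cond))
        row["n_fields"] = n_fields
        crystal_total = 0.0
        for cls, name in CLASS_NAMES.items():
            sel = grp[grp["label"] == cls]
            total = float(sel["area"].sum())
            row[f"total_area_{name}"] = total
            row[f"count_{name}"] = int(len(sel))
            row[f"mean_area_per_field_{name}"] = total / n_fields if n_fields else 0.0
            if cls in CRYSTAL_CLASSES:
                crystal_total += total
        row["total_area_crystal"] = crystal_total
        rows.append(row)
    return pd.DataFrame(rows)


def normalize_to_control(wells: pd.DataFrame,
                         is_control: pd.Series | None = None) -> pd.DataFrame:
    """Express each condition's areas as % of its experiment's control.

    The control condition is concentration 0 (or rows flagged by
    ``is_control``); there must be exactly one per experiment with a
    nonzero crystal total.  Normalization never pools across experiments.
    """
    wells = wells.copy()
    if is_control is None:
        wells["_ctrl"] = wells["concentration_nm"] == 0
    else:
        wells["_ctrl"] = np.asarray(is_control, dtype=bool)
    out = []
    for exp_id, grp in wells.groupby("experiment_id", sort=True):
        ctrl = grp[grp["_ctrl"]]
        if len(ctrl) != 1:
            raise NormalizationError(
                f"experiment {exp_id}: expected exactly 1 control condition, found {len(ctrl)}"
            )
        denom = float(ctrl["total_area_crystal"].iloc[0])
        if denom <= 0:
            raise NormalizationError(f"experiment {exp_id}: control crystal total is zero")
        g = grp.drop(columns="_ctrl").copy()
        g["normalized_total"] = g["total_area_crystal"] / denom * 100.0
        g["normalized_COM"] = g["total_area_COM"] / denom * 100.0
        g["normalized_COD"] = g["total_area_COD"] / denom * 100.0
        out.append(g)
    return pd.concat(out, ignore_index=True)


def min_inhibitory_concentration(series: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD,
                                 mode: str = "complete") -> float | None:
    """Lowest tested concentration with mean normalized area < threshold.

    ``series`` has columns concentration_nm and the mode's mean normalized
    area in % (``mean_normalized_total`` or ``mean_normalized_com``);
    concentrations must be sorted ascending.  The comparison is strict
    (area fraction < threshold); returns None when never satisfied.
    """
    if len(series) == 0:
        raise ValueError("empty concentration series")
    col = "mean_normalized_total" if mode == "complete" else "mean_normalized_com"
    if col not in series.columns:
        raise ValueError(f"series missing column {col!r}")
    conc = series["concentration_nm"].to_numpy(dtype=float)
    if not np.all(np.diff(conc) > 0):
        raise ValueError("concentrations must be sorted strictly ascending")
    frac = series[col].to_numpy(dtype=float) / 100.0
    below = np.nonzero(frac < threshold)[0]
    return float(conc[below[0]]) if len(below) else None


def dose_response(normalized: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD,
                  com_denominator: str = "total",
                  per_experiment: bool = False) -> list[InhibitionResult]:
    """MICs per compound from per-experiment normalized condition areas.

    By default the across-experiment *mean* normalized series is thresholded
    (matching mean + SD reporting per concentration); ``per_experiment=True``
    instead computes a MIC per experiment and averages the reached ones.
    ``com_denominator`` selects the reference for COM-only inhibition:
    ``"total"`` compares COM area to the control's total crystal area (the
    default), ``"com"`` to the control's COM area.
    """
    results = []
    treated = normalized[normalized["concentration_nm"] > 0]
    for compound, grp in treated.groupby("compound", sort=True):
        com_col = "normalized_COM"
        if com_denominator == "com":
            grp = grp.copy()
            com_ref = {}
            ctrl = normalized[normalized["concentration_nm"] == 0]
            for exp_id, c in ctrl.groupby("experiment_id"):
                com_total = float(c["total_area_COM"].iloc[0])
                if com_total <= 0:
                    raise NormalizationError(
                        f"experiment {exp_id}: control COM area is zero"
                    )
                com_ref[exp_id] = com_total
            grp["normalized_COM_vs_com"] = [
                row.total_area_COM / com_ref[row.experiment_id] * 100.0
                for row in grp.itertuples()
            ]
            com_col = "normalized_COM_vs_com"
        means = (
            grp.groupby("concentration_nm", sort=True)
            .agg(mean_normalized_total=("normalized_total", "mean"),
                 mean_normalized_com=(com_col, "mean"))
            .reset_index()
        )
        if per_experiment:
            mic_complete = _mean_per_experiment_mic(grp, "normalized_total", threshold)
            mic_com = _mean_per_experiment_mic(grp, com_col, threshold)
        else:
            mic_complete = min_inhibitory_concentration(means, threshold, "complete")
            mic_com = min_inhibitory_concentration(means, threshold, "com")
        results.append(InhibitionResult(
            compound=str(compound),
            concentrations_nm=tuple(means["concentration_nm"]),
            mean_normalized_total=tuple(means["mean_normalized_total"]),
            mean_normalized_com=tuple(means["mean_normalized_com"]),
            mic_complete_nm=mic_complete,
            mic_com_nm=mic_com,
            threshold=threshold,
        ))
    return results


def _mean_per_experiment_mic(grp: pd.DataFrame, col: str, threshold: float) -> float | None:
    mics = []
    for _, sub in grp.groupby("experiment_id"):
        series = (
            sub.sort_values("concentration_nm")
            .rename(columns={col: "mean_normalized_total"})
            [["concentration_nm", "mean_normalized_total"]]
        )
        mic = min_inhibitory_concentration(series, threshold, "complete")
        if mic is not None:
            mics.append(mic)
    return float(np.mean(mics)) if mics else None


def com_size_distribution(crystals: pd.DataFrame,
                          keys: list[str] | None = None) -> pd.DataFrame:
    """Pool single-COM crystal areas per condition with summary quantiles.

    Returns one row per condition: the pooled COM areas (µm², as a list),
    their count, and the 25/50/75% quantiles.  The pooled count equals the
    sum of per-field COM counts by construction.
    """
    keys = keys or ["compound", "concentration_nm"]
    com = crystals[crystals["label"] == 0]
    rows = []
    for cond, grp in com.groupby(keys, sort=True):
        areas = grp["area"].to_numpy(dtype=float)
        row = dict(zip(keys, cond))
        row["areas"] = areas.tolist()
        row["n"] = len(areas)
        q25, q50, q75 = np.percentile(areas, [25, 50, 75]) if len(areas) else (np.nan,) * 3
        row.update({"q25": q25, "median": q50, "q75": q75})
        rows.append(row)
    return pd.DataFrame(rows)
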