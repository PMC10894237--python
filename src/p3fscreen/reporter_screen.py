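"""Dual-reporter screen triage: percent-of-control, weighted score, classes.

The screen measures three channels per compound: an ALK super-enhancer
luciferase (fusion-oncogene transcriptional activity), a CMV
promoter-driven luciferase (general transcription) and XTT viability.
Each channel is normalized per plate to vehicle controls, the three
percents are combined into the weighted triage score

    (4*ALK + 2*CMV + XTT) / 7

and compounds are classified by how the two reporters move: strong
(both below 10% of control), HDACi-like (ALK down, CMV up), or
ALK-selective (ALK down, CMV unchanged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "ClassificationRules",
    "percent_of_control",
    "weighted_score",
    "classify_compound",
    "classify_table",
    "select_primary_hits",
    "score_screen",
]

CHANNELS = ("ALK_LUC", "CMV_LUC", "XTT")
_CHANNEL_COLUMN = {"ALK_LUC": "alk_pct", "CMV_LUC": "cmv_pct", "XTT": "xtt_pct"}


@dataclass(frozen=True)
class ClassificationRules:
    """Thresholds (percent of vehicle control) for the three-group partition.

    strong_threshold : both reporters below this → strong inhibitor.
    alk_decrease_threshold : ALK at or below this counts as decreased.
    cmv_increase_delta : CMV at or above 100 + delta counts as increased.
    cmv_unchanged_band : CMV within 100 ± band counts as unchanged.
    """

    strong_threshold: float = 10.0
    alk_decrease_threshold: float = 50.0
    cmv_increase_delta: float = 20.0
    cmv_unchanged_band: float = 20.0

    def __post_init__(self):
        if not (0 < self.strong_threshold < self.alk_decrease_threshold <= 100):
            raise ValueError(
                "require 0 < strong_threshold < alk_decrease_threshold <= 100"
            )


def percent_of_control(wells: pd.DataFrame) -> pd.DataFrame:
    """Normalize sample signals to the vehicle-control mean of their plate.

    ``wells`` has columns compound_id, plate_id, well, channel, role,
    signal.  For every (plate, channel) the vehicle mean is computed from
    role == 'vehicle_control' wells (>= 2 required, mean > 0), and each
    sample well becomes 100 * signal / vehicle_mean.  Compounds measured
    in fewer than the three channels are excluded with a warning.

    Returns a frame with one row per compound: compound_id, alk_pct,
    cmv_pct, xtt_pct.
    """
    required = {"compound_id", "plate_id", "channel", "role", "signal"}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"wells table missing columns: {sorted(missing)}")
    if (wells["signal"] < 0).any():
        raise ValueError("signals must be non-negative")

    vehicle = wells[wells["role"] == "vehicle_control"]
    stats = vehicle.groupby(["plate_id", "channel"])["signal"].agg(["count", "mean"])
    samples = wells[wells["role"] == "sample"].copy()
    if samples["compound_id"].isna().any() or (samples["compound_id"] == "").any():
        raise ValueError("sample wells must carry a compound_id")

    for plate_id, channel in samples.groupby(["plate_id", "channel"]).groups:
        if (plate_id, channel) not in stats.index:
            raise ValueError(f"plate {plate_id!r} has no vehicle controls for {channel}")
        row = stats.loc[(plate_id, channel)]
        if row["count"] < 2:
            raise ValueError(
                f"plate {plate_id!r} channel {channel} has <2 vehicle wells"
            )
        if row["mean"] <= 0:
            raise ValueError(
                f"plate {plate_id!r} channel {channel} vehicle mean is not positive"
            )

    vmean = stats["mean"]
    samples["pct"] = 100.0 * samples["signal"] / samples.set_index(
        ["plate_id", "channel"]
    ).index.map(vmean)

    wide = samples.pivot_table(
        index="compound_id", columns="channel", values="pct", aggfunc="mean"
    )
    have_all = wide.reindex(columns=list(CHANNELS)).notna().all(axis=1)
    n_incomplete = int((~have_all).sum())
    if n_incomplete:
        warnings.warn(
            f"excluded {n_incomplete} compound(s) measured in <3 channels",
            stacklevel=2,
        )
    wide = wide[have_all]
    out = pd.DataFrame(
        {
            "compound_id": wide.index,
            "alk_pct": wide["ALK_LUC"].to_numpy(),
            "cmv_pct": wide["CMV_LUC"].to_numpy(),
            "xtt_pct": wide["XTT"].to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def weighted_score(alk_pct, cmv_pct, xtt_pct):
    """Weighted triage score (4*ALK + 2*CMV + XTT) / 7, in percent.

    Accepts scalars or arrays; a convex combination, so the score always
    lies between the smallest and largest of its three inputs.
    """
    alk = np.asarray(alk_pct, dtype=float)
    cmv = np.asarray(cmv_pct, dtype=float)
    xtt = np.asarray(xtt_pct, dtype=float)
    for name, arr in (("alk_pct", alk), ("cmv_pct", cmv), ("xtt_pct", xtt)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} must be finite")
        if np.any(arr < 0):
            raise ValueError(f"{name} must be non-negative")
    out = (4.0 * alk + 2.0 * cmv + xtt) / 7.0
    return float(out) if out.ndim == 0 else out


def classify_compound(alk_pct: float, cmv_pct: float,
                      rules: ClassificationRules = ClassificationRules()) -> str:
    """Assign one of strong / hdaci_like / alk_selective / unclassified.

    Rules are applied in that order, so every compound gets exactly one
    label and strong takes precedence over the other two.
    """
    if alk_pct < 0 or cmv_pct < 0:
        raise ValueError("percent-of-control inputs must be non-negative")
    if alk_pct < rules.strong_threshold and cmv_pct < rules.strong_threshold:
        return "strong"
    if alk_pct <= rules.alk_decrease_threshold:
        if cmv_pct >= 100.0 + rules.cmv_increase_delta:
            return "hdaci_like"
        if abs(cmv_pct - 100.0) <= rules.cmv_unchanged_band:
            return "alk_selective"
    return "unclassified"


def classify_table(scores: pd.DataFrame,
                   rules: ClassificationRules = ClassificationRules()) -> pd.Series:
    """Vectorized :func:`classify_compound` over a scores frame."""
    alk = scores["alk_pct"].to_numpy(dtype=float)
    cmv = scores["cmv_pct"].to_numpy(dtype=float)
    if (alk < 0).any() or (cmv < 0).any():
        raise ValueError("percent-of-control inputs must be non-negative")
    labels = np.full(len(scores), "unclassified", dtype=object)
    alk_down = alk <= rules.alk_decrease_threshold
    labels[alk_down & (np.abs(cmv - 100.0) <= rules.cmv_unchanged_band)] = "alk_selective"
    labels[alk_down & (cmv >= 100.0 + rules.cmv_increase_delta)] = "hdaci_like"
    labels[(alk < rules.strong_threshold) & (cmv < rules.strong_threshold)] = "strong"
    return pd.Series(labels, index=scores.index, name="class_label")


def select_primary_hits(scores: pd.DataFrame, score_threshold: float,
                        top_n: int | None = None) -> pd.DataFrame:
    """Primary hits: weighted_score <= threshold, ranked ascending.

    Ties broken by compound_id (stable, lexicographic); ``top_n`` truncates
    after ranking.
    """
    if len(scores) == 0:
        raise ValueError("scores table is empty")
    if not (0 <= score_threshold <= 100):
        raise ValueError("score_threshold must lie in [0, 100]")
    hits = scores[scores["weighted_score"] <= score_threshold]
    hits = hits.sort_values(["weighted_score", "compound_id"], kind="mergesort")
    if top_n is not None:
        hits = hits.head(top_n)
    return hits.reset_index(drop=True)


def score_screen(wells: pd.DataFrame,
                 rules: ClassificationRules = ClassificationRules()) -> pd.DataFrame:
    """Full triage: percent-of-control → weighted score → class label."""
    scores = percent_of_control(wells)
    scores["weighted_score"] = weighted_score(
        scores["alk_pct"], scores["cmv_pct"], scores["xtt_pct"]
    )
    scores["class_label"] = classify_table(scores, rules)
    return scores
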