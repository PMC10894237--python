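"""Tiled-sgRNA depletion mapping.

Per-guide log2 fold change against a reference (plasmid) pool after
median-ratio or reads-per-million normalization, smoothed with a trailing
walking average of 4 guides, with the >4-fold depleted fraction and
hotspot intervals called against a non-targeting empirical null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DepletionProfile",
    "HotspotCall",
    "normalize_counts",
    "log_fold_depletion",
    "walking_average",
    "depleted_fraction",
    "depletion_profile",
    "call_hotspots",
]

PSEUDOCOUNT = 0.5  # added after normalization, before logs


def normalize_counts(counts: pd.DataFrame, method: str = "median_ratio",
                     reference: str | None = None) -> pd.DataFrame:
    """Normalize a guides x samples count matrix.

    median_ratio : DESeq-style size factors — per sample, the median over
        guides of count / geometric-mean-across-samples, computed on guides
        with no zero count.  When ``reference`` names a sample, factors are
        rescaled so that sample's factor is exactly 1 (normalized counts are
        then on the reference scale).
    rpm : reads per million.

    Returns the real-valued normalized matrix (counts / size_factor).
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples to normalize")
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    mat = counts.to_numpy(dtype=float)
    if method == "median_ratio":
        nonzero = (mat > 0).all(axis=1)
        if not nonzero.any():
            raise ValueError("no guide has nonzero counts in every sample")
        sub = mat[nonzero]
        geomean = np.exp(np.log(sub).mean(axis=1))
        factors = np.median(sub / geomean[:, None], axis=0)
        if reference is not None:
            if reference not in counts.columns:
                raise KeyError(f"unknown reference sample {reference!r}")
            factors = factors / factors[counts.columns.get_loc(reference)]
    elif method == "rpm":
        factors = totals.to_numpy(dtype=float) / 1e6
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    if (factors <= 0).any():
        raise ValueError("non-positive size factor")
    return pd.DataFrame(mat / factors, index=counts.index,
                        columns=counts.columns)


def log_fold_depletion(normalized: pd.DataFrame, sample_id: str,
                       reference_id: str) -> pd.Series:
    """Per-guide log2((sample + 0.5) / (reference + 0.5)); negative = depleted."""
    for sid in (sample_id, reference_id):
        if sid not in normalized.columns:
            raise KeyError(f"unknown sample id {sid!r}")
    s = normalized[sample_id].to_numpy(dtype=float)
    r = normalized[reference_id].to_numpy(dtype=float)
    lfc = np.log2((s + PSEUDOCOUNT) / (r + PSEUDOCOUNT))
    return pd.Series(lfc, index=normalized.index, name="lfc")


def walking_average(values, w: int = 4) -> np.ndarray:
    """Trailing sliding-window mean: output[i] = mean(values[i:i+w]).

    Output length is n - w + 1; requires n >= w >= 1.
    """
    values = np.asarray(values, dtype=float)
    if w < 1:
        raise ValueError("window must be >= 1")
    if values.size < w:
        raise ValueError(f"need at least w={w} values, got {values.size}")
    windows = np.lib.stride_tricks.sliding_window_view(values, w)
    return windows.mean(axis=1)


def depleted_fraction(lfcs, fold_threshold: float = 4.0) -> float:
    """Fraction of guides depleted by more than ``fold_threshold``-fold,
    i.e. with lfc strictly below -log2(fold_threshold)."""
    lfcs = np.asarray(lfcs, dtype=float)
    if lfcs.size == 0:
        raise ValueError("empty lfc list")
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    return float(np.mean(lfcs < -np.log2(fold_threshold)))


@dataclass
class DepletionProfile:
    """Per-guide depletion along the tiled gene plus its smoothed track.

    Window i covers the half-open interval
    [positions[i], positions[i + w - 1] + 1).
    """

    guide_ids: list
    positions: np.ndarray
    lfc: np.ndarray
    smoothed: np.ndarray
    window_starts: np.ndarray
    window_ends: np.ndarray
    w: int


@dataclass
class HotspotCall:
    start: int
    end: int  # half-open
    mean_smoothed_lfc: float
    n_guides: int
    n_windows: int
    empirical_p: float | None


def depletion_profile(table: pd.DataFrame, sample_id: str,
                      reference_id: str, w: int = 4,
                      method: str = "median_ratio") -> tuple[DepletionProfile, pd.Series]:
    """Normalize, compute per-guide LFC for the tiled gene, and smooth.

    ``table`` follows the guide-count schema (guide_id, target, position,
    count columns).  Returns (profile, non_targeting_lfcs); the latter is
    the empirical null for hotspot p-values.
    """
    count_cols = [c for c in table.columns
                  if c not in ("guide_id", "target", "gene", "position")]
    counts = table.set_index("guide_id")[count_cols]
    norm = normalize_counts(counts, method=method, reference=reference_id)
    lfc_all = log_fold_depletion(norm, sample_id, reference_id)

    tiled = table[table["target"] == "tiled_gene"].sort_values("position",
                                                               kind="mergesort")
    positions = tiled["position"].to_numpy(dtype=int)
    lfc = lfc_all.loc[tiled["guide_id"]].to_numpy()
    smoothed = walking_average(lfc, w)
    profile = DepletionProfile(
        guide_ids=tiled["guide_id"].tolist(),
        positions=positions,
        lfc=lfc,
        smoothed=smoothed,
        window_starts=positions[: len(smoothed)],
        window_ends=positions[w - 1:] + 1,
        w=w,
    )
    nt = table[table["target"] == "non_targeting"]["guide_id"]
    return profile, lfc_all.loc[nt]


def call_hotspots(profile: DepletionProfile, null_lfcs,
                  lfc_cutoff: float = -2.0, min_windows: int = 2,
                  n_null: int = 10000, null_seed: int = 0) -> list[HotspotCall]:
    """Call depleted hotspot intervals from the smoothed profile.

    Maximal runs of >= min_windows consecutive windows with smoothed LFC
    <= lfc_cutoff are merged into coordinate intervals.  The empirical p
    of a call is the add-one-corrected fraction of null window means (w
    non-targeting LFCs resampled n_null times with a fixed internal seed,
    so calls are deterministic) at or below the observed mean; reported as
    None when fewer than 10 non-targeting guides are available.
    """
    null_lfcs = np.asarray(null_lfcs, dtype=float)
    below = profile.smoothed <= lfc_cutoff
    calls: list[HotspotCall] = []

    null_means = None
    if null_lfcs.size >= 10:
        rng = np.random.default_rng(null_seed)
        idx = rng.integers(0, null_lfcs.size, size=(n_null, profile.w))
        null_means = null_lfcs[idx].mean(axis=1)

    i = 0
    n = below.size
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and below[j + 1]:
            j += 1
        run_len = j - i + 1
        if run_len >= min_windows:
            start = int(profile.window_starts[i])
            end = int(profile.window_ends[j])
            mean_lfc = float(profile.smoothed[i: j + 1].mean())
            in_iv = (profile.positions >= start) & (profile.positions < end)
            if null_means is not None:
                p = (1.0 + np.count_nonzero(null_means <= mean_lfc)) / (1.0 + n_null)
            else:
                p = None
            calls.append(HotspotCall(
                start=start, end=end, mean_smoothed_lfc=mean_lfc,
                n_guides=int(in_iv.sum()), n_windows=run_len,
                empirical_p=p,
            ))
        i = j + 1
    return calls
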