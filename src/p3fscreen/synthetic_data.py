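"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its spec (seed included) and returns
both the simulated tables and a ground-truth sidecar, so downstream
modules can be tested end-to-end without any external data:

* plate-format dual-reporter screens with vehicle/positive controls and
  planted compound classes,
* 4PL dose-response series on the follow-up screen's 10-fold dilution
  grid (20 uM .. 2 nM),
* negative-binomial tiled-sgRNA counts with a planted depleted hotspot
  plus essential-gene and non-targeting controls,
* two-condition region-count matrices with planted fold changes and
  per-sample spike-in totals,
* ranked gene lists with a planted enriched set.

Noise models: plate signals use multiplicative lognormal noise with a
stated CV (luminescence is positive and right-skewed); counts use the
negative binomial with mean m and dispersion a (var = m + a*m^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import DEFAULT_DOSES_MOLAR, four_pl
from .gsea_lite import GeneSet

__all__ = [
    "ScreenSimSpec",
    "TilingSimSpec",
    "RegionSimSpec",
    "RankSimSpec",
    "simulate_screen",
    "simulate_dose_response",
    "simulate_tiling_counts",
    "simulate_region_counts",
    "simulate_ranked_list",
]

SCREEN_CLASSES = ("hdaci_like", "alk_selective", "strong", "inactive")

#: Per-class mean percent-of-control for (ALK_LUC, CMV_LUC, XTT).
DEFAULT_EFFECTS = {
    "hdaci_like": (30.0, 140.0, 90.0),
    "alk_selective": (30.0, 100.0, 90.0),
    "strong": (5.0, 5.0, 40.0),
    "inactive": (100.0, 100.0, 100.0),
}

_BASELINE_SIGNAL = 1000.0  # arbitrary vehicle-level instrument units


def _exact_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment: integer counts summing to n."""
    keys = list(proportions)
    raw = np.array([proportions[k] * n for k in keys])
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="mergesort")
    for i in order[:remainder]:
        counts[i] += 1
    return dict(zip(keys, counts))


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=size)


def _nb_draw(rng: np.random.Generator, mean, dispersion: float, size=None):
    """Negative binomial with var = mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


@dataclass(frozen=True)
class ScreenSimSpec:
    n_compounds: int = 2000
    class_proportions: dict = field(
        default_factory=lambda: {
            "hdaci_like": 0.05, "alk_selective": 0.05,
            "strong": 0.02, "inactive": 0.88,
        }
    )
    effect_params: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    noise_cv: float = 0.05
    wells_per_plate: int = 384
    vehicle_controls_per_plate: int = 16
    positive_controls_per_plate: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.n_compounds <= 0:
            raise ValueError("n_compounds must be positive")
        if set(self.class_proportions) != set(SCREEN_CLASSES):
            raise ValueError(f"class_proportions must cover {SCREEN_CLASSES}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.vehicle_controls_per_plate < 2:
            raise ValueError("need >= 2 vehicle wells per plate")
        n_controls = self.vehicle_controls_per_plate + self.positive_controls_per_plate
        if self.wells_per_plate <= n_controls:
            raise ValueError("wells_per_plate must exceed control well count")


def simulate_screen(spec: ScreenSimSpec):
    """Simulate one single-dose screen; returns (wells, truth).

    ``wells`` has one row per compound per channel plus control wells;
    ``truth`` maps compound_id to its planted class.  Class counts are
    exact (largest-remainder apportionment of the proportions), class
    assignment order is shuffled across compounds, and all signals carry
    multiplicative lognormal noise with CV ``noise_cv``.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _exact_counts(spec.n_compounds, spec.class_proportions)
    labels = np.repeat(
        [c for c in SCREEN_CLASSES], [counts[c] for c in SCREEN_CLASSES]
    )
    rng.shuffle(labels)
    width = len(str(spec.n_compounds))
    compound_ids = np.array(
        [f"C{i + 1:0{width}d}" for i in range(spec.n_compounds)]
    )
    truth = pd.DataFrame({"compound_id": compound_ids, "class_label": labels})

    samples_per_plate = (
        spec.wells_per_plate
        - spec.vehicle_controls_per_plate
        - spec.positive_controls_per_plate
    )
    channels = ("ALK_LUC", "CMV_LUC", "XTT")
    effect = {
        c: dict(zip(channels, spec.effect_params[c])) for c in SCREEN_CLASSES
    }
    rows = []
    n_plates = -(-spec.n_compounds // samples_per_plate)
    for plate in range(n_plates):
        plate_id = f"P{plate + 1:03d}"
        lo = plate * samples_per_plate
        hi = min(lo + samples_per_plate, spec.n_compounds)
        for channel in channels:
            vnoise = _lognormal_factor(
                rng, spec.noise_cv, spec.vehicle_controls_per_plate
            )
            for j in range(spec.vehicle_controls_per_plate):
                rows.append(
                    ("", plate_id, f"V{j + 1:02d}", channel, "vehicle_control",
                     _BASELINE_SIGNAL * vnoise[j])
                )
            pnoise = _lognormal_factor(
                rng, spec.noise_cv, spec.positive_controls_per_plate
            )
            for j in range(spec.positive_controls_per_plate):
                rows.append(
                    ("", plate_id, f"Q{j + 1:02d}", channel, "positive_control",
                     _BASELINE_SIGNAL * 0.05 * pnoise[j])
                )
            snoise = _lognormal_factor(rng, spec.noise_cv, hi - lo)
            for j, idx in enumerate(range(lo, hi)):
                mean_pct = effect[labels[idx]][channel]
                rows.append(
                    (compound_ids[idx], plate_id, f"S{j + 1:03d}", channel,
                     "sample", _BASELINE_SIGNAL * mean_pct / 100.0 * snoise[j])
                )
    wells = pd.DataFrame(
        rows,
        columns=["compound_id", "plate_id", "well", "channel", "role", "signal"],
    )
    return wells, truth


def simulate_dose_response(
    params: tuple[float, float, float, float],
    doses=DEFAULT_DOSES_MOLAR,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    compound_id: str = "CMPD",
    channel: str = "ALK_LUC",
) -> pd.DataFrame:
    """Simulate a dose-response series from 4PL parameters + Gaussian noise.

    ``params`` is (bottom, top, ec50_molar, hill).  The default dose grid
    is the five 10-fold dilutions from 20 uM down to 2 nM.
    """
    bottom, top, ec50, hill = params
    if hill == 0:
        raise ValueError("hill slope must be nonzero")
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for rep in range(1, n_replicates + 1):
        clean = four_pl(doses, bottom, top, ec50, hill)
        noise = rng.normal(0.0, noise_sd, doses.size) if noise_sd > 0 else 0.0
        for d, r in zip(doses, clean + noise):
            records.append((compound_id, channel, d, rep, r))
    return pd.DataFrame(
        records,
        columns=["compound_id", "channel", "dose_molar", "replicate", "response"],
    )


@dataclass(frozen=True)
class TilingSimSpec:
    n_guides: int = 479
    gene_span: tuple[int, int] = (0, 4790)
    hotspot_interval: tuple[int, int] = (3000, 3350)
    hotspot_lfc: float = -3.0
    dispersion: float = 0.01
    library_size: float = 1_000_000.0
    n_essential_controls: int = 32  # 8 essential genes x 4 guides
    n_nontargeting: int = 20
    essential_lfc: float = -3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_guides < 4:
            raise ValueError("n_guides must be at least the smoothing window")
        lo, hi = self.gene_span
        hlo, hhi = self.hotspot_interval
        if not (lo <= hlo < hhi <= hi):
            raise ValueError("hotspot_interval must lie inside gene_span")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.hotspot_lfc >= 0:
            raise ValueError("hotspot_lfc must be negative (a depletion)")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")


def simulate_tiling_counts(spec: TilingSimSpec):
    """Simulate tiled-sgRNA counts; returns (table, truth).

    Tiled guides are evenly spaced across the gene span; guides whose
    position falls inside the hotspot interval have mean log2 fold change
    ``hotspot_lfc`` in the selected sample, essential-control guides have
    mean ``essential_lfc`` and non-targeting guides 0.  Both the reference
    (plasmid pool) and selected-sample counts are negative binomial around
    a common per-guide library mean.

    ``truth`` carries the planted hotspot interval and per-guide planted
    LFCs.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.gene_span
    positions = np.floor(np.linspace(lo, hi, spec.n_guides, endpoint=False)).astype(int)

    guide_ids, targets, genes, pos_col, lfc = [], [], [], [], []
    for i, p in enumerate(positions):
        guide_ids.append(f"KDM3B_g{i + 1:03d}")
        targets.append("tiled_gene")
        genes.append("KDM3B")
        pos_col.append(int(p))
        inside = spec.hotspot_interval[0] <= p < spec.hotspot_interval[1]
        lfc.append(spec.hotspot_lfc if inside else 0.0)
    n_ess_genes = max(1, spec.n_essential_controls // 4)
    for i in range(spec.n_essential_controls):
        gene = f"ESS{(i % n_ess_genes) + 1}"
        guide_ids.append(f"{gene}_g{i // n_ess_genes + 1}")
        targets.append("essential_control")
        genes.append(gene)
        pos_col.append(-1)
        lfc.append(spec.essential_lfc)
    for i in range(spec.n_nontargeting):
        guide_ids.append(f"NT_g{i + 1:02d}")
        targets.append("non_targeting")
        genes.append("non_targeting")
        pos_col.append(-1)
        lfc.append(0.0)

    lfc = np.asarray(lfc)
    n_total = len(guide_ids)
    per_guide_mean = spec.library_size / n_total
    ref = _nb_draw(rng, np.full(n_total, per_guide_mean), spec.dispersion)
    sel = _nb_draw(rng, per_guide_mean * 2.0 ** lfc, spec.dispersion)

    table = pd.DataFrame(
        {
            "guide_id": guide_ids,
            "target": targets,
            "gene": genes,
            "position": pos_col,
            "plasmid": ref,
            "selected": sel,
        }
    )
    truth = {
        "hotspot_interval": spec.hotspot_interval,
        "planted_lfc": pd.Series(lfc, index=guide_ids, name="planted_lfc"),
    }
    return table, truth


@dataclass(frozen=True)
class RegionSimSpec:
    n_regions: int = 5000
    frac_up: float = 0.1
    planted_fc: float = 4.0
    baseline_mean: float = 100.0
    dispersion: float = 0.02
    n_replicates: int = 3
    spike_totals: tuple[int, ...] | None = None  # control reps then treated reps
    global_shift: float = 1.0
    region_length: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.n_regions <= 0:
            raise ValueError("n_regions must be positive")
        if not 0 <= self.frac_up <= 1:
            raise ValueError("frac_up must lie in [0, 1]")
        if self.frac_up > 0 and round(self.frac_up * self.n_regions) < 1:
            raise ValueError("frac_up too small: fewer than one planted region")
        if self.planted_fc <= 1:
            raise ValueError("planted_fc must exceed 1")
        if self.dispersion <= 0 or self.baseline_mean <= 0:
            raise ValueError("dispersion and baseline_mean must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.global_shift <= 0:
            raise ValueError("global_shift must be > 0")
        if self.spike_totals is not None:
            if len(self.spike_totals) != 2 * self.n_replicates:
                raise ValueError("spike_totals needs one entry per sample")
            if any(t <= 0 for t in self.spike_totals):
                raise ValueError("spike totals must be positive")


def simulate_region_counts(spec: RegionSimSpec):
    """Simulate a two-condition region-count matrix; returns
    (regions, counts, spike_totals, condition_labels, truth).

    A fixed number round(frac_up * n_regions) of regions carries
    ``planted_fc`` in the treated condition; ``global_shift`` multiplies
    *all* treated target counts uniformly (a genome-wide signal change
    that library-size normalization would erase and only the spike-in
    preserves).  Spike totals default to 1e6 per sample.
    """
    rng = np.random.default_rng(spec.seed)
    sample_ids = [f"control_{i + 1}" for i in range(spec.n_replicates)] + [
        f"treated_{i + 1}" for i in range(spec.n_replicates)
    ]
    conditions = ["control"] * spec.n_replicates + ["treated"] * spec.n_replicates
    spike = (
        np.full(2 * spec.n_replicates, 1_000_000, dtype=int)
        if spec.spike_totals is None
        else np.asarray(spec.spike_totals, dtype=int)
    )

    n_planted = int(round(spec.frac_up * spec.n_regions))
    planted = np.zeros(spec.n_regions, dtype=bool)
    if n_planted:
        planted[rng.choice(spec.n_regions, size=n_planted, replace=False)] = True

    region_ids = [f"region_{i + 1:05d}" for i in range(spec.n_regions)]
    starts = np.arange(spec.n_regions) * 2 * spec.region_length
    regions = pd.DataFrame(
        {
            "chrom": "chrSim",
            "start": starts,
            "end": starts + spec.region_length,
            "name": region_ids,
            "score": 0,
            "strand": ".",
        }
    )

    base = rng.lognormal(np.log(spec.baseline_mean), 0.5, spec.n_regions)
    counts = {}
    for sid, cond in zip(sample_ids, conditions):
        mean = base.copy()
        if cond == "treated":
            mean = mean * spec.global_shift
            mean[planted] = mean[planted] * spec.planted_fc
        counts[sid] = _nb_draw(rng, mean, spec.dispersion)
    counts = pd.DataFrame(counts, index=region_ids)
    spike_totals = pd.Series(spike, index=sample_ids, name="spike_total")
    truth = pd.DataFrame({"region": region_ids, "planted_up": planted})
    labels = pd.Series(conditions, index=sample_ids, name="condition")
    return regions, counts, spike_totals, labels, truth


@dataclass(frozen=True)
class RankSimSpec:
    n_genes: int = 1000
    set_size: int = 50
    planted_shift: float = 0.0
    score_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not 0 < self.set_size < self.n_genes:
            raise ValueError("set_size must lie in (0, n_genes)")
        if self.score_noise_sd <= 0:
            raise ValueError("score_noise_sd must be positive")


def simulate_ranked_list(spec: RankSimSpec):
    """Simulate a ranked gene list with one planted set; returns
    (ranked, gene_set) where ranked is a Series (gene -> score, descending)
    and the planted members carry ``planted_shift`` added to their scores.
    """
    rng = np.random.default_rng(spec.seed)
    genes = np.array([f"G{i + 1:05d}" for i in range(spec.n_genes)])
    scores = rng.normal(0.0, spec.score_noise_sd, spec.n_genes)
    members = rng.choice(spec.n_genes, size=spec.set_size, replace=False)
    scores[members] += spec.planted_shift
    ranked = pd.Series(scores, index=genes, name="score").sort_values(
        ascending=False, kind="mergesort"
    )
    gene_set = GeneSet(
        name="PLANTED", members=frozenset(genes[members]),
        description="planted enriched set",
    )
    return ranked, gene_set
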