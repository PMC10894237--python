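"""Preranked gene-set enrichment: weighted running-sum ES, gene-set
permutation NES / p / FDR, leading-edge extraction, and construction of
UP/DOWN gene sets from a differential table.

The enrichment score follows the standard preranked definition: walking
down the ranking, set members increment the running sum proportionally to
|score|**weight_exponent (normalized by the total hit weight) and
non-members decrement it by 1/(N - m); ES is the signed extremum of the
running sum.  The null is gene-set permutation: random same-size sets
drawn from the ranked universe.

Estimator choices (documented in the methods note):

* NES normalizes ES by the mean |null ES| of matching sign.
* The permutation p-value is the add-one two-sided magnitude estimator
  p = (1 + #{|null ES| >= |ES|}) / (1 + n_perm), which is exactly uniform
  under the null by exchangeability, has floor 1/(1 + n_perm) and is
  never 0.  A result is flagged unstable when fewer than 10 null ES share
  the observed sign (the NES denominator is then poorly estimated).
* FDR across multiple sets uses the standard sign-stratified
  ratio-of-tail-proportions on null vs observed NES, clamped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "preranked_es",
    "permutation_nes",
    "gsea",
    "leading_edge",
    "make_up_down_sets",
]


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (GMT record)."""

    name: str
    members: frozenset
    description: str = ""

    def __post_init__(self):
        if not self.members:
            raise ValueError("gene set members must be non-empty")
        object.__setattr__(self, "members", frozenset(self.members))


@dataclass
class EnrichmentResult:
    name: str
    es: float
    nes: float
    p: float
    fdr: float
    size: int
    leading_edge: list
    running_sum: np.ndarray
    n_perm: int
    unstable: bool = False


def _validate_ranked(ranked: pd.Series) -> pd.Series:
    if ranked.index.has_duplicates:
        raise ValueError("duplicate gene ids in ranked list")
    if ranked.isna().any():
        raise ValueError("ranked list contains NaN scores")
    return ranked.sort_values(ascending=False, kind="mergesort")


def _hit_mask(ranked: pd.Series, members) -> np.ndarray:
    hit = ranked.index.isin(list(members))
    m = int(hit.sum())
    if m == 0:
        raise ValueError("gene set has no members in the ranked universe")
    if m == len(ranked):
        raise ValueError("gene set covers the entire ranked universe")
    return hit


def _running_sum(scores: np.ndarray, hit: np.ndarray,
                 weight_exponent: float) -> np.ndarray:
    n = scores.size
    m = int(hit.sum())
    w = np.abs(scores[hit]) ** weight_exponent
    total = w.sum()
    inc = np.full(n, -1.0 / (n - m))
    if total > 0:
        inc[hit] = w / total
    else:  # all hit scores zero: fall back to equal hit weights
        inc[hit] = 1.0 / m
    return np.cumsum(inc)


def _signed_extremum(run: np.ndarray) -> tuple[float, int]:
    i = int(np.argmax(np.abs(run)))  # first index at ties
    return float(run[i]), i


def preranked_es(ranked: pd.Series, gene_set: GeneSet | set,
                 weight_exponent: float = 1.0):
    """Weighted preranked enrichment score.

    Parameters
    ----------
    ranked : pd.Series
        Scores indexed by unique gene id (any order; sorted descending
        internally).
    gene_set : GeneSet or set of gene ids.
    weight_exponent : float
        1.0 = the "weighted" scoring scheme; 0.0 = classic KS-style.

    Returns
    -------
    (es, running_sum)
    """
    ranked = _validate_ranked(ranked)
    members = gene_set.members if isinstance(gene_set, GeneSet) else gene_set
    hit = _hit_mask(ranked, members)
    run = _running_sum(ranked.to_numpy(dtype=float), hit, weight_exponent)
    es, _ = _signed_extremum(run)
    return es, run


def _null_es(scores: np.ndarray, m: int, n_perm: int,
             weight_exponent: float, rng: np.random.Generator,
             block: int = 256) -> np.ndarray:
    """Vectorized null ES from random same-size member sets."""
    n = scores.size
    w_all = np.abs(scores) ** weight_exponent
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        keys = rng.random((b, n))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        inc = np.full((b, n), -1.0 / (n - m))
        w = w_all[idx]
        tot = w.sum(axis=1, keepdims=True)
        rows = np.arange(b)[:, None]
        inc[rows, idx] = np.where(tot > 0, w / np.where(tot > 0, tot, 1.0), 1.0 / m)
        run = np.cumsum(inc, axis=1)
        pos = np.abs(run).argmax(axis=1)
        out[done:done + b] = run[np.arange(b), pos]
        done += b
    return out


def permutation_nes(ranked: pd.Series, gene_set: GeneSet,
                    n_perm: int = 1000, seed: int | None = None,
                    weight_exponent: float = 1.0) -> EnrichmentResult:
    """Gene-set permutation enrichment test for one set.

    Draws ``n_perm`` random sets of the same effective size from the
    ranked universe, normalizes ES by the mean |null ES| of matching sign
    (NES), and reports the add-one magnitude permutation p-value with
    floor 1/(1 + n_perm).  Fully deterministic for a fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ranked = _validate_ranked(ranked)
    hit = _hit_mask(ranked, gene_set.members)
    scores = ranked.to_numpy(dtype=float)
    run = _running_sum(scores, hit, weight_exponent)
    es, _ = _signed_extremum(run)

    rng = np.random.default_rng(seed)
    null = _null_es(scores, int(hit.sum()), n_perm, weight_exponent, rng)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    unstable = same_sign.size < 10
    denom = np.abs(same_sign).mean() if same_sign.size else np.abs(null).mean()
    nes = es / denom if denom > 0 else 0.0
    p = (1.0 + np.count_nonzero(np.abs(null) >= abs(es))) / (1.0 + n_perm)

    # single-set FDR: tail proportion of same-sign null NES beyond the
    # observed NES (the multi-set version lives in gsea())
    if denom > 0 and same_sign.size:
        null_nes = same_sign / denom
        fdr = min(1.0, np.count_nonzero(np.abs(null_nes) >= abs(nes))
                  / same_sign.size) if same_sign.size else 1.0
        fdr = max(fdr, 0.0)
    else:
        fdr = 1.0

    le = leading_edge(ranked, gene_set, es=es, running_sum=run)
    return EnrichmentResult(
        name=gene_set.name, es=es, nes=nes, p=float(p), fdr=float(fdr),
        size=int(hit.sum()), leading_edge=le, running_sum=run,
        n_perm=n_perm, unstable=bool(unstable),
    )


def gsea(ranked: pd.Series, gene_sets: list[GeneSet], n_perm: int = 1000,
         seed: int | None = None, weight_exponent: float = 1.0):
    """Enrichment over multiple sets with sign-stratified permutation FDR.

    Returns (results_table, results) where results_table is a DataFrame
    (set, es, nes, p, fdr, size, leading_edge_size) and results the list
    of per-set :class:`EnrichmentResult` (FDR field updated in place to
    the multi-set estimate).
    """
    if not gene_sets:
        raise ValueError("no gene sets supplied")
    ranked = _validate_ranked(ranked)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(gene_sets))
    results, null_nes_all = [], []
    for gs, cs in zip(gene_sets, child_seeds):
        rng = np.random.default_rng(cs)
        hit = _hit_mask(ranked, gs.members)
        scores = ranked.to_numpy(dtype=float)
        run = _running_sum(scores, hit, weight_exponent)
        es, _ = _signed_extremum(run)
        null = _null_es(scores, int(hit.sum()), n_perm, weight_exponent, rng)
        pos_mean = np.abs(null[null > 0]).mean() if (null > 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        denom = pos_mean if es >= 0 else neg_mean
        nes = es / denom if np.isfinite(denom) and denom > 0 else 0.0
        null_nes = np.where(null > 0,
                            null / pos_mean if np.isfinite(pos_mean) else np.nan,
                            null / neg_mean if np.isfinite(neg_mean) else np.nan)
        null_nes_all.append(null_nes[np.isfinite(null_nes)])
        p = (1.0 + np.count_nonzero(np.abs(null) >= abs(es))) / (1.0 + n_perm)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        results.append(EnrichmentResult(
            name=gs.name, es=es, nes=nes, p=float(p), fdr=1.0,
            size=int(hit.sum()),
            leading_edge=leading_edge(ranked, gs, es=es, running_sum=run),
            running_sum=run, n_perm=n_perm, unstable=bool(same.size < 10),
        ))

    pooled = np.concatenate(null_nes_all) if null_nes_all else np.array([])
    obs = np.array([r.nes for r in results])
    for r in results:
        if r.nes >= 0:
            null_tail = np.mean(pooled[pooled >= 0] >= r.nes) if (pooled >= 0).any() else 1.0
            obs_tail = np.mean(obs[obs >= 0] >= r.nes) if (obs >= 0).any() else 1.0
        else:
            null_tail = np.mean(pooled[pooled < 0] <= r.nes) if (pooled < 0).any() else 1.0
            obs_tail = np.mean(obs[obs < 0] <= r.nes) if (obs < 0).any() else 1.0
        r.fdr = float(min(1.0, null_tail / obs_tail)) if obs_tail > 0 else 1.0

    table = pd.DataFrame(
        {
            "set": [r.name for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p": [r.p for r in results],
            "fdr": [r.fdr for r in results],
            "size": [r.size for r in results],
            "leading_edge_size": [len(r.leading_edge) for r in results],
        }
    )
    return table, results


def leading_edge(ranked: pd.Series, gene_set: GeneSet | set,
                 es: float | None = None,
                 running_sum: np.ndarray | None = None) -> list:
    """Members driving the enrichment signal.

    For positive ES: set members at or before the running-sum maximum;
    mirrored for negative ES.  An ES of exactly 0 yields an empty list.
    """
    ranked = _validate_ranked(ranked)
    members = gene_set.members if isinstance(gene_set, GeneSet) else gene_set
    hit = _hit_mask(ranked, members)
    if running_sum is None:
        running_sum = _running_sum(ranked.to_numpy(dtype=float), hit, 1.0)
        es, _ = _signed_extremum(running_sum)
    if es == 0:
        return []
    if es > 0:
        peak = int(np.argmax(running_sum))
        keep = np.zeros(len(ranked), dtype=bool)
        keep[: peak + 1] = True
    else:
        trough = int(np.argmin(running_sum))
        keep = np.zeros(len(ranked), dtype=bool)
        keep[trough:] = True
    return list(ranked.index[hit & keep])


def make_up_down_sets(diff_table: pd.Series, k: int = 50,
                      prefix: str = "SET"):
    """Build UP/DOWN gene sets from a differential ranking statistic.

    ``diff_table`` maps gene id -> statistic (e.g. log2 fold change).  The
    UP set takes the k largest strictly positive statistics, the DOWN set
    the k smallest strictly negative ones; boundary ties break by
    lexicographic gene id (smaller id included).  If fewer than k genes
    qualify in a direction, all are taken and a shortfall flag is set.

    Returns (up_set, down_set, flags) with flags = {'up_shortfall':
    bool, 'down_shortfall': bool}.
    """
    if len(diff_table) == 0:
        raise ValueError("differential table is empty")
    if diff_table.index.has_duplicates:
        raise ValueError("duplicate gene ids in differential table")
    pos = diff_table[diff_table > 0]
    neg = diff_table[diff_table < 0]
    if pos.empty or neg.empty:
        raise ValueError("need at least one gene in each direction")

    up_order = pos.to_frame("stat").reset_index(names="gene").sort_values(
        ["stat", "gene"], ascending=[False, True], kind="mergesort"
    )
    down_order = neg.to_frame("stat").reset_index(names="gene").sort_values(
        ["stat", "gene"], ascending=[True, True], kind="mergesort"
    )
    up_genes = up_order["gene"].head(k).tolist()
    down_genes = down_order["gene"].head(k).tolist()
    flags = {
        "up_shortfall": len(up_genes) < k,
        "down_shortfall": len(down_genes) < k,
    }
    up = GeneSet(name=f"{prefix}_UP", members=frozenset(up_genes),
                 description=f"top {len(up_genes)} upregulated")
    down = GeneSet(name=f"{prefix}_DOWN", members=frozenset(down_genes),
                   description=f"top {len(down_genes)} downregulated")
    return up, down, flags
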