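"""GC3-ranked pre-ranked gene-set enrichment with a permutation null.

Transcripts are ranked by the log2 ratio of their GC3% to the mean GC3% of
the analysed set.  For each gene set a weighted running-sum enrichment score
(ES) is computed on that ranking (hit increments proportional to
|score|^weight, default weight 1; uniform miss decrements), the null comes
from random gene-label permutations, p-values are two-sided against the
signed null, and the Benjamini-Hochberg step-up controls the FDR across
sets.  Positive ES = set concentrated among GC3-rich transcripts (GP2-like);
negative ES = AU3-rich (GP1-like).

Also here: derivation of the GP1/GP2 gene groups from enrichment sign, and
the GC3-perturbation robustness protocol (re-run the whole analysis after
jittering every gene's GC3%, count the sets that stay significant in at
least ``min_hits`` replicates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

DEFAULT_MIN_SIZE = 5
DEFAULT_MAX_SIZE = 500


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankedGeneList:
    """(gene_id, score) pairs sorted by descending score; score is the log2
    ratio of the gene's GC3% to the mean GC3% of all included genes."""

    entries: tuple[tuple[str, float], ...]
    mean_gc3_pct: float

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.entries)

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, s in self.entries], dtype=float)

    def reversed(self) -> "RankedGeneList":
        return RankedGeneList(entries=self.entries[::-1], mean_gc3_pct=self.mean_gc3_pct)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style: id, description, members)."""

    sets: dict[str, tuple[str, tuple[str, ...]]]  # set_id -> (name, members)

    def __post_init__(self) -> None:
        for sid, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {sid!r} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {sid!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_id: str) -> tuple[str, ...]:
        return self.sets[set_id][1]


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    name: str
    size: int                      # members present in the ranked list
    es: float
    nes: float
    p_perm: float
    fdr_bh: float
    direction: int                 # sign(ES): +1 GC3-enriched, -1 AU3-enriched
    leading_edge: tuple[str, ...]


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def rank_by_gc3(gc3: pd.Series | pd.DataFrame) -> RankedGeneList:
    """Rank genes by log2(gc3_pct / mean gc3_pct), descending.

    Accepts a per-gene gc3 Series or a composition table with a ``gc3_pct``
    column.  Genes with gc3 = 0 are excluded (log undefined) with a warning.
    Ties are broken by gene id, lexicographically.
    """
    if isinstance(gc3, pd.DataFrame):
        gc3 = gc3["gc3_pct"]
    gc3 = gc3.astype(float)
    zero = gc3 <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} genes with gc3_pct <= 0 excluded from ranking")
        gc3 = gc3[~zero]
    if len(gc3) < 2:
        raise ValueError("need >= 2 genes with positive GC3 to rank")
    mean = float(gc3.mean())
    scores = np.log2(gc3 / mean)
    order = sorted(zip(gc3.index, scores), key=lambda t: (-t[1], t[0]))
    return RankedGeneList(entries=tuple((g, float(s)) for g, s in order),
                          mean_gc3_pct=mean)


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

def _running_sum_es(
    weights: np.ndarray, hit: np.ndarray
) -> tuple[float, int]:
    """Weighted Kolmogorov-Smirnov-like running sum.

    ``weights`` = |score|^weight in ranked order; ``hit`` boolean mask of set
    membership.  Returns (ES, index of the extremum).
    """
    n = weights.size
    k = int(hit.sum())
    hit_w = np.where(hit, weights, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        # all member scores are exactly zero: fall back to unweighted hits
        hit_w = hit.astype(float)
        denom = float(k)
    inc = hit_w / denom - (~hit) / (n - k)
    running = np.cumsum(inc)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), idx


def enrichment_score(
    ranked: RankedGeneList, members: Sequence[str], weight: float = 1.0
) -> tuple[float, tuple[str, ...]]:
    """ES of one gene set on a ranked list, plus its leading-edge genes."""
    genes = ranked.gene_ids
    member_set = set(members)
    hit = np.fromiter((g in member_set for g in genes), bool, count=len(genes))
    w = np.abs(ranked.scores) ** weight
    es, idx = _running_sum_es(w, hit)
    if es >= 0:
        leading = tuple(g for g, h in zip(genes[: idx + 1], hit[: idx + 1]) if h)
    else:
        leading = tuple(g for g, h in zip(genes[idx:], hit[idx:]) if h)
    return es, leading


def _null_es(
    weights: np.ndarray, k: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null ES distribution for sets of size k by gene-label permutation,
    vectorised over permutations."""
    n = weights.size
    # random k-subsets: argpartition of uniform noise
    u = rng.random((n_perm, n))
    idx = np.argpartition(u, k - 1, axis=1)[:, :k]
    hit = np.zeros((n_perm, n), dtype=bool)
    rows = np.repeat(np.arange(n_perm), k)
    hit[rows, idx.ravel()] = True
    hit_w = hit * weights
    denom = hit_w.sum(axis=1, keepdims=True)
    zero = denom[:, 0] == 0
    if zero.any():
        hit_w[zero] = hit[zero].astype(float)
        denom = hit_w.sum(axis=1, keepdims=True)
    inc = hit_w / denom - (~hit) / (n - k)
    running = np.cumsum(inc, axis=1)
    ext = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), ext]


def preranked_enrichment(
    ranked: RankedGeneList,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int | None = None,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> list[EnrichmentResult]:
    """Pre-ranked enrichment of every analysable set with permutation p and
    BH FDR across sets.

    Sets with fewer than ``min_size`` members present in the list, or more
    than ``max_size``, are skipped (logged); a set covering the entire list
    is an error.  Null ES distributions are shared between sets of equal
    effective size.  Two-sided p against the signed null; NES = ES divided
    by the mean |null ES| of same-sign permutations.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-value resolution will be poor")
    rng = np.random.default_rng(seed)
    genes = ranked.gene_ids
    gene_index = set(genes)
    w = np.abs(ranked.scores) ** weight

    analysed: list[tuple[str, str, tuple[str, ...]]] = []
    for sid, (name, members) in sets.sets.items():
        present = tuple(m for m in members if m in gene_index)
        if len(present) >= len(genes):
            raise ValueError(f"gene set {sid!r} covers the entire ranked list")
        if not (min_size <= len(present) <= max_size):
            warnings.warn(
                f"gene set {sid!r}: {len(present)} members in list, outside "
                f"[{min_size}, {max_size}]; skipped"
            )
            continue
        analysed.append((sid, name, present))
    if not analysed:
        return []

    null_cache: dict[int, np.ndarray] = {}
    rows: list[dict] = []
    for sid, name, present in analysed:
        k = len(present)
        es, leading = enrichment_score(ranked, present, weight)
        if k not in null_cache:
            null_cache[k] = _null_es(w, k, n_perm, rng)
        null = null_cache[k]
        # numerical ties (same running-sum height reached along a different
        # accumulation path) count as at-least-as-extreme
        p = (1.0 + np.sum(np.abs(null) >= abs(es) - 1e-12)) / (n_perm + 1.0)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        scale = np.abs(same_sign).mean() if same_sign.size else np.abs(null).mean()
        nes = es / scale if scale > 0 else 0.0
        rows.append(
            dict(set_id=sid, name=name, size=k, es=es, nes=nes, p_perm=p,
                 leading_edge=leading)
        )
    qs = bh_fdr([r["p_perm"] for r in rows])
    return [
        EnrichmentResult(
            set_id=r["set_id"], name=r["name"], size=r["size"], es=r["es"],
            nes=r["nes"], p_perm=r["p_perm"], fdr_bh=float(q),
            direction=int(np.sign(r["es"])) if r["es"] != 0 else 0,
            leading_edge=r["leading_edge"],
        )
        for r, q in zip(rows, qs)
    ]


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# GP1 / GP2 derivation and robustness
# ---------------------------------------------------------------------------

def derive_groups(
    results: Sequence[EnrichmentResult],
    fdr_cut: float = 0.01,
    use_leading_edge: bool = True,
    sets: GeneSetCollection | None = None,
) -> tuple[set[str], set[str]]:
    """GP1/GP2 gene groups from enrichment sign at the FDR cut.

    GP1 = union of (leading-edge) genes of significant negative-ES sets
    (AU3-rich); GP2 = same for positive ES (GC3-rich).  Genes landing in
    both groups are excluded from both, with a warning.  With
    ``use_leading_edge=False`` full set memberships are used (requires
    ``sets``).
    """
    gp1: set[str] = set()
    gp2: set[str] = set()
    any_sig = False
    for res in results:
        if res.fdr_bh >= fdr_cut or res.es == 0:
            continue
        any_sig = True
        if use_leading_edge:
            genes = set(res.leading_edge)
        else:
            if sets is None:
                raise ValueError("full-membership mode needs the GeneSetCollection")
            genes = set(sets.members(res.set_id))
        (gp1 if res.es < 0 else gp2).update(genes)
    if not any_sig:
        warnings.warn("no significant sets at the requested FDR; GP1 and GP2 empty")
    overlap = gp1 & gp2
    if overlap:
        warnings.warn(f"{len(overlap)} genes in both GP1 and GP2 excluded from both")
        gp1 -= overlap
        gp2 -= overlap
    return gp1, gp2


def perturbation_robustness(
    gc3: pd.Series | pd.DataFrame,
    sets: GeneSetCollection,
    delta_pct_list: Sequence[float],
    n_reps: int = 5,
    n_perm: int = 1000,
    fdr_cut: float = 0.01,
    min_hits: int = 5,
    seed: int | None = None,
    mode: str = "additive",
) -> pd.DataFrame:
    """Count gene sets that stay significant under GC3 jitter.

    For each delta (percentage points), ``n_reps`` replicates add independent
    uniform noise in [-delta, +delta] to every gene's GC3% (clipped to
    (0, 100]), re-rank and re-run the enrichment; a set "survives" when its
    FDR is below ``fdr_cut`` in at least ``min_hits`` replicates.  Returns a
    DataFrame (delta, surviving_count).  ``mode="multiplicative"`` scales by
    (1 + U(-delta, delta)/100) instead.
    """
    if isinstance(gc3, pd.DataFrame):
        gc3 = gc3["gc3_pct"]
    if n_reps < min_hits:
        raise ValueError(f"n_reps={n_reps} < min_hits={min_hits}")
    if any(d < 0 for d in delta_pct_list):
        raise ValueError("deltas must be non-negative")
    master = np.random.default_rng(seed)
    rows = []
    for delta in delta_pct_list:
        if delta == 0:
            # zero jitter: every replicate is the same analysis, so one run
            # suffices and the count equals the unperturbed significant count
            ranked = rank_by_gc3(gc3)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                results = preranked_enrichment(
                    ranked, sets, n_perm=n_perm,
                    seed=int(master.integers(2**31)),
                )
            surviving = sum(1 for r in results if r.fdr_bh < fdr_cut)
            rows.append({"delta": 0.0, "surviving_count": surviving})
            continue
        hits: dict[str, int] = {}
        for rep in range(n_reps):
            rep_rng = np.random.default_rng(master.integers(2**31))
            noise = rep_rng.uniform(-delta, delta, size=len(gc3))
            if mode == "additive":
                jittered = gc3.to_numpy(dtype=float) + noise
            elif mode == "multiplicative":
                jittered = gc3.to_numpy(dtype=float) * (1.0 + noise / 100.0)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            jittered = np.clip(jittered, 1e-9, 100.0)
            ranked = rank_by_gc3(pd.Series(jittered, index=gc3.index))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                results = preranked_enrichment(
                    ranked, sets, n_perm=n_perm,
                    seed=int(rep_rng.integers(2**31)),
                )
            for res in results:
                if res.fdr_bh < fdr_cut:
                    hits[res.set_id] = hits.get(res.set_id, 0) + 1
        surviving = sum(1 for v in hits.values() if v >= min_hits)
        rows.append({"delta": float(delta), "surviving_count": surviving})
    return pd.DataFrame(rows)
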