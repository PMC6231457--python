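"""Gene-set statistics for co-expression modules.

Two complementary engines:

* hypergeometric over-representation of a discrete module against a
  GO/KEGG/hallmark-style collection, with Benjamini-Hochberg adjustment
  applied separately within each set family;
* preranked GSEA: the weighted Kolmogorov-Smirnov-style running-sum
  enrichment score over a ranked gene list (e.g. genes ranked by their
  correlation to a candidate gene), with a gene-label permutation null and
  sign-matched NES normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import GeneSetCollection

DEFAULT_MIN_TERM_SIZE = 5
DEFAULT_MAX_TERM_SIZE = 2000


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set's overlap with a module.

    ``N`` genes in the universe, ``K`` of them annotated to the term,
    ``n`` in the module, ``k`` in the overlap; ``p_hyper`` is the
    upper-tail hypergeometric probability P(X >= k) and ``p_adj`` its
    BH-adjusted value within the term's family.
    """

    term_id: str
    term_name: str
    family: str
    N: int
    K: int
    n: int
    k: int
    p_hyper: float
    p_adj: float


@dataclass(frozen=True)
class GseaResult:
    set_id: str
    es: float
    nes: float
    p_perm: float
    n_perm: int
    seed: int
    n_hits: int


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed in log space.

    ``N`` universe size, ``K`` annotated genes, ``n`` draws (module size),
    ``k`` observed overlap.  ``k = 0`` gives exactly 1.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValidationError(f"{name} must be a non-negative integer, got {v}")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if K > N or n > N:
        raise ValidationError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(n, K):
        raise ValidationError(f"k={k} exceeds min(n={n}, K={K})")
    if k == 0:
        return 1.0
    # survival function at k-1 is the upper tail including k
    return float(stats.hypergeom(N, K, n).sf(k - 1))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adjusted_(i) = min_{j >= i} (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def enrich_module(module_genes, collection: GeneSetCollection, universe,
                  min_term_size: int = DEFAULT_MIN_TERM_SIZE,
                  max_term_size: int = DEFAULT_MAX_TERM_SIZE) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of a module against a collection.

    The universe is the reference gene population (all annotated symbols on
    the platform after deduplication); set members are intersected with it
    before counting, and terms outside the [min, max] size bounds after
    restriction are skipped.  BH is applied separately within each family.
    """
    universe = {g.upper() for g in universe}
    module = {g.upper() for g in module_genes} & universe
    if not universe:
        raise ValidationError("empty universe")
    if not module:
        raise ValidationError("empty module (after universe restriction)")
    N, n = len(universe), len(module)

    raw: list[tuple] = []
    for s in collection:
        members = set(s.members) & universe
        K = len(members)
        if K < min_term_size or K > max_term_size:
            continue
        k = len(members & module)
        p = hypergeom_upper_tail(k, K, n, N)
        raw.append((s, K, k, p))

    results: list[EnrichmentResult] = []
    for family in sorted({s.family for s, *_ in raw}):
        fam = [t for t in raw if t[0].family == family]
        adj = bh_adjust([t[3] for t in fam])
        for (s, K, k, p), pa in zip(fam, adj):
            results.append(EnrichmentResult(
                term_id=s.term_id, term_name=s.name, family=family,
                N=N, K=K, n=n, k=k, p_hyper=p, p_adj=float(pa)))
    results.sort(key=lambda r: (r.p_adj, r.p_hyper, r.term_id))
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results],
                        columns=["term_id", "term_name", "family", "N", "K",
                                 "n", "k", "p_hyper", "p_adj"])


# ---------------------------------------------------------------------------
# Preranked GSEA
# ---------------------------------------------------------------------------

def _running_sum_extremum(scores: np.ndarray, hit_pos: np.ndarray,
                          weight_exponent: float) -> float:
    """Signed extremum of the weighted KS running sum.

    ``scores`` are the ranking scores in descending order; ``hit_pos`` the
    (sorted) positions of set members.  Hits increment by
    |score|^w normalized over in-set hits; misses decrement by
    1/(N - set size).  Only positions adjacent to hits can host the
    extremum, so the scan is O(set size).
    """
    n_genes = scores.size
    m = hit_pos.size
    w = np.abs(scores[hit_pos]) ** weight_exponent
    total = w.sum()
    if total == 0.0:
        # all in-set scores are exactly zero: fall back to unweighted hits
        w = np.ones(m)
        total = float(m)
    hit_steps = np.cumsum(w) / total
    miss_unit = 1.0 / (n_genes - m) if n_genes > m else 0.0
    # running value just after hit i (0-based): hit_steps[i] - misses so far
    misses_after = (hit_pos + 1) - np.arange(1, m + 1)
    after = hit_steps - misses_after * miss_unit
    # running value just before hit i
    before = np.concatenate(([0.0], hit_steps[:-1])) - (hit_pos - np.arange(m)) * miss_unit
    hi = after.max()
    lo = min(before.min(), 0.0)
    return float(hi if hi >= -lo else lo)


def gsea_preranked(ranking: pd.Series, gene_set, weight_exponent: float = 1.0,
                   n_perm: int = 1000, seed: int = 0) -> GseaResult:
    """Preranked GSEA of one gene set against a scored gene ranking.

    Parameters
    ----------
    ranking:
        Series of scores indexed by unique gene symbol (e.g. Pearson r of
        each gene against a candidate gene); sorted descending internally,
        ties broken by symbol for determinism.
    gene_set:
        An :class:`~seedcoex.io.GeneSet` or any object with ``members``
        (or a plain iterable of symbols).
    weight_exponent:
        Exponent on |score| for hit increments (0 = classic unweighted KS,
        1 = canonical weighted statistic).
    n_perm, seed:
        Size of the gene-label permutation null and its RNG seed; the
        permutation p-value is (1 + #{same-sign perms as or more extreme})
        / (1 + #{same-sign perms}).
    """
    if ranking.index.has_duplicates:
        raise ValidationError("ranking genes must be unique")
    members = getattr(gene_set, "members", gene_set)
    set_id = getattr(gene_set, "term_id", "gene_set")
    member_set = {g.upper() for g in members}
    genes = np.asarray(ranking.index.str.upper())
    in_set = np.isin(genes, list(member_set))
    if not in_set.any():
        raise ValidationError(f"gene set {set_id!r} has no overlap with the ranking")

    order = np.lexsort((np.asarray(genes), -ranking.to_numpy(dtype=float)))
    scores = ranking.to_numpy(dtype=float)[order]
    hits = np.flatnonzero(in_set[order])
    m = hits.size
    n_genes = scores.size
    if m == n_genes:
        # degenerate: every ranked gene is in the set
        return GseaResult(set_id=set_id, es=1.0, nes=np.nan, p_perm=1.0,
                          n_perm=n_perm, seed=seed, n_hits=m)

    es = _running_sum_extremum(scores, hits, weight_exponent)

    rng = np.random.default_rng(seed)
    perm_es = np.empty(n_perm)
    for i in range(n_perm):
        pos = np.sort(rng.choice(n_genes, size=m, replace=False))
        perm_es[i] = _running_sum_extremum(scores, pos, weight_exponent)

    # compare against the same-sign permutation distribution only: the
    # observed extremum is exchangeable with permutation extrema of its own
    # sign, so this yields a valid (slightly conservative) one-sided p
    if es >= 0:
        same_sign = perm_es[perm_es >= 0]
        extreme = int(np.sum(same_sign >= es))
    else:
        same_sign = perm_es[perm_es < 0]
        extreme = int(np.sum(same_sign <= es))
    p_perm = (1 + extreme) / (1 + same_sign.size)
    nes = (float(es / np.abs(same_sign).mean())
           if same_sign.size and np.abs(same_sign).mean() > 0 else np.nan)
    return GseaResult(set_id=set_id, es=es, nes=nes, p_perm=p_perm,
                      n_perm=n_perm, seed=seed, n_hits=m)


def gsea_frame(results: list[GseaResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results],
                        columns=["set_id", "es", "nes", "p_perm", "n_perm",
                                 "seed", "n_hits"])
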