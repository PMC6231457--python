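"""Seed-gene co-expression: correlation tables, filtering, module intersection.

The guilt-by-association workflow: pick a seed gene (here typically the
EMT transcription factors SNAI1/Snail and SNAI2/Slug), correlate every
other probe on the array against the seed's expression profile, keep genes
whose Pearson r clears an absolute cutoff at nominal significance, collapse
duplicate probes to one representative per symbol, and intersect the
resulting modules across seeds to find genes co-regulated by both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (InsufficientDataError, UndefinedCorrelationError,
                     UnknownGeneError, ValidationError)
from .io import ExpressionMatrix

DEFAULT_R_CUTOFF = 0.3
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_SAMPLES = 10


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class SeedCorrelationTable:
    """Per-probe Pearson correlation against one seed gene.

    ``table`` columns: probe_id, symbol, r, p, n_used, skipped.  Rows that
    could not be correlated (too few pairwise-complete samples, or constant
    after completion) are kept with ``skipped=True`` and NaN statistics
    rather than silently dropped.
    """

    seed: str
    seed_probe: str
    table: pd.DataFrame
    min_samples: int

    def usable(self) -> pd.DataFrame:
        return self.table[~self.table["skipped"]]


@dataclass
class CoexpressionModule:
    """Genes surviving the |r| and p filters against one seed, by sign."""

    seed: str
    positive: set[str]
    negative: set[str]
    r_cutoff: float
    alpha: float
    r: dict[str, float] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)

    @property
    def members(self) -> set[str]:
        return self.positive | self.negative

    @property
    def size(self) -> int:
        return len(self.positive) + len(self.negative)


@dataclass
class ModuleIntersection:
    """Common and exclusive genes between two seed modules."""

    seed_a: str
    seed_b: str
    common: set[str]
    exclusive_a: set[str]
    exclusive_b: set[str]
    # per common gene: (r against seed A, r against seed B, signs agree?)
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_common(self) -> int:
        return len(self.common)

    @property
    def sign_concordant(self) -> set[str]:
        if self.annotations.empty:
            return set()
        mask = self.annotations["sign_concordant"]
        return set(self.annotations.loc[mask, "symbol"])


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def pearson_with_p(x, y, min_samples: int = DEFAULT_MIN_SAMPLES):
    """Pearson r with a two-sided p-value on pairwise-complete entries.

    The p-value comes from the exact t transform
    ``t = r * sqrt((n-2) / (1-r^2))`` with ``n-2`` degrees of freedom;
    perfect (anti)collinearity yields p = 0.

    Returns ``(r, p, n_used)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    n_used = int(mask.sum())
    if n_used < max(min_samples, 3):
        raise InsufficientDataError(
            f"only {n_used} pairwise-complete samples (need >= {max(min_samples, 3)})")
    xs, ys = x[mask], y[mask]
    xd = xs - xs.mean()
    yd = ys - ys.mean()
    denom = np.sqrt((xd * xd).sum() * (yd * yd).sum())
    if denom == 0.0:
        raise UndefinedCorrelationError("constant vector after pairwise completion")
    r = float(np.clip((xd * yd).sum() / denom, -1.0, 1.0))
    if abs(r) >= 1.0:
        return (1.0 if r > 0 else -1.0), 0.0, n_used
    t = r * np.sqrt((n_used - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df=n_used - 2))
    return r, min(p, 1.0), n_used


def reference_probe(matrix: ExpressionMatrix, symbol: str) -> str:
    """The representative probe for a symbol: the one with largest variance."""
    probes = matrix.probes_for_symbol(symbol)
    if not probes:
        raise UnknownGeneError(f"gene symbol {symbol!r} not on the matrix")
    variances = matrix.values.loc[probes].var(axis=1, ddof=1)
    # ties broken by probe id for determinism
    order = sorted(probes, key=lambda p: (-variances[p], p))
    return order[0]


def seed_correlation_table(matrix: ExpressionMatrix, seed: str,
                           min_samples: int = DEFAULT_MIN_SAMPLES) -> SeedCorrelationTable:
    """Correlate every non-seed probe against the seed's reference profile.

    The seed's own probe rows (all probes mapping to the seed symbol) are
    excluded.  Probes with too few pairwise-complete samples, or constant
    values, are recorded with ``skipped=True``.
    """
    seed = seed.upper()
    seed_probe = reference_probe(matrix, seed)
    seed_vals = matrix.values.loc[seed_probe].to_numpy(dtype=float)
    seed_probes = set(matrix.probes_for_symbol(seed))

    probes, symbols, rs, ps, ns, skipped = [], [], [], [], [], []
    vals = matrix.values.to_numpy(dtype=float)
    for idx, probe in enumerate(matrix.probe_ids):
        if probe in seed_probes:
            continue
        probes.append(probe)
        symbols.append(matrix.gene_symbols[probe])
        try:
            r, p, n = pearson_with_p(seed_vals, vals[idx], min_samples=min_samples)
            rs.append(r); ps.append(p); ns.append(n); skipped.append(False)
        except (InsufficientDataError, UndefinedCorrelationError):
            rs.append(np.nan); ps.append(np.nan); ns.append(0); skipped.append(True)

    table = pd.DataFrame({
        "probe_id": probes, "symbol": symbols, "r": rs, "p": ps,
        "n_used": ns, "skipped": skipped,
    })
    return SeedCorrelationTable(seed=seed, seed_probe=seed_probe,
                                table=table, min_samples=min_samples)


def deduplicate_probes(ctab: SeedCorrelationTable) -> SeedCorrelationTable:
    """Collapse duplicate probes to one representative row per gene symbol.

    The representative is the probe with the most significant (smallest)
    p-value; ties break to the larger |r|, then the lexicographically
    smallest probe id.  Probes with an empty symbol pass through unchanged.
    """
    t = ctab.table
    annotated = t[(t["symbol"] != "") & ~t["skipped"]]
    unannotated = t[t["symbol"] == ""]
    # skipped annotated probes only survive if their symbol has no usable probe
    skipped_annotated = t[(t["symbol"] != "") & t["skipped"]]

    # one global stable sort by (p asc, |r| desc, probe_id asc); the first
    # occurrence of each symbol is its representative
    ranked = annotated.assign(_negabsr=-annotated["r"].abs()).sort_values(
        by=["p", "_negabsr", "probe_id"], kind="mergesort")
    keep_idx = list(ranked.index[~ranked["symbol"].duplicated()])
    usable_symbols = set(annotated["symbol"])
    orphan_idx = [i for i, row in skipped_annotated.iterrows()
                  if row["symbol"] not in usable_symbols]
    # one skipped representative per orphan symbol (smallest probe id)
    orphans = skipped_annotated.loc[orphan_idx].sort_values("probe_id")
    orphans = orphans[~orphans["symbol"].duplicated()]

    keep = set(keep_idx) | set(orphans.index) | set(unannotated.index)
    out = t[t.index.isin(keep)]  # selection only, input order preserved
    return SeedCorrelationTable(seed=ctab.seed, seed_probe=ctab.seed_probe,
                                table=out.reset_index(drop=True),
                                min_samples=ctab.min_samples)


def filter_module(ctab: SeedCorrelationTable,
                  r_cutoff: float = DEFAULT_R_CUTOFF,
                  alpha: float = DEFAULT_ALPHA) -> CoexpressionModule:
    """Apply the |r| > cutoff and p < alpha filters (both strict).

    Survivors are partitioned into positive and negative sets by the sign
    of r.  Unannotated probes are excluded from symbol-level modules.
    """
    if not (0.0 <= r_cutoff < 1.0):
        raise ValidationError(f"r_cutoff must be in [0, 1), got {r_cutoff}")
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    t = ctab.usable()
    t = t[t["symbol"] != ""]
    passed = t[(t["r"].abs() > r_cutoff) & (t["p"] < alpha)]
    positive = set(passed.loc[passed["r"] > 0, "symbol"])
    negative = set(passed.loc[passed["r"] < 0, "symbol"])
    return CoexpressionModule(
        seed=ctab.seed, positive=positive, negative=negative,
        r_cutoff=r_cutoff, alpha=alpha,
        r=dict(zip(passed["symbol"], passed["r"])),
        p=dict(zip(passed["symbol"], passed["p"])),
    )


def intersect_modules(a: CoexpressionModule, b: CoexpressionModule) -> ModuleIntersection:
    """Genes common to two seed modules, ignoring correlation sign.

    Sign concordance (whether a common gene correlates in the same
    direction with both seeds) is reported per gene, not imposed.
    """
    common = a.members & b.members
    rows = []
    for g in sorted(common):
        ra, rb = a.r.get(g, np.nan), b.r.get(g, np.nan)
        rows.append({"symbol": g, "r_seed_a": ra, "r_seed_b": rb,
                     "sign_concordant": bool(np.sign(ra) == np.sign(rb))})
    annotations = pd.DataFrame(rows, columns=["symbol", "r_seed_a", "r_seed_b",
                                              "sign_concordant"])
    return ModuleIntersection(
        seed_a=a.seed, seed_b=b.seed, common=common,
        exclusive_a=a.members - common, exclusive_b=b.members - common,
        annotations=annotations,
    )


def correlation_table_frame(ctab: SeedCorrelationTable,
                            module: CoexpressionModule | None = None) -> pd.DataFrame:
    """Flatten a correlation table (plus optional filter flags) for output."""
    t = ctab.table.copy()
    t["sign"] = np.sign(t["r"]).fillna(0).astype(int)
    if module is not None:
        t["passed_filter"] = t["symbol"].isin(module.members) & ~t["skipped"]
    return t[["symbol", "probe_id", "r", "p", "n_used", "sign"] +
             (["passed_filter"] if module is not None else []) + ["skipped"]]
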