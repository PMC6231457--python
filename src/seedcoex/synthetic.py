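"""Synthetic expression data with planted, fully known structure.

The generator emulates the shape of a seed-gene co-expression study on a
bulk tumor microarray cohort: two seed genes (SNAI1/SNAI2 by default) act
as latent-factor anchors; per-seed blocks of genes are planted at a
controllable correlation and sign; an overlap block correlates with both
seeds; a candidate marker gene carries a subgroup-specific expression
shift; everything else is independent background. Probe-level duplication,
gene sets enriched inside the planted blocks, an EMT-style signature tied
to the candidate, exponential survival with an elevated hazard in the
marker-high group, and Ct values linearly mapped from expression complete
the picture.

Planting uses a direct latent-factor construction: a gene targeted at
correlation rho to seed factor f is drawn as
``g = sign * rho * f + sqrt(1 - rho^2) * eps`` with iid standard normal
eps, so its population correlation to the seed is exactly ``sign * rho``.
Genes tied to two factors use ``rho_1 f_1 + rho_2 f_2`` with the residual
variance adjusted accordingly.

All randomness derives from one master seed through named
``numpy.random.SeedSequence`` child streams (expression, duplication,
gene_sets, survival, qpcr), so regeneration is bit-identical and adding
draws to one component never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import (ExpressionMatrix, GeneSet, GeneSetCollection,
                 write_expression_matrix, write_gene_sets, write_tsv)

_STREAMS = ("expression", "duplication", "gene_sets", "survival", "qpcr")

DEFAULT_SUBGROUPS = {
    # proportions loosely follow the site mix of published ependymoma
    # cohorts: supratentorial ~30%, posterior fossa ~55%, spinal ~15%
    "ST-RELA+": 0.16, "ST-RELA-": 0.14, "PF-A": 0.36, "PF-B": 0.20, "SP": 0.14,
}
AGGRESSIVE_SUBGROUPS = ("ST-RELA+", "PF-A")


@dataclass
class PlantedBlock:
    """A block of genes planted against one seed factor."""

    seed: str
    n_positive: int
    n_negative: int
    rho: float

    @property
    def size(self) -> int:
        return self.n_positive + self.n_negative


@dataclass
class SyntheticConfig:
    """Study-scale defaults for the simulated cohort.

    The cohort size (100 samples) and block geometry (tens of planted
    genes per seed against ~1000 background genes) are scaled to a typical
    single-platform microarray series; the candidate gene's planted
    correlations are chosen so that, after its subgroup shift, its observed
    correlation with the two seeds sits near 0.44 and 0.52.
    """

    n_samples: int = 100
    n_background: int = 960
    blocks: tuple[PlantedBlock, ...] = (
        PlantedBlock(seed="SNAI1", n_positive=24, n_negative=16, rho=0.6),
        PlantedBlock(seed="SNAI2", n_positive=24, n_negative=16, rho=0.6),
    )
    overlap_size: int = 30            # genes correlated with both seeds
    overlap_rho: float = 0.6
    candidate: str = "IL1R1"          # one overlap gene, subgroup-shifted
    candidate_rho: tuple[float, float] = (0.489, 0.579)
    duplication_rate: float = 0.10    # probability a gene gets a second probe
    duplicate_noise_sd: float = 0.3
    base_mean_range: tuple[float, float] = (5.0, 9.0)
    subgroups: dict = field(default_factory=lambda: dict(DEFAULT_SUBGROUPS))
    # per-gene additive log2 shifts in the named subgroups
    subgroup_effects: dict = field(default_factory=lambda: {
        "IL1R1": (1.0, AGGRESSIVE_SUBGROUPS),
    })
    # gene sets
    n_enriched_terms: int = 4         # terms drawn preferentially from blocks
    enriched_fraction: float = 0.8    # share of an enriched term inside a block
    n_null_terms: int = 20
    term_size: int = 30
    # EMT-style signature against the candidate (positive/negative/uncorrelated
    # counts mirror the 44/4/13 split of a 61-gene signature)
    signature_pos: int = 44
    signature_neg: int = 4
    signature_null: int = 13
    signature_pos_rho: float = 0.5
    signature_neg_rho: float = 0.4
    # survival: exponential times, hazard multiplied for marker-high samples
    baseline_hazard: float = 0.02     # events per month in the low group
    log_hr: float = float(np.log(4.37))
    censoring_hazard: float = 0.01
    max_followup: float = 120.0       # months, administrative censoring
    # qPCR: Ct = ct_intercept - ct_slope * expression + noise
    ct_intercept: float = 40.0
    ct_slope: float = 1.0
    ct_noise_sd: float = 0.2
    housekeeping_ct: dict = field(default_factory=lambda: {"ACTB": 18.0, "GAPDH": 19.0})
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 4:
            raise ValidationError("n_samples must be >= 4")
        for b in self.blocks:
            if not (-1.0 < b.rho < 1.0):
                raise ValidationError(f"rho must be in (-1, 1), got {b.rho}")
            if b.size < 0 or b.size > self.n_background + b.size:
                raise ValidationError("invalid block size")
        if not (-1.0 < self.overlap_rho < 1.0):
            raise ValidationError("overlap_rho must be in (-1, 1)")
        r1, r2 = self.candidate_rho
        if r1 * r1 + r2 * r2 >= 1.0:
            raise ValidationError("candidate_rho magnitudes too large (rho1^2+rho2^2 >= 1)")
        if 2 * self.overlap_rho ** 2 >= 1.0 + 1e-12:
            raise ValidationError("overlap_rho too large for a two-factor gene")
        for rate in (self.duplication_rate,):
            if not (0.0 <= rate <= 1.0):
                raise ValidationError("rates must be in [0, 1]")
        if abs(sum(self.subgroups.values()) - 1.0) > 1e-9:
            raise ValidationError("subgroup proportions must sum to 1")
        if self.signature_pos_rho ** 2 >= 1 or self.signature_neg_rho ** 2 >= 1:
            raise ValidationError("signature rho out of range")


@dataclass
class SyntheticTruth:
    """The planted structure against which recovery is scored."""

    planted: dict          # seed -> {symbol: sign}
    overlap: set           # symbols correlated with both seeds
    background: set
    signature: dict        # symbol -> class in {positive, negative, none}
    enriched_terms: set    # term ids planted inside blocks
    subgroup_effects: dict
    log_hr: float
    marker_high: set       # sample ids in the elevated-hazard group
    seed: int

    def members(self, seed: str) -> set:
        return set(self.planted[seed])


@dataclass
class SyntheticBundle:
    matrix: ExpressionMatrix
    metadata: pd.DataFrame
    gene_sets: GeneSetCollection
    signature: GeneSet
    qpcr: pd.DataFrame
    truth: SyntheticTruth
    config: SyntheticConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit the exact file formats the readers consume."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": out / "expression.tsv",
            "metadata": out / "metadata.tsv",
            "gene_sets": out / "gene_sets.gmt",
            "signatures": out / "signatures.gmt",
            "qpcr": out / "qpcr.tsv",
            "truth": out / "truth.tsv",
            "config": out / "config.txt",
        }
        write_expression_matrix(self.matrix, paths["expression"])
        write_tsv(self.metadata.reset_index(drop=True), paths["metadata"])
        write_gene_sets(self.gene_sets, paths["gene_sets"])
        sig_col = GeneSetCollection()
        sig_col.add(self.signature)
        write_gene_sets(sig_col, paths["signatures"])
        write_tsv(self.qpcr, paths["qpcr"])
        write_tsv(_truth_frame(self.truth), paths["truth"])
        paths["config"].write_text(_config_echo(self.config))
        return paths


def _truth_frame(truth: SyntheticTruth) -> pd.DataFrame:
    rows = []
    for seed, members in sorted(truth.planted.items()):
        for sym, sign in sorted(members.items()):
            rows.append(("planted", seed, sym, sign))
    for sym in sorted(truth.overlap):
        rows.append(("overlap", "", sym, ""))
    for sym, klass in sorted(truth.signature.items()):
        rows.append(("signature", klass, sym, ""))
    for term in sorted(truth.enriched_terms):
        rows.append(("enriched_term", "", term, ""))
    for sid in sorted(truth.marker_high):
        rows.append(("marker_high", "", sid, ""))
    rows.append(("log_hr", "", "", truth.log_hr))
    rows.append(("seed", "", "", truth.seed))
    return pd.DataFrame(rows, columns=["kind", "context", "key", "value"])


def _config_echo(config: SyntheticConfig) -> str:
    lines = []
    for key, val in sorted(vars(config).items()):
        lines.append(f"{key}={val!r}")
    return "\n".join(lines) + "\n"


def _streams(master_seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(master_seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticBundle:
    """Generate a full synthetic study with known planted structure."""
    config = config if config is not None else SyntheticConfig()
    config.validate()
    rngs = _streams(config.seed)
    rng = rngs["expression"]
    n = config.n_samples

    sample_ids = [f"S{i:03d}" for i in range(1, n + 1)]
    subgroup_names = list(config.subgroups)
    props = np.array([config.subgroups[g] for g in subgroup_names])
    counts = np.floor(props * n).astype(int)
    while counts.sum() < n:
        counts[int(np.argmax(props * n - counts))] += 1
    subgroup = np.repeat(subgroup_names, counts)
    rng.shuffle(subgroup)
    site = np.array([g.split("-")[0] for g in subgroup])

    seeds = [b.seed for b in config.blocks]
    factors = {s: rng.standard_normal(n) for s in seeds}

    symbols: list[str] = []
    z_rows: list[np.ndarray] = []
    truth_planted: dict[str, dict] = {s: {} for s in seeds}

    for s in seeds:
        symbols.append(s)
        z_rows.append(factors[s])

    for b in config.blocks:
        signs = [1] * b.n_positive + [-1] * b.n_negative
        for i, sign in enumerate(signs, start=1):
            sym = f"{b.seed}M{i:03d}"
            g = sign * b.rho * factors[b.seed] + np.sqrt(1 - b.rho ** 2) * rng.standard_normal(n)
            symbols.append(sym)
            z_rows.append(g)
            truth_planted[b.seed][sym] = sign

    overlap: set[str] = set()
    if len(seeds) >= 2 and config.overlap_size > 0:
        f1, f2 = factors[seeds[0]], factors[seeds[1]]
        rho = config.overlap_rho
        resid = np.sqrt(max(1.0 - 2 * rho ** 2, 0.0))
        n_plain = config.overlap_size - 1  # candidate takes one slot
        for i in range(1, n_plain + 1):
            sym = f"OVL{i:03d}"
            g = rho * f1 + rho * f2 + resid * rng.standard_normal(n)
            symbols.append(sym)
            z_rows.append(g)
            overlap.add(sym)
            truth_planted[seeds[0]][sym] = 1
            truth_planted[seeds[1]][sym] = 1
        r1, r2 = config.candidate_rho
        g = (r1 * f1 + r2 * f2 +
             np.sqrt(1.0 - r1 ** 2 - r2 ** 2) * rng.standard_normal(n))
        symbols.append(config.candidate)
        z_rows.append(g)
        overlap.add(config.candidate)
        truth_planted[seeds[0]][config.candidate] = 1 if r1 > 0 else -1
        truth_planted[seeds[1]][config.candidate] = 1 if r2 > 0 else -1

    candidate_z = z_rows[symbols.index(config.candidate)] if config.candidate in symbols else None

    signature_truth: dict[str, str] = {}
    sig_members: list[str] = []
    if candidate_z is not None:
        sig_specs = ([("positive", config.signature_pos_rho)] * config.signature_pos +
                     [("negative", -config.signature_neg_rho)] * config.signature_neg +
                     [("none", 0.0)] * config.signature_null)
        cz = (candidate_z - candidate_z.mean()) / candidate_z.std()
        for i, (klass, rho) in enumerate(sig_specs, start=1):
            sym = f"EMTSIG{i:03d}"
            g = rho * cz + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
            symbols.append(sym)
            z_rows.append(g)
            signature_truth[sym] = klass
            sig_members.append(sym)

    background: set[str] = set()
    for i in range(1, config.n_background + 1):
        sym = f"BGD{i:04d}"
        symbols.append(sym)
        z_rows.append(rng.standard_normal(n))
        background.add(sym)

    # map latent z-scores to a log2 expression scale and add subgroup shifts
    lo, hi = config.base_mean_range
    means = rng.uniform(lo, hi, size=len(symbols))
    expr = np.vstack(z_rows) + means[:, None]
    for gene, (shift, groups) in config.subgroup_effects.items():
        if gene in symbols:
            mask = np.isin(subgroup, list(groups))
            expr[symbols.index(gene), mask] += shift

    # probe-level duplication: noisy resampled copies of the same symbol
    dup_rng = rngs["duplication"]
    probe_ids = [f"P{i:05d}_at" for i in range(1, len(symbols) + 1)]
    probe_symbols = list(symbols)
    rows = [expr[i] for i in range(len(symbols))]
    dup_mask = dup_rng.random(len(symbols)) < config.duplication_rate
    for i in np.flatnonzero(dup_mask):
        probe_ids.append(f"P{i + 1:05d}_s_at")
        probe_symbols.append(symbols[i])
        rows.append(expr[i] + config.duplicate_noise_sd * dup_rng.standard_normal(n))

    values = pd.DataFrame(np.vstack(rows),
                          index=pd.Index(probe_ids, name="probe_id"),
                          columns=sample_ids)
    matrix = ExpressionMatrix(values=values,
                              gene_symbols=pd.Series(probe_symbols, index=values.index,
                                                     name="gene_symbol"))

    # gene sets: enriched terms sampled preferentially from planted blocks
    gs_rng = rngs["gene_sets"]
    universe = np.array(sorted(set(symbols)))
    collection = GeneSetCollection()
    enriched_terms: set[str] = set()
    block_pools = [sorted(truth_planted[b.seed]) for b in config.blocks]
    if overlap:
        block_pools.append(sorted(overlap))
    families = ("KEGG", "GO-BP")
    for t in range(config.n_enriched_terms):
        pool = block_pools[t % len(block_pools)]
        n_in = min(int(round(config.enriched_fraction * config.term_size)), len(pool))
        inside = gs_rng.choice(pool, size=n_in, replace=False)
        bg_pool = sorted(background - set(inside))
        filler = gs_rng.choice(bg_pool, size=config.term_size - n_in, replace=False)
        term_id = f"PLANTED_TERM_{t + 1:02d}"
        collection.add(GeneSet(term_id=term_id, name=f"planted term {t + 1}",
                               members=tuple(sorted(set(inside) | set(filler))),
                               family=families[t % len(families)]))
        enriched_terms.add(term_id)
    for t in range(config.n_null_terms):
        members = gs_rng.choice(universe, size=config.term_size, replace=False)
        collection.add(GeneSet(term_id=f"NULL_TERM_{t + 1:02d}",
                               name=f"null term {t + 1}",
                               members=tuple(sorted(set(members))),
                               family=families[t % len(families)]))

    signature = GeneSet(term_id="EMT_SIGNATURE", name="synthetic EMT signature",
                        members=tuple(sig_members) if sig_members else ("NONE",),
                        family="EMT-signature")

    # survival: exponential times, elevated hazard for marker-high samples
    sv_rng = rngs["survival"]
    if candidate_z is not None:
        cand_expr = matrix.values.loc[
            matrix.probes_for_symbol(config.candidate)[0]].to_numpy()
    else:
        cand_expr = np.zeros(n)
    high = cand_expr > np.median(cand_expr)
    hazard = config.baseline_hazard * np.exp(config.log_hr * high)
    event_time = sv_rng.exponential(1.0 / hazard)
    censor_time = np.minimum(sv_rng.exponential(1.0 / config.censoring_hazard, size=n),
                             config.max_followup)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    age = np.where(subgroup == "PF-A",
                   sv_rng.uniform(1, 18, size=n), sv_rng.uniform(18, 70, size=n))
    mib1 = np.where(high, "high", "low")  # proliferation tracks the marker

    metadata = pd.DataFrame({
        "sample_id": sample_ids,
        "site": site,
        "subgroup": subgroup,
        "age": np.round(age, 1),
        "survival_time": np.round(time, 3),
        "event": event,
        "mib1_class": mib1,
    }).set_index("sample_id", drop=False)

    # qPCR: Ct linearly tied to expression plus noise, two housekeepers
    qp_rng = rngs["qpcr"]
    qpcr_rows = []
    targets = seeds + ([config.candidate] if candidate_z is not None else [])
    for target in targets:
        t_expr = matrix.values.loc[matrix.probes_for_symbol(target)[0]].to_numpy()
        ct_t = (config.ct_intercept - config.ct_slope * t_expr +
                qp_rng.normal(0, config.ct_noise_sd, size=n))
        ct_actb = config.housekeeping_ct["ACTB"] + qp_rng.normal(0, 0.15, size=n)
        ct_gapdh = config.housekeeping_ct["GAPDH"] + qp_rng.normal(0, 0.15, size=n)
        for j, sid in enumerate(sample_ids):
            qpcr_rows.append((sid, subgroup[j], target,
                              round(float(ct_t[j]), 4), round(float(ct_actb[j]), 4),
                              round(float(ct_gapdh[j]), 4)))
    qpcr = pd.DataFrame(qpcr_rows, columns=["sample_id", "group", "target",
                                            "ct_target", "ct_actb", "ct_gapdh"])

    truth = SyntheticTruth(
        planted=truth_planted, overlap=overlap, background=background,
        signature=signature_truth, enriched_terms=enriched_terms,
        subgroup_effects=dict(config.subgroup_effects), log_hr=config.log_hr,
        marker_high={sample_ids[i] for i in np.flatnonzero(high)},
        seed=config.seed)

    return SyntheticBundle(matrix=matrix, metadata=metadata, gene_sets=collection,
                           signature=signature, qpcr=qpcr, truth=truth,
                           config=config)
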