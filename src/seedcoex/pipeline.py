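"""End-to-end orchestration: seeds -> modules -> intersection -> follow-up.

``run_pipeline`` executes the whole funnel from a single config: per-seed
correlation tables, probe deduplication, cutoff filtering, module
intersection, gene-set enrichment, candidate selection, signature
correlations, preranked GSEA, group comparisons, ΔΔCt quantification and
expression-dichotomized survival. Every stage writes plain TSV under
``out_dir/<stage>/`` and the run manifest records seeds, config hash and
per-stage row counts, so the module-size funnel is always auditable.
Given identical config and seeds the output bundle is byte-identical
across runs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (ddct_fold_change, fold_change_frame,
                          compare_groups, signature_correlation_summary)
from .coexpression import (CoexpressionModule, ModuleIntersection,
                           correlation_table_frame, deduplicate_probes,
                           filter_module, intersect_modules, reference_probe,
                           seed_correlation_table)
from .enrichment import (enrich_module, enrichment_frame, gsea_frame,
                         gsea_preranked)
from .errors import SeedcoexError, StageError, ValidationError
from .io import (ExpressionMatrix, GeneSetCollection, read_expression_matrix,
                 read_gene_sets, read_qpcr_table, read_sample_metadata,
                 write_tsv)
from .survival import (cox_univariate, dichotomize_expression, km_estimate,
                       km_frame, logrank_test)


@dataclass
class PipelineConfig:
    expression_path: str = ""
    metadata_path: str = ""
    gene_sets_paths: tuple[str, ...] = ()
    signature_paths: tuple[str, ...] = ()
    qpcr_path: str = ""
    dialect: str = "plain-tsv"
    seeds: tuple[str, ...] = ("SNAI1", "SNAI2")
    candidate: str = "IL1R1"          # gene symbol, or "auto"
    target_subgroups: tuple[str, ...] = ("ST-RELA+", "PF-A")
    r_cutoff: float = 0.3
    alpha: float = 0.05
    min_samples: int = 10
    adjust_correlation_p: bool = False  # BH-adjust r p-values before the filter
    min_term_size: int = 5
    max_term_size: int = 2000
    gsea_weight: float = 1.0
    gsea_n_perm: int = 1000
    gsea_seed: int = 0
    survival_method: str = "median"
    calibrator_group: str = ""        # mandatory for the ΔΔCt stage
    out_dir: str = "seedcoex_out"

    def __post_init__(self) -> None:
        self.seeds = tuple(s.upper() for s in self.seeds)
        if not self.seeds:
            raise ValidationError("need at least one seed gene")
        if not (0.0 <= self.r_cutoff < 1.0):
            raise ValidationError("r_cutoff must be in [0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        for key in ("gene_sets_paths", "signature_paths", "seeds", "target_subgroups"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        # out_dir is excluded: where the bundle lands does not change what
        # was computed, and identical analyses must hash identically
        items = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        canon = repr(sorted(items.items()))
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    modules: dict[str, CoexpressionModule]
    intersection: ModuleIntersection | None
    candidate: str
    candidate_ranking: pd.DataFrame
    enrichment: pd.DataFrame
    gsea: pd.DataFrame
    signature_summaries: pd.DataFrame
    group_tests: pd.DataFrame
    fold_changes: pd.DataFrame
    survival_fit: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def auto_select_candidate(intersection: ModuleIntersection,
                          matrix: ExpressionMatrix, metadata: pd.DataFrame,
                          target_subgroups) -> tuple[str, pd.DataFrame]:
    """Rank common genes by their subgroup contrast and return the top one.

    Score = standardized mean expression difference between the target
    subgroups and all other samples, descending; the full ranking is
    returned so the selection is auditable.
    """
    if not intersection.common:
        raise ValidationError("empty intersection: no common genes to rank")
    targets = set(target_subgroups)
    in_target = metadata["subgroup"].isin(targets)
    if in_target.sum() == 0:
        raise ValidationError(f"no samples in target subgroups {sorted(targets)}")
    sample_order = [s for s in matrix.sample_ids if s in metadata.index]
    mask = in_target.reindex(sample_order).to_numpy(dtype=bool)

    rows = []
    for gene in sorted(intersection.common):
        vals = matrix.values.loc[reference_probe(matrix, gene), sample_order]
        vals = vals.to_numpy(dtype=float)
        a, b = vals[mask], vals[~mask]
        sd = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2) if len(b) > 1 else a.std(ddof=1)
        score = (a.mean() - b.mean()) / sd if sd > 0 else 0.0
        rows.append({"symbol": gene, "score": float(score),
                     "mean_target": float(a.mean()),
                     "mean_other": float(b.mean()) if len(b) else np.nan})
    ranking = pd.DataFrame(rows).sort_values(
        by=["score", "symbol"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return str(ranking.loc[0, "symbol"]), ranking


def _stage(name: str):
    """Decorator-free stage guard: re-raise errors tagged with the stage."""
    class _Ctx:
        def __enter__(self):
            return self
        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, SeedcoexError) and not isinstance(exc, StageError):
                raise StageError(name, type(exc).__name__, str(exc)) from exc
            return False
    return _Ctx()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    marker.write_text("run in progress or aborted\n")
    manifest: dict = {"seedcoex_version": __version__,
                      "config_hash": config.config_hash(),
                      "gsea_seed": config.gsea_seed,
                      "seeds": ",".join(config.seeds)}

    with _stage("inputs"):
        matrix = read_expression_matrix(config.expression_path, dialect=config.dialect)
        metadata = read_sample_metadata(config.metadata_path)
        collection = GeneSetCollection()
        for p in config.gene_sets_paths:
            collection = collection.merged(read_gene_sets(p))
        signatures = GeneSetCollection()
        for p in config.signature_paths:
            signatures = signatures.merged(read_gene_sets(p, family="signature"))
        qpcr = read_qpcr_table(config.qpcr_path) if config.qpcr_path else None
        manifest["n_probes"] = matrix.n_probes
        manifest["n_samples"] = matrix.n_samples

    # --- per-seed correlation tables, dedup, modules -----------------------
    modules: dict[str, CoexpressionModule] = {}
    dedup_tables = {}
    with _stage("coexpression"):
        for seed in config.seeds:
            ctab = seed_correlation_table(matrix, seed, min_samples=config.min_samples)
            ctab = deduplicate_probes(ctab)
            if config.adjust_correlation_p:
                from .enrichment import bh_adjust
                usable = ~ctab.table["skipped"]
                ctab.table.loc[usable, "p"] = bh_adjust(
                    ctab.table.loc[usable, "p"].to_numpy())
            module = filter_module(ctab, r_cutoff=config.r_cutoff, alpha=config.alpha)
            modules[seed] = module
            dedup_tables[seed] = ctab
            frame = correlation_table_frame(ctab, module)
            write_tsv(frame, out / "coexpression" / f"{seed}_correlations.tsv")
            (out / "coexpression" / f"{seed}_module.txt").write_text(
                "\n".join(sorted(module.members)) + "\n")
            manifest[f"module_size_{seed}"] = module.size
            manifest[f"module_positive_{seed}"] = len(module.positive)
            manifest[f"module_negative_{seed}"] = len(module.negative)

    # --- intersection ------------------------------------------------------
    intersection = None
    with _stage("intersection"):
        if len(config.seeds) >= 2:
            intersection = intersect_modules(modules[config.seeds[0]],
                                             modules[config.seeds[1]])
            write_tsv(intersection.annotations, out / "intersection" / "common_genes.tsv")
            manifest["n_common_genes"] = intersection.n_common
            manifest["n_common_sign_concordant"] = len(intersection.sign_concordant)

    # --- enrichment --------------------------------------------------------
    universe = matrix.symbols()
    enr_frames = []
    with _stage("enrichment"):
        if len(collection):
            for seed, module in modules.items():
                if not module.members:
                    continue
                res = enrich_module(module.members, collection, universe,
                                    min_term_size=config.min_term_size,
                                    max_term_size=config.max_term_size)
                f = enrichment_frame(res)
                f.insert(0, "module", seed)
                enr_frames.append(f)
        enrichment = (pd.concat(enr_frames, ignore_index=True) if enr_frames
                      else pd.DataFrame())
        if len(enrichment):
            write_tsv(enrichment, out / "enrichment" / "module_enrichment.tsv")
        manifest["n_enrichment_rows"] = int(len(enrichment))

    # --- candidate selection ----------------------------------------------
    with _stage("candidate"):
        if config.candidate.lower() == "auto":
            if intersection is None:
                raise ValidationError("auto candidate selection needs two seeds")
            candidate, ranking = auto_select_candidate(
                intersection, matrix, metadata, config.target_subgroups)
        else:
            candidate = config.candidate.upper()
            if not matrix.probes_for_symbol(candidate):
                raise ValidationError(f"candidate gene {candidate!r} not on matrix")
            ranking = pd.DataFrame({"symbol": [candidate], "score": [np.nan],
                                    "mean_target": [np.nan], "mean_other": [np.nan]})
        write_tsv(ranking, out / "candidate" / "candidate_ranking.tsv")
        manifest["candidate"] = candidate

    # --- follow-up: candidate correlation ranking, GSEA, signatures --------
    with _stage("followup"):
        cand_tab = deduplicate_probes(
            seed_correlation_table(matrix, candidate, min_samples=config.min_samples))
        usable = cand_tab.usable()
        usable = usable[usable["symbol"] != ""]
        cand_ranking = pd.Series(usable["r"].to_numpy(),
                                 index=pd.Index(usable["symbol"]))
        write_tsv(usable[["symbol", "r", "p", "n_used"]].sort_values(
            "r", ascending=False, kind="mergesort"),
            out / "followup" / "candidate_correlations.tsv")

        gsea_results = []
        for s in sorted(collection, key=lambda s: s.term_id):
            if not (set(s.members) & set(cand_ranking.index)):
                continue
            gsea_results.append(gsea_preranked(
                cand_ranking, s, weight_exponent=config.gsea_weight,
                n_perm=config.gsea_n_perm, seed=config.gsea_seed))
        gsea = gsea_frame(gsea_results)
        if len(gsea):
            write_tsv(gsea, out / "followup" / "gsea.tsv")
        manifest["n_gsea_sets"] = int(len(gsea))

        sig_rows = []
        for s in sorted(signatures, key=lambda s: s.term_id):
            summ = signature_correlation_summary(matrix, candidate, s,
                                                 alpha=config.alpha,
                                                 min_samples=config.min_samples)
            sig_rows.append({"signature": s.term_id,
                             "n_matched": summ.n_matched,
                             "n_unmatched": len(summ.unmatched),
                             "frac_positive": summ.fraction("positive"),
                             "frac_negative": summ.fraction("negative"),
                             "frac_none": summ.fraction("none")})
            write_tsv(summ.table, out / "followup" / f"signature_{s.term_id}.tsv")
        signature_summaries = pd.DataFrame(
            sig_rows, columns=["signature", "n_matched", "n_unmatched",
                               "frac_positive", "frac_negative", "frac_none"])
        if len(signature_summaries):
            write_tsv(signature_summaries, out / "followup" / "signature_summaries.tsv")

        group_rows = []
        sample_order = [s for s in matrix.sample_ids if s in metadata.index]
        cand_expr = matrix.values.loc[reference_probe(matrix, candidate), sample_order]
        sub = metadata.loc[sample_order, "subgroup"]
        if sub.nunique() >= 2 and (sub.value_counts() >= 2).all():
            stat, p = compare_groups(cand_expr.to_numpy(), sub.to_numpy(), test="anova")
            group_rows.append({"comparison": "subgroup_anova", "statistic": stat, "p": p})
        mib = metadata.loc[sample_order, "mib1_class"]
        known = mib.isin(["high", "low"])
        if known.sum() >= 4 and mib[known].nunique() == 2 and (mib[known].value_counts() >= 2).all():
            stat, p = compare_groups(cand_expr[known.to_numpy()].to_numpy(),
                                     mib[known].to_numpy(), test="t")
            group_rows.append({"comparison": "mib1_high_vs_low", "statistic": stat, "p": p})
        group_tests = pd.DataFrame(group_rows, columns=["comparison", "statistic", "p"])
        if len(group_tests):
            write_tsv(group_tests, out / "followup" / "group_tests.tsv")

    # --- ΔΔCt --------------------------------------------------------------
    fold_changes = pd.DataFrame()
    with _stage("qpcr"):
        if qpcr is not None:
            if not config.calibrator_group:
                raise ValidationError("calibrator_group is required when a "
                                      "qPCR table is provided")
            fold_changes = fold_change_frame(
                ddct_fold_change(qpcr, config.calibrator_group))
            write_tsv(fold_changes, out / "qpcr" / "fold_changes.tsv")
            manifest["n_qpcr_rows"] = int(len(fold_changes))

    # --- survival ----------------------------------------------------------
    survival_fit = pd.DataFrame()
    with _stage("survival"):
        surv_meta = metadata.dropna(subset=["survival_time", "event"])
        surv_samples = [s for s in matrix.sample_ids if s in surv_meta.index]
        if len(surv_samples) >= 4 and surv_meta.loc[surv_samples, "event"].sum() >= 2:
            expr = matrix.values.loc[reference_probe(matrix, candidate), surv_samples]
            split = dichotomize_expression(expr.astype(float),
                                           method=config.survival_method)
            time = surv_meta.loc[surv_samples, "survival_time"].to_numpy(dtype=float)
            event = surv_meta.loc[surv_samples, "event"].to_numpy(dtype=int)
            grp = split.groups.loc[surv_samples].to_numpy()
            km_frames = [km_frame(km_estimate(time[grp == g], event[grp == g]), g)
                         for g in ("high", "low")]
            write_tsv(pd.concat(km_frames, ignore_index=True),
                      out / "survival" / "km_curves.tsv")
            chi2, p_lr = logrank_test(time, event, grp)
            fit = cox_univariate(time, event, (grp == "high").astype(float))
            survival_fit = pd.DataFrame([{
                "candidate": candidate, "cutpoint_method": split.method,
                "cutpoint": split.cutpoint, "n": fit.n, "n_events": fit.n_events,
                "beta": fit.beta, "hr": fit.hr, "se": fit.se, "z": fit.z,
                "p_wald": fit.p, "converged": fit.converged,
                "logrank_chi2": chi2, "logrank_p": p_lr}])
            write_tsv(survival_fit, out / "survival" / "cox_fit.tsv")
            manifest["survival_hr"] = fit.hr
            manifest["logrank_p"] = p_lr

    # --- manifest ----------------------------------------------------------
    manifest_path = out / "manifest.txt"
    manifest_path.write_text(
        "".join(f"{k}={manifest[k]}\n" for k in sorted(manifest)))
    marker.unlink()

    return PipelineResult(config=config, modules=modules, intersection=intersection,
                          candidate=candidate, candidate_ranking=ranking,
                          enrichment=enrichment, gsea=gsea,
                          signature_summaries=signature_summaries,
                          group_tests=group_tests, fold_changes=fold_changes,
                          survival_fit=survival_fit, manifest=manifest)
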