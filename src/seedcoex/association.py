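"""Candidate-gene follow-up: signature correlations, group tests, ΔΔCt.

These are the analyses applied to a candidate gene (e.g. IL1R1) once the
co-expression funnel has produced it: how it correlates with published
EMT/stemness/MDSC signatures, whether its expression differs between
sample groups (molecular subgroups, MIB1 high vs low), and relative qPCR
quantification by the comparative-Ct method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import pearson_with_p, reference_probe
from .errors import InsufficientDataError, ValidationError
from .io import ExpressionMatrix


@dataclass
class SignatureCorrelationSummary:
    """Per-gene correlation of a signature with a candidate gene.

    Each matched signature gene is classified positive (r > threshold,
    p < alpha), negative (r < -threshold, p < alpha) or none; fractions are
    over matched genes only.
    """

    candidate: str
    signature_id: str
    table: pd.DataFrame  # columns: symbol, r, p, n_used, klass
    unmatched: tuple[str, ...]
    r_threshold: float
    alpha: float

    @property
    def n_matched(self) -> int:
        return len(self.table)

    def fraction(self, klass: str) -> float:
        if self.n_matched == 0:
            return float("nan")
        return float((self.table["klass"] == klass).sum() / self.n_matched)

    @property
    def fractions(self) -> dict[str, float]:
        return {k: self.fraction(k) for k in ("positive", "negative", "none")}


def signature_correlation_summary(matrix: ExpressionMatrix, candidate: str,
                                  signature, r_threshold: float = 0.0,
                                  alpha: float = 0.05,
                                  min_samples: int = 10) -> SignatureCorrelationSummary:
    """Correlate a candidate gene against every gene of a signature.

    Signature genes with several probes are collapsed to the most
    significant probe, mirroring the module deduplication rule. Signature
    genes absent from the matrix are reported in ``unmatched`` and never
    enter the denominators.
    """
    candidate = candidate.upper()
    cand_probe = reference_probe(matrix, candidate)
    cand_vals = matrix.values.loc[cand_probe].to_numpy(dtype=float)
    members = getattr(signature, "members", signature)
    sig_id = getattr(signature, "term_id", "signature")

    rows, unmatched = [], []
    for gene in members:
        gene = gene.upper()
        probes = matrix.probes_for_symbol(gene)
        if not probes:
            unmatched.append(gene)
            continue
        best = None
        for probe in sorted(probes):
            if probe == cand_probe:
                vals = cand_vals
            else:
                vals = matrix.values.loc[probe].to_numpy(dtype=float)
            try:
                r, p, n = pearson_with_p(cand_vals, vals, min_samples=min_samples)
            except Exception:
                continue
            if best is None or (p, -abs(r)) < (best[1], -abs(best[0])):
                best = (r, p, n)
        if best is None:
            unmatched.append(gene)
            continue
        r, p, n = best
        if p < alpha and r > r_threshold:
            klass = "positive"
        elif p < alpha and r < -r_threshold:
            klass = "negative"
        else:
            klass = "none"
        rows.append({"symbol": gene, "r": r, "p": p, "n_used": n, "klass": klass})

    table = pd.DataFrame(rows, columns=["symbol", "r", "p", "n_used", "klass"])
    return SignatureCorrelationSummary(
        candidate=candidate, signature_id=sig_id, table=table,
        unmatched=tuple(unmatched), r_threshold=r_threshold, alpha=alpha)


def compare_groups(values, labels, test: str = "t"):
    """Compare expression between sample groups.

    ``test="t"`` runs a two-sided Welch (unequal-variance) t-test on exactly
    two groups; ``test="anova"`` a one-way ANOVA on two or more groups.
    Returns ``(statistic, p)``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValidationError("values and labels must align")
    mask = np.isfinite(values)
    values, labels = values[mask], labels[mask]
    # groups ordered by sorted label so the sign of the t statistic is
    # deterministic (and flips when the labels are swapped)
    groups = [values[labels == g] for g in np.unique(labels)]
    if any(len(g) < 2 for g in groups):
        raise InsufficientDataError("every group needs at least 2 members")
    if test == "t":
        if len(groups) != 2:
            raise ValidationError(f"t-test needs exactly 2 groups, got {len(groups)}")
        stat, p = stats.ttest_ind(groups[0], groups[1], equal_var=False)
    elif test == "anova":
        if len(groups) < 2:
            raise ValidationError("anova needs at least 2 groups")
        stat, p = stats.f_oneway(*groups)
    else:
        raise ValidationError(f"unknown test {test!r}")
    return float(stat), float(p)


@dataclass(frozen=True)
class FoldChangeResult:
    sample_id: str
    target: str
    group: str
    dct: float
    ddct: float
    fold_change: float
    calibrator_group: str


def ddct_fold_change(qpcr: pd.DataFrame, calibrator_group: str) -> list[FoldChangeResult]:
    """Relative quantification by the comparative-Ct (2^-ΔΔCt) method.

    Per sample, ΔCt = target Ct minus the arithmetic mean of the ACTB and
    GAPDH Cts (equivalent to geometric-mean normalization of the linear
    quantities).  ΔΔCt subtracts the calibrator group's mean ΔCt for the
    same target; fold change is 2^-ΔΔCt, so the calibrator group has
    geometric-mean fold change 1 by construction.
    """
    required = {"sample_id", "group", "target", "ct_target", "ct_actb", "ct_gapdh"}
    missing = required - set(qpcr.columns)
    if missing:
        raise ValidationError(f"qPCR table missing columns {sorted(missing)}")
    for col in ("ct_target", "ct_actb", "ct_gapdh"):
        bad = qpcr[pd.to_numeric(qpcr[col], errors="coerce").isna()]
        if len(bad):
            raise ValidationError(
                f"missing/invalid {col} for sample {bad['sample_id'].iloc[0]!r}")
    if calibrator_group not in set(qpcr["group"]):
        raise ValidationError(f"calibrator group {calibrator_group!r} not present")

    df = qpcr.copy()
    df["dct"] = df["ct_target"] - (df["ct_actb"] + df["ct_gapdh"]) / 2.0
    calib = df[df["group"] == calibrator_group].groupby("target")["dct"].mean()

    results = []
    for _, row in df.iterrows():
        if row["target"] not in calib.index:
            raise ValidationError(
                f"no calibrator samples for target {row['target']!r}")
        ddct = row["dct"] - calib[row["target"]]
        results.append(FoldChangeResult(
            sample_id=str(row["sample_id"]), target=str(row["target"]),
            group=str(row["group"]), dct=float(row["dct"]), ddct=float(ddct),
            fold_change=float(2.0 ** (-ddct)), calibrator_group=calibrator_group))
    return results


def fold_change_frame(results: list[FoldChangeResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results],
                        columns=["sample_id", "group", "target", "dct",
                                 "ddct", "fold_change", "calibrator_group"])
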