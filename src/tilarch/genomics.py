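"""Linking the morphologic risk score to genomics.

Risk-correlated gene discovery (Pearson, P < 0.05), differential
expression between risk strata (Wilcoxon rank-sum with Benjamini-Hochberg
FDR < 0.05 and |log2 fold change| > 1), single-sample gene-set enrichment
activity indices, mutation-vs-risk association and per-gene survival
stratification at the median expression split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

log = logging.getLogger(__name__)


@dataclass
class GeneSet:
    """Named collection of gene identifiers."""

    name: str
    genes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file (name, description, members per tab-separated line)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                sets.append(GeneSet(parts[0], [g for g in parts[2:] if g]))
    return sets


def _align(expr: pd.DataFrame, series: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    common = [s for s in expr.columns if s in set(series.index)]
    if len(common) < 3:
        raise ValidationError("need at least 3 overlapping samples")
    return expr[common], series.loc[common]


def risk_correlated_genes(expr: pd.DataFrame, risk: pd.Series,
                          p_threshold: float = 0.05) -> pd.DataFrame:
    """Per-gene Pearson correlation with the risk score.

    Constant genes (zero variance) are excluded with a log entry.
    Returns a table with ``r``, ``p`` and a ``selected`` flag (p below
    threshold).
    """
    expr, risk = _align(expr, risk)
    mat = expr.to_numpy(float)
    y = risk.to_numpy(float)
    n = len(y)
    sd = mat.std(axis=1)
    const = sd == 0
    if const.any():
        log.info("excluding %d constant genes from correlation", const.sum())
    xz = mat - mat.mean(axis=1, keepdims=True)
    yz = y - y.mean()
    denom = np.sqrt((xz ** 2).sum(axis=1) * (yz ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xz @ yz) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1 - r ** 2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    out = pd.DataFrame({"r": r, "p": p}, index=expr.index)
    out.loc[const, ["r", "p"]] = np.nan
    out["selected"] = (out["p"] < p_threshold).fillna(False)
    return out.loc[~const]


def de_between_risk_groups(expr: pd.DataFrame, groups: pd.Series,
                           pseudocount: float = 1.0,
                           fdr_threshold: float = 0.05,
                           lfc_threshold: float = 1.0) -> pd.DataFrame:
    """Wilcoxon rank-sum DE between high- and low-risk samples.

    log2FC = log2((mean_high + c) / (mean_low + c)); BH FDR across genes;
    a gene is selected when q < ``fdr_threshold`` and |log2FC| >
    ``lfc_threshold``.
    """
    expr, groups = _align(expr, groups)
    high = groups == "high"
    low = groups == "low"
    if high.sum() < 2 or low.sum() < 2:
        raise ValidationError("each risk group needs at least 2 samples")
    hi = expr.loc[:, high.to_numpy()].to_numpy(float)
    lo = expr.loc[:, low.to_numpy()].to_numpy(float)
    pvals = np.empty(len(expr))
    for j in range(len(expr)):
        if np.all(hi[j] == hi[j][0]) and np.all(lo[j] == lo[j][0]) \
                and hi[j][0] == lo[j][0]:
            pvals[j] = 1.0
            continue
        pvals[j] = stats.mannwhitneyu(hi[j], lo[j],
                                      alternative="two-sided").pvalue
    qvals = multipletests(pvals, method="fdr_bh")[1]
    l2fc = np.log2((hi.mean(axis=1) + pseudocount)
                   / (lo.mean(axis=1) + pseudocount))
    out = pd.DataFrame({"log2fc": l2fc, "p": pvals, "q": qvals},
                       index=expr.index)
    out["selected"] = (out["q"] < fdr_threshold) & \
                      (out["log2fc"].abs() > lfc_threshold)
    return out


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    return multipletests(np.asarray(pvals, float), method="fdr_bh")[1]


def ssgsea(expr: pd.DataFrame, gene_set: GeneSet,
           alpha: float = 0.75) -> pd.Series:
    """Single-sample gene-set enrichment activity index per sample.

    Genes are ordered by descending expression (average ranks for ties
    weight the increments).  The running sum rises by rank^alpha
    (normalized over the set) at member genes and falls uniformly at
    non-members; the activity index is the integral of the running sum,
    scaled by the range between the integrals obtained when the set sits
    at the very top and at the very bottom of an untied ranking — a
    sample-independent constant, so indices are comparable across sets.
    """
    members = [g for g in gene_set.genes if g in expr.index]
    dropped = set(gene_set.genes) - set(members)
    if dropped:
        log.info("gene set %s: %d members absent from expression",
                 gene_set.name, len(dropped))
    if not members:
        raise ValidationError(
            f"gene set {gene_set.name!r} has no members in the matrix")
    n = len(expr.index)
    is_member = expr.index.isin(members).astype(bool)
    n_mem = int(is_member.sum())
    # rank weights of a tie-free ranking, used for the normalization range
    ranks_ref = np.arange(n, 0, -1, dtype=float)  # descending positions
    w_top = ranks_ref[:n_mem] ** alpha
    w_bot = ranks_ref[n - n_mem:] ** alpha
    es_max = _running_sum_integral(np.arange(n_mem), w_top, n, n_mem)
    es_min = _running_sum_integral(np.arange(n - n_mem, n), w_bot, n, n_mem)
    denom = es_max - es_min
    if denom == 0:
        denom = 1.0
    scores = {}
    for sample in expr.columns:
        vals = expr[sample].to_numpy(float)
        order = np.lexsort((np.arange(n), -vals))  # stable descending
        ranks = stats.rankdata(vals)  # ascending average ranks
        member_pos = np.flatnonzero(is_member[order])
        weights = ranks[order][member_pos] ** alpha
        es = _running_sum_integral(member_pos, weights, n, n_mem)
        scores[sample] = es / denom
    return pd.Series(scores, name=f"ssgsea_{gene_set.name}")


def _running_sum_integral(member_pos: np.ndarray, weights: np.ndarray,
                          n: int, n_mem: int) -> float:
    """Sum of the weighted KS running sum over all n ranked positions."""
    inc = np.zeros(n)
    wsum = weights.sum()
    if wsum == 0:
        wsum = 1.0
    inc[member_pos] = weights / wsum
    dec = np.zeros(n)
    if n > n_mem:
        nonmember = np.setdiff1d(np.arange(n), member_pos, assume_unique=True)
        dec[nonmember] = 1.0 / (n - n_mem)
    running = np.cumsum(inc - dec)
    return float(running.sum())


def signature_group_test(activity: pd.Series, groups: pd.Series,
                         exact_max_n: int = 10) -> dict:
    """Two-sided Wilcoxon rank-sum of an activity index between groups.

    Exact enumeration for groups of at most ``exact_max_n`` samples each,
    otherwise the tie-corrected normal approximation with continuity
    correction.  All-tied inputs return p = 1 with a warning.
    """
    activity, groups = activity.align(groups, join="inner")
    hi = activity[groups == "high"].to_numpy(float)
    lo = activity[groups == "low"].to_numpy(float)
    if len(hi) < 2 or len(lo) < 2:
        raise ValidationError("each group needs at least 2 samples")
    if np.all(np.concatenate([hi, lo]) == hi[0]):
        warnings.warn("all activity values tied; p = 1")
        return {"p": 1.0, "direction": 0, "statistic": len(hi) * len(lo) / 2}
    method = "exact" if max(len(hi), len(lo)) <= exact_max_n else "asymptotic"
    try:
        res = stats.mannwhitneyu(hi, lo, alternative="two-sided", method=method)
    except ValueError:  # exact method cannot handle ties
        res = stats.mannwhitneyu(hi, lo, alternative="two-sided",
                                 method="asymptotic")
    direction = int(np.sign(np.median(hi) - np.median(lo)))
    return {"p": float(res.pvalue), "direction": direction,
            "statistic": float(res.statistic)}


def mutation_risk_association(risk: pd.Series, mutations: pd.DataFrame,
                              surv: pd.DataFrame,
                              min_group: int = 3) -> pd.DataFrame:
    """Per-gene mutant vs wild-type: Wilcoxon on risk, log-rank on PFS.

    Genes with fewer than ``min_group`` mutants or wild-types are skipped
    with a log entry.
    """
    surv = surv.copy()
    surv["patient_id"] = surv["patient_id"].astype(str)
    surv = surv.set_index("patient_id")
    common = [s for s in mutations.columns if s in set(risk.index)
              and s in set(surv.index)]
    rows = []
    for gene in mutations.index:
        mut = mutations.loc[gene, common].to_numpy(int).astype(bool)
        n_mut, n_wt = int(mut.sum()), int((~mut).sum())
        if min(n_mut, n_wt) < min_group:
            log.info("skipping %s: %d mutants / %d wild-type",
                     gene, n_mut, n_wt)
            continue
        r = risk.loc[common].to_numpy(float)
        wil = stats.mannwhitneyu(r[mut], r[~mut], alternative="two-sided")
        t = surv.loc[common, "time"].to_numpy(float)
        e = surv.loc[common, "event"].to_numpy(int)
        lr = logrank_test(t[mut], t[~mut], e[mut], e[~mut])
        rows.append({"gene": gene, "n_mut": n_mut, "n_wt": n_wt,
                     "wilcoxon_p": float(wil.pvalue),
                     "risk_median_mut": float(np.median(r[mut])),
                     "risk_median_wt": float(np.median(r[~mut])),
                     "logrank_p": float(lr.p_value)})
    return pd.DataFrame(rows,
                        columns=["gene", "n_mut", "n_wt", "wilcoxon_p",
                                 "risk_median_mut", "risk_median_wt",
                                 "logrank_p"]).set_index("gene")


@dataclass
class GeneSurvivalResult:
    gene: str
    endpoint: str
    logrank_p: float
    km_curves: pd.DataFrame
    n_low: int
    n_high: int
    degenerate_split: bool = False


def per_gene_survival(gene_expr: pd.Series, surv: pd.DataFrame,
                      endpoint: str = "PFS") -> GeneSurvivalResult:
    """KM curves and log-rank p at the gene's median-expression split.

    Samples at or below the median go to the low group (ties to low); a
    split in which at least half the samples tie at the median is flagged
    degenerate with a warning.
    """
    if endpoint not in ("PFS", "OS"):
        raise ValidationError("endpoint must be 'PFS' or 'OS'")
    tcol, ecol = ("time", "event") if endpoint == "PFS" else ("os_time", "os_event")
    surv = surv.copy()
    surv["patient_id"] = surv["patient_id"].astype(str)
    surv = surv.set_index("patient_id")
    common = [s for s in gene_expr.index if s in set(surv.index)]
    x = gene_expr.loc[common].to_numpy(float)
    med = np.median(x)
    low = x <= med
    degenerate = (x == med).sum() >= len(x) / 2
    if degenerate:
        warnings.warn(f"median split of {gene_expr.name!r} is degenerate "
                      "(>= half of samples tie at the median); ties to low")
    n_low, n_high = int(low.sum()), int((~low).sum())
    if min(n_low, n_high) < 4:
        warnings.warn(f"fewer than 4 patients in a split of {gene_expr.name!r}")
    if n_high == 0:
        return GeneSurvivalResult(str(gene_expr.name), endpoint, 1.0,
                                  pd.DataFrame(), n_low, n_high, True)
    t = surv.loc[common, tcol].to_numpy(float)
    e = surv.loc[common, ecol].to_numpy(int)
    lr = logrank_test(t[low], t[~low], e[low], e[~low])
    curves = []
    for name, sel in (("low", low), ("high", ~low)):
        km = KaplanMeierFitter()
        km.fit(t[sel], e[sel], label=name)
        tab = km.survival_function_.reset_index()
        tab.columns = ["time", "survival"]
        tab["group"] = name
        curves.append(tab)
    return GeneSurvivalResult(str(gene_expr.name), endpoint,
                              float(lr.p_value),
                              pd.concat(curves, ignore_index=True),
                              n_low, n_high, bool(degenerate))
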