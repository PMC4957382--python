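"""Reference-gene stability and comparative-Ct differential expression.

Implements geNorm's M statistic (average pairwise log-ratio SD, lower is
more stable) with its iterative worst-removal trace, a simplified two-group
NormFinder-style variance decomposition, the Livak-Schmittgen comparative
Ct method (2^-ddCt, mature vs early stage), and the unpaired two-tailed
pooled-variance Student t test used for significance calls.  A miRNA or
gene is called differentially expressed when the fold change exceeds 2 in
either direction and the t-test p-value is below 0.05; those thresholds are
arguments, not constants.

Technical replicates are averaged per biological replicate before any
statistic; biological replicates are the experimental unit throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

GROUP_EARLY = "early"
GROUP_MATURE = "mature"

CT_COLUMNS = ["assay", "tissue", "group", "biological_rep", "technical_rep", "Ct"]


@dataclass
class FoldChangeResult:
    assay: str
    tissue: str
    fold_change: float
    p_value: float
    n_early: int
    n_mature: int
    significant: bool = False
    direction: str = "none"


def t_test(sample_a, sample_b) -> float:
    """Two-sided pooled-variance (equal-variance) Student t-test p-value.

    Degenerate inputs follow a documented convention: zero pooled variance
    with equal means -> p = 1.0; zero pooled variance with unequal means ->
    p = 0.0.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    na, nb = a.size, b.size
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if pooled == 0.0:
        return 1.0 if diff == 0.0 else 0.0
    t = diff / math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    df = na + nb - 2
    return float(2.0 * sps.t.sf(abs(t), df))


def _check_ct(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns: {missing}")
    if (ct["Ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return ct


def average_technical(ct: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct per (assay, tissue, group, biological_rep)."""
    _check_ct(ct)
    return (ct.groupby(["assay", "tissue", "group", "biological_rep"],
                       as_index=False)["Ct"].mean())


def ddct_fold_change(ct: pd.DataFrame, target_assay: str,
                     reference_assay: str, tissue: str,
                     group_early: str = GROUP_EARLY,
                     group_mature: str = GROUP_MATURE) -> FoldChangeResult:
    """Comparative-Ct fold change of ``target_assay`` (mature vs early).

    Per biological replicate, dCt = Ct_target - Ct_reference (technical
    replicates averaged first); ddCt = mean dCt(mature) - mean dCt(early);
    fold change = 2^-ddCt.  The early group is the calibrator (fold change 1
    by the reporting convention).  The p-value is the unpaired two-tailed
    pooled-variance t-test on the two dCt samples.
    """
    avg = average_technical(ct)
    avg = avg[avg["tissue"] == tissue]
    dcts = {}
    for group in (group_early, group_mature):
        sub = avg[avg["group"] == group].pivot(index="biological_rep",
                                               columns="assay", values="Ct")
        if (sub.empty or target_assay not in sub.columns
                or reference_assay not in sub.columns):
            raise ValueError(
                f"group {group!r} missing assay data for tissue {tissue!r}")
        dct = (sub[target_assay] - sub[reference_assay]).dropna()
        if len(dct) < 2:
            raise ValueError(f"group {group!r} has < 2 biological replicates")
        dcts[group] = dct.to_numpy()
    ddct = dcts[group_mature].mean() - dcts[group_early].mean()
    fold = 2.0 ** (-ddct)
    p = t_test(dcts[group_early], dcts[group_mature])
    return FoldChangeResult(assay=target_assay, tissue=tissue,
                            fold_change=fold, p_value=p,
                            n_early=len(dcts[group_early]),
                            n_mature=len(dcts[group_mature]))


def call_differential(results, fc_threshold: float = 2.0,
                      alpha: float = 0.05, adjust: str = None):
    """Set significance flags and directions on FoldChangeResults.

    ``significant`` iff fold change > ``fc_threshold`` or <
    ``1/fc_threshold`` and p < ``alpha``.  ``adjust='bh'`` applies a
    Benjamini-Hochberg correction across the result list before the alpha
    comparison (off by default, matching per-assay testing).
    """
    results = list(results)
    pvals = [r.p_value for r in results]
    if adjust == "bh" and pvals:
        pvals = list(sps.false_discovery_control(pvals, method="bh"))
    for r, p in zip(results, pvals):
        fold_ok = r.fold_change > fc_threshold or r.fold_change < 1.0 / fc_threshold
        r.significant = bool(fold_ok and p < alpha)
        if r.significant:
            r.direction = "up" if r.fold_change > 1.0 else "down"
        else:
            r.direction = "none"
    return results


def genorm_stability(quantities: pd.DataFrame):
    """geNorm M per assay plus the iterative worst-removal trace.

    ``quantities`` has assays as rows and samples as columns, holding
    strictly positive relative quantities.  M_j is the mean over all other
    assays k of the SD (ddof=1) across samples of log2(q_j / q_k); assays
    are ranked ascending in M (most stable first).  The trace records the
    removal order (worst first) down to the final pair.
    """
    if quantities.shape[0] < 3:
        raise ValueError("geNorm needs at least 3 candidate assays")
    if quantities.shape[1] < 2:
        raise ValueError("geNorm needs at least 2 samples")
    if (quantities <= 0).any().any():
        raise ValueError("zero or negative quantity: log-ratio undefined")
    logq = np.log2(quantities.astype(float))

    def m_values(frame):
        assays = frame.index
        vals = {}
        arr = frame.to_numpy()
        for j, a in enumerate(assays):
            sds = [np.std(arr[j] - arr[k], ddof=1)
                   for k in range(len(assays)) if k != j]
            vals[a] = float(np.mean(sds))
        return pd.Series(vals)

    M = m_values(logq).sort_values(kind="stable")
    trace = []
    working = logq.copy()
    while working.shape[0] > 2:
        cur = m_values(working)
        worst = cur.sort_values(kind="stable").index[-1]
        trace.append((worst, float(cur[worst])))
        working = working.drop(index=worst)
    return M, trace


def normfinder_stability(quantities: pd.DataFrame, groups) -> pd.Series:
    """Simplified two-group NormFinder-style stability per assay.

    On log2 quantities, stability = sqrt(intergroup variance of the group
    means + mean intragroup variance); 0 for an assay constant everywhere.
    ``groups`` labels each sample column.
    """
    groups = np.asarray(groups)
    if quantities.shape[1] != groups.size:
        raise ValueError("one group label per sample column required")
    labels = pd.unique(groups)
    if labels.size < 2:
        raise ValueError("NormFinder needs at least 2 groups")
    for g in labels:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    if (quantities <= 0).any().any():
        raise ValueError("zero or negative quantity: log undefined")
    logq = np.log2(quantities.astype(float))
    out = {}
    for assay, row in logq.iterrows():
        means = np.array([row[groups == g].mean() for g in labels])
        intra = np.mean([row[groups == g].var(ddof=1) for g in labels])
        inter = means.var(ddof=1)
        out[assay] = float(np.sqrt(inter + intra))
    return pd.Series(out).sort_values(kind="stable")


def quantities_from_ct(ct: pd.DataFrame, assays=None) -> pd.DataFrame:
    """Relative quantity matrix (assays x samples) from a Ct table.

    Quantities are 2^-Ct rescaled per assay to a geometric mean of 1 (the
    rescaling cancels in every pairwise log-ratio, and keeps numbers in a
    readable range).  Samples are (tissue, group, biological_rep) cells with
    technical replicates averaged.
    """
    avg = average_technical(ct)
    if assays is not None:
        avg = avg[avg["assay"].isin(list(assays))]
    avg = avg.assign(sample=avg["tissue"] + ":" + avg["group"] + ":"
                     + avg["biological_rep"].astype(str))
    mat = avg.pivot(index="assay", columns="sample", values="Ct")
    q = 2.0 ** (-mat)
    geo = np.exp(np.log(q).mean(axis=1))
    return q.div(geo, axis=0)
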