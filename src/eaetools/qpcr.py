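"""qRT-PCR relative quantification.

Technical triplicates are averaged after a conditional Grubbs outlier test
(run only when the triplicate SD exceeds 0.25 cycles), expression is
normalized to an endogenous-control gene and centered on the vehicle group
(-ddCp, which equals log2 fold change), and treated groups are compared to
vehicle by unpaired t-test with Welch's correction applied when an F pretest
finds unequal variances.

A note on the n = 3 boundary: the Grubbs statistic of a triplicate cannot
exceed (n-1)/sqrt(n) = 1.1547, and the two-sided 5% critical value is
1.1543, so removal is possible only when two of the three values nearly
coincide.  The critical value is computed from the t-distribution closed
form rather than a table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrubbsResult",
    "WelchComparison",
    "DdCpResult",
    "grubbs_critical_value",
    "filter_triplicate_grubbs",
    "neg_delta_delta_cp",
    "compare_groups_welch",
]


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from its t-distribution form,

    G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2)),
    t = upper (alpha / 2n) quantile of t with n-2 df.
    """
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


@dataclass(frozen=True)
class GrubbsResult:
    kept: np.ndarray
    removed: float | None
    mean_cp: float
    sd: float
    tested: bool
    g: float | None = None
    g_crit: float | None = None


def filter_triplicate_grubbs(
    values, sd_trigger: float = 0.25, alpha: float = 0.05,
) -> GrubbsResult:
    """Conditionally Grubbs-filter one technical-replicate set.

    The test runs only when the sample SD exceeds ``sd_trigger`` cycles
    (and n >= 3); it is single-pass: at most one value — the most extreme —
    is removed, and only if G exceeds the two-sided critical value.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two replicate Cp values")
    sd = float(np.std(x, ddof=1))
    if x.size < 3 or sd <= sd_trigger:
        return GrubbsResult(kept=x, removed=None, mean_cp=float(np.mean(x)),
                            sd=sd, tested=False)
    dev = np.abs(x - np.mean(x))
    g = float(dev.max() / sd)
    crit = grubbs_critical_value(x.size, alpha)
    if g > crit:
        i = int(np.argmax(dev))
        kept = np.delete(x, i)
        return GrubbsResult(kept=kept, removed=float(x[i]),
                            mean_cp=float(np.mean(kept)),
                            sd=float(np.std(kept, ddof=1)), tested=True,
                            g=g, g_crit=crit)
    return GrubbsResult(kept=x, removed=None, mean_cp=float(np.mean(x)),
                        sd=sd, tested=True, g=g, g_crit=crit)


@dataclass(frozen=True)
class WelchComparison:
    t: float
    df: float
    p: float
    welch_applied: bool
    f_stat: float
    f_p: float


def compare_groups_welch(
    vehicle, treated, alpha: float = 0.05,
) -> WelchComparison:
    """Unpaired two-tailed t-test of treated vs vehicle.

    An F ratio pretest (two-sided, at ``alpha``) decides between the pooled
    and the Welch form; the t sign follows treated - vehicle.
    """
    a = np.asarray(vehicle, dtype=float)
    b = np.asarray(treated, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0.0 and vb == 0.0:
        raise ValueError("zero variance in both groups")
    if va >= vb:
        f, dfn, dfd = (np.inf if vb == 0 else va / vb), a.size - 1, b.size - 1
    else:
        f, dfn, dfd = vb / va, b.size - 1, a.size - 1
    f_p = min(1.0, 2.0 * float(stats.f.sf(f, dfn, dfd)))
    welch = f_p < alpha
    res = stats.ttest_ind(b, a, equal_var=not welch)
    return WelchComparison(t=float(res.statistic), df=float(res.df),
                           p=float(res.pvalue), welch_applied=welch,
                           f_stat=float(f), f_p=f_p)


@dataclass
class DdCpResult:
    samples: pd.DataFrame        # sample_id, group, gene, delta_cp, neg_ddcp, fold_change
    group_summary: pd.DataFrame  # gene, group, n, mean_neg_ddcp, sem
    comparisons: dict            # (gene, group) -> WelchComparison vs vehicle


def neg_delta_delta_cp(
    cp_table: pd.DataFrame,
    target_genes=None,
    *,
    endogenous_gene: str = "Gapdh",
    vehicle_group: str = "Vehicle",
    sd_trigger: float = 0.25,
    alpha: float = 0.05,
) -> DdCpResult:
    """-ddCp relative quantification.

    Per sample and gene the replicate Cp values are Grubbs-filtered and
    averaged; dCp = Cp_target - Cp_endogenous; -ddCp = -(dCp - vehicle-group
    mean dCp); fold change = 2^(-ddCp).  The vehicle group therefore
    averages -ddCp = 0 exactly for every gene.  Samples lacking the
    endogenous gene are dropped with a warning.  Each treated group with at
    least two samples is compared to vehicle (Welch-corrected t as needed).

    ``cp_table`` columns: sample_id, group, gene, replicate, cp.
    """
    genes = set(cp_table["gene"].unique())
    if endogenous_gene not in genes:
        raise ValueError(f"endogenous gene {endogenous_gene!r} absent")
    if vehicle_group not in set(cp_table["group"].unique()):
        raise ValueError(f"vehicle group {vehicle_group!r} absent")
    if target_genes is None:
        target_genes = sorted(genes - {endogenous_gene})

    mean_cp = (cp_table.groupby(["sample_id", "group", "gene"])["cp"]
               .apply(lambda v: filter_triplicate_grubbs(
                   v.to_numpy(), sd_trigger, alpha).mean_cp)
               .rename("mean_cp").reset_index())
    endo = mean_cp[mean_cp["gene"] == endogenous_gene][
        ["sample_id", "mean_cp"]].rename(columns={"mean_cp": "endo_cp"})

    rows = []
    comparisons = {}
    for gene in target_genes:
        sub = mean_cp[mean_cp["gene"] == gene].merge(
            endo, on="sample_id", how="left")
        missing = sub["endo_cp"].isna()
        if missing.any():
            warnings.warn(
                f"{int(missing.sum())} sample(s) without endogenous Cp "
                f"dropped for gene {gene}")
            sub = sub[~missing]
        sub = sub.assign(delta_cp=sub["mean_cp"] - sub["endo_cp"])
        veh = sub.loc[sub["group"] == vehicle_group, "delta_cp"]
        if veh.empty:
            raise ValueError(f"no vehicle sample with gene {gene}")
        sub = sub.assign(neg_ddcp=-(sub["delta_cp"] - veh.mean()))
        sub = sub.assign(fold_change=2.0 ** sub["neg_ddcp"])
        rows.append(sub[["sample_id", "group", "gene", "delta_cp",
                         "neg_ddcp", "fold_change"]])
        veh_vals = sub.loc[sub["group"] == vehicle_group, "neg_ddcp"].to_numpy()
        for grp in sub["group"].unique():
            if grp == vehicle_group:
                continue
            trt = sub.loc[sub["group"] == grp, "neg_ddcp"].to_numpy()
            if veh_vals.size >= 2 and trt.size >= 2:
                try:
                    comparisons[(gene, grp)] = compare_groups_welch(
                        veh_vals, trt, alpha)
                except ValueError as err:
                    warnings.warn(f"comparison {gene}/{grp} skipped: {err}")

    samples = pd.concat(rows, ignore_index=True)
    group_summary = (samples.groupby(["gene", "group"])["neg_ddcp"]
                     .agg(n="size", mean_neg_ddcp="mean",
                          sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
                     .reset_index())
    return DdCpResult(samples=samples, group_summary=group_summary,
                      comparisons=comparisons)
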