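"""Cohort-level statistics of pattern timelines and morphometrics.

Aggregates per-couple pattern timelines, aligned to tight cell coupling
(t0), into percent-of-couples time courses with dispersion, the log2
central/invagination ratio curve (values above 0 indicate preferential
central accumulation), cumulative off-interface lamella fractions, and
exact two-proportion condition comparisons with Holm adjustment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .config import StatsParams
from .labels import PATTERNS


def pattern_frequencies(
    timelines: list[dict[float, str]],
    condition: str,
    params: StatsParams | None = None,
    experiment_ids: list | None = None,
) -> pd.DataFrame:
    """Percent of couples per pattern per aligned timepoint.

    Couples lacking a timepoint contribute to neither numerator nor
    denominator there; timepoints with no couples are omitted.  An extra
    ``any`` row gives the percent of couples with accumulation in any
    pattern.  Dispersion is the binomial standard error
    ``100*sqrt(p(1-p)/n)`` by default, or the between-experiment SEM of
    per-experiment percentages when ``experiment_ids`` are given and the
    configuration selects the ``experiment`` mode.
    """
    params = params or StatsParams()
    rows = []
    times = sorted({t for tl in timelines for t in tl})
    for t in times:
        labels = [tl[t] for tl in timelines if t in tl]
        exps = (
            [e for tl, e in zip(timelines, experiment_ids) if t in tl]
            if experiment_ids is not None
            else None
        )
        n = len(labels)
        if n == 0:
            continue
        counts = {p: labels.count(p) for p in PATTERNS}
        counts["any"] = n - counts["none"]
        for p in list(PATTERNS) + ["any"]:
            k = counts[p]
            frac = k / n
            if params.dispersion == "experiment" and exps is not None:
                per_exp = [
                    np.mean([lab == p if p != "any" else lab != "none"
                             for lab, e2 in zip(labels, exps) if e2 == e])
                    for e in sorted(set(exps))
                ]
                se = (
                    100 * np.std(per_exp, ddof=1) / np.sqrt(len(per_exp))
                    if len(per_exp) > 1 else np.nan
                )
            else:
                se = 100 * np.sqrt(frac * (1 - frac) / n)
            rows.append(
                {
                    "condition": condition,
                    "time_rel_s": float(t),
                    "pattern": p,
                    "n": n,
                    "count": k,
                    "percent": 100 * frac,
                    "se": se,
                }
            )
    return pd.DataFrame(rows)


def central_invagination_ratio(
    table: pd.DataFrame,
    params: StatsParams | None = None,
) -> pd.DataFrame:
    """log2 of (central couples / invagination couples) per timepoint.

    A continuity constant (0.5 couples by default, the Haldane–Anscombe
    correction) keeps the ratio finite when one count is zero.  Positive
    values indicate preferential central accumulation.
    """
    params = params or StatsParams()
    c = params.continuity
    rows = []
    for (cond, t), grp in table.groupby(["condition", "time_rel_s"]):
        by = dict(zip(grp.pattern, grp["count"]))
        if "central" not in by or "invagination" not in by:
            continue
        rows.append(
            {
                "condition": cond,
                "time_rel_s": t,
                "log2_central_over_invagination": float(
                    np.log2((by["central"] + c) / (by["invagination"] + c))
                ),
            }
        )
    return pd.DataFrame(rows)


def cumulative_off_interface(
    morph: pd.DataFrame,
    condition: str | None = None,
    params: StatsParams | None = None,
) -> pd.DataFrame:
    """Cumulative percent of couples with an off-interface lamella.

    ``morph`` needs columns couple_id, time_rel_s and
    has_off_interface_lamella.  At each aligned timepoint t the value is
    the percentage of couples flagged at any time in (0, t]; the curve is
    non-decreasing by construction.
    """
    params = params or StatsParams()
    couples = sorted(morph.couple_id.unique())
    n = len(couples)
    flagged = morph[
        morph.has_off_interface_lamella & (morph.time_rel_s > 0)
    ]
    first_flag = flagged.groupby("couple_id").time_rel_s.min()
    rows = []
    for t in params.grid():
        if t <= 0:
            continue
        k = int((first_flag <= t).sum())
        rows.append(
            {
                "condition": condition,
                "time_rel_s": float(t),
                "n": n,
                "count": k,
                "cumulative_percent": 100.0 * k / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def compare_conditions(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    patterns: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Exact two-proportion tests per pattern per timepoint, Holm-adjusted.

    For each shared timepoint the couples showing a pattern in condition A
    versus B are compared with a two-sided Fisher exact test; p-values are
    Holm-adjusted within each pattern's time course.  Timepoints absent
    from either table (zero n) are skipped.
    """
    patterns = patterns or list(PATTERNS) + ["any"]
    rows = []
    for p in patterns:
        a = table_a[table_a.pattern == p].set_index("time_rel_s")
        b = table_b[table_b.pattern == p].set_index("time_rel_s")
        times = sorted(set(a.index) & set(b.index))
        ps, recs = [], []
        for t in times:
            ka, na = int(a.loc[t, "count"]), int(a.loc[t, "n"])
            kb, nb = int(b.loc[t, "count"]), int(b.loc[t, "n"])
            if na == 0 or nb == 0:
                continue
            _, pval = fisher_exact(
                [[ka, na - ka], [kb, nb - kb]], alternative="two-sided"
            )
            ps.append(pval)
            recs.append((t, ka, na, kb, nb, pval))
        if not recs:
            continue
        adj = multipletests(ps, alpha=alpha, method="holm")[1]
        for (t, ka, na, kb, nb, pval), padj in zip(recs, adj):
            rows.append(
                {
                    "pattern": p,
                    "time_rel_s": float(t),
                    "count_a": ka,
                    "n_a": na,
                    "count_b": kb,
                    "n_b": nb,
                    "p_raw": pval,
                    "p_holm": padj,
                    "significant": padj < alpha,
                }
            )
    return pd.DataFrame(rows)


def plot_time_course(table: pd.DataFrame, path) -> None:
    """Percent-of-couples time courses, one line per pattern."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for (cond, p), grp in table.groupby(["condition", "pattern"]):
        if p == "none":
            continue
        grp = grp.sort_values("time_rel_s")
        ax.errorbar(
            grp.time_rel_s, grp.percent, yerr=grp.se,
            label=f"{cond}: {p}", capsize=2,
        )
    ax.set_xlabel("time relative to tight coupling (s)")
    ax.set_ylabel("% of cell couples")
    ax.set_ylim(bottom=0)
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ratio(series: pd.DataFrame, path) -> None:
    """log2 central/invagination ratio versus aligned time, zero line shown."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for cond, grp in series.groupby("condition"):
        grp = grp.sort_values("time_rel_s")
        ax.plot(
            grp.time_rel_s, grp.log2_central_over_invagination,
            marker="o", label=cond,
        )
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("time relative to tight coupling (s)")
    ax.set_ylabel("log2 central / invagination")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
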