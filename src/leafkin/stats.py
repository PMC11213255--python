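"""Per-bin group statistics: ANOVA, Tukey HSD and compact letter displays.

Replicate plants are the experimental unit; statistics are computed per
2-h zeitgeber bin independently (no multiplicity correction across bins —
a deliberate mirror of how such kinetic panels are conventionally
presented, and a documented caveat).  One-way ANOVA when only a treatment
factor is present, two-way with interaction when a genotype factor is
added; the two-way case uses Type II sums of squares, the conventional
default for unbalanced factorials without interaction emphasis.

Letters follow the insert-and-absorb construction: groups sharing a letter
are not significantly different under Tukey-adjusted pairwise tests at the
chosen alpha.
"""

from __future__ import annotations

import string

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

DEFAULT_ALPHA = 0.05


def _check_groups(data: pd.DataFrame, value: str, factors: list[str]) -> None:
    for factor in factors:
        counts = data.dropna(subset=[value]).groupby(factor, observed=True)[value].size()
        if len(counts) < 2:
            raise ValueError(f"factor {factor!r} needs >= 2 levels, has {len(counts)}")
        small = counts[counts < 2]
        if len(small):
            raise ValueError(
                f"groups with n < 2 for factor {factor!r}: {dict(small)}"
            )


def anova(data: pd.DataFrame, value: str = "value",
          factors: list[str] | None = None) -> pd.DataFrame:
    """Fixed-effects ANOVA table (effect, F, df1, df2, p).

    One-way for a single factor; two-way with interaction (Type II sums of
    squares) for two.  Every tested group must have n >= 2.
    """
    factors = factors or ["treatment"]
    if len(factors) not in (1, 2):
        raise ValueError("one or two factors supported")
    data = data.dropna(subset=[value] + factors)
    _check_groups(data, value, factors)

    terms = [f"C({f})" for f in factors]
    if len(factors) == 2:
        terms.append(f"C({factors[0]}):C({factors[1]})")
    formula = f"{value} ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=data).fit()
    table = sm.stats.anova_lm(fit, typ=2)

    df_resid = float(table.loc["Residual", "df"])
    rows = []
    for term, factor_label in zip(terms, factors + (["interaction"] if len(factors) == 2 else [])):
        rows.append({
            "effect": factor_label,
            "F": float(table.loc[term, "F"]),
            "df1": float(table.loc[term, "df"]),
            "df2": df_resid,
            "p": float(table.loc[term, "PR(>F)"]),
        })
    return pd.DataFrame(rows)


def tukey_hsd(data: pd.DataFrame, value: str = "value", group: str = "treatment"
              ) -> tuple[list[str], np.ndarray]:
    """Tukey honest-significant-difference pairwise comparisons.

    Returns (group labels, symmetric matrix of studentized-range adjusted
    p-values with unit diagonal).  Group order is sorted label order.
    """
    data = data.dropna(subset=[value, group])
    _check_groups(data, value, [group])
    labels = sorted(data[group].unique())
    samples = [data.loc[data[group] == g, value].to_numpy(float) for g in labels]
    res = scipy.stats.tukey_hsd(*samples)
    p = np.asarray(res.pvalue, dtype=float)
    np.fill_diagonal(p, 1.0)
    return labels, p


def compact_letter_display(p_matrix: np.ndarray, groups: list[str],
                           means: dict[str, float] | None = None,
                           alpha: float = DEFAULT_ALPHA) -> dict[str, str]:
    """Letters per group such that two groups share a letter iff their
    adjusted pairwise p >= alpha.

    Insert-and-absorb: start from one letter covering all groups; for each
    significant pair, split every letter containing both; absorb letters
    whose membership is a subset of another's.  Groups are ordered by
    descending mean (ties broken by input order) so the first letter lands
    on the largest group, as the convention reads.
    """
    p = np.asarray(p_matrix, dtype=float)
    k = len(groups)
    if p.shape != (k, k):
        raise ValueError(f"p matrix shape {p.shape} does not match {k} groups")
    if not np.allclose(p, p.T, atol=1e-12):
        raise ValueError("pairwise p matrix must be symmetric")

    if means is not None:
        order = sorted(range(k), key=lambda i: (-means[groups[i]], i))
    else:
        order = list(range(k))

    # letter sets hold positions in `order`
    letters: list[set[int]] = [set(range(k))]
    for a in range(k):
        for b in range(a + 1, k):
            i, j = order[a], order[b]
            if p[i, j] < alpha:
                for s in [s for s in letters if a in s and b in s]:
                    letters.remove(s)
                    s1, s2 = s - {b}, s - {a}
                    for cand in (s1, s2):
                        if not any(cand <= other for other in letters):
                            letters = [o for o in letters if not o < cand]
                            letters.append(cand)

    # deterministic ordering: by smallest member position
    letters.sort(key=lambda s: sorted(s))
    if len(letters) > len(string.ascii_lowercase):
        raise ValueError("more letter classes than letters available")
    out = {g: "" for g in groups}
    for letter, s in zip(string.ascii_lowercase, letters):
        for pos in sorted(s):
            out[groups[order[pos]]] += letter
    return out


def summarize(long: pd.DataFrame, value: str = "value",
              by: list[str] | None = None) -> pd.DataFrame:
    """Group mean ± SEM (sd/sqrt(n), sample sd, ddof=1; SEM missing at n=1)."""
    by = by or ["treatment", "zt_h"]
    g = long.dropna(subset=[value]).groupby(by, observed=True)[value]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="size").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] < 2, "sem"] = np.nan
    return out.drop(columns="sd")


def binned_stats(binned: pd.DataFrame, metric: str, alpha: float = DEFAULT_ALPHA,
                 factors: list[str] | None = None,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full statistical presentation for one metric from per-plant bin means.

    ``binned`` is the long per-plant bin table (plant_id, treatment,
    bin_start_zt_h, metric, mean[, genotype]).  Per bin: ANOVA across the
    factor groups, Tukey pairwise tests on the first factor, letters, and
    mean ± SEM.  Returns (summary table with letters, ANOVA table); rows of
    the summary share a letter within a bin iff not significantly different.
    """
    factors = factors or ["treatment"]
    df = binned[binned["metric"] == metric]
    if df.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    summary_rows = []
    anova_rows = []
    for bin_start, sub in df.groupby("bin_start_zt_h"):
        at = anova(sub, value="mean", factors=factors)
        at.insert(0, "bin_start_zt_h", bin_start)
        anova_rows.append(at)

        labels, p = tukey_hsd(sub, value="mean", group=factors[0])
        gmeans = sub.groupby(factors[0], observed=True)["mean"].mean().to_dict()
        letters = compact_letter_display(p, labels, means=gmeans, alpha=alpha)
        summ = summarize(sub, value="mean", by=[factors[0]])
        summ.insert(0, "bin_start_zt_h", bin_start)
        summ["letter"] = summ[factors[0]].map(letters)
        summary_rows.append(summ)

    summary = pd.concat(summary_rows, ignore_index=True)
    summary = summary.rename(columns={factors[0]: "group"})
    summary = summary[["bin_start_zt_h", "group", "mean", "sem", "n", "letter"]]
    return summary, pd.concat(anova_rows, ignore_index=True)
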