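"""Factorial inference: two-way ANOVA, protected LSD letters, correlations.

The incubation is a balanced 2 x 2 factorial (straw x wood ash, n = 3
jars per cell). Two views of the same data are reported:

* a two-way ANOVA with interaction giving the straw, ash and straw x ash
  p-value columns of the treatment table;
* a one-way ANOVA across the four treatment cells whose error term feeds
  Fisher's protected LSD: pairwise comparisons are attempted only when the
  omnibus F is significant, and means are labelled with compact letters
  ("a" for the largest mean downward; treatments share a letter iff their
  difference is below LSD = t(1 - alpha/2, df_err) * sqrt(2 * MSE / n)).

Pearson correlation matrices carry two-tailed p-values from the exact
t transform and significance flags at 0.05 / 0.01; no multiplicity
correction is applied (matching common practice for these summary tables).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "two_way_anova",
    "one_way_anova",
    "lsd_letters",
    "correlation_matrix",
    "type1_error_simulation",
]


def _check_factorial(design: pd.DataFrame) -> None:
    required = {"straw", "ash", "value"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"factorial design missing columns: {sorted(missing)}")
    counts = design.groupby(["straw", "ash"]).size()
    if len(counts) != 4:
        raise ValueError("design must be fully crossed 2 x 2 (one or more empty cells)")
    if (counts < 2).any():
        raise ValueError("need >= 2 replicates per cell for a nonzero error df")


def two_way_anova(design: pd.DataFrame) -> pd.DataFrame:
    """Balanced two-way ANOVA with interaction.

    ``design`` carries boolean/0-1 columns ``straw`` and ``ash`` plus
    ``value``. Returns a frame indexed by effect (``straw``, ``ash``,
    ``straw:ash``, ``residual``) with ``ss``, ``df``, ``F`` and ``p``.
    A zero-variance response yields F = 0, p = 1 for every effect.
    """
    _check_factorial(design)
    d = design.assign(straw=design["straw"].astype(int), ash=design["ash"].astype(int))
    v = d["value"].to_numpy(dtype=float)
    effects = ["straw", "ash", "straw:ash"]
    # constant response: every SS is 0/0 noise; report no evidence of effects
    if ((v - v.mean()) ** 2).sum() <= 1e-12 * max(1.0, v.mean() ** 2) * v.size:
        n = v.size
        return pd.DataFrame(
            {
                "ss": [0.0, 0.0, 0.0, 0.0],
                "df": [1.0, 1.0, 1.0, float(n - 4)],
                "F": [0.0, 0.0, 0.0, np.nan],
                "p": [1.0, 1.0, 1.0, np.nan],
            },
            index=effects + ["residual"],
        )
    fit = smf.ols("value ~ C(straw) * C(ash)", data=d).fit()
    tab = anova_lm(fit, typ=2)
    tab.index = effects + ["residual"]
    return tab.rename(columns={"sum_sq": "ss", "PR(>F)": "p"})[["ss", "df", "F", "p"]]


def one_way_anova(values: pd.DataFrame, group: str = "treatment") -> dict:
    """One-way ANOVA across treatment cells (the omnibus test for LSD).

    Returns ``F``, ``p``, ``mse``, ``df_error`` and the per-group ``n``.
    A zero-variance response yields F = 0, p = 1.
    """
    groups = [g["value"].to_numpy() for _, g in values.groupby(group, sort=False)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ns = np.array([len(g) for g in groups])
    if (ns < 2).any():
        raise ValueError("every group needs >= 2 replicates")
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_e = int(ns.sum() - len(groups))
    mse = ss_within / df_e
    if mse == 0:
        f_stat, p = (0.0, 1.0) if ss_between < 1e-30 else (np.inf, 0.0)
    else:
        f_stat = (ss_between / df_b) / mse
        p = float(scipy.stats.f.sf(f_stat, df_b, df_e))
    return {"F": float(f_stat), "p": p, "mse": float(mse), "df_error": df_e, "n": ns}


def lsd_letters(
    values: pd.DataFrame, alpha: float = 0.05, group: str = "treatment"
) -> pd.DataFrame:
    """Compact letter display from Fisher's protected LSD.

    ``values`` is long-format with a grouping column and ``value``.
    Replication must be balanced (the design of interest always is).
    If the omnibus one-way F is not significant at ``alpha``, all groups
    share the letter "a". Otherwise letters are assigned from the largest
    mean downward with the standard insert-and-absorb sweep; two groups
    share a letter iff |mean difference| <= LSD.
    """
    stats = values.groupby(group, sort=False)["value"].agg(["mean", "sem", "size"])
    if stats["size"].nunique() != 1:
        raise ValueError("unbalanced replication is not supported for LSD letters")
    n = int(stats["size"].iloc[0])
    omnibus = one_way_anova(values, group=group)
    order = stats.sort_values("mean", ascending=False).index.to_list()

    if omnibus["p"] > alpha:
        letters = {g: "a" for g in order}
    else:
        t_crit = scipy.stats.t.ppf(1 - alpha / 2, omnibus["df_error"])
        lsd = t_crit * np.sqrt(2 * omnibus["mse"] / n)
        m = stats.loc[order, "mean"].to_numpy()  # descending
        k = len(order)
        # the "not significantly different" relation |mi - mj| <= LSD is an
        # interval graph on the ordered means, so each letter is a maximal
        # run [i..j] with m[i] - m[j] <= LSD (insert-and-absorb collapses to
        # keeping only runs not contained in a longer one)
        runs = []
        for i in range(k):
            j = i
            while j + 1 < k and m[i] - m[j + 1] <= lsd:
                j += 1
            runs.append((i, j))
        keep = [
            (i, j)
            for (i, j) in runs
            if not any((i2 <= i and j <= j2) and (i2, j2) != (i, j) for (i2, j2) in runs)
        ]
        alphabet = "abcdefghijklmnopqrstuvwxyz"
        letters = {g: "" for g in order}
        for letter, (i, j) in zip(alphabet, sorted(set(keep))):
            for g in order[i : j + 1]:
                letters[g] += letter

    out = stats.loc[order].reset_index().rename(columns={"sem": "se", "size": "n"})
    out["letters"] = [letters[g] for g in order]
    return out


def correlation_matrix(variables: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Pairwise Pearson correlations with p-values and significance flags.

    ``variables`` is a samples x variables numeric frame (n >= 3 rows).
    Returns dict of aligned frames ``r``, ``p`` and ``flag`` (``""``,
    ``"*"`` for p < 0.05, ``"**"`` for p < 0.01; diagonal left blank).
    """
    if len(variables) < 3:
        raise ValueError("need at least 3 observations for a correlation p-value")
    stds = variables.std(ddof=1)
    dead = stds[stds == 0].index.to_list()
    if dead:
        raise ValueError(f"zero-variance variables: {dead}")
    cols = variables.columns
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            res = scipy.stats.pearsonr(variables[a], variables[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    flag = p.map(lambda v: "**" if v < 0.01 else "*" if v < 0.05 else "")
    np.fill_diagonal(flag.values, "")
    return {"r": r, "p": p, "flag": flag}


def type1_error_simulation(
    n_runs: int = 2000,
    n_per_cell: int = 3,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Null rejection rates of the two-way ANOVA effects.

    Simulates ``n_runs`` balanced 2 x 2 x ``n_per_cell`` datasets with no
    true effects (iid standard Gaussian response) and returns the fraction
    of runs rejecting each effect at ``alpha``. Under a correct test each
    rate estimates alpha itself.
    """
    rng = np.random.default_rng(seed)
    straw = np.repeat([0, 0, 1, 1], n_per_cell)
    ash = np.repeat([0, 1, 0, 1], n_per_cell)
    rejections = {"straw": 0, "ash": 0, "straw:ash": 0}
    for _ in range(n_runs):
        design = pd.DataFrame(
            {"straw": straw, "ash": ash, "value": rng.standard_normal(straw.size)}
        )
        tab = two_way_anova(design)
        for eff in rejections:
            if tab.loc[eff, "p"] < alpha:
                rejections[eff] += 1
    return {eff: count / n_runs for eff, count in rejections.items()}
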