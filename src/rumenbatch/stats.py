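"""Treatment comparisons and correlation screens.

Treatment means are compared by one-way ANOVA on the experimental units
(per-run bottle averages), with a pooled SEM ``sqrt(MSE / n)`` and compact
significance letters from pairwise Tukey HSD at alpha = 0.05 (unprotected
LSD available as an alternative).  Letters follow the publication
convention: groups sharing a letter do not differ pairwise, and letters are
assigned in descending-mean order starting at "a".

Association screens use Spearman's rank correlation with average ranks for
ties; cells are starred only when |rho| > 0.1 and p <= 0.05
(* 0.01 < p <= 0.05, ** 0.001 < p <= 0.01, *** p <= 0.001), with no
multiple-testing correction.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidInputError

__all__ = [
    "GroupComparison", "compare_groups", "compact_letters",
    "group_summary_table", "spearman_matrix", "star_annotation",
]


@dataclass(frozen=True)
class GroupComparison:
    """One row of a treatment-comparison table."""

    means: Mapping[str, float]
    pooled_sem: float
    f_statistic: float
    p_value: float
    letters: Mapping[str, str]
    n_per_group: Mapping[str, int]


def _anova(groups: dict[str, np.ndarray]) -> tuple[float, float, float, int]:
    """Return (F, p, MSE, df_within) handling the zero-variance corner."""
    values = list(groups.values())
    n_total = sum(v.size for v in values)
    k = len(values)
    df_w = n_total - k
    grand = np.concatenate(values).mean()
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in values)
    ss_among = sum(v.size * (v.mean() - grand) ** 2 for v in values)
    mse = ss_within / df_w
    if mse == 0:
        if ss_among == 0:
            return 0.0, 1.0, 0.0, df_w
        return np.inf, 0.0, 0.0, df_w
    f = (ss_among / (k - 1)) / mse
    p = float(sps.f.sf(f, k - 1, df_w))
    return float(f), p, float(mse), df_w


def _pairwise_p(means: dict[str, float], ns: dict[str, int], mse: float,
                df_w: int, k: int,
                method: Literal["tukey", "lsd"]) -> dict[frozenset, float]:
    out: dict[frozenset, float] = {}
    for g1, g2 in combinations(means, 2):
        diff = abs(means[g1] - means[g2])
        if mse == 0:
            out[frozenset((g1, g2))] = 1.0 if diff == 0 else 0.0
            continue
        if method == "tukey":
            # Tukey-Kramer studentized-range statistic
            se = np.sqrt(mse / 2.0 * (1.0 / ns[g1] + 1.0 / ns[g2]))
            q = diff / se
            p = float(sps.studentized_range.sf(q, k, df_w))
        elif method == "lsd":
            se = np.sqrt(mse * (1.0 / ns[g1] + 1.0 / ns[g2]))
            t = diff / se
            p = float(2.0 * sps.t.sf(t, df_w))
        else:
            raise InvalidInputError(f"unknown post-hoc method {method!r}")
        out[frozenset((g1, g2))] = p
    return out


def compact_letters(means: Mapping[str, float],
                    significant: Mapping[frozenset, bool]) -> dict[str, str]:
    """Compact letter display via the insert-and-absorb algorithm.

    *significant* maps each unordered group pair to whether it differs.
    Groups sharing any letter are not significantly different; letter classes
    are ordered by their best (largest) member mean, so higher means get
    earlier letters.
    """
    groups = list(means)
    columns: list[set[str]] = [set(groups)]
    for pair, sig in significant.items():
        if not sig:
            continue
        g1, g2 = tuple(pair)
        for col in [c for c in columns if g1 in c and g2 in c]:
            columns.remove(col)
            for dropped in (g1, g2):
                new = col - {dropped}
                if new and not any(new <= other for other in columns):
                    columns.append(new)
        # absorb: drop columns that became subsets of others
        columns = [c for c in columns
                   if not any(c < other for other in columns)]
    columns.sort(key=lambda c: -max(means[g] for g in c))
    alphabet = string.ascii_lowercase
    letters: dict[str, list[str]] = {g: [] for g in groups}
    for i, col in enumerate(columns):
        for g in col:
            letters[g].append(alphabet[i % len(alphabet)])
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    method: Literal["tukey", "lsd"] = "tukey",
) -> GroupComparison:
    """One-way ANOVA with pooled SEM and compact significance letters."""
    groups = {g: np.asarray(v, dtype=float)
              for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise InvalidInputError("need at least two groups")
    for g, v in groups.items():
        if v.size < 2:
            raise InvalidInputError(
                f"group {g!r} has {v.size} unit(s); at least 2 are required")
    f, p, mse, df_w = _anova(groups)
    means = {g: float(v.mean()) for g, v in groups.items()}
    ns = {g: int(v.size) for g, v in groups.items()}
    # pooled SEM on the mean of n units; harmonic mean guards mild imbalance
    n_eff = len(ns) / sum(1.0 / n for n in ns.values())
    sem = float(np.sqrt(mse / n_eff))
    pairwise = _pairwise_p(means, ns, mse, df_w, len(groups), method)
    significant = {pair: pv <= alpha for pair, pv in pairwise.items()}
    letters = compact_letters(means, significant)
    return GroupComparison(means=means, pooled_sem=sem, f_statistic=f,
                           p_value=p, letters=letters, n_per_group=ns)


def group_summary_table(
    units: pd.DataFrame,
    value_columns: Sequence[str],
    group_column: str = "treatment",
    alpha: float = 0.05,
    method: Literal["tukey", "lsd"] = "tukey",
    group_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Publication-shaped summary: one row per parameter.

    Columns are the per-treatment means annotated with letters (e.g.
    ``"42.0 a"``), the pooled SEM, and the ANOVA p-value.
    """
    if group_order is None:
        group_order = list(dict.fromkeys(units[group_column]))
    rows = []
    for col in value_columns:
        data = {g: units.loc[units[group_column] == g, col].to_numpy()
                for g in group_order}
        cmp_res = compare_groups(data, alpha=alpha, method=method)
        row: dict[str, object] = {"parameter": col}
        show_letters = cmp_res.p_value <= alpha
        for g in group_order:
            mean = cmp_res.means[g]
            letter = f" {cmp_res.letters[g]}" if show_letters else ""
            row[g] = f"{mean:.4g}{letter}"
            row[f"{g}_mean"] = mean
        row["SEM"] = cmp_res.pooled_sem
        row["p_value"] = cmp_res.p_value
        rows.append(row)
    return pd.DataFrame(rows)


def star_annotation(rho: float, p: float, min_abs_rho: float = 0.1) -> str:
    """Publication star convention for a correlation cell."""
    if np.isnan(rho) or np.isnan(p) or abs(rho) <= min_abs_rho or p > 0.05:
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    return "*"


def spearman_matrix(
    x: pd.DataFrame,
    y: pd.DataFrame,
    min_pairs: int = 4,
) -> dict[str, pd.DataFrame]:
    """Spearman rho / p / stars for every (x column, y column) pair.

    Rows of *x* and *y* are matched on index; constant columns yield NA
    cells.  Returns ``{"rho": ..., "p": ..., "stars": ...}`` DataFrames
    indexed by x columns with y columns as columns.
    """
    common = x.index.intersection(y.index)
    if common.size < min_pairs:
        raise InvalidInputError(
            f"only {common.size} matched samples; need >= {min_pairs}")
    xs, ys = x.loc[common], y.loc[common]
    rho = pd.DataFrame(index=x.columns, columns=y.columns, dtype=float)
    pval = rho.copy()
    stars = pd.DataFrame("", index=x.columns, columns=y.columns)
    for cx in x.columns:
        vx = xs[cx].to_numpy(dtype=float)
        for cy in y.columns:
            vy = ys[cy].to_numpy(dtype=float)
            if np.unique(vx).size < 2 or np.unique(vy).size < 2:
                rho.loc[cx, cy] = np.nan
                pval.loc[cx, cy] = np.nan
                continue
            r, p = sps.spearmanr(vx, vy)
            rho.loc[cx, cy] = r
            pval.loc[cx, cy] = p
            stars.loc[cx, cy] = star_annotation(r, p)
    return {"rho": rho, "p": pval, "stars": stars}
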