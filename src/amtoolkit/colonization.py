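"""Colonization quantification and group-comparison statistics.

Each biological replicate is scored for fungal structures (pigment,
intracellular hyphae, arbuscules, vesicles, spores) as presence/absence at
n equally spaced transverse positions (default 10); the per-replicate
colonization ratio is x/n.  Genotypes are compared per structure either
with a Kruskal-Wallis omnibus test followed by pairwise Wilcoxon rank-sum
tests, or with one-way ANOVA followed by Tukey's HSD, and the pairwise
decisions are summarised as a compact letter display: groups sharing no
letter differ at the chosen alpha, and a group labelled "ab" differs from
neither "a" nor "b".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

STRUCTURES = ("pigment", "intracellular_hyphae", "arbuscules", "vesicles", "spores")


class InsufficientReplicationError(ValueError):
    """Group comparisons need at least two groups with two values each."""


class ObservationGridError(ValueError):
    """Incomplete replicate x structure x position observation grid."""


def colonization_ratio(observations: pd.DataFrame,
                       n_positions: int | None = None) -> pd.DataFrame:
    """Per-replicate, per-structure x/n colonization ratios.

    ``observations`` is long-format with columns replicate, genotype,
    structure, position, observed (0/1).  Every (replicate, structure) must
    cover positions 1..n exactly once.
    """
    required = {"replicate", "genotype", "structure", "position", "observed"}
    missing = required - set(observations.columns)
    if missing:
        raise ObservationGridError(f"observation table missing columns {sorted(missing)}")
    if n_positions is None:
        n_positions = int(observations["position"].max())
    expected = set(range(1, n_positions + 1))
    rows = []
    for (rep, geno, struct), grp in observations.groupby(
            ["replicate", "genotype", "structure"], sort=True):
        pos = list(grp["position"])
        if sorted(pos) != sorted(expected) or len(pos) != len(expected):
            raise ObservationGridError(
                f"replicate {rep!r} structure {struct!r}: positions incomplete "
                f"or duplicated (expected 1..{n_positions})"
            )
        vals = grp["observed"].to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ObservationGridError(
                f"replicate {rep!r} structure {struct!r}: observed must be 0/1"
            )
        rows.append(
            {"replicate": rep, "genotype": geno, "structure": struct,
             "ratio": float(vals.sum() / n_positions)}
        )
    return pd.DataFrame(rows)


def _check_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise InsufficientReplicationError("need at least 2 groups")
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size < 2:
            raise InsufficientReplicationError(
                f"group {name!r} has {arr.size} value(s); need >= 2 replicates"
            )
        out[name] = arr
    return out


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p (df = groups - 1).

    All values identical across groups is a degenerate case reported as
    H = 0, p = 1.
    """
    g = _check_groups(groups)
    pooled = np.concatenate(list(g.values()))
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*g.values())
    return float(h), float(p)


def pairwise_wilcoxon(groups: Mapping[str, Sequence[float]]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-sided rank-sum p for every group pair.

    The exact null distribution is used when both samples have n <= 8 and
    the pooled values are tie-free; otherwise the normal approximation with
    midranks, tie correction and continuity correction.  Returns the
    symmetric p matrix (unit diagonal) and a matching matrix of method tags.
    """
    g = _check_groups(groups)
    names = list(g)
    p = pd.DataFrame(1.0, index=names, columns=names)
    meth = pd.DataFrame("-", index=names, columns=names)
    for a, b in combinations(names, 2):
        x, y = g[a], g[b]
        pooled = np.concatenate([x, y])
        tie_free = len(np.unique(pooled)) == pooled.size
        if tie_free and len(x) <= 8 and len(y) <= 8:
            method = "exact"
        else:
            method = "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                                 use_continuity=True)
        p.loc[a, b] = p.loc[b, a] = float(res.pvalue)
        meth.loc[a, b] = meth.loc[b, a] = method
    return p, meth


def significance_letters(
    pairwise_p: pd.DataFrame,
    means: Mapping[str, float],
    alpha: float = 0.05,
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Guarantees: every pair with p >= alpha shares at least one letter; every
    pair with p < alpha shares none.  Letters are assigned scanning groups
    in order of decreasing group mean; redundant (absorbed) letter sets are
    removed.  Raises on an asymmetric p matrix.
    """
    names = list(pairwise_p.index)
    if list(pairwise_p.columns) != names:
        raise ValueError("pairwise p matrix must have matching rows/columns")
    arr = pairwise_p.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, equal_nan=True):
        raise ValueError("pairwise decision matrix is asymmetric")
    order = sorted(names, key=lambda n: (-float(means[n]), str(n)))
    cols: list[set] = [set(order)]
    for i, a in enumerate(order):
        for b in order[i + 1:]:
            if float(pairwise_p.loc[a, b]) >= alpha:
                continue
            for c in [c for c in cols if a in c and b in c]:
                cols.remove(c)
                for piece in (c - {a}, c - {b}):
                    if piece and not any(piece <= other for other in cols):
                        cols = [o for o in cols if not o < piece]
                        cols.append(piece)
    # deterministic letter order: by first member in the mean ordering
    pos = {n: i for i, n in enumerate(order)}
    cols.sort(key=lambda c: (min(pos[n] for n in c), -len(c), sorted(c)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {n: "" for n in names}
    for k, c in enumerate(cols):
        for n in c:
            letters[n] += alphabet[k % 26]
    return {n: "".join(sorted(letters[n])) for n in names}


@dataclass
class GroupComparisonResult:
    """Per-structure omnibus + post hoc summary."""

    structure: str
    method: str               # "kruskal-wilcoxon" | "anova-tukey"
    group_values: dict[str, list[float]]
    statistic: float
    p_value: float
    pairwise_p: pd.DataFrame
    letters: dict[str, str]
    alpha: float
    degenerate: bool = False


def anova_tukey(groups: Mapping[str, Sequence[float]],
                alpha: float = 0.05) -> GroupComparisonResult:
    """One-way ANOVA with Tukey HSD post hoc and letter classes.

    Tukey p-values come from the studentized-range distribution with pooled
    within-group variance.  When every value is identical the F statistic is
    undefined; this degenerate case is reported as no-difference with a
    diagnostic flag.
    """
    g = _check_groups(groups)
    names = list(g)
    pooled = np.concatenate(list(g.values()))
    means = {n: float(v.mean()) for n, v in g.items()}
    if np.all(pooled == pooled[0]):
        p = pd.DataFrame(1.0, index=names, columns=names)
        return GroupComparisonResult(
            structure="", method="anova-tukey",
            group_values={n: list(v) for n, v in g.items()},
            statistic=float("nan"), p_value=1.0, pairwise_p=p,
            letters={n: "a" for n in names}, alpha=alpha, degenerate=True,
        )
    f, p_omni = stats.f_oneway(*g.values())
    hsd = stats.tukey_hsd(*g.values())
    pmat = pd.DataFrame(hsd.pvalue, index=names, columns=names)
    np.fill_diagonal(pmat.values, 1.0)
    letters = significance_letters(pmat, means, alpha=alpha)
    return GroupComparisonResult(
        structure="", method="anova-tukey",
        group_values={n: list(v) for n, v in g.items()},
        statistic=float(f), p_value=float(p_omni), pairwise_p=pmat,
        letters=letters, alpha=alpha,
    )


def kruskal_posthoc(groups: Mapping[str, Sequence[float]],
                    alpha: float = 0.05) -> GroupComparisonResult:
    """Kruskal-Wallis omnibus + pairwise Wilcoxon + letter classes."""
    g = _check_groups(groups)
    means = {n: float(v.mean()) for n, v in g.items()}
    h, p_omni = kruskal_wallis(g)
    pmat, _ = pairwise_wilcoxon(g)
    letters = significance_letters(pmat, means, alpha=alpha)
    return GroupComparisonResult(
        structure="", method="kruskal-wilcoxon",
        group_values={n: list(v) for n, v in g.items()},
        statistic=h, p_value=p_omni, pairwise_p=pmat,
        letters=letters, alpha=alpha,
        degenerate=(np.all(np.concatenate(list(g.values()))
                           == np.concatenate(list(g.values()))[0])),
    )


def compare_structures(
    ratios: pd.DataFrame,
    value_col: str = "ratio",
    method: str = "kruskal",
    alpha: float = 0.05,
) -> list[GroupComparisonResult]:
    """Run the chosen group comparison for every structure in a ratio table."""
    if method not in {"kruskal", "anova"}:
        raise ValueError("method must be 'kruskal' or 'anova'")
    results = []
    for struct, sub in ratios.groupby("structure", sort=True):
        groups = {
            geno: grp[value_col].to_list()
            for geno, grp in sub.groupby("genotype", sort=True)
        }
        res = kruskal_posthoc(groups, alpha) if method == "kruskal" \
            else anova_tukey(groups, alpha)
        res.structure = str(struct)
        results.append(res)
    return results
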