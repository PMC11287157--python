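"""Differential expression and the cross-species induction overlay.

The DE caller is a deliberately minimal negative-binomial two-group Wald
test: median-of-ratios normalization, method-of-moments dispersion pooled
across genes (counts are modelled with a shared NB dispersion), a delta-
method standard error on the log2 ratio of normalized group means, and a
normal-tail p-value.  It is not numerically equivalent to full GLM engines;
precomputed DE tables are accepted wherever a table of calls is consumed.

Calls use strict thresholds (log2FC > |threshold| and BH-adjusted p < alpha),
matching the convention "log2 fold change > |1|, adjusted P < 0.05".
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

UP = "up"
DOWN = "down"
NS = "ns"

LN2 = np.log(2.0)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample normalization factors.

    factor_s = median over all-nonzero genes of count_gs / geometric-mean_g.
    Raises when no gene is nonzero in every sample (a pseudo-reference
    fallback would be needed for such sparse data).
    """
    mask = (counts > 0).all(axis=1)
    if not mask.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; consider a "
            "pseudo-reference fallback"
        )
    sub = counts.loc[mask].to_numpy(dtype=float)
    gm = np.exp(np.log(sub).mean(axis=1, keepdims=True))  # geometric mean
    sf = np.median(sub / gm, axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _pooled_dispersion(norm: np.ndarray, ia: np.ndarray, ib: np.ndarray,
                       floor_mean: float = 5.0) -> float:
    """Method-of-moments NB dispersion pooled across genes.

    Per gene: alpha = (pooled within-group variance - mean) / mean^2; genes
    with mean below ``floor_mean`` (the small-count floor) are excluded from
    pooling.  Negative estimates are clipped at zero before averaging.
    """
    na, nb = len(ia), len(ib)
    mu_a = norm[:, ia].mean(axis=1)
    mu_b = norm[:, ib].mean(axis=1)
    ss = ((norm[:, ia] - mu_a[:, None]) ** 2).sum(axis=1) + \
         ((norm[:, ib] - mu_b[:, None]) ** 2).sum(axis=1)
    w = ss / max(na + nb - 2, 1)
    m = (mu_a + mu_b) / 2.0
    ok = m >= floor_mean
    if not ok.any():
        return 0.01
    alpha = np.clip((w[ok] - m[ok]) / m[ok] ** 2, 0.0, None)
    return float(alpha.mean())


def de_test(
    counts: pd.DataFrame,
    group_mock: Sequence[str],
    group_colonized: Sequence[str],
    dispersion: float | str = "pooled",
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """NB two-group Wald test; log2FC is colonized over mock.

    Genes with all-zero counts in both groups are reported with log2FC 0 and
    p 1 and flagged untestable.  ``dispersion`` is "pooled" (shared across
    genes, the default), "per-gene", or a fixed float.
    """
    group_mock = list(group_mock)
    group_colonized = list(group_colonized)
    if len(group_mock) < 2 or len(group_colonized) < 2:
        raise ValueError("each group needs at least 2 replicates")
    if factors is None:
        factors = size_factors(counts[group_mock + group_colonized])
    norm = counts[group_mock + group_colonized].to_numpy(dtype=float) / \
        factors[group_mock + group_colonized].to_numpy(dtype=float)
    na, nb = len(group_mock), len(group_colonized)
    ia = np.arange(na)
    ib = np.arange(na, na + nb)

    mu_a = norm[:, ia].mean(axis=1)
    mu_b = norm[:, ib].mean(axis=1)
    untestable = (mu_a == 0) & (mu_b == 0)

    if dispersion == "pooled":
        alpha = np.full(len(norm), _pooled_dispersion(norm, ia, ib))
    elif dispersion == "per-gene":
        w = (((norm[:, ia] - mu_a[:, None]) ** 2).sum(axis=1) +
             ((norm[:, ib] - mu_b[:, None]) ** 2).sum(axis=1)) / max(na + nb - 2, 1)
        m = np.maximum((mu_a + mu_b) / 2.0, 0.5)
        alpha = np.clip((w - m) / m ** 2, 0.0, None)
    else:
        alpha = np.full(len(norm), float(dispersion))

    # small-count floor on the means entering the ratio and its SE
    fa = np.maximum(mu_a, 0.5)
    fb = np.maximum(mu_b, 0.5)
    lfc = np.log2(fb / fa)
    var_a = (fa + alpha * fa**2) / na
    var_b = (fb + alpha * fb**2) / nb
    se = np.sqrt(var_a / fa**2 + var_b / fb**2) / LN2
    z = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    lfc = np.where(untestable, 0.0, lfc)
    p = np.where(untestable, 1.0, p)
    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "base_mean": (mu_a + mu_b) / 2.0,
            "log2_fold_change": lfc,
            "p_value": p,
            "untestable": untestable,
        }
    ).set_index("gene_id")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_de_table(de: pd.DataFrame) -> pd.DataFrame:
    """Add BH-adjusted p-values; untestable genes are excluded from m."""
    de = de.copy()
    testable = ~de.get("untestable", pd.Series(False, index=de.index))
    padj = np.full(len(de), np.nan)
    if testable.any():
        padj[testable.to_numpy()] = bh_adjust(de.loc[testable, "p_value"])
    de["p_adjusted"] = padj
    return de


def call_de(de: pd.DataFrame, lfc_threshold: float = 1.0,
            alpha: float = 0.05) -> pd.DataFrame:
    """Assign up/down/ns calls with strict inequalities at both thresholds."""
    if "p_adjusted" not in de.columns:
        raise ValueError("adjusted p-values missing; run adjust_de_table first")
    de = de.copy()
    lfc = de["log2_fold_change"].to_numpy(dtype=float)
    padj = de["p_adjusted"].to_numpy(dtype=float)
    sig = np.nan_to_num(padj, nan=1.0) < alpha
    call = np.where(sig & (lfc > lfc_threshold), UP,
                    np.where(sig & (lfc < -lfc_threshold), DOWN, NS))
    de["call"] = call
    de.attrs["lfc_threshold"] = lfc_threshold
    de.attrs["alpha"] = alpha
    return de


def venn_counts(sets: Mapping[str, Iterable]) -> dict[str, int]:
    """Exclusive region counts for exactly three sets.

    Keys join member names with '&'; the seven region counts sum to the size
    of the union.
    """
    names = list(sets)
    if len(names) != 3:
        raise ValueError("venn_counts expects exactly 3 sets")
    as_sets = {n: set(sets[n]) for n in names}
    out: dict[str, int] = {}
    for r in (1, 2, 3):
        for inc in combinations(names, r):
            region = set.intersection(*(as_sets[n] for n in inc))
            for other in names:
                if other not in inc:
                    region -= as_sets[other]
            out["&".join(inc)] = len(region)
    return out


@dataclass
class OverlaySummary:
    n_focal_up: int
    n_conserved_induced: int

    @property
    def fraction(self) -> float:
        return self.n_conserved_induced / self.n_focal_up if self.n_focal_up else float("nan")

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def cross_species_overlay(
    focal_calls: Mapping[str, str] | pd.DataFrame,
    reference_calls: Mapping[str, str] | pd.DataFrame,
    ortholog_map: pd.DataFrame,
    rule: str = "any",
) -> tuple[pd.DataFrame, OverlaySummary, list[str]]:
    """Overlay focal DE calls with reference DE calls through the ortholog map.

    ``ortholog_map`` columns: family_id, focal_gene, reference_genes
    (semicolon-joined).  A family is conserved_induced when its focal gene is
    up and - under the default any-up rule - at least one reference ortholog
    is up ("all" requires every mapped reference gene up).  Families whose
    focal gene carries a call but which are missing from the map are returned
    in the unmapped report and excluded from all denominators.
    """
    if rule not in {"any", "all"}:
        raise ValueError("rule must be 'any' or 'all'")

    def lookup(calls, gene):
        if isinstance(calls, pd.DataFrame):
            return calls["call"].get(gene, NS)
        return calls.get(gene, NS)

    def called_genes(calls):
        if isinstance(calls, pd.DataFrame):
            return set(calls.index)
        return set(calls)

    required = {"family_id", "focal_gene", "reference_genes"}
    if not required <= set(ortholog_map.columns):
        raise ValueError(f"ortholog map needs columns {sorted(required)}")

    mapped_focal = set(ortholog_map["focal_gene"])
    unmapped = sorted(called_genes(focal_calls) - mapped_focal)

    rows = []
    for _, r in ortholog_map.iterrows():
        focal_call = lookup(focal_calls, r["focal_gene"])
        refs = [g for g in str(r["reference_genes"]).split(";") if g]
        ref_calls = [lookup(reference_calls, g) for g in refs]
        if not ref_calls:
            ref_up = False
        elif rule == "any":
            ref_up = any(c == UP for c in ref_calls)
        else:
            ref_up = all(c == UP for c in ref_calls)
        rows.append(
            {
                "family_id": r["family_id"],
                "focal_call": focal_call,
                "reference_calls": ";".join(ref_calls),
                "conserved_induced": bool(focal_call == UP and ref_up),
            }
        )
    overlay = pd.DataFrame(rows).set_index("family_id")
    n_up = int((overlay["focal_call"] == UP).sum())
    n_ci = int(overlay["conserved_induced"].sum())
    return overlay, OverlaySummary(n_up, n_ci), unmapped


def core_set(patterns: Mapping[str, object], overlay: pd.DataFrame) -> list[str]:
    """Families both recursively coeliminated and induced in both species.

    ``patterns`` maps family_id to a
    :class:`~amtoolkit.coelimination.ConservationPattern` (or its label
    string); the core set intersects the "AM-only / lost-in-nonhost" class
    with conserved_induced overlay records, sorted by family id.
    """
    from .coelimination import CORE_PATTERN

    out = []
    for fam, pat in patterns.items():
        label = pat if isinstance(pat, str) else pat.label
        if label != CORE_PATTERN:
            continue
        if fam in overlay.index and bool(overlay.loc[fam, "conserved_induced"]):
            out.append(fam)
    return sorted(out)
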