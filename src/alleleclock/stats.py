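"""Category-level statistics over NC values and frequency spectra.

Implements the downstream analysis applied to panels of annotated coding
variants: site-frequency spectra by functional category, the excess-of-rare
deleterious-fraction estimate (with the synonymous spectrum as the neutral
expectation), per-MAC comparisons of the NC statistic between categories
(rank tests, normalized effect sizes, percentile-bootstrap confidence
intervals), sample-size-weighted meta-analysis over MAC classes, rank
correlation with continuous damage scores, and population-private fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "CategoryComparison",
    "sfs_by_category",
    "deleterious_fraction",
    "compare_nc",
    "bootstrap_ci",
    "meta_combine",
    "spearman_vs_score",
    "private_fraction",
]


@dataclass(frozen=True)
class CategoryComparison:
    mac: int
    category: str
    n: int
    mean_nc: float
    effect_size: float  # (mean - baseline mean) / baseline SD at same MAC
    ci_low: float
    ci_high: float
    p: float  # one-sided Mann-Whitney vs the baseline category


def sfs_by_category(
    variants: pd.DataFrame, mac_range: tuple[int, int] = (2, 6)
) -> pd.DataFrame:
    """Counts of variants per (MAC, category) over a MAC range.

    Returns a table indexed by MAC with one column per category present in
    the input (zero-filled) plus a ``total`` row of per-category totals over
    the range.
    """
    lo, hi = mac_range
    cats = sorted(variants["category"].unique()) if len(variants) else []
    macs = list(range(lo, hi + 1))
    table = pd.DataFrame(0, index=pd.Index(macs, name="mac"), columns=cats, dtype=int)
    sub = variants[(variants["mac"] >= lo) & (variants["mac"] <= hi)]
    for (mac, cat), grp in sub.groupby(["mac", "category"]):
        table.loc[mac, cat] = len(grp)
    if len(table.columns):
        table.loc["total"] = table.sum(axis=0)
    return table


def deleterious_fraction(
    n_cat_at_mac: int, total_cat: int, n_syn_at_mac: int, total_syn: int
) -> float:
    """Excess fraction of a category at a MAC relative to the neutral expectation.

    Treating the synonymous spectrum as neutral, the expected count of
    category variants at this MAC is ``total_cat * n_syn_at_mac / total_syn``;
    the deleterious fraction is the observed excess divided by the observed
    count::

        (n_cat_at_mac - total_cat * n_syn_at_mac / total_syn) / n_cat_at_mac

    The value can be negative (a deficit) and is returned as-is.
    """
    if total_syn <= 0 or n_cat_at_mac <= 0:
        raise ZeroDivisionError("counts must be positive")
    if n_cat_at_mac > total_cat or n_syn_at_mac > total_syn:
        raise ValueError("per-MAC counts cannot exceed totals")
    expected = total_cat * n_syn_at_mac / total_syn
    return (n_cat_at_mac - expected) / n_cat_at_mac


def _mannwhitney_one_sided(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided Mann-Whitney p-value for x stochastically greater than y.

    Exact null distribution for small samples without ties; the
    tie-corrected normal approximation otherwise (NC values tie frequently
    because distances are integers).
    """
    pooled = np.concatenate([x, y])
    small = len(x) < 20 and len(y) < 20
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if small and not has_ties else "asymptotic"
    return float(
        sps.mannwhitneyu(x, y, alternative="greater", method=method).pvalue
    )


def bootstrap_ci(
    values_cat: np.ndarray,
    values_baseline: np.ndarray,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    ci: float = 0.95,
) -> tuple[float, float]:
    """Percentile-bootstrap CI for the normalized mean difference.

    Resamples variants with replacement within each group and recomputes
    ``(mean_cat - mean_base) / sd_base`` on every replicate; returns the
    percentile interval of that bootstrap distribution.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(values_cat, dtype=float)
    y = np.asarray(values_baseline, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    xb = x[rng.integers(0, x.size, (n_boot, x.size))]
    yb = y[rng.integers(0, y.size, (n_boot, y.size))]
    sd = yb.std(axis=1, ddof=1) if y.size > 1 else np.zeros(n_boot)
    diff = xb.mean(axis=1) - yb.mean(axis=1)
    effs = np.where(sd > 0, diff / np.where(sd > 0, sd, 1.0), 0.0)
    alpha = (1.0 - ci) / 2.0
    return (
        float(np.quantile(effs, alpha)),
        float(np.quantile(effs, 1.0 - alpha)),
    )


def compare_nc(
    nc_table: pd.DataFrame,
    baseline_category: str = "synonymous",
    mac_values: tuple[int, ...] = (2, 3, 4, 5, 6),
    n_boot: int = 1000,
    seed: int | None = None,
    min_n: int = 2,
) -> pd.DataFrame:
    """Per-MAC comparison of NC distributions against a baseline category.

    ``nc_table`` needs columns mac, category, nc (censored rows, with NaN nc,
    are dropped and counted).  For every MAC value and every category with at
    least ``min_n`` uncensored variants, reports the variant count, mean NC,
    effect size in baseline-SD units, a 95% percentile-bootstrap CI and the
    one-sided rank-test p-value (alternative: category NC greater than
    baseline, i.e. younger alleles).  A final block with ``mac = "2-6"``
    (more generally the joined range) carries the sample-size-weighted
    meta-analytic p-value per category.
    """
    rng = np.random.default_rng(seed)
    t = nc_table.dropna(subset=["nc"])
    n_censored = len(nc_table) - len(t)
    if n_censored:
        logger.info("compare_nc: dropped %d censored variants", n_censored)
    rows = []
    per_cat_p: dict[str, list[tuple[float, int]]] = {}
    for mac in mac_values:
        at_mac = t[t["mac"] == mac]
        base = at_mac[at_mac["category"] == baseline_category]["nc"].to_numpy()
        if base.size < min_n:
            logger.warning("compare_nc: baseline has %d < %d at MAC %d", base.size, min_n, mac)
            continue
        sd_base = base.std(ddof=1)
        rows.append(
            {
                "mac": mac,
                "category": baseline_category,
                "n": base.size,
                "mean_nc": base.mean(),
                "effect_size": 0.0,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "p": np.nan,
                "baseline": True,
            }
        )
        for cat in sorted(at_mac["category"].unique()):
            if cat == baseline_category:
                continue
            vals = at_mac[at_mac["category"] == cat]["nc"].to_numpy()
            if vals.size < min_n:
                logger.warning(
                    "compare_nc: category %s has %d < %d at MAC %d, omitted",
                    cat, vals.size, min_n, mac,
                )
                continue
            eff = (vals.mean() - base.mean()) / sd_base
            lo, hi = bootstrap_ci(vals, base, n_boot=n_boot, seed=rng)
            p = _mannwhitney_one_sided(vals, base)
            per_cat_p.setdefault(cat, []).append((p, vals.size))
            rows.append(
                {
                    "mac": mac,
                    "category": cat,
                    "n": vals.size,
                    "mean_nc": vals.mean(),
                    "effect_size": eff,
                    "ci_low": lo,
                    "ci_high": hi,
                    "p": p,
                    "baseline": False,
                }
            )
    mac_label = f"{min(mac_values)}-{max(mac_values)}"
    for cat, pn in sorted(per_cat_p.items()):
        ps = np.array([p for p, _ in pn])
        ns = np.array([n for _, n in pn])
        rows.append(
            {
                "mac": mac_label,
                "category": cat,
                "n": int(ns.sum()),
                "mean_nc": np.nan,
                "effect_size": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "p": meta_combine(ps, ns),
                "baseline": False,
            }
        )
    return pd.DataFrame(rows)


def meta_combine(p_values, sample_sizes) -> float:
    """Stouffer's weighted-Z combination of one-sided p-values.

    Weights are the square roots of the sample sizes:
    ``Z = sum(sqrt(n_i) z_i) / sqrt(sum(n_i))`` with ``z_i`` the one-sided
    normal quantile of ``p_i``.  Degenerate p-values are clipped to
    ``[1e-300, 1 - 1e-16]`` with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    n = np.asarray(sample_sizes, dtype=float)
    if p.shape != n.shape or p.size == 0:
        raise ValueError("p_values and sample_sizes must be equal-length, non-empty")
    if np.any(n <= 0):
        raise ValueError("sample sizes must be positive")
    if np.any((p <= 0) | (p >= 1)):
        logger.warning("meta_combine: clipping degenerate p-values")
        p = np.clip(p, 1e-300, 1.0 - 1e-16)
    z = sps.norm.isf(p)
    w = np.sqrt(n)
    Z = float(np.sum(w * z) / np.sqrt(np.sum(w**2)))
    return float(sps.norm.sf(Z))


def spearman_vs_score(nc_values, damage_scores) -> tuple[float, float]:
    """Spearman rank correlation with a one-sided p for rho > 0."""
    x = np.asarray(nc_values, dtype=float)
    y = np.asarray(damage_scores, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("zero variance: Spearman correlation undefined")
    res = sps.spearmanr(x, y, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def private_fraction(
    variants: pd.DataFrame,
    population_column: str = "populations",
    frequency_column: str = "mac",
) -> pd.DataFrame:
    """Proportion of population-private variants per category and frequency class.

    Each variant carries the set (or iterable) of populations in which its
    allele is observed; a variant is private when that set has exactly one
    element.  An empty presence set is an error.
    """
    sizes = variants[population_column].map(len)
    if (sizes == 0).any():
        raise ValueError("variant with empty population presence set")
    t = variants.assign(_private=sizes == 1)
    out = (
        t.groupby(["category", frequency_column])["_private"]
        .agg(n="size", private_fraction="mean")
        .reset_index()
    )
    return out
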