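"""Per-site differential editing between two conditions.

Each site is tested with a binomial logistic regression of edited counts on
the group label: under the null all replicates share one editing proportion,
under the alternative each group has its own (logit p = b0 + b1 * group).
With a single binary covariate the likelihood is maximised by the pooled
group proportions, so the likelihood-ratio statistic has a closed form; its
null distribution is chi-square with one degree of freedom (no
overdispersion term).  Significant sites are classified up/down at a BH-FDR
cutoff combined with a minimum absolute difference of pooled group levels
(the "10p"/"20p" thresholds: 10% or 20% difference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests


@dataclass
class SiteGroupCounts:
    """Edited (k) and total (n) counts per replicate for the two groups at
    one site."""

    site: tuple
    group_a: str
    group_b: str
    k_a: list[int] = field(default_factory=list)
    n_a: list[int] = field(default_factory=list)
    k_b: list[int] = field(default_factory=list)
    n_b: list[int] = field(default_factory=list)

    def validate(self, min_coverage: int = 0) -> None:
        for k, n in zip(self.k_a + self.k_b, self.n_a + self.n_b):
            if not 0 <= k <= n:
                raise ValueError(f"invalid counts k={k}, n={n}")
            if n < min_coverage:
                raise ValueError(f"replicate coverage {n} below floor {min_coverage}")
        if not self.n_a or not self.n_b:
            raise ValueError("each group needs at least one replicate")


def _binom_ll(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    # log-likelihood up to the constant binomial coefficient (cancels in LRT)
    return xlogy(k, p) + xlogy(n - k, 1.0 - p)


def lrt_binomial_glm(counts: SiteGroupCounts) -> tuple[float, float]:
    """Likelihood-ratio test of equal editing proportion between two groups.

    Replicates within a group share the group proportion.  Returns
    (statistic, p); boundary configurations (all-zero or all-edited in both
    groups) give statistic 0 and p = 1.
    """
    counts.validate()
    k1, n1 = sum(counts.k_a), sum(counts.n_a)
    k2, n2 = sum(counts.k_b), sum(counts.n_b)
    d, p = lrt_binomial_many(
        np.array([k1]), np.array([n1]), np.array([k2]), np.array([n2])
    )
    return float(d[0]), float(p[0])


def lrt_binomial_many(
    k1: np.ndarray, n1: np.ndarray, k2: np.ndarray, n2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised closed-form LRT on per-group summed counts.

    The group sums are sufficient statistics because replicates share the
    group proportion; D = 2(l1 - l0) with MLEs k/n per group and pooled
    under the null, compared to chi-square(1).
    """
    k1 = np.asarray(k1, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise ValueError("both groups need positive total coverage")
    p1 = k1 / n1
    p2 = k2 / n2
    p0 = (k1 + k2) / (n1 + n2)
    ll1 = _binom_ll(k1, n1, p1) + _binom_ll(k2, n2, p2)
    ll0 = _binom_ll(k1, n1, p0) + _binom_ll(k2, n2, p0)
    d = np.maximum(2.0 * (ll1 - ll0), 0.0)
    return d, chi2.sf(d, df=1)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def test_differential(
    counts: list[SiteGroupCounts] | pd.DataFrame,
    fdr: float = 0.05,
    diffs: tuple[float, ...] = (0.10, 0.20),
    min_coverage: int = 10,
    delta_mode: str = "pooled",
) -> pd.DataFrame:
    """Run the per-site LRT over many sites and classify up/down/ns.

    A site is testable only if every replicate meets ``min_coverage`` in
    both groups.  Delta is the difference of pooled group levels
    (``delta_mode='pooled'``) or of replicate-mean levels
    (``delta_mode='mean'``); classification requires both q < fdr and
    |delta| >= the difference threshold, separately per threshold.
    """
    if delta_mode not in ("pooled", "mean"):
        raise ValueError("delta_mode must be 'pooled' or 'mean'")
    if isinstance(counts, pd.DataFrame):
        counts = dataframe_to_counts(counts)
    keep: list[SiteGroupCounts] = []
    for c in counts:
        c.validate()
        if min(c.n_a + c.n_b) < min_coverage:
            continue
        keep.append(c)
    if not keep:
        return pd.DataFrame(
            columns=["site", "level_a", "level_b", "delta", "statistic", "p", "q"]
            + [f"class_{int(d * 100)}p" for d in diffs]
        )
    k1 = np.array([sum(c.k_a) for c in keep], dtype=float)
    n1 = np.array([sum(c.n_a) for c in keep], dtype=float)
    k2 = np.array([sum(c.k_b) for c in keep], dtype=float)
    n2 = np.array([sum(c.n_b) for c in keep], dtype=float)
    d, p = lrt_binomial_many(k1, n1, k2, n2)
    q = bh_fdr(p)
    if delta_mode == "pooled":
        la, lb = k1 / n1, k2 / n2
    else:
        la = np.array([np.mean(np.array(c.k_a) / np.array(c.n_a)) for c in keep])
        lb = np.array([np.mean(np.array(c.k_b) / np.array(c.n_b)) for c in keep])
    delta = lb - la
    out = pd.DataFrame(
        {
            "site": [c.site for c in keep],
            "level_a": la,
            "level_b": lb,
            "delta": delta,
            "statistic": d,
            "p": p,
            "q": q,
        }
    )
    for diff in diffs:
        cls = np.where(
            (q < fdr) & (delta >= diff),
            "up",
            np.where((q < fdr) & (delta <= -diff), "down", "ns"),
        )
        out[f"class_{int(round(diff * 100))}p"] = cls
    return out


def classify_sites(
    results: pd.DataFrame, fdr: float = 0.05, diffs: tuple[float, ...] = (0.10, 0.20)
) -> dict[str, dict[str, int]]:
    """Up/down/ns counts per difference threshold from a results table."""
    summary: dict[str, dict[str, int]] = {}
    for diff in diffs:
        up = int(((results["q"] < fdr) & (results["delta"] >= diff)).sum())
        down = int(((results["q"] < fdr) & (results["delta"] <= -diff)).sum())
        summary[f"{int(round(diff * 100))}p"] = {
            "up": up,
            "down": down,
            "ns": int(len(results) - up - down),
        }
    return summary


def counts_from_site_tables(
    tables: dict[tuple[str, int], pd.DataFrame],
    group_a: str,
    group_b: str,
) -> list[SiteGroupCounts]:
    """Assemble per-site group counts from per-(condition, replicate)
    EditSite tables; only sites present in every replicate of both groups
    are testable."""
    by_cond: dict[str, list[pd.DataFrame]] = {}
    for (cond, _rep), df in sorted(tables.items()):
        by_cond.setdefault(cond, []).append(df)
    if group_a not in by_cond or group_b not in by_cond:
        raise ValueError("both groups need at least one replicate table")

    def index(df):
        return {
            (r["chrom"], int(r["pos"]), r["strand"]): (int(r["n_edited"]), int(r["n_edited"]) + int(r["n_ref"]))
            for _, r in df.iterrows()
        }

    idx_a = [index(df) for df in by_cond[group_a]]
    idx_b = [index(df) for df in by_cond[group_b]]
    keys = set(idx_a[0])
    for m in idx_a[1:] + idx_b:
        keys &= set(m)
    out = []
    for key in sorted(keys):
        c = SiteGroupCounts(site=key, group_a=group_a, group_b=group_b)
        for m in idx_a:
            k, n = m[key]
            c.k_a.append(k)
            c.n_a.append(n)
        for m in idx_b:
            k, n = m[key]
            c.k_b.append(k)
            c.n_b.append(n)
        out.append(c)
    return out


def dataframe_to_counts(df: pd.DataFrame) -> list[SiteGroupCounts]:
    """Long-format (site, group, replicate, k, n) table to SiteGroupCounts."""
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError("expected exactly two groups")
    ga, gb = groups
    out = []
    for site, sub in df.groupby("site"):
        c = SiteGroupCounts(site=site, group_a=ga, group_b=gb)
        for _, r in sub.iterrows():
            if r["group"] == ga:
                c.k_a.append(int(r["k"]))
                c.n_a.append(int(r["n"]))
            else:
                c.k_b.append(int(r["k"]))
                c.n_b.append(int(r["n"]))
        out.append(c)
    return out
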