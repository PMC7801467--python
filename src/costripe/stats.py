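"""Nonparametric group comparisons for bin datasets.

Two families of comparisons drive the Results-level claims this pipeline
supports: Mann-Whitney U tests between two stripe groups' laminar bin
datasets, and Kruskal-Wallis tests (omnibus plus Bonferroni-corrected
pairwise contrasts) across the three V2 stripe types or the three L4
sublayers.  With three comparisons at a family-wise alpha of 0.05 the
Bonferroni-corrected per-comparison alpha is 0.05/3, reported to three
decimals as 0.017; significance checks use the unrounded value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .compartment import RadialProfile


@dataclass
class TestConfig:
    """Family-wise error control for a set of pairwise comparisons."""

    __test__ = False  # not a pytest class

    family_alpha: float = 0.05
    n_comparisons: int = 1
    two_sided: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.family_alpha < 1):
            raise ValueError("family_alpha must be in (0, 1)")
        if self.n_comparisons < 1:
            raise ValueError("n_comparisons must be positive")

    @property
    def corrected_alpha(self) -> float:
        return self.family_alpha / self.n_comparisons

    @property
    def corrected_alpha_display(self) -> float:
        """Corrected alpha rounded to 3 decimals, for reporting only."""
        return round(self.corrected_alpha, 3)


@dataclass
class TestResult:
    __test__ = False  # not a pytest class

    method: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    corrected_alpha: float | None = None
    significant: bool | None = None
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.corrected_alpha is not None and self.significant is None:
            self.significant = bool(self.p_value < self.corrected_alpha)


@dataclass
class BinLocationDataset:
    """Normalized B_ctr->I_ctr distances of high-intensity profile bins."""

    locations: np.ndarray
    case_id: str = ""
    layer_id: str | None = None
    stripe_type: str = ""

    def __len__(self) -> int:
        return len(self.locations)


_EXACT_MAX_N = 16


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], two_sided: bool = True
) -> TestResult:
    """Mann-Whitney U test for two independent samples.

    The U statistic uses midranks for ties.  The p-value is exact (full
    enumeration of the null permutation distribution) when the samples are
    tie-free and n1 + n2 <= 16; otherwise the normal approximation with tie
    and continuity corrections is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    alternative = "two-sided" if two_sided else "greater"
    tie_free = np.unique(np.concatenate([a, b])).size == a.size + b.size
    if tie_free and a.size + b.size <= _EXACT_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative=alternative, method=method, use_continuity=True
    )
    return TestResult(
        method=f"mann-whitney-{method}",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        group_sizes=(a.size, b.size),
    )


@dataclass
class KruskalWallisResults:
    """Omnibus Kruskal-Wallis plus Bonferroni-corrected pairwise contrasts."""

    omnibus: TestResult
    pairwise: list[TestResult] = field(default_factory=list)
    corrected_alpha: float = float("nan")
    corrected_alpha_display: float = float("nan")


def kruskal_wallis_pairwise(
    groups: dict[str, Sequence[float]], cfg: TestConfig | None = None
) -> KruskalWallisResults:
    """Kruskal-Wallis omnibus test with pairwise post-hoc contrasts.

    The omnibus H statistic carries the standard tie correction.  Each pair
    of groups is then compared with a two-group Kruskal-Wallis test
    (equivalent to a Wilcoxon rank-sum test) against a Bonferroni-corrected
    per-comparison alpha of ``family_alpha / n_pairs``.
    """
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(groups[k], dtype=float) for k in names}
    if any(v.size == 0 for v in arrays.values()):
        raise ValueError("all groups must be nonempty")
    pairs = list(combinations(names, 2))
    if cfg is None:
        cfg = TestConfig(n_comparisons=len(pairs))
    alpha = cfg.corrected_alpha

    if np.ptp(np.concatenate(list(arrays.values()))) == 0:
        # every observation identical: H = 0 by convention, p = 1
        omnibus = TestResult(
            method="kruskal-wallis",
            statistic=0.0,
            p_value=1.0,
            group_sizes=tuple(arrays[k].size for k in names),
            groups=tuple(names),
        )
    else:
        H, p = sps.kruskal(*(arrays[k] for k in names))
        omnibus = TestResult(
            method="kruskal-wallis",
            statistic=float(H),
            p_value=float(p),
            group_sizes=tuple(arrays[k].size for k in names),
            groups=tuple(names),
        )
    pairwise = []
    for x, y in pairs:
        ax, ay = arrays[x], arrays[y]
        if np.ptp(np.concatenate([ax, ay])) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.kruskal(ax, ay)
        pairwise.append(
            TestResult(
                method="kruskal-wallis-pairwise",
                statistic=float(stat),
                p_value=float(p),
                group_sizes=(ax.size, ay.size),
                corrected_alpha=alpha,
                groups=(x, y),
            )
        )
    return KruskalWallisResults(
        omnibus=omnibus,
        pairwise=pairwise,
        corrected_alpha=alpha,
        corrected_alpha_display=cfg.corrected_alpha_display,
    )


def dunn_pairwise(
    groups: dict[str, Sequence[float]], cfg: TestConfig | None = None
) -> list[TestResult]:
    """Dunn's post-hoc z-tests on the joint ranking (optional alternative).

    Uses the tie-corrected pooled rank variance; offered alongside the
    default pairwise rank-sum contrasts.
    """
    names = sorted(groups)
    arrays = {k: np.asarray(groups[k], dtype=float) for k in names}
    pooled = np.concatenate([arrays[k] for k in names])
    ranks = sps.rankdata(pooled)
    n = pooled.size
    mean_rank = {}
    start = 0
    for k in names:
        size = arrays[k].size
        mean_rank[k] = ranks[start : start + size].mean()
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12 * (n - 1))
    pairs = list(combinations(names, 2))
    if cfg is None:
        cfg = TestConfig(n_comparisons=len(pairs))
    out = []
    for x, y in pairs:
        nx, ny = arrays[x].size, arrays[y].size
        se = np.sqrt((n * (n + 1) / 12 - tie_term) * (1 / nx + 1 / ny))
        z = (mean_rank[x] - mean_rank[y]) / se
        p = 2 * sps.norm.sf(abs(z))
        out.append(
            TestResult(
                method="dunn",
                statistic=float(z),
                p_value=float(p),
                group_sizes=(nx, ny),
                corrected_alpha=cfg.corrected_alpha,
                groups=(x, y),
            )
        )
    return out


def select_high_bins(
    profile: RadialProfile, threshold: float = 0.70, **labels
) -> BinLocationDataset:
    """Locations (bin centers) of profile bins with value strictly > threshold.

    On a normalized profile the maximum bin (1.0) always qualifies.
    """
    vals = np.asarray(profile.bin_values, dtype=float)
    keep = np.isfinite(vals) & (vals > threshold)
    return BinLocationDataset(
        locations=np.asarray(profile.bin_centers)[keep].copy(), **labels
    )


def compare_compartment_location(
    datasets: dict[str, dict[str, np.ndarray]],
    cfg: TestConfig | None = None,
    include_pooled: bool = True,
) -> pd.DataFrame:
    """Layer-by-layer and pooled stripe-type comparisons of bin locations.

    ``datasets[stripe_type][layer]`` holds the normalized high-bin locations
    for that stripe group and layer.  Each layer (and, when requested, the
    pooled set across layers) is compared across stripe types with
    :func:`kruskal_wallis_pairwise`; a stripe group missing a layer flags
    that row instead of failing.
    """
    stripes = sorted(datasets)
    if len(stripes) < 2:
        raise ValueError("need at least 2 stripe groups")
    layers = sorted({ly for s in stripes for ly in datasets[s]})
    rows = []
    targets = [(ly, {s: datasets[s].get(ly) for s in stripes}) for ly in layers]
    if include_pooled:
        pooled = {
            s: np.concatenate([np.asarray(v) for v in datasets[s].values()])
            if datasets[s]
            else None
            for s in stripes
        }
        targets.append(("pooled", pooled))
    for label, groups in targets:
        present = {
            s: np.asarray(v)
            for s, v in groups.items()
            if v is not None and np.asarray(v).size > 0
        }
        pairs = list(combinations(stripes, 2))
        if len(present) >= 2:
            res = kruskal_wallis_pairwise(
                {k: v for k, v in present.items()}, cfg
            )
            by_pair = {tuple(r.groups): r for r in res.pairwise}
        else:
            by_pair = {}
        for pair in pairs:
            r = by_pair.get(tuple(sorted(pair)))
            if r is None:
                rows.append(
                    {
                        "layer": label,
                        "group_a": pair[0],
                        "group_b": pair[1],
                        "n_a": 0 if groups.get(pair[0]) is None else int(np.asarray(groups[pair[0]]).size),
                        "n_b": 0 if groups.get(pair[1]) is None else int(np.asarray(groups[pair[1]]).size),
                        "statistic": np.nan,
                        "p_value": np.nan,
                        "corrected_alpha": np.nan,
                        "significant": False,
                        "note": "missing data",
                    }
                )
            else:
                rows.append(
                    {
                        "layer": label,
                        "group_a": r.groups[0],
                        "group_b": r.groups[1],
                        "n_a": r.group_sizes[0],
                        "n_b": r.group_sizes[1],
                        "statistic": r.statistic,
                        "p_value": round(r.p_value, 3),
                        "corrected_alpha": r.corrected_alpha,
                        "significant": r.significant,
                        "note": "",
                    }
                )
    return pd.DataFrame(rows)
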