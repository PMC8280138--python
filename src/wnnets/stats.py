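"""Group-level statistics on per-sample degrees and weights.

Two complementary detectors are provided.  SSPs (statistically significant
proteins) are proteins whose per-sample *degrees* differ between a treated
group and its control at BH-adjusted p < 0.1 — a network-level signal driven
by a protein's neighbourhood.  SFCPs (significant fold-change proteins) are
proteins whose own normalized spectral counts shift by more than 2-fold
(|log2 fc| > 1) with BH-adjusted p < 0.1 — the conventional abundance-level
signal.  High-degree sets, absolute-difference summaries and exclusive set
intersections complete the comparison toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .design import ComparisonDesign, comparison_label

__all__ = [
    "bh_adjust",
    "detect_ssp",
    "detect_sfcp",
    "high_degree_sets",
    "HighDegreeSets",
    "difference_summary",
    "DifferenceSummary",
    "set_intersections",
    "IntersectionSummary",
    "ssp_subnetwork",
]


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, clipped to 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _row_ttests(
    treated: np.ndarray, control: np.ndarray, equal_var: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample t-tests with a defined limit for degenerate rows.

    When both groups are constant the t statistic is 0/0: equal means get
    p = 1 (no evidence of difference), unequal means p = 0 (the difference is
    exact), matching the limiting behaviour as variances shrink.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind(treated, control, axis=1, equal_var=equal_var)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    degenerate = np.isnan(p)
    if degenerate.any():
        mt = treated.mean(axis=1)
        mc = control.mean(axis=1)
        equal = np.isclose(mt, mc, rtol=1e-12, atol=0.0)
        t[degenerate & equal] = 0.0
        p[degenerate & equal] = 1.0
        t[degenerate & ~equal] = np.sign((mt - mc)[degenerate & ~equal]) * np.inf
        p[degenerate & ~equal] = 0.0
    return t, p


def _comparison_frame(
    values: pd.DataFrame,
    design: ComparisonDesign,
    treated: str,
    control: str,
    equal_var: bool,
    min_samples: int,
) -> pd.DataFrame:
    for group in (treated, control):
        n = len(design.samples_of(group))
        if n < min_samples:
            raise ValueError(
                f"group {group!r} has {n} samples; at least {min_samples} required"
            )
    x_t = values[design.samples_of(treated)].to_numpy(dtype=float)
    x_c = values[design.samples_of(control)].to_numpy(dtype=float)
    t, p = _row_ttests(x_t, x_c, equal_var=equal_var)
    return pd.DataFrame(
        {
            "comparison": comparison_label(treated, control),
            "protein": values.index,
            "mean_treated": x_t.mean(axis=1),
            "mean_control": x_c.mean(axis=1),
            "t": t,
            "pvalue": p,
        }
    )


def detect_ssp(
    degrees: pd.DataFrame,
    design: ComparisonDesign,
    alpha: float = 0.1,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Detect statistically significant proteins from a degree matrix.

    For every comparison, each protein's treated-sample degrees are tested
    against its control-sample degrees (Welch t-test by default) and p-values
    are BH-adjusted within that comparison's protein family.  A protein is an
    SSP when the adjusted p-value falls below ``alpha``.
    """
    frames = []
    for treated, control in design.comparisons:
        frame = _comparison_frame(degrees, design, treated, control, equal_var, 2)
        frame["p_adjusted"] = bh_adjust(frame["pvalue"].to_numpy())
        frame["is_ssp"] = frame["p_adjusted"] < alpha
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def detect_sfcp(
    weights: pd.DataFrame,
    design: ComparisonDesign,
    log2_threshold: float = 1.0,
    alpha: float = 0.1,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Detect significant fold-change proteins from the weight matrix.

    The fold change is the ratio of group-mean normalized counts,
    treated / control (defined because the shared-protein filter guarantees
    strictly positive weights).  A protein is an SFCP when
    ``|log2 fold change| > log2_threshold`` *and* the BH-adjusted t-test
    p-value on the per-sample weights is below ``alpha``.
    """
    if (weights.to_numpy() <= 0).any():
        raise ValueError("weight matrix must be strictly positive")
    frames = []
    for treated, control in design.comparisons:
        frame = _comparison_frame(weights, design, treated, control, equal_var, 1)
        frame["fold_change"] = frame["mean_treated"] / frame["mean_control"]
        frame["log2_fold_change"] = np.log2(frame["fold_change"])
        frame["p_adjusted"] = bh_adjust(frame["pvalue"].to_numpy())
        frame["is_sfcp"] = (
            frame["log2_fold_change"].abs() > log2_threshold
        ) & (frame["p_adjusted"] < alpha)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class HighDegreeSets:
    """Per-group high-degree protein sets and the quantile thresholds used."""

    sets: Mapping[str, frozenset]
    thresholds: Mapping[str, float]
    group_means: pd.DataFrame
    q: float


def high_degree_sets(
    degrees: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    q: float = 0.75,
) -> HighDegreeSets:
    """Proteins strictly above a group's degree quantile ("hubs").

    Each protein is summarised by its mean degree over the group's samples;
    the group threshold is the ``q``-quantile (linear interpolation) of those
    means, and the set contains proteins strictly above it.  With the default
    ``q = 0.75`` these are the ControlPs / TreatedPs of a four-group design.
    """
    if not 0 < q < 1:
        raise ValueError(f"quantile q must be in (0, 1), got {q}")
    means = {}
    sets = {}
    thresholds = {}
    for group, samples in groups.items():
        if len(samples) == 0:
            raise ValueError(f"group {group!r} is empty")
        m = degrees[list(samples)].mean(axis=1)
        thr = float(np.quantile(m.to_numpy(), q))
        means[group] = m
        thresholds[group] = thr
        sets[group] = frozenset(m.index[m > thr])
    return HighDegreeSets(
        sets=sets, thresholds=thresholds, group_means=pd.DataFrame(means), q=q
    )


@dataclass(frozen=True)
class DifferenceSummary:
    """Absolute treated-minus-control mean-degree differences per comparison.

    ``per_protein`` holds |mean treated − mean control| per protein (rows) and
    comparison (columns); ``global_mean`` averages each column; ``ratios``
    holds every ordered pair of comparisons' global means (the Difference
    Ratio between two comparisons)."""

    per_protein: pd.DataFrame
    global_mean: Mapping[str, float]
    ratios: Mapping[tuple[str, str], float]

    def ratio(self, numerator: str, denominator: str) -> float:
        return self.ratios[(numerator, denominator)]


def difference_summary(
    degrees: pd.DataFrame, design: ComparisonDesign
) -> DifferenceSummary:
    """Summarise how far each treated group's degrees moved from control."""
    cols = {}
    for treated, control in design.comparisons:
        mt = degrees[design.samples_of(treated)].mean(axis=1)
        mc = degrees[design.samples_of(control)].mean(axis=1)
        cols[comparison_label(treated, control)] = (mt - mc).abs()
    per_protein = pd.DataFrame(cols)
    global_mean = {label: float(col.mean()) for label, col in per_protein.items()}
    ratios = {
        (a, b): global_mean[a] / global_mean[b]
        for a, b in permutations(global_mean, 2)
        if global_mean[b] != 0
    }
    return DifferenceSummary(
        per_protein=per_protein, global_mean=global_mean, ratios=ratios
    )


@dataclass(frozen=True)
class IntersectionSummary:
    """Exclusive (upset-style) intersection counts over named protein sets.

    ``exclusive`` has one boolean column per set plus ``count`` and
    ``members``; each row is one non-empty membership pattern and counts the
    proteins belonging to exactly those sets, so the counts sum to the size of
    the union."""

    exclusive: pd.DataFrame
    set_sizes: Mapping[str, int]


def set_intersections(named_sets: Mapping[str, Iterable[Hashable]]) -> IntersectionSummary:
    """Exclusive membership counts for every non-empty combination of sets."""
    if not named_sets:
        raise ValueError("at least one set is required")
    sets = {name: set(s) for name, s in named_sets.items()}
    names = list(sets)
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo)) if combo else set()
            outside = set.union(*(sets[n] for n in names if n not in combo), set())
            exclusive = inside - outside
            rows.append(
                {
                    **{n: (n in combo) for n in names},
                    "count": len(exclusive),
                    "members": tuple(sorted(map(str, exclusive))),
                }
            )
    frame = pd.DataFrame(rows)
    return IntersectionSummary(
        exclusive=frame, set_sizes={n: len(s) for n, s in sets.items()}
    )


def ssp_subnetwork(
    master: nx.Graph,
    ssps: Iterable[Hashable],
    sfcps: Iterable[Hashable] = (),
) -> nx.Graph:
    """Induced subgraph on the SSPs and their first neighbours, with roles.

    Every node carries a ``role`` attribute: ``"ssp"``, ``"sfcp"``, ``"both"``
    (in both sets), or ``"contributor"`` — a neighbour in neither set whose
    weight nonetheless feeds the SSPs' degrees (a candidate upstream driver).
    """
    ssps = set(ssps)
    sfcps = set(sfcps)
    outside = ssps - set(master.nodes)
    if outside:
        raise ValueError(f"SSPs not in the master network: {sorted(map(str, outside))}")
    nodes = set(ssps)
    for v in ssps:
        nodes.update(master.neighbors(v))
    sub: nx.Graph = master.subgraph(nodes).copy()
    for n in sub.nodes:
        if n in ssps and n in sfcps:
            role = "both"
        elif n in ssps:
            role = "ssp"
        elif n in sfcps:
            role = "sfcp"
        else:
            role = "contributor"
        sub.nodes[n]["role"] = role
    return sub
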