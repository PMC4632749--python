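"""Correlation-network construction and cross-variety comparison.

The procedure, per variety:

1. *Ratio to control*: each 35 degC sample's metabolite abundance is divided
   by the mean control (25 degC) abundance of the same variety and metabolite,
   yielding unitless temperature-response profiles.
2. *Spearman correlation*: every metabolite pair is scored by the rank
   correlation of its ratio profiles, with a two-sided significance test —
   exact permutation enumeration for small n (<= 9 by default), the classic
   t approximation with n - 2 degrees of freedom otherwise.
3. *Filtering*: pairs with |rho| below the threshold (default 0.5) or p at or
   above alpha (default 0.05) are dropped; edges are by definition significant
   positive correlations, so negative survivors are dropped too unless the
   sign policy says otherwise.
4. *Comparison*: the two varieties' networks are intersected; edges present in
   both are "common", the rest are unique responses of each variety.

Constant ratio profiles (rank correlation undefined) are excluded from the
pair scan with a logged notice.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import AbundanceTable, sorted_pair

logger = logging.getLogger(__name__)

#: largest n for which the exact permutation null is enumerated (9! = 362880)
EXACT_PERMUTATION_MAX_N = 9


@dataclass(frozen=True)
class RatioMatrix:
    """Treatment samples x metabolites, each divided by its control mean."""

    variety: str
    ratios: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.ratios <= 0).any().any():
            raise ValueError("ratio matrix must be strictly positive")

    @property
    def metabolites(self) -> list[str]:
        return list(self.ratios.columns)


@dataclass(frozen=True)
class CorrelationNetwork:
    """Metabolite nodes (with class labels) and filtered correlation edges."""

    variety: str
    nodes: Mapping[str, str]                       # metabolite -> class
    edges: Mapping[tuple[str, str], tuple[float, float]]  # pair -> (rho, p)

    def __post_init__(self) -> None:
        for (a, b) in self.edges:
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            if (a, b) != sorted_pair(a, b):
                raise ValueError(f"edge {a, b} not stored in sorted order")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_pairs(self) -> set[tuple[str, str]]:
        return set(self.edges)


@dataclass(frozen=True)
class NetworkComparison:
    """Common vs variety-unique edge sets of two varieties' networks."""

    varieties: tuple[str, str]
    common: frozenset
    unique: Mapping[str, frozenset]
    percent_common: Mapping[str, float]

    def n_common(self) -> int:
        return len(self.common)


def ratio_to_control(
    table: AbundanceTable,
    variety: str,
    control_temp: str = "25",
    treatment_temp: str = "35",
    n_control: int | None = None,
) -> RatioMatrix:
    """Divide each treatment sample by the variety's mean control abundance.

    ``n_control`` restricts the control mean to the first n control replicates
    (the historical convention of a 4-vine chamber); default uses all.
    """
    control = table.subset(cultivar=variety, temperature=control_temp)
    treatment = table.subset(cultivar=variety, temperature=treatment_temp)
    if control.n_samples == 0:
        raise ValueError(f"{variety}: no control samples at {control_temp} degC")
    if treatment.n_samples == 0:
        raise ValueError(f"{variety}: no treatment samples at {treatment_temp} degC")
    control_data = control.data
    if n_control is not None:
        if not 1 <= n_control <= control.n_samples:
            raise ValueError(f"n_control={n_control} out of range")
        control_data = control_data.iloc[:n_control]
    ratios = treatment.data / control_data.mean(axis=0)
    return RatioMatrix(variety=variety, ratios=ratios.reset_index(drop=True))


def spearman_rho(x, y) -> float:
    """Spearman's rank correlation: Pearson correlation of average ranks."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


@lru_cache(maxsize=8)
def _permutation_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _exact_null_pvalue(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided p from full enumeration of rank permutations (tie-aware)."""
    n = len(rx)
    perms = _permutation_matrix(n)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float((rxc**2).sum() * (ryc**2).sum()))
    null = (ryc[perms] @ rxc) / denom
    return float(np.mean(np.abs(null) >= abs(rho_obs) - 1e-12))


def spearman_pvalue(
    x, y, method: str = "auto"
) -> tuple[float, float]:
    """(rho, two-sided p) with exact or t-approximate significance.

    ``method``: ``exact_permutation`` enumerates all n! rank permutations
    (n <= 9 enforced for tractability); ``t_approx`` uses
    t = rho sqrt((n-2)/(1-rho^2)) with n-2 df; ``auto`` picks exact for
    n <= 9. |rho| = 1 under the t approximation falls back to the exact
    tail 2/n!.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    rho = spearman_rho(x, y)
    if method == "auto":
        method = "exact_permutation" if n <= EXACT_PERMUTATION_MAX_N else "t_approx"
    if method == "exact_permutation":
        if n > EXACT_PERMUTATION_MAX_N:
            raise ValueError(f"exact enumeration limited to n <= {EXACT_PERMUTATION_MAX_N}")
        p = _exact_null_pvalue(stats.rankdata(x), stats.rankdata(y), rho)
    elif method == "t_approx":
        if abs(rho) >= 1.0 - 1e-12:
            # t statistic diverges; exact tail of a perfect monotone pairing
            p = 2.0 / math.factorial(n)
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    else:
        raise ValueError(f"unknown p-value method {method!r}")
    return rho, min(p, 1.0)


def correlation_matrix(
    ratio: RatioMatrix, method: str = "auto"
) -> pd.DataFrame:
    """All-pairs rho and p for one variety's ratio profiles.

    Returns a long DataFrame (source, target, rho, p) over sorted pairs;
    constant-profile metabolites are skipped with a logged notice.
    """
    usable = []
    for name in ratio.metabolites:
        if np.ptp(ratio.ratios[name].to_numpy()) == 0:
            logger.warning(
                "%s: constant ratio profile for %r; excluded from pair scan",
                ratio.variety, name,
            )
        else:
            usable.append(name)
    rows = []
    values = {name: ratio.ratios[name].to_numpy(float) for name in usable}
    for a, b in itertools.combinations(sorted(usable), 2):
        rho, p = spearman_pvalue(values[a], values[b], method=method)
        rows.append((a, b, rho, p))
    return pd.DataFrame(rows, columns=["source", "target", "rho", "p"])


def build_network(
    ratio: RatioMatrix,
    annotation: Mapping[str, str],
    threshold: float = 0.5,
    alpha: float = 0.05,
    sign_policy: str = "positive_only",
    method: str = "auto",
    fdr: bool = False,
) -> CorrelationNetwork:
    """Score all pairs, filter on |rho| >= threshold and p < alpha, assemble.

    Under the default ``positive_only`` policy negative-rho survivors are
    dropped (edges represent significant positive co-response); ``both``
    keeps them. Nodes are the metabolites incident to at least one retained
    edge. ``fdr`` applies Benjamini-Hochberg across all scanned pairs first.
    """
    if sign_policy not in ("positive_only", "both"):
        raise ValueError(f"unknown sign policy {sign_policy!r}")
    matrix = correlation_matrix(ratio, method=method)
    n_scanned = len(matrix)
    if fdr and n_scanned:
        from statsmodels.stats.multitest import multipletests

        matrix = matrix.assign(p=multipletests(matrix["p"], method="fdr_bh")[1])
    passing_rho = matrix[np.abs(matrix["rho"]) >= threshold]
    passing_p = passing_rho[passing_rho["p"] < alpha]
    if sign_policy == "positive_only":
        kept = passing_p[passing_p["rho"] > 0]
    else:
        kept = passing_p
    logger.info(
        "%s: %d pairs scanned, %d pass |rho|>=%g, %d pass p<%g, %d negative dropped",
        ratio.variety, n_scanned, len(passing_rho), threshold, len(passing_p),
        alpha, len(passing_p) - len(kept),
    )
    edges = {
        sorted_pair(r.source, r.target): (float(r.rho), float(r.p))
        for r in kept.itertuples()
    }
    nodes = sorted({name for pair in edges for name in pair})
    return CorrelationNetwork(
        variety=ratio.variety,
        nodes={name: annotation.get(name, "unknown") for name in nodes},
        edges=edges,
    )


def compare_networks(
    net_a: CorrelationNetwork, net_b: CorrelationNetwork
) -> NetworkComparison:
    """Intersect two varieties' edge sets: common vs variety-unique edges.

    An edge is common iff the same unordered metabolite pair appears in both
    networks (the rho values need not match). ``percent_common`` for each
    variety is 100 x |common| / |edges of that variety|.
    """
    edges_a = net_a.edge_pairs()
    edges_b = net_b.edge_pairs()
    common = frozenset(edges_a & edges_b)

    def pct(edges: set) -> float:
        return 100.0 * len(common) / len(edges) if edges else 0.0

    return NetworkComparison(
        varieties=(net_a.variety, net_b.variety),
        common=common,
        unique={
            net_a.variety: frozenset(edges_a - common),
            net_b.variety: frozenset(edges_b - common),
        },
        percent_common={net_a.variety: pct(edges_a), net_b.variety: pct(edges_b)},
    )


def unique_edge_network(
    net: CorrelationNetwork, comparison: NetworkComparison
) -> CorrelationNetwork:
    """The variety-unique subnetwork (common edges removed), re-derived nodes."""
    unique = comparison.unique[net.variety]
    edges = {pair: net.edges[pair] for pair in sorted(unique)}
    nodes = sorted({name for pair in edges for name in pair})
    return CorrelationNetwork(
        variety=net.variety,
        nodes={name: net.nodes[name] for name in nodes},
        edges=edges,
    )
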