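"""Co-occurrence network construction from rank-normalised abundances.

Pairwise association between taxa is the tie-aware Spearman coefficient:
the Pearson product-moment correlation of the (average-midrank) normalised
rank vectors,

    r_xy = sum_i (x_i - xbar)(y_i - ybar) / ((n - 1) s_x s_y),

with sample standard deviations.  An undirected edge joins two taxa when
|r| reaches the critical r-value at a chosen confidence level (default 99%);
the sign of r is kept as edge metadata ("positive"/"negative" interaction).
Zero-variance (all-tied) taxa have undefined correlations and are excluded
from pairing but reported.

Topology (density, diameter of the largest component) and centralities
(degree, shortest-path betweenness) summarise each network; the hub analysis
collects nodes whose degree is at least N% of the maximum degree (N varied
60-90%) together with their lineage/phenotype composition, and two networks
are compared through their shared, equally-signed edges (core interactions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .tables import PHENOTYPE_KEYS, RankMatrix, TaxonRecord, ValidationError

POSITIVE = "positive"
NEGATIVE = "negative"


def spearman_ties(x_ranks, y_ranks) -> float:
    """Tie-aware Spearman coefficient: Pearson correlation of rank vectors.

    Returns NaN (undefined-correlation signal) if either vector has zero
    variance.
    """
    x = np.asarray(x_ranks, dtype=float)
    y = np.asarray(y_ranks, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("rank vectors must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise ValidationError("need at least 3 samples")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt((dx * dx).sum() / (n - 1))
    sy = np.sqrt((dy * dy).sum() / (n - 1))
    if sx == 0 or sy == 0:
        return float("nan")
    r = (dx * dy).sum() / ((n - 1) * sx * sy)
    return float(np.clip(r, -1.0, 1.0))


@dataclass
class CorrelationMatrix:
    """Symmetric taxon x taxon rank-correlation matrix.

    Entries involving zero-variance taxa are NaN; ``undefined_taxa`` lists
    them.
    """

    taxa: list[str]
    r: np.ndarray
    n: int
    undefined_taxa: list[str]


def correlation_matrix(ranks: RankMatrix) -> CorrelationMatrix:
    """All-pairs tie-aware Spearman correlations of a rank matrix."""
    vals = ranks.values
    n = vals.shape[1]
    if n < 3:
        raise ValidationError("need at least 3 samples")
    sd = vals.std(axis=1)
    defined = sd > 0
    r = np.full((vals.shape[0], vals.shape[0]), np.nan)
    if defined.sum() >= 1:
        sub = np.atleast_2d(np.corrcoef(vals[defined]))
        ii = np.flatnonzero(defined)
        r[np.ix_(ii, ii)] = np.clip(sub, -1.0, 1.0)
    for i in np.flatnonzero(defined):
        r[i, i] = 1.0
    undefined = [t for t, d in zip(ranks.taxa, defined) if not d]
    return CorrelationMatrix(ranks.taxa, r, n, undefined)


def critical_r(
    n: int,
    confidence: float = 0.99,
    method: str = "t_approx",
    perm_reps: int = 10_000,
    seed: int = 0,
) -> float:
    """Minimum |r| significant at the given two-tailed confidence level.

    ``t_approx``: invert t = r sqrt((n-2)/(1-r^2)) at the critical t with
    n-2 degrees of freedom.  ``permutation``: the (1 - alpha) quantile of
    |r| over random rank permutations (|r| folds the two tails together).
    """
    if n < 4:
        raise ValidationError("critical_r needs n >= 4")
    if not (0 < confidence < 1):
        raise ValidationError("confidence must be in (0, 1)")
    alpha = 1.0 - confidence
    if method == "t_approx":
        tc = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
        return float(tc / np.sqrt(n - 2 + tc * tc))
    if method == "permutation":
        rng = np.random.default_rng(seed)
        base = np.arange(1, n + 1, dtype=float)
        x = (base - base.mean()) / base.std()
        rs = np.empty(perm_reps)
        for i in range(perm_reps):
            y = rng.permutation(base)
            rs[i] = abs(np.dot(x, (y - y.mean()) / y.std()) / n)
        return float(np.quantile(rs, 1.0 - alpha))
    raise ValidationError(f"unknown critical_r method {method!r}")


@dataclass
class CooccurrenceNetwork:
    """Per-class co-occurrence graph with signed correlation edges."""

    graph: nx.Graph
    klass: str
    critical_r: float
    confidence: float
    excluded_taxa: list[str] = field(default_factory=list)

    @property
    def edges(self) -> set:
        """Edges as (frozenset{a, b}, sign) pairs."""
        return {
            (frozenset((a, b)), d["sign"]) for a, b, d in self.graph.edges(data=True)
        }


def build_network(
    ranks: RankMatrix,
    annotations: dict[str, TaxonRecord] | None = None,
    confidence: float = 0.99,
    klass: str = "",
    method: str = "t_approx",
    perm_reps: int = 10_000,
    seed: int = 0,
) -> CooccurrenceNetwork:
    """All-pairs correlation, thresholded at the critical r-value.

    Pairs with r >= r_crit become positive edges, r <= -r_crit negative
    edges; intermediate values are insignificant and create no edge.  Every
    taxon with defined variance is a node (isolated nodes are dropped from
    summaries, matching plotted networks).
    """
    if len(ranks.samples) < 4:
        raise ValidationError("network construction needs >= 4 samples")
    corr = correlation_matrix(ranks)
    eligible = [t for t in corr.taxa if t not in set(corr.undefined_taxa)]
    if len(eligible) < 2:
        raise ValidationError("need >= 2 taxa with nonzero rank variance")
    r0 = critical_r(corr.n, confidence, method=method, perm_reps=perm_reps, seed=seed)
    g = nx.Graph()
    annotations = annotations or {}
    idx = {t: i for i, t in enumerate(corr.taxa)}
    for t in eligible:
        rec = annotations.get(t)
        attrs = {}
        if rec is not None:
            attrs.update(rec.lineage)
            attrs.update(rec.phenotypes)
        g.add_node(t, **attrs)
    for a_i, a in enumerate(eligible):
        for b in eligible[a_i + 1:]:
            r = corr.r[idx[a], idx[b]]
            if np.isnan(r):
                continue
            if r >= r0:
                g.add_edge(a, b, r=float(r), sign=POSITIVE)
            elif r <= -r0:
                g.add_edge(a, b, r=float(r), sign=NEGATIVE)
    return CooccurrenceNetwork(g, klass, r0, confidence, corr.undefined_taxa)


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    density: float
    diameter: int | None
    degree: dict[str, int]
    betweenness: dict[str, float]


def summarize_network(net: CooccurrenceNetwork) -> NetworkSummary:
    """Topology and centrality summary over nodes incident to >= 1 edge."""
    g = net.graph.edge_subgraph(net.graph.edges).copy() if net.graph.number_of_edges() \
        else nx.Graph()
    v = g.number_of_nodes()
    e = g.number_of_edges()
    density = 2.0 * e / (v * (v - 1)) if v >= 2 else 0.0
    diameter = None
    if v:
        comp = max(nx.connected_components(g), key=len)
        if len(comp) >= 2:
            diameter = int(nx.diameter(g.subgraph(comp)))
        else:
            diameter = 0
    degree = {n: int(d) for n, d in g.degree()}
    betweenness = nx.betweenness_centrality(g, normalized=True) if v else {}
    return NetworkSummary(v, e, density, diameter, degree, betweenness)


@dataclass
class HubReport:
    threshold_pct: float
    hubs: frozenset
    phylum_composition: dict[str, int]
    phenotype_composition: dict[str, dict[str, int]]


def hub_analysis(net: CooccurrenceNetwork, thresholds=(60, 70, 80, 90)) -> list[HubReport]:
    """Nodes whose degree is at least N% of the maximum degree, with lineage
    and phenotype composition, for each threshold N."""
    if net.graph.number_of_edges() == 0:
        raise ValidationError("hub analysis needs a network with >= 1 edge")
    g = net.graph.edge_subgraph(net.graph.edges)
    degrees = dict(g.degree())
    dmax = max(degrees.values())
    reports = []
    for pct in thresholds:
        if not (0 < pct <= 100):
            raise ValidationError("hub thresholds must be in (0, 100]")
        cut = pct / 100.0 * dmax
        hubs = frozenset(n for n, d in degrees.items() if d >= cut)
        phyla: dict[str, int] = {}
        phen: dict[str, dict[str, int]] = {k: {} for k in PHENOTYPE_KEYS}
        for h in hubs:
            attrs = g.nodes[h]
            ph = attrs.get("phylum", "Unclassified")
            phyla[ph] = phyla.get(ph, 0) + 1
            for key in PHENOTYPE_KEYS:
                if key in attrs:
                    phen[key][attrs[key]] = phen[key].get(attrs[key], 0) + 1
        reports.append(HubReport(float(pct), hubs, phyla, phen))
    return reports


def core_interactions(a: CooccurrenceNetwork, b: CooccurrenceNetwork) -> set:
    """Edges (taxon pair + sign) present in both networks."""
    return a.edges & b.edges


def edge_table(net: CooccurrenceNetwork) -> pd.DataFrame:
    """Edge list as a sorted DataFrame (taxon_a, taxon_b, r, sign)."""
    rows = [
        (min(u, v), max(u, v), d["r"], d["sign"])
        for u, v, d in net.graph.edges(data=True)
    ]
    return pd.DataFrame(
        sorted(rows), columns=["taxon_a", "taxon_b", "r", "sign"]
    )


def write_graphml(net: CooccurrenceNetwork, path) -> None:
    g = net.graph.copy()
    for _, _, d in g.edges(data=True):
        d["r"] = float(d["r"])
    for n, d in g.degree():
        g.nodes[n]["degree"] = int(d)
    nx.write_graphml(g, path)
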