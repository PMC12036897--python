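"""Co-occurrence networks, motif enrichment and cross-replicate tests.

Dosage states (or loci) are nodes; each analysable contrast contributes an
edge weighted by its centered Jaccard/Tanimoto value, flagged significant
when the cJ/T bootstrap p is below the chosen level.  Node importance is
eigenvector centrality on the absolute-weight graph.  Third- and
fourth-order structure is quantified by a census of connected induced
subgraphs (path/triangle; path/star/cycle/tadpole/diamond/clique) compared
against a degree-preserving rewiring null.  The replicated G test
decomposes association across crosses into G_total = G_pooled + G_het,
where a significant heterogeneity term means the direction or strength of
an interaction depends on the genetic background.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from functools import lru_cache

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .contingency import g_independence
from .cooccurrence import StatePairResult, state_pair_table
from .io import DosageState, GenotypeMatrix

# ---------------------------------------------------------------------------
# motif classes

#: canonical (size, sorted degree sequence) -> motif name
_CLASS_NAMES = {
    (3, (1, 1, 2)): "path_3",
    (3, (2, 2, 2)): "triangle",
    (4, (1, 1, 1, 3)): "star_4",
    (4, (1, 1, 2, 2)): "path_4",
    (4, (1, 2, 2, 3)): "tadpole",
    (4, (2, 2, 2, 2)): "cycle_4",
    (4, (2, 2, 3, 3)): "diamond",
    (4, (3, 3, 3, 3)): "clique_4",
}

#: short aliases ordered within each size by edge count then degree sequence
MOTIF_ALIASES = {
    "path_3": "s.3.1",
    "triangle": "s.3.2",
    "star_4": "s.4.1",
    "path_4": "s.4.2",
    "tadpole": "s.4.3",
    "cycle_4": "s.4.4",
    "diamond": "s.4.5",
    "clique_4": "s.4.6",
}

MOTIF_NAMES = tuple(MOTIF_ALIASES)


@lru_cache(maxsize=None)
def _isoclass_names(size: int) -> tuple[str | None, ...]:
    """Map igraph undirected isomorphism-class indices to motif names
    (None for disconnected classes)."""
    n_classes = {3: 4, 4: 11}[size]
    names = []
    for idx in range(n_classes):
        g = ig.Graph.Isoclass(size, idx, directed=False)
        if g.is_connected():
            key = (size, tuple(sorted(g.degree())))
            names.append(_CLASS_NAMES[key])
        else:
            names.append(None)
    return tuple(names)


def _to_igraph(g: nx.Graph) -> ig.Graph:
    nodes = list(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges]
    return ig.Graph(n=len(nodes), edges=edges, directed=False)


def motif_census(g: nx.Graph, sizes: tuple[int, ...] = (3, 4)) -> dict[str, int]:
    """Counts of connected induced subgraphs on 3 and 4 nodes.

    Disconnected node subsets are not counted.  Parallel edges and
    self-loops are not supported (simple undirected graphs only).
    """
    size3 = ("path_3", "triangle")
    counts = {n: 0 for n in MOTIF_NAMES
              if (n in size3 and 3 in sizes) or (n not in size3 and 4 in sizes)}
    gi = _to_igraph(g)
    for size in sizes:
        if size not in (3, 4):
            raise ValueError("motif sizes supported: 3 and 4")
        if gi.vcount() < size:
            continue
        raw = gi.motifs_randesu(size=size)
        for idx, name in enumerate(_isoclass_names(size)):
            if name is not None:
                v = raw[idx]
                counts[name] = int(v) if not np.isnan(v) else 0
    return counts


# ---------------------------------------------------------------------------
# network construction


def build_network(
    contrasts: list[StatePairResult],
    alpha_level: float = 0.05,
    granularity: str = "state",
    meta: pd.Series | None = None,
) -> nx.Graph:
    """Build the co-occurrence network of one cross.

    Nodes are dosage-state labels (``granularity="state"``) or loci
    (``"locus"``, keeping the strongest-|cJ/T| contrast per pair).  Edges
    carry the cJ/T weight, its sign, the bootstrap p, a ``significant``
    flag (cJT_p < alpha_level) and an ``omnibus_significant`` flag from a
    Benjamini-Hochberg correction of the omnibus p-values across the pairs
    seen in this call.  Node attribute ``centrality`` holds eigenvector
    centrality of the absolute-weight graph.
    """
    if granularity not in ("state", "locus"):
        raise ValueError("granularity must be 'state' or 'locus'")
    g = nx.Graph()
    if not contrasts:
        return g

    pair_p: dict[tuple[str, str], float] = {}
    for c in contrasts:
        key = tuple(sorted((c.state_a.locus, c.state_b.locus)))
        pair_p[key] = c.omnibus_p
    keys = sorted(pair_p)
    adj = multipletests([pair_p[k] for k in keys], method="fdr_bh")[1]
    pair_flag = {k: bool(q < alpha_level) for k, q in zip(keys, adj)}

    def node_of(state: DosageState):
        return state.label if granularity == "state" else state.locus

    best: dict[tuple, StatePairResult] = {}
    for c in contrasts:
        u, v = node_of(c.state_a), node_of(c.state_b)
        key = (u, v) if u <= v else (v, u)
        if key not in best or abs(c.cJT) > abs(best[key].cJT):
            best[key] = c

    for (u, v), c in best.items():
        pk = tuple(sorted((c.state_a.locus, c.state_b.locus)))
        g.add_edge(
            u, v,
            weight=c.cJT,
            sign=int(np.sign(c.cJT)),
            p=c.cJT_p,
            significant=bool(c.cJT_p < alpha_level),
            omnibus_significant=pair_flag[pk],
        )
        for node, state in ((u, c.state_a), (v, c.state_b)):
            g.nodes[node]["locus"] = state.locus
            if c.cross_id is not None:
                g.nodes[node]["cross"] = c.cross_id
            if meta is not None and state.locus in meta.index:
                g.nodes[node]["chromosome"] = meta[state.locus]

    _attach_centrality(g)
    return g


def _attach_centrality(g: nx.Graph) -> None:
    if g.number_of_edges() == 0:
        for v in g:
            g.nodes[v]["centrality"] = 0.0
        return
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    for u, v, d in g.edges(data=True):
        h.add_edge(u, v, absweight=abs(d.get("weight", 1.0)))
    cent = nx.eigenvector_centrality_numpy(h, weight="absweight")
    for v, score in cent.items():
        g.nodes[v]["centrality"] = float(abs(score))


def significant_subgraph(g: nx.Graph) -> nx.Graph:
    """Subgraph of edges flagged significant (raw cJ/T p below level)."""
    h = nx.Graph()
    h.add_nodes_from(g.nodes(data=True))
    h.add_edges_from(
        (u, v, d) for u, v, d in g.edges(data=True) if d.get("significant")
    )
    return h


# ---------------------------------------------------------------------------
# rewiring null and motif enrichment


def rewired_nulls(
    g: nx.Graph,
    R: int = 1000,
    swaps_per_edge: int = 10,
    seed: int | None = None,
):
    """Yield R degree-preserving rewirings of ``g`` (double-edge swaps).

    Each replicate attempts ``swaps_per_edge * |E|`` swaps.  Graphs too
    sparse to swap are yielded unchanged.
    """
    pyrng = random.Random(seed)
    m = g.number_of_edges()
    for _ in range(R):
        h = nx.Graph(g.edges)
        h.add_nodes_from(g.nodes)
        if m >= 2:
            try:
                nswap = swaps_per_edge * m
                nx.double_edge_swap(h, nswap=nswap, max_tries=100 * nswap, seed=pyrng)
            except nx.NetworkXException:
                pass  # unswappable degree sequence: null falls back to g
        yield h


def motif_enrichment(
    g: nx.Graph,
    R: int = 1000,
    swaps_per_edge: int = 10,
    min_count: int = 200,
    seed: int | None = None,
    sizes: tuple[int, ...] = (3, 4),
) -> pd.DataFrame:
    """Motif over-representation against the degree-preserving null.

    One-sided permutation p = (1 + #{null ≥ observed})/(R + 1); Z-scores
    and obs/exp ratios from the null moments; BH correction across the
    motif classes that pass the ``min_count`` filter (scarcer motifs are
    excluded before correction, following the minimum-count rule).
    """
    if g.number_of_edges() < 1:
        raise ValueError("graph has no edges")
    obs = motif_census(g, sizes=sizes)
    null_counts = {name: np.empty(R, dtype=float) for name in obs}
    for r, h in enumerate(rewired_nulls(g, R=R, swaps_per_edge=swaps_per_edge, seed=seed)):
        cen = motif_census(h, sizes=sizes)
        for name in obs:
            null_counts[name][r] = cen[name]

    rows = []
    for name in obs:
        null = null_counts[name]
        mean, sd = float(null.mean()), float(null.std(ddof=1)) if R > 1 else 0.0
        z = (obs[name] - mean) / sd if sd > 0 else np.nan
        ratio = obs[name] / mean if mean > 0 else np.nan
        p = (1 + int(np.sum(null >= obs[name]))) / (R + 1)
        rows.append(
            {
                "motif": name,
                "alias": MOTIF_ALIASES[name],
                "observed": obs[name],
                "null_mean": mean,
                "null_sd": sd,
                "Z": z,
                "ratio": ratio,
                "p_perm": p,
                "included": obs[name] >= min_count,
            }
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = np.nan
    inc = df["included"].to_numpy()
    if inc.any():
        df.loc[inc, "p_adj"] = multipletests(df.loc[inc, "p_perm"].values, method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# replicated G heterogeneity test


@dataclass(frozen=True)
class ReplicatedG:
    G_total: float
    df_total: int
    p_total: float
    G_pooled: float
    df_pooled: int
    p_pooled: float
    G_het: float
    df_het: int
    p_het: float
    per_cross: tuple = ()


def _chi2_p(stat: float, df: int) -> float:
    return float(stats.chi2.sf(stat, df)) if df > 0 else 1.0


def replicated_g(tables, williams: bool = False) -> ReplicatedG:
    """Replicated G independence test across crosses for one state pair.

    G_total sums the per-cross 2×2 independence G statistics; G_pooled is
    the G of the element-wise summed table (df 1); G_het = G_total −
    G_pooled measures heterogeneity of association among crosses.  A cross
    with a degenerate margin contributes G = 0 with df 0.  ``williams``
    applies the 2×2 Williams correction to every component (sensitivity
    analysis only — it breaks exact additivity).
    """
    tables = [np.asarray(t, dtype=float) for t in tables]
    if len(tables) < 2:
        raise ValueError("need at least two crosses")
    per = [g_independence(t, williams=williams) for t in tables]
    G_total = float(sum(g for g, _, _ in per))
    df_total = int(sum(df for _, df, _ in per))
    pooled = np.sum(tables, axis=0)
    G_pooled, df_pooled, p_pooled = g_independence(pooled, williams=williams)
    # defined as the difference; mildly negative values can occur for
    # independence tests because each cross estimates its own margins
    G_het = G_total - G_pooled
    df_het = max(df_total - df_pooled, 0)
    return ReplicatedG(
        G_total, df_total, _chi2_p(G_total, df_total),
        G_pooled, df_pooled, p_pooled,
        G_het, df_het, _chi2_p(G_het, df_het),
        per_cross=tuple(per),
    )


def replicated_g_from_crosses(
    crosses: dict[str, GenotypeMatrix], state_a: DosageState, state_b: DosageState
) -> ReplicatedG:
    """Build the per-cross 2×2 dosage-state submatrices for a state pair
    and run the replicated G test (pairwise-complete individuals per
    cross; RR is the absence class on both axes)."""
    tables = [
        state_pair_table(m, state_a, state_b).as_array() for m in crosses.values()
    ]
    return replicated_g(tables)


# ---------------------------------------------------------------------------
# segregation distortion vs interaction summary


def sdv_interaction_summary(
    sd: pd.DataFrame, omnibus: pd.DataFrame, level: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Relate per-locus SDV to pairwise interaction signal.

    ``sd`` needs columns (locus, SDV); ``omnibus`` needs (locus_a, locus_b,
    p).  Returns a per-locus table (SDV, number of pairwise tests with raw
    p < level, mean pairwise p) and Spearman correlations of SDV with both
    metrics.  Loci with no valid pairs are excluded; a constant SDV vector
    leaves the correlations undefined (NaN).
    """
    rows = []
    for _, r in sd.iterrows():
        locus = r["locus"]
        mask = (omnibus["locus_a"] == locus) | (omnibus["locus_b"] == locus)
        ps = omnibus.loc[mask, "p"]
        if ps.empty:
            continue
        rows.append(
            {
                "locus": locus,
                "SDV": r["SDV"],
                "n_pairs": int(len(ps)),
                "n_significant": int((ps < level).sum()),
                "mean_p": float(ps.mean()),
            }
        )
    per_locus = pd.DataFrame(rows)
    out = {"rho_count": np.nan, "p_count": np.nan, "rho_meanp": np.nan, "p_meanp": np.nan}
    if len(per_locus) >= 3 and per_locus["SDV"].nunique() > 1:
        for key, col in (("count", "n_significant"), ("meanp", "mean_p")):
            if per_locus[col].nunique() > 1:
                rho, p = stats.spearmanr(per_locus["SDV"], per_locus[col])
                out[f"rho_{key}"], out[f"p_{key}"] = float(rho), float(p)
    return per_locus, out
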