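"""Per-group co-expression networks and hub/bottleneck centrality ranking.

Candidate genes (the dysregulated set) are correlated against the full
panel within each response group.  The correlation method is gated by
Shapiro-Wilk normality: if any gene in any group rejects normality at
alpha = 0.05, Spearman's rank correlation is used (the expected outcome for
expression data), otherwise Pearson.  Gene pairs with ``|rho| > 0.9``
(strict) become edges of an undirected graph whose nodes are the genes
incident to at least one surviving edge; degree centrality (integer edge
count, "hubs") and normalized betweenness centrality ("bottlenecks") are
computed on the unweighted thresholded graph, with the signed rho kept as
an edge annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .dgea import NormalizedExpression

__all__ = [
    "CorrelationMatrix",
    "normality_gate",
    "correlation_matrix",
    "threshold_edges",
    "build_graph",
    "degree_centrality",
    "betweenness_centrality",
    "centrality_table",
    "rank_hubs_bottlenecks",
    "compare_groups",
]

RHO_CUTOFF = 0.9
SHAPIRO_ALPHA = 0.05


@dataclass
class CorrelationMatrix:
    """Candidate x full-panel correlation coefficients for one group."""

    rho: pd.DataFrame  # rows = candidate genes, columns = all panel targets
    method: str
    group: str

    def __post_init__(self) -> None:
        if self.method not in ("spearman", "pearson"):
            raise ValueError(f"unknown correlation method {self.method!r}")
        a = self.rho.to_numpy()
        if np.nanmax(np.abs(a)) > 1 + 1e-12:
            raise ValueError("|rho| must not exceed 1")


def normality_gate(
    norm: NormalizedExpression, alpha: float = SHAPIRO_ALPHA
) -> tuple[str, pd.DataFrame]:
    """Choose the correlation method by per-gene, per-group Shapiro-Wilk.

    Returns ``("spearman", report)`` if any gene in any group rejects
    normality at ``alpha``, else ``("pearson", report)``.  The report has one
    row per (gene, group) with the test p-value and a ``normal`` flag; a
    constant expression vector cannot be tested and is counted as
    non-normal with a warning.
    """
    rows = []
    any_reject = False
    for group in sorted(norm.groups.unique()):
        block = norm.group_values(group)
        if len(block) < 3:
            raise ValueError(f"group {group!r} has fewer than 3 samples")
        for gene in block.columns:
            x = block[gene].to_numpy()
            if np.ptp(x) == 0:
                warnings.warn(
                    f"gene {gene} constant in group {group}; treated as "
                    "non-normal",
                    RuntimeWarning,
                    stacklevel=2,
                )
                p = 0.0
            else:
                p = float(stats.shapiro(x).pvalue)
            reject = p < alpha
            any_reject = any_reject or reject
            rows.append(
                {"gene": gene, "group": group, "shapiro_p": p, "normal": not reject}
            )
    report = pd.DataFrame(rows)
    return ("spearman" if any_reject else "pearson"), report


def correlation_matrix(
    norm: NormalizedExpression,
    candidates: list[str],
    method: str,
    group: str,
) -> CorrelationMatrix:
    """Correlate candidate genes against every panel gene within one group.

    Spearman uses average ranks for ties.  Pairs involving a constant
    vector get rho = 0 (no monotone association is estimable).
    """
    unknown = [g for g in candidates if g not in norm.values.columns]
    if unknown:
        raise KeyError(f"candidate genes absent from expression: {unknown}")
    block = norm.group_values(group)
    if len(block) < 3:
        raise ValueError(f"group {group!r} has fewer than 3 samples")
    data = block.to_numpy()
    if method == "spearman":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", stats.ConstantInputWarning)
            rho_full = stats.spearmanr(data).statistic
        if np.ndim(rho_full) == 0:  # scipy collapses the 2-gene case
            r = float(rho_full)
            rho_full = np.array([[1.0, r], [r, 1.0]])
    elif method == "pearson":
        with np.errstate(invalid="ignore", divide="ignore"):
            rho_full = np.corrcoef(data, rowvar=False)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    rho_full = np.atleast_2d(np.asarray(rho_full, dtype=float))
    np.fill_diagonal(rho_full, 1.0)
    rho_full = np.nan_to_num(rho_full, nan=0.0)
    full = pd.DataFrame(rho_full, index=block.columns, columns=block.columns)
    return CorrelationMatrix(rho=full.loc[candidates], method=method, group=group)


def threshold_edges(
    corr: CorrelationMatrix,
    cutoff: float = RHO_CUTOFF,
    strict: bool = True,
) -> list[tuple[str, str, float]]:
    """Unordered gene pairs with ``|rho|`` beyond the cutoff.

    Strict inequality by default; self-pairs are dropped and each pair is
    reported once with its signed rho.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    edges: dict[frozenset, float] = {}
    arr = corr.rho.to_numpy()
    rows = list(corr.rho.index)
    cols = list(corr.rho.columns)
    ii, jj = np.nonzero(
        (np.abs(arr) > cutoff) if strict else (np.abs(arr) >= cutoff)
    )
    for i, j in zip(ii, jj):
        a, b = rows[i], cols[j]
        if a == b:
            continue
        edges.setdefault(frozenset((a, b)), float(arr[i, j]))
    return [tuple(sorted(pair)) + (rho,) for pair, rho in sorted(
        edges.items(), key=lambda kv: tuple(sorted(kv[0]))
    )]


def build_graph(
    edges: list[tuple[str, str, float]], group: str | None = None
) -> nx.Graph:
    """Undirected graph from thresholded edges; only connected genes appear.

    The signed correlation is stored as edge attribute ``rho``; centralities
    ignore it (the graph is treated as unweighted).
    """
    graph = nx.Graph(group=group)
    for a, b, rho in edges:
        graph.add_edge(a, b, rho=rho)
    return graph


def degree_centrality(graph: nx.Graph) -> dict[str, int]:
    """Integer edge count per node (hub score)."""
    return {node: int(deg) for node, deg in graph.degree()}


def betweenness_centrality(graph: nx.Graph) -> dict[str, float]:
    """Exact normalized betweenness on the unweighted graph.

    Brandes' algorithm (via networkx) normalized by ``(n-1)(n-2)/2`` with
    ``n`` the number of nodes in the graph, so values live in [0, 1]; graphs
    with fewer than 3 nodes have all-zero betweenness.
    """
    if graph.number_of_nodes() < 3:
        return {node: 0.0 for node in graph.nodes()}
    return nx.betweenness_centrality(graph, normalized=True, weight=None)


def centrality_table(graph: nx.Graph) -> pd.DataFrame:
    """Per-gene DC/BC with dense, tie-aware hub and bottleneck ranks."""
    dc = degree_centrality(graph)
    bc = betweenness_centrality(graph)
    table = pd.DataFrame(
        {"DC": pd.Series(dc, dtype=int), "BC": pd.Series(bc, dtype=float)}
    ).sort_index()
    if len(table):
        table["hub_rank"] = (
            table["DC"].rank(method="dense", ascending=False).astype(int)
        )
        table["bottleneck_rank"] = (
            table["BC"].rank(method="dense", ascending=False).astype(int)
        )
    else:
        table["hub_rank"] = pd.Series(dtype=int)
        table["bottleneck_rank"] = pd.Series(dtype=int)
    table.index.name = "gene"
    return table


def _top_k(table: pd.DataFrame, rank_col: str, score_col: str, k: int) -> list[dict]:
    # sort by rank then alphabetically for deterministic tie listing
    ordered = table.reset_index().sort_values([rank_col, "gene"], kind="stable")
    out = []
    for _, row in ordered.iterrows():
        if len(out) >= k and row[rank_col] > out[-1]["rank"]:
            break
        out.append(
            {
                "gene": row["gene"],
                "rank": int(row[rank_col]),
                "score": row[score_col],
                "tied": False,
            }
        )
    ranks = [e["rank"] for e in out]
    for e in out:
        e["tied"] = ranks.count(e["rank"]) > 1
    return out


def rank_hubs_bottlenecks(table: pd.DataFrame, k: int = 10) -> dict:
    """Top-k hub (by DC) and bottleneck (by BC) reports.

    Ties share a rank and are all reported (so a top-k list may exceed k
    entries when the k-th place is tied); alphabetical order breaks ties for
    display only.
    """
    if table.empty:
        return {"hubs": [], "bottlenecks": []}
    k = min(k, len(table))
    return {
        "hubs": _top_k(table, "hub_rank", "DC", k),
        "bottlenecks": _top_k(table, "bottleneck_rank", "BC", k),
    }


def compare_groups(a: pd.DataFrame, b: pd.DataFrame, k: int = 10) -> dict:
    """Shared/unique top-k hubs and bottlenecks, plus per-gene deltas.

    ``a`` and ``b`` are centrality tables of the two response groups built
    over the same panel.
    """
    def top_set(table: pd.DataFrame, kind: str) -> set:
        return {e["gene"] for e in rank_hubs_bottlenecks(table, k)[kind]}

    out = {}
    for kind in ("hubs", "bottlenecks"):
        sa, sb = top_set(a, kind), top_set(b, kind)
        out[kind] = {
            "shared": sorted(sa & sb),
            "unique_a": sorted(sa - sb),
            "unique_b": sorted(sb - sa),
        }
    genes = sorted(set(a.index) | set(b.index))
    deltas = pd.DataFrame(index=pd.Index(genes, name="gene"))
    for col in ("DC", "BC"):
        va = a[col].reindex(genes).fillna(0)
        vb = b[col].reindex(genes).fillna(0)
        deltas[f"{col}_a"] = va
        deltas[f"{col}_b"] = vb
        deltas[f"{col}_delta"] = va - vb
    out["deltas"] = deltas
    return out
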