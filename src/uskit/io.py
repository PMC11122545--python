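"""Ct-matrix container, CSV I/O and network export/import.

The on-disk Ct matrix format is a plain CSV (comma separated, dot decimal,
UTF-8, one header row): first column ``sample_id``, second column ``group``
(``responder`` / ``non_responder``), remaining columns one per gene symbol.
Cells hold threshold-cycle values; wells that never amplified carry the token
``Undetermined`` and are masked and replaced by a configurable ceiling Ct
(default 35.0, the usual detection-limit convention for these arrays).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .panel import GenePanel

__all__ = [
    "CtMatrix",
    "UNDETERMINED",
    "DEFAULT_CT_CEILING",
    "RESPONDER",
    "NON_RESPONDER",
    "read_ct_matrix",
    "write_ct_matrix",
    "export_network",
    "read_network",
]

UNDETERMINED = "Undetermined"
DEFAULT_CT_CEILING = 35.0

RESPONDER = "responder"
NON_RESPONDER = "non_responder"
_GROUPS = (RESPONDER, NON_RESPONDER)
# tolerated spellings on input, normalized to the canonical labels
_GROUP_ALIASES = {
    "responder": RESPONDER,
    "non_responder": NON_RESPONDER,
    "non-responder": NON_RESPONDER,
    "nonresponder": NON_RESPONDER,
}


@dataclass
class CtMatrix:
    """Raw threshold-cycle values for samples x genes with response labels.

    ``ct`` is a float DataFrame (rows = samples, columns = genes, targets
    then housekeeping in panel order); ``groups`` maps each sample to
    ``responder`` or ``non_responder``; ``undetermined`` flags wells where no
    amplification was observed (their Ct holds the ceiling value).
    """

    ct: pd.DataFrame
    groups: pd.Series
    undetermined: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    ct_ceiling: float = DEFAULT_CT_CEILING

    def __post_init__(self) -> None:
        if self.undetermined is None:
            self.undetermined = pd.DataFrame(
                False, index=self.ct.index, columns=self.ct.columns
            )
        self.validate()

    def validate(self) -> None:
        self.ct.index.name = "sample_id"
        self.undetermined.index.name = "sample_id"
        self.groups.index.name = "sample_id"
        if self.ct.index.has_duplicates:
            dupes = self.ct.index[self.ct.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if self.ct.columns.has_duplicates:
            dupes = self.ct.columns[self.ct.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dupes}")
        if not self.groups.index.equals(self.ct.index):
            raise ValueError("group labels do not match sample ids")
        bad = set(self.groups.unique()) - set(_GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        counts = self.groups.value_counts()
        for g in _GROUPS:
            if counts.get(g, 0) < 2:
                raise ValueError(f"group {g!r} has fewer than 2 samples")
        if self.undetermined.shape != self.ct.shape:
            raise ValueError("undetermined mask shape mismatch")
        measured = self.ct.to_numpy()[~self.undetermined.to_numpy()]
        if not np.all(np.isfinite(measured)):
            raise ValueError("non-finite Ct value in a measured (unmasked) well")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def n_samples(self) -> int:
        return len(self.ct)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def require_panel(self, panel: GenePanel) -> None:
        """Check every panel gene (housekeeping first) is present."""
        present = set(self.ct.columns)
        for gene in panel.housekeeping_genes:
            if gene not in present:
                raise ValueError(f"housekeeping gene {gene} missing from Ct matrix")
        missing = [g for g in panel.target_genes if g not in present]
        if missing:
            raise ValueError(f"panel target genes missing from Ct matrix: {missing}")


def read_ct_matrix(
    path: str | Path,
    panel: GenePanel,
    ct_ceiling: float = DEFAULT_CT_CEILING,
) -> CtMatrix:
    """Read and validate a Ct CSV against a panel.

    ``Undetermined`` cells are masked and set to ``ct_ceiling``.  Missing
    housekeeping genes, unknown group labels and duplicate sample ids are
    fatal.
    """
    raw = pd.read_csv(path, dtype=str)
    sample_col, group_col = raw.columns[:2]
    if raw[sample_col].duplicated().any():
        dupes = raw[sample_col][raw[sample_col].duplicated()].tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")
    raw = raw.set_index(sample_col)
    try:
        groups = raw[group_col].map(lambda s: _GROUP_ALIASES[s.strip().lower()])
    except KeyError as exc:
        raise ValueError(f"unknown group label {exc.args[0]!r}") from None
    genes = raw.columns[1:]
    values = raw[genes]
    mask = values == UNDETERMINED
    ct = values.mask(mask, np.nan).astype(float)
    ct = ct.where(~mask, ct_ceiling)
    matrix = CtMatrix(
        ct=ct, groups=groups, undetermined=mask.astype(bool), ct_ceiling=ct_ceiling
    )
    matrix.require_panel(panel)
    return matrix


def write_ct_matrix(matrix: CtMatrix, path: str | Path) -> None:
    """Write the CSV dialect read by :func:`read_ct_matrix`."""
    out = matrix.ct.astype(object).copy()
    out[matrix.undetermined] = UNDETERMINED
    out.insert(0, "group", matrix.groups)
    out.index.name = "sample_id"
    out.to_csv(path)


def export_network(
    graph: nx.Graph, fmt: str, path: str | Path, interaction: str = "co_expr"
) -> None:
    """Export a co-expression graph as SIF or GraphML.

    SIF rows read ``GENE_A co_expr GENE_B``; isolated nodes are written as a
    bare name on their own line.  GraphML carries the signed correlation as
    edge attribute ``rho`` and the symbol as node attribute ``gene``, so the
    file round-trips losslessly through :func:`read_network`.
    """
    fmt = fmt.upper()
    path = Path(path)
    if fmt == "SIF":
        with open(path, "w") as fh:
            written = set()
            for u, v in sorted(graph.edges()):
                fh.write(f"{u}\t{interaction}\t{v}\n")
                written.update((u, v))
            for node in sorted(set(graph.nodes()) - written):
                fh.write(f"{node}\n")
    elif fmt == "GRAPHML":
        export = nx.Graph()
        for node in graph.nodes():
            export.add_node(node, gene=str(node))
        for u, v, data in graph.edges(data=True):
            export.add_edge(u, v, rho=float(data.get("rho", data.get("weight", 0.0))))
        nx.write_graphml(export, path)
    else:
        raise ValueError(f"unsupported network format {fmt!r} (use SIF or GraphML)")


def read_network(path: str | Path) -> nx.Graph:
    """Read a GraphML network written by :func:`export_network`."""
    graph = nx.read_graphml(path)
    out = nx.Graph()
    for node, data in graph.nodes(data=True):
        out.add_node(data.get("gene", node))
    for u, v, data in graph.edges(data=True):
        gu = graph.nodes[u].get("gene", u)
        gv = graph.nodes[v].get("gene", v)
        out.add_edge(gu, gv, rho=float(data["rho"]))
    return out
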