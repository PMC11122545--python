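"""Gene panel definition for the 84-gene inflammatory-response qPCR array.

A panel is the contract between every pipeline stage: which gene symbols are
measured targets and which are housekeeping references used for within-sample
normalization.  The bundled default panel carries the gene symbols of the
ustekinumab-response signature (dysregulated chemokines, interleukins and
their receptors) plus synthetic placeholder symbols (``SYN01``..``SYN43``)
padding the target list to the array's nominal 84 genes; real analyses
replace it with the actual array layout via :func:`read_panel`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "GenePanel",
    "default_panel",
    "read_panel",
    "HOUSEKEEPING_GENES",
    "SIGNATURE_FOLD_REGULATIONS",
]

#: Reference genes used for within-sample normalization (arithmetic mean Ct).
HOUSEKEEPING_GENES = ("ACTB", "B2M", "GAPDH", "HPRT1", "RPLP0")

#: Signed fold regulations (non-responders vs responders) of the published
#: ustekinumab-response signature: 29 genes past the +/-2-fold threshold plus
#: the modestly upregulated TNFSF14 (+1.38, significant but below the
#: fold cutoff).  Positive = overexpressed in non-responders; negative values
#: are the negative reciprocal of the fold change.
SIGNATURE_FOLD_REGULATIONS: dict[str, float] = {
    # upregulated in non-responders
    "CXCL2": 6.95, "CXCL3": 6.66, "BCL6": 5.68, "CXCL5": 5.67,
    "FASLG": 3.93, "CRP": 3.04, "CCL21": 3.03, "CXCR1": 2.86,
    "CD40": 2.68, "IL22": 2.61, "CCL11": 2.55, "CXCL1": 2.34,
    "CCL2": 2.2, "CCL16": 2.19, "IL17A": 2.19, "IL1B": 2.14,
    # downregulated in non-responders
    "IL23A": -24.3, "CCR2": -16.86, "IL23R": -13.59, "CCL24": -12.61,
    "CCL22": -9.44, "ITGB2": -2.73, "CXCL9": -2.68, "CCR1": -2.63,
    "C3AR1": -2.25, "CXCL10": -2.17, "NOS2": -2.13, "CD40LG": -2.08,
    "LY96": -2.07,
    # significant but under the fold threshold
    "TNFSF14": 1.38,
}

# Genes named in the co-expression / classification results but not in the
# dysregulated signature; they belong to the same inflammation panel.
_EXTRA_PANEL_GENES = (
    "CCR7", "CSF1", "CCL13", "IL1RN", "CCL19", "CEBPB", "IL1A",
    "LTA", "TLR5", "CCL5", "CCL23",
)

_N_TARGETS = 84


@dataclass(frozen=True)
class GenePanel:
    """Ordered target and housekeeping gene symbol lists.

    Invariants: the two lists are disjoint, contain no duplicates, and the
    housekeeping list is non-empty.  Checked at construction.
    """

    target_genes: tuple[str, ...]
    housekeeping_genes: tuple[str, ...] = HOUSEKEEPING_GENES
    panel_name: str = field(default="custom")

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_genes", tuple(self.target_genes))
        object.__setattr__(
            self, "housekeeping_genes", tuple(self.housekeeping_genes)
        )
        if not self.housekeeping_genes:
            raise ValueError("panel must declare at least one housekeeping gene")
        for label, genes in (
            ("target", self.target_genes),
            ("housekeeping", self.housekeeping_genes),
        ):
            dupes = {g for g in genes if list(genes).count(g) > 1}
            if dupes:
                raise ValueError(f"duplicate {label} gene symbols: {sorted(dupes)}")
        overlap = set(self.target_genes) & set(self.housekeeping_genes)
        if overlap:
            raise ValueError(
                "genes listed as both target and housekeeping: "
                f"{sorted(overlap)}"
            )

    @property
    def all_genes(self) -> tuple[str, ...]:
        """Targets followed by housekeeping genes, in panel order."""
        return self.target_genes + self.housekeeping_genes

    @property
    def n_targets(self) -> int:
        return len(self.target_genes)


def default_panel() -> GenePanel:
    """Bundled 84-target inflammation/autoimmunity panel.

    Contains every gene symbol of the ustekinumab-response signature and its
    co-expression neighbourhood, padded with clearly synthetic placeholder
    symbols to the array's 84 targets, plus the five housekeeping genes.
    """
    named = tuple(SIGNATURE_FOLD_REGULATIONS) + _EXTRA_PANEL_GENES
    n_pad = _N_TARGETS - len(named)
    placeholders = tuple(f"SYN{i:02d}" for i in range(1, n_pad + 1))
    return GenePanel(
        target_genes=named + placeholders,
        housekeeping_genes=HOUSEKEEPING_GENES,
        panel_name="inflammation-autoimmunity-84",
    )


def read_panel(path: str | Path) -> GenePanel:
    """Read a panel definition from YAML or CSV.

    YAML layout::

        panel_name: my-panel
        target_genes: [CXCL2, IL23A, ...]
        housekeeping_genes: [ACTB, B2M, ...]

    CSV layout: two columns ``gene,role`` with role in
    ``{target, housekeeping}``; an optional first line ``# name: my-panel``.
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ValueError(f"panel file {path} is not a mapping")
        return GenePanel(
            target_genes=tuple(doc.get("target_genes", ())),
            housekeeping_genes=tuple(
                doc.get("housekeeping_genes", HOUSEKEEPING_GENES)
            ),
            panel_name=str(doc.get("panel_name", path.stem)),
        )
    targets: list[str] = []
    housekeeping: list[str] = []
    name = path.stem
    with open(path, newline="") as fh:
        first = fh.readline()
        if first.startswith("# name:"):
            name = first.split(":", 1)[1].strip()
        else:
            fh.seek(0)
        for row in csv.reader(fh):
            if not row or row[0].startswith("#"):
                continue
            gene, role = row[0].strip(), row[1].strip().lower()
            if gene.lower() == "gene" and role == "role":
                continue  # header
            if role == "target":
                targets.append(gene)
            elif role == "housekeeping":
                housekeeping.append(gene)
            else:
                raise ValueError(f"unknown panel role {role!r} for gene {gene}")
    return GenePanel(tuple(targets), tuple(housekeeping), name)


def write_panel(panel: GenePanel, path: str | Path) -> None:
    """Write a panel as YAML (round-trips through :func:`read_panel`)."""
    doc = {
        "panel_name": panel.panel_name,
        "target_genes": list(panel.target_genes),
        "housekeeping_genes": list(panel.housekeeping_genes),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
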