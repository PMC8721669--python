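"""Hierarchical marker gating into immune subsets.

The panel (CD3, CD8, FoxP3, CD20, CD68, PanCK) resolves each cell to exactly
one label. T lineage is gated first: CD3⁺ cells split by FoxP3 then CD8 —
CD3⁺FoxP3⁺ regulatory ("FoxP3_T"), CD3⁺CD8⁺ cytotoxic ("CD8_T"), and the
CD3⁺CD8⁻FoxP3⁻ remainder conventionally reported as helper T cells
("CD4_T"), since CD4 itself is not stained. Non-T cells fall through to
CD20⁺ B cells, CD68⁺ macrophages, PanCK⁺ tumor cells, else "Other".

FoxP3 takes precedence over CD8 for the rare CD3⁺CD8⁺FoxP3⁺ double call
(the more specific functional label), and T lineage wins over CD20/CD68/
PanCK spillover; both conflicts are counted and reported.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from .core import CORE_MARKERS
from .errors import SchemaError, StateError

PHENOTYPES = (
    "B_cell",
    "CD8_T",
    "FoxP3_T",
    "CD4_T",
    "Macrophage",
    "Tumor_cell",
    "Other",
)
T_SUBSETS = ("CD8_T", "FoxP3_T", "CD4_T")
#: The five TLS composition features, in the order used for clustering.
TLS_FEATURES = ("B_cell", "CD4_T", "CD8_T", "FoxP3_T", "Macrophage")
LYMPHOCYTES = ("B_cell", "CD8_T", "FoxP3_T", "CD4_T")


def assign_phenotypes(cells: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Append a ``phenotype`` column; return (table, conflict report).

    Pointwise gating: the label of a row depends only on that row's markers.
    The conflict report counts CD3⁺CD8⁺FoxP3⁺ cells and T-lineage cells
    carrying CD20/CD68/PanCK spillover.
    """
    for m in CORE_MARKERS:
        if m not in cells.columns:
            raise SchemaError(f"marker column {m!r} missing")
    cd3 = cells["CD3"].to_numpy(bool)
    cd8 = cells["CD8"].to_numpy(bool)
    foxp3 = cells["FoxP3"].to_numpy(bool)
    cd20 = cells["CD20"].to_numpy(bool)
    cd68 = cells["CD68"].to_numpy(bool)
    panck = cells["PanCK"].to_numpy(bool)

    label = np.full(len(cells), "Other", dtype=object)
    label[panck] = "Tumor_cell"
    label[cd68] = "Macrophage"
    label[cd20] = "B_cell"
    # T lineage overrides lineage spillover
    label[cd3] = "CD4_T"
    label[cd3 & cd8] = "CD8_T"
    label[cd3 & foxp3] = "FoxP3_T"

    conflicts = {
        "cd8_foxp3_double_positive": int((cd3 & cd8 & foxp3).sum()),
        "t_lineage_spillover": int((cd3 & (cd20 | cd68 | panck)).sum()),
    }
    out = cells.copy()
    out["phenotype"] = label
    return out, conflicts


def phenotype_counts(cells: pd.DataFrame) -> dict[str, int]:
    """Count of each phenotype label; keys cover all labels, values sum to
    the number of rows."""
    if "phenotype" not in cells.columns:
        raise StateError("phenotypes not assigned; run assign_phenotypes first")
    if cells["phenotype"].isna().any():
        raise StateError("cell table contains unassigned phenotypes")
    counts = Counter(cells["phenotype"])
    return {label: int(counts.get(label, 0)) for label in PHENOTYPES}
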