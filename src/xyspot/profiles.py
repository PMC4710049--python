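"""Per-cell transcript profiles and classification.

Counts assigned spots per cell, partitions cells into the six mutually
exclusive X/Y categories used for the two-gene hybridizations, evaluates the
overlapping four-gene co-expression categories, and normalizes signal counts
to counts per 1000 cells so sections of different size are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, UndefinedRateError
from .quant import UNASSIGNED, CellMap


class PairCategory(str, Enum):
    """Six-way per-cell partition for a two-gene (X vs Y homolog) experiment.

    MIXED means at least one signal of each homolog; the *_SPECIFIC classes
    require at least two signals of one homolog and none of the other, and the
    *_EQ_1 classes exactly one signal in total. The six classes are mutually
    exclusive and exhaustive.
    """

    NO_SIGNAL = "no_signal"
    X_EQ_1 = "x_eq_1"
    Y_EQ_1 = "y_eq_1"
    MIXED = "mixed"
    X_SPECIFIC = "x_specific"
    Y_SPECIFIC = "y_specific"


@dataclass
class ClassificationSummary:
    counts: dict[PairCategory, int]
    total_cells: int

    def __post_init__(self):
        if sum(self.counts.values()) != self.total_cells:
            raise ConsistencyError("six-way category counts must sum to total_cells")

    def as_dict(self) -> dict[str, int]:
        out = {cat.value: self.counts.get(cat, 0) for cat in PairCategory}
        out["total_cells"] = self.total_cells
        return out


#: Canonical order of the four genes in a co-expression experiment:
#: protocadherin X/Y then neuroligin X/Y.
COEXPRESSION_KEYS = (
    "PX>=1", "PY>=1", "NX>=1", "NY>=1",
    "PX+Y>=2", "NX+Y>=2", "PX+NX>=2", "PY+NY>=2", "PX+NY>=2", "PY+NX>=2",
    "PX+NX+NY>=3", "PY+NX+NY>=3", "PX+PY+NX>=3", "PX+PY+NY>=3",
    "PXandY+NXandY>=4", "no_signal", "total",
)

# which of the four gene slots (PX, PY, NX, NY) each predicate requires >= 1 of
_COEXPRESSION_PREDICATES: dict[str, tuple[int, ...]] = {
    "PX>=1": (0,), "PY>=1": (1,), "NX>=1": (2,), "NY>=1": (3,),
    "PX+Y>=2": (0, 1), "NX+Y>=2": (2, 3),
    "PX+NX>=2": (0, 2), "PY+NY>=2": (1, 3), "PX+NY>=2": (0, 3), "PY+NX>=2": (1, 2),
    "PX+NX+NY>=3": (0, 2, 3), "PY+NX+NY>=3": (1, 2, 3),
    "PX+PY+NX>=3": (0, 1, 2), "PX+PY+NY>=3": (0, 1, 3),
    "PXandY+NXandY>=4": (0, 1, 2, 3),
}


def profile_cells(
    spots: pd.DataFrame, cells: CellMap, gene_set: Sequence[str]
) -> tuple[pd.DataFrame, int]:
    """Count assigned spots per cell and gene.

    Returns a profile table indexed by cell label with one integer column per
    declared gene (cells with zero spots included), plus the number of
    UNASSIGNED spots that were excluded. A spot citing a cell label absent
    from the map raises ConsistencyError.
    """
    labels = cells.labels
    profiles = pd.DataFrame(
        0, index=pd.Index(labels, name="cell_id"), columns=list(gene_set), dtype=int
    )
    unknown_genes = set(spots["gene"]) - set(gene_set)
    if unknown_genes:
        raise ConsistencyError(f"spots carry undeclared genes: {sorted(unknown_genes)}")
    assigned = spots[spots["cell_id"] != UNASSIGNED]
    n_unassigned = len(spots) - len(assigned)
    missing = set(assigned["cell_id"]) - set(labels.tolist())
    if missing:
        raise ConsistencyError(f"spots reference unknown cell labels: {sorted(missing)}")
    if len(assigned):
        counts = assigned.groupby(["cell_id", "gene"]).size()
        for (cid, gene), k in counts.items():
            profiles.loc[cid, gene] = int(k)
    return profiles, n_unassigned


def classify_pair(profile: Mapping[str, int], x_gene: str, y_gene: str) -> PairCategory:
    """Classify one cell's (X count, Y count) into the six-way partition."""
    x, y = int(profile[x_gene]), int(profile[y_gene])
    if x < 0 or y < 0:
        raise ConsistencyError("spot counts must be non-negative")
    if x >= 1 and y >= 1:
        return PairCategory.MIXED
    if x == 0 and y == 0:
        return PairCategory.NO_SIGNAL
    if y == 0:
        return PairCategory.X_EQ_1 if x == 1 else PairCategory.X_SPECIFIC
    return PairCategory.Y_EQ_1 if y == 1 else PairCategory.Y_SPECIFIC


def summarize_pair(
    profiles: pd.DataFrame, x_gene: str, y_gene: str
) -> ClassificationSummary:
    """Six-way category counts over a sample's cell profiles (vectorized)."""
    x = profiles[x_gene].to_numpy()
    y = profiles[y_gene].to_numpy()
    mixed = (x >= 1) & (y >= 1)
    counts = {
        PairCategory.NO_SIGNAL: int(((x == 0) & (y == 0)).sum()),
        PairCategory.X_EQ_1: int(((x == 1) & (y == 0)).sum()),
        PairCategory.Y_EQ_1: int(((x == 0) & (y == 1)).sum()),
        PairCategory.MIXED: int(mixed.sum()),
        PairCategory.X_SPECIFIC: int(((x >= 2) & (y == 0)).sum()),
        PairCategory.Y_SPECIFIC: int(((y >= 2) & (x == 0)).sum()),
    }
    return ClassificationSummary(counts=counts, total_cells=len(profiles))


def specificity_view(summary: ClassificationSummary) -> dict[str, int]:
    """Three-class view over cells with at least two assigned signals.

    Mirrors the coarser X-specific / Y-specific / mixed reading of the
    six-way partition (every mixed cell has >= 2 signals by construction).
    """
    return {
        "x_specific": summary.counts[PairCategory.X_SPECIFIC],
        "y_specific": summary.counts[PairCategory.Y_SPECIFIC],
        "mixed": summary.counts[PairCategory.MIXED],
    }


def coexpression_summary(
    profiles: pd.DataFrame, genes: Sequence[str]
) -> dict[str, int]:
    """Overlapping four-gene co-expression categories.

    ``genes`` orders the four columns as (PX, PY, NX, NY). Each compound
    category requires at least one signal of every gene it names (the only
    reading consistent with a ligation-verified per-gene detection); the
    categories overlap, so counts need not sum to the total.
    """
    if len(genes) != 4:
        raise ConsistencyError("co-expression summary requires exactly four genes")
    present = np.stack([profiles[g].to_numpy() >= 1 for g in genes], axis=1)
    out: dict[str, int] = {}
    for key, slots in _COEXPRESSION_PREDICATES.items():
        out[key] = int(present[:, slots].all(axis=1).sum())
    out["no_signal"] = int((~present.any(axis=1)).sum())
    out["total"] = len(profiles)
    return out


def per_1000_cells(signal_count: float, total_cells: int) -> float:
    """Signals per 1000 cells; the section-size normalization."""
    if total_cells <= 0:
        raise UndefinedRateError("per-1000-cells rate undefined for zero cells")
    return 1000.0 * signal_count / total_cells


def profiles_from_counts(
    category_counts: Mapping[str, int], x_gene: str = "X", y_gene: str = "Y"
) -> pd.DataFrame:
    """Construct a minimal profile table realizing printed six-way counts.

    Keys follow PairCategory values. Useful for checking that published
    per-category cell counts partition the published totals.
    """
    reps = {
        PairCategory.NO_SIGNAL: (0, 0),
        PairCategory.X_EQ_1: (1, 0),
        PairCategory.Y_EQ_1: (0, 1),
        PairCategory.MIXED: (1, 1),
        PairCategory.X_SPECIFIC: (2, 0),
        PairCategory.Y_SPECIFIC: (0, 2),
    }
    rows = []
    for cat, (x, y) in reps.items():
        rows.extend([(x, y)] * int(category_counts.get(cat.value, 0)))
    df = pd.DataFrame(rows, columns=[x_gene, y_gene], dtype=int)
    df.index = pd.RangeIndex(1, len(df) + 1, name="cell_id")
    return df
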