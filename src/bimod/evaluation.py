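"""Validation metrics.

Two kinds of comparison are supported: set overlap between a predicted module
and a reference reaction set (recall / precision / F-measure), and agreement
between the module decompositions of two runs (Adjusted Rand index over the
induced node partitions, where every node outside a significant module falls
into one shared "unassigned" block).

A small curated benchmark ships with the package: the central-carbon
reactions of the yeast diauxic shift (glycolysis/gluconeogenesis, the TCA
cycle and the pathway connecting them), each annotated with the module label
assigned by a simulated-annealing run, by a greedy comparator method, and
with an expert flag marking the reactions differentially expressed on
glucose exhaustion (+1 induced, -1 repressed, 0 unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import pandas as pd
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "Partition",
    "round_half_away",
    "recall_precision_f",
    "adjusted_rand",
    "partition_from_run",
    "load_central_carbon_benchmark",
    "benchmark_recall",
]


@dataclass(frozen=True)
class Partition:
    """Disjoint blocks of node IDs covering a universe; by convention the
    final block is the "unassigned" remainder."""

    blocks: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for b in self.blocks:
            if b & seen:
                raise ValueError("partition blocks must be pairwise disjoint")
            seen |= b

    @property
    def universe(self) -> frozenset[str]:
        return frozenset().union(*self.blocks) if self.blocks else frozenset()

    def labels(self, order: list[str]) -> list[int]:
        """Block index of each node, in the given node order."""
        lookup = {n: i for i, b in enumerate(self.blocks) for n in b}
        return [lookup[n] for n in order]


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (so 0.625 -> 0.63), unlike banker's rounding."""
    exp = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(exp, rounding=ROUND_HALF_UP))


def recall_precision_f(
    predicted: set[str],
    reference: set[str],
    decimals: int | None = None,
) -> tuple[float, float, float]:
    """Set-overlap metrics of a predicted node set against a reference.

    recall = |P & R| / |R|; precision = |P & R| / |P| (0 for empty P);
    F = harmonic mean (0 when both are 0).  With ``decimals`` set, all three
    are rounded half away from zero, the convention used when quoting the
    values to two decimal places.
    """
    if not reference:
        raise ValueError("reference set must be non-empty")
    hits = len(set(predicted) & set(reference))
    recall = hits / len(reference)
    precision = hits / len(predicted) if predicted else 0.0
    f = (2 * recall * precision / (recall + precision)) if (recall + precision) else 0.0
    if decimals is not None:
        return (round_half_away(recall, decimals),
                round_half_away(precision, decimals),
                round_half_away(f, decimals))
    return recall, precision, f


def adjusted_rand(a: Partition, b: Partition) -> float:
    """Adjusted Rand index between two partitions of the same universe:
    1 for identical partitions, ~0 in expectation for independent ones."""
    if a.universe != b.universe:
        raise ValueError("partitions must cover the same universe")
    order = sorted(a.universe)
    if not order:
        raise ValueError("cannot compare empty partitions")
    return float(adjusted_rand_score(a.labels(order), b.labels(order)))


def partition_from_run(
    modules: list,
    universe: set[str],
) -> Partition:
    """Partition induced by the significant modules of one run: one block per
    module plus the unassigned remainder (always appended, possibly empty)."""
    blocks: list[frozenset[str]] = []
    assigned: set[str] = set()
    for mod in modules:
        nodes = frozenset(mod.node_ids)
        if not nodes <= set(universe):
            raise ValueError("module nodes outside the stated universe")
        if nodes & assigned:
            raise ValueError("modules must be node-disjoint")
        blocks.append(nodes)
        assigned |= nodes
    blocks.append(frozenset(universe) - frozenset(assigned))
    return Partition(tuple(b for b in blocks if b or len(blocks) == 1))


def load_central_carbon_benchmark() -> pd.DataFrame:
    """The bundled diauxic-shift central-carbon benchmark table."""
    with resources.files("bimod.data").joinpath(
        "diauxic_central_carbon.tsv"
    ).open("r") as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"reaction_id": str})
    return df


def benchmark_recall(
    df: pd.DataFrame, pathway: str, method: str, decimals: int | None = 2
) -> float:
    """Recall of one method's designated module against the expert reference
    for one benchmark pathway.

    The reference is the set of reactions the expert flagged as changed in
    the pathway's direction (+1 for up-regulated pathways, -1 for the
    repressed connection pathway).  The designated module is the modal
    non-"0" module label among the flagged rows; predicted reactions are the
    pathway rows carrying that label.
    """
    sub = df[df["pathway"] == pathway]
    if sub.empty:
        raise ValueError(f"unknown pathway {pathway!r}")
    col = f"{method}_module"
    if col not in df.columns:
        raise ValueError(f"unknown method {method!r}")
    flag = -1 if (sub["expert_flag"] == -1).any() else 1
    reference = set(sub.loc[sub["expert_flag"] == flag, "reaction_id"])
    flagged_labels = sub.loc[(sub["expert_flag"] == flag) & (sub[col] != "0"), col]
    if flagged_labels.empty:
        return 0.0
    module_label = flagged_labels.mode().iloc[0]
    predicted = set(sub.loc[sub[col] == module_label, "reaction_id"])
    recall, _, _ = recall_precision_f(predicted, reference, decimals=decimals)
    return recall
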