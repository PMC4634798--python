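"""Post-selection summaries of between-class abundance differences.

For a binary phenotype, each selected feature is summarized by its mean
relative abundance per class and the signed difference of the two means;
the report is sorted by the absolute difference, largest first.  Class order
for the sign convention is lexicographic: a positive difference means the
feature's average relative abundance is higher in the lexicographically
first class, a negative one that it is higher in the second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AbundanceTable, LabelVector

__all__ = [
    "GroupDifferenceRecord",
    "relative_abundance",
    "group_difference_report",
    "write_difference_report",
]


@dataclass
class GroupDifferenceRecord:
    feature_id: str
    taxonomy: str
    selection_rank: int
    mean_abundance_per_class: dict[str, float]
    difference: float


def relative_abundance(table: AbundanceTable) -> np.ndarray:
    """Per-sample normalized counts: every column sums to 1."""
    totals = table.counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"sample {table.sample_ids[zero[0]]!r} has zero total count"
        )
    return table.counts / totals


def group_difference_report(
    table: AbundanceTable,
    labels: LabelVector,
    selection,
    top_n: int | None = None,
) -> list[GroupDifferenceRecord]:
    """Rank selected features by absolute between-class mean difference."""
    if len(labels.classes) != 2:
        raise ValueError("the difference report is pairwise; need exactly 2 classes")
    if not selection.feature_indices:
        raise ValueError("selection is empty")
    rel = relative_abundance(table)
    values = np.asarray(labels.values)
    c1, c2 = labels.classes  # lexicographic, fixed by LabelVector
    mask1 = values == c1
    mask2 = values == c2
    records = []
    for rank, idx in enumerate(selection.feature_indices, start=1):
        m1 = float(rel[idx, mask1].mean())
        m2 = float(rel[idx, mask2].mean())
        records.append(
            GroupDifferenceRecord(
                feature_id=table.feature_ids[idx],
                taxonomy=table.taxonomy[idx],
                selection_rank=rank,
                mean_abundance_per_class={c1: m1, c2: m2},
                difference=m1 - m2,
            )
        )
    records.sort(key=lambda r: -abs(r.difference))
    if top_n is not None:
        records = records[:top_n]
    return records


def write_difference_report(
    records: list[GroupDifferenceRecord], labels: LabelVector, path: str
) -> None:
    """Write the ranked difference report as TSV with a sign-convention header."""
    c1, c2 = labels.classes
    with open(path, "w") as fh:
        fh.write(
            f"# difference = mean({c1}) - mean({c2}); negative means higher "
            f"average relative abundance in {c2}\n"
        )
        fh.write(
            f"feature_id\ttaxonomy\tselection_rank\tmean_{c1}\tmean_{c2}\tdifference\n"
        )
        for r in records:
            fh.write(
                f"{r.feature_id}\t{r.taxonomy}\t{r.selection_rank}\t"
                f"{r.mean_abundance_per_class[c1]:.10g}\t"
                f"{r.mean_abundance_per_class[c2]:.10g}\t{r.difference:.10g}\n"
            )
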