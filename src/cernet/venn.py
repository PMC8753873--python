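"""Profile intersection (Venn-style list comparison) and candidate reports.

Identifier comparison is string-based after trimming and uppercasing —
the same semantics as pasting two gene lists into a web Venn tool.
Mixing transcript ids with gene symbols is therefore the caller's
responsibility; nothing here maps between id namespaces.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .cerna import CeRNAEdge

__all__ = ["VennResult", "intersect_profiles", "candidate_report", "read_id_list"]


def _normalize(ids: Iterable[str]) -> set[str]:
    return {str(i).strip().upper() for i in ids if str(i).strip()}


@dataclass(frozen=True)
class VennResult:
    """Exact two-set partition: A-only, B-only, and the intersection."""

    set_a_label: str
    set_b_label: str
    only_a: tuple[str, ...]
    only_b: tuple[str, ...]
    both: tuple[str, ...]

    @property
    def size_a(self) -> int:
        return len(self.only_a) + len(self.both)

    @property
    def size_b(self) -> int:
        return len(self.only_b) + len(self.both)


def intersect_profiles(
    set_a: Iterable[str],
    set_b: Iterable[str],
    label_a: str = "A",
    label_b: str = "B",
) -> VennResult:
    """Partition two id sets into A-only / B-only / both (sorted output)."""
    a, b = _normalize(set_a), _normalize(set_b)
    return VennResult(
        set_a_label=label_a,
        set_b_label=label_b,
        only_a=tuple(sorted(a - b)),
        only_b=tuple(sorted(b - a)),
        both=tuple(sorted(a & b)),
    )


def candidate_report(
    venn: VennResult,
    de_mrna_table: pd.DataFrame,
    edges: Sequence[CeRNAEdge],
    id_column: str = "lncrna_id",
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Per-intersected-mRNA table joining DE and ceRNA statistics.

    One row per id in ``venn.both`` with its log2fc, p, direction, shared
    count k and q — the quantities a wet-lab follow-up would start from —
    sorted by q ascending.  Ids missing from either source are collected
    in a discrepancy dict rather than dropped silently.
    """
    de_by_id = {
        str(i).strip().upper(): row
        for i, row in zip(de_mrna_table[id_column], de_mrna_table.to_dict("records"))
    }
    edge_by_id = {e.mrna_id.strip().upper(): e for e in edges}
    rows = []
    discrepancies: dict[str, list[str]] = {"missing_de": [], "missing_edge": []}
    for mrna in venn.both:
        de_row = de_by_id.get(mrna)
        edge = edge_by_id.get(mrna)
        if de_row is None:
            discrepancies["missing_de"].append(mrna)
        if edge is None:
            discrepancies["missing_edge"].append(mrna)
        if de_row is None or edge is None:
            continue
        rows.append(
            {
                "mrna_id": mrna,
                "log2fc": de_row["log2fc"],
                "fold_change": de_row.get("fold_change"),
                "p_value": de_row["p_value"],
                "direction": "up" if de_row["log2fc"] >= 0 else "down",
                "k_shared_mirnas": edge.k,
                "q_value": edge.q_value,
            }
        )
    columns = [
        "mrna_id", "log2fc", "fold_change", "p_value",
        "direction", "k_shared_mirnas", "q_value",
    ]
    report = pd.DataFrame(rows, columns=columns)
    if len(report):
        report = report.sort_values("q_value", kind="stable").reset_index(drop=True)
    return report, discrepancies


def read_id_list(path: str | Path, column: str | None = None) -> list[str]:
    """Read ids from a newline-delimited list, or one column of a TSV."""
    path = Path(path)
    if column is None:
        return [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column not in df.columns:
        raise ValueError(f"column {column!r} not in {path}")
    return [str(v) for v in df[column].dropna()]


def write_venn(path: str | Path, venn: VennResult) -> None:
    """VennResult as a sectioned TSV."""
    with open(path, "w") as fh:
        fh.write(f"[both]\t{len(venn.both)}\n")
        fh.writelines(f"{i}\n" for i in venn.both)
        fh.write(f"[only_{venn.set_a_label}]\t{len(venn.only_a)}\n")
        fh.writelines(f"{i}\n" for i in venn.only_a)
        fh.write(f"[only_{venn.set_b_label}]\t{len(venn.only_b)}\n")
        fh.writelines(f"{i}\n" for i in venn.only_b)
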