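"""Differential-expression table screening and ranking.

Operates on tables with columns ``lncrna_id``, ``gene_name``,
``log2fc``, ``fold_change``, ``p_value`` (and optionally
``chromosome``).  The screening convention is |log2FC| >= threshold
(non-strict, i.e. at least twofold linear change at the default of 1)
combined with p < cutoff (strict), matching the usual "P less than
0.05" reporting convention.

A 40-row worked-example table (the top-20 up- and top-20 down-regulated
lncRNAs from an oleic-acid-induced hepatocyte steatosis screen) ships
with the package for arithmetic self-checks; see
:func:`load_example_top40`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DERecord",
    "ScreenResult",
    "fold_change_from_log2fc",
    "screen_differential",
    "top_n_by_direction",
    "chromosome_distribution",
    "load_de_table",
    "write_de_table",
    "load_annotation",
    "load_example_top40",
]

UNPLACED = "unplaced"

_REQUIRED = ("lncrna_id", "log2fc", "p_value")


@dataclass(frozen=True)
class DERecord:
    """One transcript's differential-expression row."""

    lncrna_id: str
    gene_name: str
    log2fc: float
    fold_change: float
    p_value: float
    chromosome: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"{self.lncrna_id}: p_value {self.p_value} outside [0, 1]")
        if self.fold_change <= 0:
            raise ValueError(f"{self.lncrna_id}: fold_change must be positive")


def fold_change_from_log2fc(log2fc: float) -> float:
    """Linear fold change 2**log2fc."""
    if not math.isfinite(log2fc):
        raise ValueError("log2fc must be finite")
    return 2.0 ** log2fc


def _as_frame(table: pd.DataFrame | Iterable[DERecord]) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        missing = [c for c in _REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"DE table missing column(s) {missing}")
        return table
    records = list(table)
    return pd.DataFrame(
        {
            "lncrna_id": [r.lncrna_id for r in records],
            "gene_name": [r.gene_name for r in records],
            "log2fc": [r.log2fc for r in records],
            "fold_change": [r.fold_change for r in records],
            "p_value": [r.p_value for r in records],
        }
    )


@dataclass
class ScreenResult:
    """Rows surviving the DE screen, with direction counts."""

    table: pd.DataFrame
    n_up: int
    n_down: int

    @property
    def n_total(self) -> int:
        return len(self.table)


def screen_differential(
    table: pd.DataFrame | Iterable[DERecord],
    min_abs_log2fc: float = 1.0,
    max_p: float = 0.05,
) -> ScreenResult:
    """Retain rows with |log2fc| >= ``min_abs_log2fc`` and p < ``max_p``.

    Input order is preserved; direction counts split retained rows by the
    sign of log2fc.
    """
    if min_abs_log2fc < 0:
        raise ValueError("min_abs_log2fc must be non-negative")
    df = _as_frame(table)
    keep = (df["log2fc"].abs() >= min_abs_log2fc) & (df["p_value"] < max_p)
    out = df.loc[keep].copy()
    return ScreenResult(
        table=out,
        n_up=int((out["log2fc"] > 0).sum()),
        n_down=int((out["log2fc"] < 0).sum()),
    )


def top_n_by_direction(
    table: pd.DataFrame | Iterable[DERecord],
    n: int = 20,
    max_p: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-``n`` rows by log2fc in each direction among rows with p < ``max_p``.

    The up list is sorted by log2fc descending, the down list ascending;
    ties break by ascending p_value, then lexicographic id, so output is
    fully deterministic.  Fewer than ``n`` eligible rows returns them all.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    df = _as_frame(table)
    eligible = df.loc[df["p_value"] < max_p].copy()
    up = eligible.sort_values(
        ["log2fc", "p_value", "lncrna_id"], ascending=[False, True, True]
    ).head(n)
    down = eligible.sort_values(
        ["log2fc", "p_value", "lncrna_id"], ascending=[True, True, True]
    ).head(n)
    return up.reset_index(drop=True), down.reset_index(drop=True)


def chromosome_distribution(
    table: pd.DataFrame | Iterable[DERecord],
    annotation: Mapping[str, str],
) -> dict[str, tuple[int, int]]:
    """Per-chromosome (up, down) counts; unannotated ids tally as "unplaced".

    Direction is the sign of log2fc (>= 0 counts as up), so the counts
    always conserve the input row total.
    """
    df = _as_frame(table)
    counts: dict[str, list[int]] = {}
    for tid, l2fc in zip(df["lncrna_id"], df["log2fc"]):
        chrom = annotation.get(tid, UNPLACED)
        pair = counts.setdefault(chrom, [0, 0])
        pair[0 if l2fc >= 0 else 1] += 1
    return {c: (u, d) for c, (u, d) in sorted(counts.items())}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_de_table(
    path: str | Path,
    fold_change_rtol: float = 1e-3,
) -> pd.DataFrame:
    """Read a DE TSV; recompute or verify the fold_change column.

    If fold_change is absent it is recomputed from log2fc; if present but
    inconsistent with 2**log2fc beyond ``fold_change_rtol`` relative
    tolerance, loading fails loudly (corrupted or mislabeled tables should
    not pass silently).  Tables transcribed from low-precision printed
    sources need a looser tolerance.
    """
    df = pd.read_csv(path, sep="\t", dtype={"lncrna_id": str})
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"DE table missing column(s) {missing}")
    if "gene_name" not in df.columns:
        df["gene_name"] = ""
    df["gene_name"] = df["gene_name"].fillna("")
    expected = np.exp2(df["log2fc"].to_numpy(dtype=float))
    if "fold_change" in df.columns:
        got = df["fold_change"].to_numpy(dtype=float)
        rel = np.abs(got - expected) / expected
        if (rel > fold_change_rtol).any():
            worst = df["lncrna_id"].iloc[int(np.argmax(rel))]
            raise ValueError(
                f"fold_change inconsistent with 2**log2fc (worst row {worst!r}, "
                f"relative error {rel.max():.2e} > {fold_change_rtol:.0e})"
            )
    else:
        df["fold_change"] = expected
    return df


def write_de_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_annotation(path: str | Path) -> dict[str, str]:
    """Read an id->chromosome map from a 2-column TSV or a BED file.

    BED input (>= 4 columns, integer start/end in columns 2-3) uses only
    the chrom and name fields; coordinates are ignored.
    """
    out: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cells = line.split("\t")
            if len(cells) >= 4 and cells[1].isdigit() and cells[2].isdigit():
                out[cells[3]] = cells[0]  # BED: chrom, start, end, name
            elif len(cells) >= 2:
                out[cells[0]] = cells[1]  # TSV: id, chrom
            else:
                raise ValueError(f"unparseable annotation line: {line!r}")
    return out


def load_example_top40() -> pd.DataFrame:
    """The bundled 40-row worked-example table (top-20 up / top-20 down).

    Fold-change cells are printed at 3-4 decimal places, hence the loose
    consistency tolerance.
    """
    ref = resources.files("cernet").joinpath("data/top40_lncrnas.tsv")
    with resources.as_file(ref) as path:
        return load_de_table(path, fold_change_rtol=5e-3)
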