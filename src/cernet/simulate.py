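"""Synthetic input generation with machine-readable ground truth.

Every input the pipeline consumes can be generated here: mature miRNA
sets, transcript FASTA with binding sites implanted at known
coordinates, differential-expression tables with a prescribed
up/down/null profile, qPCR Ct plates with known true fold changes, and
Oil-red-O OD510 readings.  Each generator is deterministic given its
seed (per-stream sub-seeds are derived from one integer), and returns a
:class:`GroundTruth` describing exactly what was written, so downstream
stages can be tested for exact recovery.

The generators emulate the shape of a published oleic-acid hepatocyte
steatosis study (648 significant lncRNAs, 351 up / 297 down; a
241-mRNA ceRNA neighbourhood sharing 119 miRNAs with the anchor
lncRNA; qPCR folds such as 0.35 for the anchor) without any real
sequence content: backgrounds are i.i.d. nucleotides at a chosen GC
fraction, and effect sizes are drawn from simple parametric spreads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .targets import (
    MiRNA,
    canonical_site_sequence,
    reverse_complement,
    _SITE_LENGTH,
)

__all__ = [
    "GroundTruth",
    "PlanError",
    "generate_mirna_set",
    "generate_transcripts",
    "generate_de_table",
    "generate_chromosome_annotation",
    "generate_qpcr_plate",
    "generate_od_table",
    "build_cerna_fixture",
    "CernaFixture",
]


class PlanError(ValueError):
    """An implant plan is internally inconsistent (overlaps, bad bounds)."""


#: One planned site implant: (mirna_id, transcript_id, start, site_type).
Implant = tuple[str, str, int, str]


@dataclass
class GroundTruth:
    """What a generator actually wrote, in machine-readable form."""

    rng_seed: int
    implant_plan: list[Implant] = field(default_factory=list)
    true_de_labels: dict[str, str] = field(default_factory=dict)
    true_log2fc: dict[str, float] = field(default_factory=dict)
    true_fold: dict[tuple[str, str], float] = field(default_factory=dict)

    def validate_against(self, transcripts: Mapping[str, str] | None = None,
                         counts: tuple[int, int, int] | None = None) -> None:
        """Check the declared invariants; raise ValueError on violation."""
        if transcripts is not None:
            for mid, tid, start, site_type in self.implant_plan:
                if tid not in transcripts:
                    raise ValueError(f"planned transcript {tid!r} was not generated")
                if not 0 <= start <= len(transcripts[tid]) - _SITE_LENGTH[site_type]:
                    raise ValueError(f"site at {tid}:{start} outside transcript")
        if counts is not None:
            labels = list(self.true_de_labels.values())
            got = (labels.count("up"), labels.count("down"), labels.count("null"))
            if got != tuple(counts):
                raise ValueError(f"label counts {got} != requested {counts}")

    # -- structured-text serialization (key/value + table sections) --------

    def to_text(self) -> str:
        lines = ["[meta]", f"rng_seed\t{self.rng_seed}"]
        lines.append("[implant_plan]")
        lines.append("mirna_id\ttranscript_id\tstart\tsite_type")
        for mid, tid, start, st in self.implant_plan:
            lines.append(f"{mid}\t{tid}\t{start}\t{st}")
        lines.append("[true_de_labels]")
        lines.append("transcript_id\tlabel")
        for tid, lab in self.true_de_labels.items():
            lines.append(f"{tid}\t{lab}")
        lines.append("[true_log2fc]")
        lines.append("transcript_id\tlog2fc")
        for tid, v in self.true_log2fc.items():
            lines.append(f"{tid}\t{v!r}")
        lines.append("[true_fold]")
        lines.append("gene\tgroup\tfold")
        for (gene, group), v in self.true_fold.items():
            lines.append(f"{gene}\t{group}\t{v!r}")
        return "\n".join(lines) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "GroundTruth":
        gt = cls(rng_seed=0)
        section = None
        for raw in text.splitlines():
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                section = line[1:-1]
                header_pending = section != "meta"
                continue
            if section != "meta" and header_pending:
                header_pending = False  # skip column header row
                continue
            cells = line.split("\t")
            if section == "meta":
                if cells[0] == "rng_seed":
                    gt.rng_seed = int(cells[1])
            elif section == "implant_plan":
                gt.implant_plan.append((cells[0], cells[1], int(cells[2]), cells[3]))
            elif section == "true_de_labels":
                gt.true_de_labels[cells[0]] = cells[1]
            elif section == "true_log2fc":
                gt.true_log2fc[cells[0]] = float(cells[1])
            elif section == "true_fold":
                gt.true_fold[(cells[0], cells[1])] = float(cells[2])
        return gt

    @classmethod
    def read(cls, path: str | Path) -> "GroundTruth":
        return cls.from_text(Path(path).read_text())


def _streams(rng_seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent deterministic sub-streams from one seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(rng_seed).spawn(n)]


def _random_rna(rng: np.random.Generator, length: int, gc_fraction: float = 0.5) -> str:
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    return "".join(rng.choice(["A", "C", "G", "U"], size=length, p=p))


# ---------------------------------------------------------------------------
# miRNA sets
# ---------------------------------------------------------------------------

def generate_mirna_set(
    n: int,
    length_range: tuple[int, int] = (21, 23),
    rng_seed: int = 0,
) -> list[MiRNA]:
    """``n`` random mature miRNAs with unique ids and unique seed7 regions.

    Seed7 uniqueness (4^7 = 16384 possibilities, so rejection sampling is
    cheap for realistic n) guarantees that a site implanted for one miRNA
    can never be an exact canonical site of another, which keeps implant
    ground truth unambiguous.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if not (18 <= lo <= hi <= 25):
        raise ValueError("length_range must satisfy 18 <= lo <= hi <= 25")
    (rng,) = _streams(rng_seed, 1)
    mirnas: list[MiRNA] = []
    seen_seed7: set[str] = set()
    width = max(4, len(str(n)))
    while len(mirnas) < n:
        length = int(rng.integers(lo, hi + 1))
        seq = _random_rna(rng, length)
        if seq[1:8] in seen_seed7:
            continue
        seen_seed7.add(seq[1:8])
        mirnas.append(MiRNA(id=f"mir-{len(mirnas) + 1:0{width}d}", sequence=seq))
    return mirnas


# ---------------------------------------------------------------------------
# Transcripts with implanted sites
# ---------------------------------------------------------------------------

def generate_transcripts(
    mirnas: Sequence[MiRNA],
    transcript_ids: Sequence[str],
    plan: Iterable[Implant],
    length: int | Mapping[str, int] = 1000,
    gc_fraction: float = 0.5,
    rng_seed: int = 0,
    mask_chance_sites: bool = False,
) -> tuple[dict[str, str], GroundTruth]:
    """Random background transcripts with exact canonical sites written in.

    Every planned site is written verbatim (the canonical site string for
    its class, including the transcript-side A of 8mer/7mer-A1 sites) at
    its 0-based offset, so substring read-back recovers it exactly.

    With ``mask_chance_sites`` the background (everything outside planned
    site windows) is additionally scrubbed of chance 6mer seed cores of
    *any* supplied miRNA, giving fixtures whose target sets equal the plan
    exactly; leave it off to study chance-match statistics.
    """
    mirna_by_id = {m.id: m for m in mirnas}
    lengths = (
        {tid: int(length) for tid in transcript_ids}
        if isinstance(length, int)
        else {tid: int(length[tid]) for tid in transcript_ids}
    )
    plan = list(plan)
    # validate the plan
    windows: dict[str, list[tuple[int, int]]] = {tid: [] for tid in transcript_ids}
    for mid, tid, start, site_type in plan:
        if mid not in mirna_by_id:
            raise ValueError(f"unknown miRNA id {mid!r} in plan")
        if tid not in lengths:
            raise ValueError(f"unknown transcript id {tid!r} in plan")
        if site_type not in _SITE_LENGTH:
            raise PlanError(f"unknown site type {site_type!r}")
        end = start + _SITE_LENGTH[site_type]
        if start < 0 or end > lengths[tid]:
            raise PlanError(f"site {mid}@{tid}:{start} outside transcript bounds")
        for s, e in windows[tid]:
            if start < e and s < end:
                raise PlanError(f"overlapping planned sites on {tid} at {start}")
        windows[tid].append((start, end))

    (rng,) = _streams(rng_seed, 1)
    transcripts: dict[str, list[str]] = {
        tid: list(_random_rna(rng, lengths[tid], gc_fraction))
        for tid in transcript_ids
    }
    for mid, tid, start, site_type in plan:
        site = canonical_site_sequence(mirna_by_id[mid], site_type)
        transcripts[tid][start : start + len(site)] = site

    if mask_chance_sites:
        _mask_chance_sites(transcripts, list(mirnas), windows, rng)

    out = {tid: "".join(chars) for tid, chars in transcripts.items()}
    gt = GroundTruth(rng_seed=rng_seed, implant_plan=plan)
    gt.validate_against(transcripts=out)
    return out, gt


def _mask_chance_sites(
    transcripts: dict[str, list[str]],
    mirnas: Sequence[MiRNA],
    windows: Mapping[str, Sequence[tuple[int, int]]],
    rng: np.random.Generator,
    max_rounds: int = 60,
) -> None:
    """Mutate background until no chance site survives outside implants.

    Phase one destroys every stray 6mer seed core with at least one
    unprotected position (removing all four canonical site classes at
    that locus).  Cores lying entirely inside a planned window are the
    implants themselves — except that an 8mer site string of a *different*
    miRNA can straddle a window boundary, with its core protected but its
    m8 or A1 position in free background; phase two scans full 8mer site
    strings and mutates an unprotected position of any unplanned hit.
    Unplanned 8mers entirely inside one 8-nt window are impossible when
    seed7 regions are unique, and planned windows are spaced by >= 2 nt,
    so every unplanned hit has a mutable position.
    """
    # sorted for determinism: set iteration order varies with hash seeding
    cores = sorted({reverse_complement(m.seed6) for m in mirnas})
    sites8 = sorted({reverse_complement(m.seed7) + "A" for m in mirnas})
    for tid, chars in transcripts.items():
        protected = np.zeros(len(chars), dtype=bool)
        planned_starts = {s for s, _e in windows.get(tid, ())}
        for s, e in windows.get(tid, ()):
            protected[s:e] = True
        for round_no in range(max_rounds + 1):
            seq = "".join(chars)
            dirty = False
            for pattern, width, skip_planned in (
                [(c, 6, False) for c in cores] + [(s8, 8, True) for s8 in sites8]
            ):
                i = seq.find(pattern)
                while i != -1:
                    if not (skip_planned and i in planned_starts):
                        free = [p for p in range(i, i + width) if not protected[p]]
                        if free:
                            p = int(rng.choice(free))
                            alternatives = [b for b in "ACGU" if b != chars[p]]
                            chars[p] = str(rng.choice(alternatives))
                            dirty = True
                    i = seq.find(pattern, i + 1)
            if not dirty:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError(f"chance-site masking did not converge on {tid}")


# ---------------------------------------------------------------------------
# Differential-expression tables
# ---------------------------------------------------------------------------

def _auto_ids(prefix: str, n: int, start: int = 1) -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(start, start + n)]


def generate_de_table(
    n_up: int,
    n_down: int,
    n_null: int,
    effect_low: float = 1.0,
    p_sig: float = 0.01,
    rng_seed: int = 0,
    id_prefix: str = "LNC",
    up_ids: Sequence[str] = (),
    down_ids: Sequence[str] = (),
    null_ids: Sequence[str] = (),
) -> tuple[pd.DataFrame, GroundTruth]:
    """A DE table with a prescribed up/down/null profile.

    True DE rows get |log2FC| >= ``effect_low`` (threshold plus an
    exponential tail, mean 0.7) and p drawn log-uniform in (1e-6,
    ``p_sig``); null rows get log2FC ~ Normal(0, 0.5) and p uniform in
    (0.05, 1), so they fail a (|log2FC| >= 1, p < 0.05) screen via the p
    cutoff regardless of effect.  ``*_ids`` may pin the leading ids of
    each class (e.g. to place a known transcript among the down rows);
    the rest are auto-generated.  Row order is shuffled.
    """
    if min(n_up, n_down, n_null) < 0:
        raise ValueError("counts must be non-negative")
    if effect_low < 1:
        raise ValueError("effect_low must be >= 1")
    if not 0 < p_sig < 0.05:
        raise ValueError("p_sig must lie in (0, 0.05)")
    for ids, n, name in ((up_ids, n_up, "up"), (down_ids, n_down, "down"),
                         (null_ids, n_null, "null")):
        if len(ids) > n:
            raise ValueError(f"more {name}_ids than {name} rows requested")

    rng_fc, rng_p, rng_misc = _streams(rng_seed, 3)

    def fill(ids: Sequence[str], n: int, offset: int) -> list[str]:
        return list(ids) + _auto_ids(id_prefix, n - len(ids), start=offset + len(ids) + 1)

    ids_up = fill(up_ids, n_up, 0)
    ids_down = fill(down_ids, n_down, n_up)
    ids_null = fill(null_ids, n_null, n_up + n_down)

    l2fc = np.concatenate([
        effect_low + rng_fc.exponential(0.7, n_up),
        -(effect_low + rng_fc.exponential(0.7, n_down)),
        rng_fc.normal(0.0, 0.5, n_null),
    ])
    pvals = np.concatenate([
        np.exp(rng_p.uniform(np.log(1e-6), np.log(p_sig), n_up + n_down)),
        rng_p.uniform(0.05, 1.0, n_null),
    ])
    ids = ids_up + ids_down + ids_null
    labels = ["up"] * n_up + ["down"] * n_down + ["null"] * n_null
    genes = [
        "" if rng_misc.random() < 0.15 else f"GENE{rng_misc.integers(1, 20000):05d}"
        for _ in ids
    ]
    df = pd.DataFrame({
        "lncrna_id": ids,
        "gene_name": genes,
        "log2fc": l2fc,
        "fold_change": np.exp2(l2fc),
        "p_value": pvals,
        "label": labels,
    })
    order = rng_misc.permutation(len(df))
    df = df.iloc[order].reset_index(drop=True)
    gt = GroundTruth(
        rng_seed=rng_seed,
        true_de_labels=dict(zip(df["lncrna_id"], df["label"])),
        true_log2fc=dict(zip(df["lncrna_id"], df["log2fc"])),
    )
    gt.validate_against(counts=(n_up, n_down, n_null))
    return df.drop(columns="label"), gt


_CHROMOSOMES = [f"chr{i}" for i in range(1, 23)] + ["chrX"]


def generate_chromosome_annotation(
    ids: Sequence[str],
    rng_seed: int = 0,
    include_y: bool = False,
    missing_fraction: float = 0.0,
) -> dict[str, str]:
    """Random id->chromosome map, weighted toward chr1/chr5/chr11, no chrY.

    Mirrors the qualitative karyogram of the study conditions: loci on
    every chromosome except Y, with chromosomes 1, 5 and 11 the densest.
    A ``missing_fraction`` of ids can be left unannotated.
    """
    (rng,) = _streams(rng_seed, 1)
    chroms = _CHROMOSOMES + (["chrY"] if include_y else [])
    weights = np.array(
        [3.0 if c in ("chr1", "chr5", "chr11") else 1.0 for c in chroms]
    )
    weights /= weights.sum()
    out: dict[str, str] = {}
    for tid in ids:
        if rng.random() < missing_fraction:
            continue
        out[tid] = str(rng.choice(chroms, p=weights))
    return out


# ---------------------------------------------------------------------------
# qPCR plates and OD readings
# ---------------------------------------------------------------------------

def generate_qpcr_plate(
    genes: Sequence[str],
    groups: Sequence[str],
    true_fold: Mapping[tuple[str, str], float],
    n_replicates: int = 3,
    ct_noise_sd: float = 0.0,
    rng_seed: int = 0,
    reference_gene: str = "ACTB",
    control_group: str = "control",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulated Ct table: Ct = baseline - log2(fold) + Normal(0, sd).

    Per-gene baselines are drawn once (reference gene near Ct 15,
    targets in 20-28), so the reference gene's Ct does not depend on
    group.  ``true_fold`` maps (gene, group) to the simulated expression
    fold versus the control group; the control group and the reference
    gene are fixed at fold 1.
    """
    if reference_gene not in genes:
        raise ValueError(f"reference gene {reference_gene!r} not in genes")
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} not in groups")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")

    folds: dict[tuple[str, str], float] = {}
    for gene in genes:
        for group in groups:
            if gene == reference_gene or group == control_group:
                f = float(true_fold.get((gene, group), 1.0))
                if not math.isclose(f, 1.0):
                    raise ValueError(
                        f"true_fold for ({gene}, {group}) must be 1 "
                        "(control group / reference gene)"
                    )
                folds[(gene, group)] = 1.0
            else:
                folds[(gene, group)] = float(true_fold.get((gene, group), 1.0))
    for gene, group in true_fold:
        if gene not in genes or group not in groups:
            raise ValueError(f"true_fold key ({gene}, {group}) outside the plate")

    rng_base, rng_noise = _streams(rng_seed, 2)
    baseline = {
        gene: (15.0 if gene == reference_gene else float(rng_base.uniform(20, 28)))
        for gene in genes
    }
    rows = []
    for group in groups:
        for rep in range(1, n_replicates + 1):
            sample = f"{group}_{rep}"
            for gene in genes:
                ct = (
                    baseline[gene]
                    - math.log2(folds[(gene, group)])
                    + (rng_noise.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
                )
                rows.append((sample, group, gene, ct))
    df = pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct"])
    gt = GroundTruth(rng_seed=rng_seed, true_fold=dict(folds))
    return df, gt


def generate_od_table(
    group_params: Mapping[str, tuple[float, float]],
    n_replicates: int = 3,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """OD510 readings per group: Normal(mean, sd), truncated at zero."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    (rng,) = _streams(rng_seed, 1)
    rows = []
    for group, (mean, sd) in group_params.items():
        vals = np.clip(rng.normal(mean, sd, n_replicates), 0.0, None)
        rows.extend((group, float(v)) for v in vals)
    return pd.DataFrame(rows, columns=["group", "od510"])


# ---------------------------------------------------------------------------
# The composite ceRNA fixture
# ---------------------------------------------------------------------------

@dataclass
class CernaFixture:
    """Everything needed for a shared-miRNA ceRNA run with known truth."""

    mirnas: list[MiRNA]
    transcripts: dict[str, str]
    anchor_id: str
    partner_ids: list[str]
    decoy_ids: list[str]
    ground_truth: GroundTruth
    anchor_mirna_ids: list[str]

    @property
    def candidate_ids(self) -> list[str]:
        return self.partner_ids + self.decoy_ids


def build_cerna_fixture(
    rng_seed: int = 0,
    n_mirnas: int = 300,
    n_anchor_mirnas: int = 119,
    partner_ids: Sequence[str] = ("RXRB", "RNPEPL1", "CD82", "MADD", "KLC2"),
    n_decoys: int = 236,
    shared_per_partner: int | None = None,
    cover_anchor_set: bool = True,
    decoy_shared_max: int = 1,
    anchor_id: str = "LINC01260",
    transcript_length: int = 800,
) -> CernaFixture:
    """A masked implant fixture for the shared-miRNA enrichment test.

    The anchor transcript carries one 8mer site for each of
    ``n_anchor_mirnas`` miRNAs out of a universe of ``n_mirnas``.  Each
    partner mRNA shares a planned subset of the anchor's miRNAs
    (``shared_per_partner`` sites each, or — with ``cover_anchor_set`` —
    a partition of the whole anchor set so the union over partners equals
    it exactly).  Decoys carry sites for non-anchor miRNAs plus at most
    ``decoy_shared_max`` anchor miRNAs.  Backgrounds are scrubbed of
    chance seed cores, so 8mer-level prediction recovers the plan
    exactly.
    """
    if n_anchor_mirnas >= n_mirnas:
        raise ValueError("anchor miRNA set must be a strict subset of the universe")
    rng, = _streams(rng_seed, 1)
    seq_seed = int(rng.integers(0, 2**31 - 1))
    mirnas = generate_mirna_set(n_mirnas, rng_seed=int(rng.integers(0, 2**31 - 1)))
    anchor_mirnas = [m.id for m in mirnas[:n_anchor_mirnas]]
    other_mirnas = [m.id for m in mirnas[n_anchor_mirnas:]]

    partner_ids = list(partner_ids)
    decoy_ids = _auto_ids("CEM", n_decoys)
    transcript_ids = [anchor_id] + partner_ids + decoy_ids

    def place(tid: str, mirna_ids: Sequence[str], tlen: int) -> list[Implant]:
        """Non-overlapping 8mer placements at jittered, evenly spaced slots."""
        k = len(mirna_ids)
        if k == 0:
            return []
        slot = tlen // k
        if slot < 10:
            raise PlanError(f"transcript {tid} too short for {k} sites")
        plan = []
        for i, mid in enumerate(mirna_ids):
            jitter = int(rng.integers(0, slot - 9))
            plan.append((str(mid), tid, i * slot + jitter, "8mer"))
        return plan

    anchor_len = max(transcript_length, 20 * n_anchor_mirnas)
    lengths = {tid: transcript_length for tid in transcript_ids}
    lengths[anchor_id] = anchor_len

    plan: list[Implant] = place(anchor_id, anchor_mirnas, anchor_len)

    # partner shared sets: a partition of the anchor set, or fixed-size subsets
    if cover_anchor_set:
        shuffled = list(rng.permutation(anchor_mirnas))
        assignments: list[list[str]] = [[] for _ in partner_ids]
        for i, mid in enumerate(shuffled):
            assignments[i % len(partner_ids)].append(mid)
        if shared_per_partner is not None:
            for j, block in enumerate(assignments):
                if len(block) < shared_per_partner:
                    extra = [m for m in shuffled if m not in block]
                    block.extend(extra[: shared_per_partner - len(block)])
                assignments[j] = block[:max(shared_per_partner, len(block))]
    else:
        if shared_per_partner is None:
            raise ValueError("shared_per_partner required when not covering")
        assignments = [
            list(rng.choice(anchor_mirnas, size=shared_per_partner, replace=False))
            for _ in partner_ids
        ]
    for tid, block in zip(partner_ids, assignments):
        plan.extend(place(tid, block, lengths[tid]))

    # decoys: 3 sites from the non-anchor pool, plus at most decoy_shared_max
    # anchor miRNAs on alternating decoys
    for i, tid in enumerate(decoy_ids):
        block = list(rng.choice(other_mirnas, size=3, replace=False))
        if decoy_shared_max > 0 and i % 2 == 0:
            block.extend(
                rng.choice(anchor_mirnas, size=decoy_shared_max, replace=False)
            )
        plan.extend(place(tid, block, lengths[tid]))

    transcripts, gt = generate_transcripts(
        mirnas,
        transcript_ids,
        plan,
        length=lengths,
        rng_seed=seq_seed,
        mask_chance_sites=True,
    )
    return CernaFixture(
        mirnas=mirnas,
        transcripts=transcripts,
        anchor_id=anchor_id,
        partner_ids=partner_ids,
        decoy_ids=decoy_ids,
        ground_truth=gt,
        anchor_mirna_ids=anchor_mirnas,
    )
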