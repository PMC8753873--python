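"""Seed-based miRNA target-site prediction with a duplex alignment score.

Canonical site classes follow the TargetScan convention.  Writing the
transcript 5'->3', a seed match is the reverse complement of the miRNA
seed; miRNA position 1 lies opposite the transcript nucleotide at the
3' end of the site:

    6mer     reverse complement of miRNA positions 2-7          (6 nt)
    7mer-m8  reverse complement of miRNA positions 2-8          (7 nt)
    7mer-A1  6mer followed by an A on the transcript            (7 nt)
    8mer     7mer-m8 followed by an A on the transcript         (8 nt)

The transcript A opposite miRNA position 1 is required as a literal A
regardless of the identity of miRNA position 1.  Seed matching is
Watson-Crick only; G:U wobble is tolerated (and scored) only by the
duplex alignment, which extends the pairing into the miRNA 3' region.

Coordinates are 0-based half-open on the transcript plus strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "MiRNA",
    "TargetSite",
    "TargetMap",
    "ScoringWeights",
    "SITE_TYPES",
    "SITE_TYPE_RANK",
    "normalize_rna",
    "reverse_complement",
    "canonical_site_sequence",
    "find_seed_sites",
    "duplex_score",
    "predict_targets",
    "read_fasta",
    "write_fasta",
]

_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: Site classes in ascending stringency.
SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
SITE_TYPE_RANK = {name: rank for rank, name in enumerate(SITE_TYPES)}

_SITE_LENGTH = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}


def normalize_rna(sequence: str) -> str:
    """Uppercase and convert T to U; reject anything outside {A,C,G,U}.

    No IUPAC ambiguity codes are accepted: mixed or degenerate bases in
    input FASTA are a hard error rather than a silent wildcard.
    """
    seq = str(sequence).strip().upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(
            f"invalid nucleotide(s) {sorted(bad)} after RNA normalization"
        )
    return seq


def reverse_complement(sequence: str) -> str:
    """Reverse complement in the RNA alphabet."""
    return "".join(_RNA_COMPLEMENT[b] for b in reversed(sequence))


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA sequence, 5'->3', with derived seed regions."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if not self.id:
            raise ValueError("miRNA id must be non-empty")
        if not 18 <= len(self.sequence) <= 25:
            raise ValueError(
                f"miRNA {self.id!r}: length {len(self.sequence)} outside [18, 25]"
            )

    @property
    def seed6(self) -> str:
        """Nucleotides 2-7 (1-based), the minimal seed."""
        return self.sequence[1:7]

    @property
    def seed7(self) -> str:
        """Nucleotides 2-8 (1-based), the extended seed including m8."""
        return self.sequence[1:8]


@dataclass(frozen=True)
class TargetSite:
    """One predicted binding site on a transcript.

    ``start``/``end`` are 0-based half-open transcript offsets;
    ``site_sequence`` is the transcript substring at those offsets.
    """

    mirna_id: str
    transcript_id: str
    start: int
    end: int
    site_type: str
    duplex_score: float
    site_sequence: str

    def __post_init__(self) -> None:
        expected = _SITE_LENGTH.get(self.site_type)
        if expected is None:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.end - self.start != expected:
            raise ValueError(
                f"{self.site_type} site must span {expected} nt, "
                f"got [{self.start}, {self.end})"
            )
        if len(self.site_sequence) != expected:
            raise ValueError("site_sequence length disagrees with coordinates")


def canonical_site_sequence(mirna: MiRNA, site_type: str) -> str:
    """The exact transcript string (5'->3') of a perfect canonical site."""
    core6 = reverse_complement(mirna.seed6)
    core7 = reverse_complement(mirna.seed7)
    if site_type == "6mer":
        return core6
    if site_type == "7mer-m8":
        return core7
    if site_type == "7mer-A1":
        return core6 + "A"
    if site_type == "8mer":
        return core7 + "A"
    raise ValueError(f"unknown site type {site_type!r}")


@dataclass(frozen=True)
class ScoringWeights:
    """Pair and gap weights for the duplex alignment score.

    Watson-Crick pairs reward ``match``, G:U pairs ``wobble``, all other
    juxtapositions ``mismatch``; the first base of a gap costs
    ``gap_open`` and each further base ``gap_extend``.  Substitution
    scores at miRNA seed positions (2-8, 1-based) are multiplied by
    ``seed_multiplier``; gap costs are not.
    """

    match: float = 5.0
    wobble: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    seed_multiplier: float = 2.0
    seed_start: int = 2
    seed_end: int = 8

    def pair_score(self, mirna_base: str, transcript_base: str, position: int) -> float:
        if _RNA_COMPLEMENT[mirna_base] == transcript_base:
            s = self.match
        elif {mirna_base, transcript_base} == {"G", "U"}:
            s = self.wobble
        else:
            s = self.mismatch
        if self.seed_start <= position <= self.seed_end:
            s *= self.seed_multiplier
        return s


DEFAULT_WEIGHTS = ScoringWeights()

_NEG_INF = float("-inf")


def duplex_score(
    mirna: MiRNA, site_window: str, weights: ScoringWeights = DEFAULT_WEIGHTS
) -> float:
    """Score the miRNA:window duplex with a seed-weighted affine-gap alignment.

    The window is the transcript substring 5'->3' with the seed site at
    its 3' end, optionally extended 5'-ward so the miRNA 3' region can
    pair.  The alignment is local but anchored at the window's 3' end:
    any window prefix and any miRNA overhang may be left unpaired for
    free, internal gaps are penalized, and the duplex must reach the
    window's last nucleotide.  This is a deliberately simple additive
    score, not a thermodynamic ΔG.
    """
    window = normalize_rna(site_window)
    if not window:
        raise ValueError("empty site window")
    mir = mirna.sequence
    rev = mir[::-1]  # index j -> miRNA position len(mir) - j (1-based)
    L, W = len(rev), len(window)

    def sub(i: int, j: int) -> float:
        # window index i (0-based), rev index j
        position = L - j
        return weights.pair_score(rev[j], window[i], position)

    go, ge = weights.gap_open, weights.gap_extend
    # M: rev[j] paired with window[i]; X: window[i] opposite a gap;
    # Y: rev[j] opposite a gap (internal miRNA gap).  Starting fresh at
    # any (i, j) is free (unaligned window prefix / miRNA 5'-overhang).
    M = [[_NEG_INF] * (L + 1) for _ in range(W + 1)]
    X = [[_NEG_INF] * (L + 1) for _ in range(W + 1)]
    Y = [[_NEG_INF] * (L + 1) for _ in range(W + 1)]
    for i in range(1, W + 1):
        for j in range(1, L + 1):
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0.0)
            M[i][j] = diag + sub(i - 1, j - 1)
            X[i][j] = max(M[i - 1][j] + go, Y[i - 1][j] + go, X[i - 1][j] + ge)
            Y[i][j] = max(M[i][j - 1] + go, X[i][j - 1] + go, Y[i][j - 1] + ge)
    # The duplex ends at the window's 3' end; trailing miRNA is free.
    return max(max(M[W]), max(X[W]))


def find_seed_sites(
    mirna: MiRNA,
    transcript_id: str,
    sequence: str,
    weights: ScoringWeights = DEFAULT_WEIGHTS,
    flank: int = 15,
) -> list[TargetSite]:
    """All non-redundant canonical sites of ``mirna`` on a transcript.

    Each 6mer-core match locus yields exactly one site, classified with
    the most specific class that applies there (8mer > 7mer-m8 >
    7mer-A1 > 6mer).  The duplex score is computed on the site plus
    ``flank`` nt of upstream transcript (where the miRNA 3' region can
    pair).  Transcripts shorter than 6 nt yield no sites.
    """
    seq = normalize_rna(sequence)
    core6 = reverse_complement(mirna.seed6)
    m8 = reverse_complement(mirna.seed7)[0]  # base opposite miRNA position 8
    sites: list[TargetSite] = []
    i = seq.find(core6)
    while i != -1:
        has_m8 = i > 0 and seq[i - 1] == m8
        has_a1 = i + 6 < len(seq) and seq[i + 6] == "A"
        if has_m8 and has_a1:
            start, end, site_type = i - 1, i + 7, "8mer"
        elif has_m8:
            start, end, site_type = i - 1, i + 6, "7mer-m8"
        elif has_a1:
            start, end, site_type = i, i + 7, "7mer-A1"
        else:
            start, end, site_type = i, i + 6, "6mer"
        window = seq[max(0, start - flank) : end]
        sites.append(
            TargetSite(
                mirna_id=mirna.id,
                transcript_id=transcript_id,
                start=start,
                end=end,
                site_type=site_type,
                duplex_score=duplex_score(mirna, window, weights),
                site_sequence=seq[start:end],
            )
        )
        i = seq.find(core6, i + 1)
    return sites


@dataclass
class TargetMap:
    """Per-transcript miRNA target sets with the underlying sites.

    ``targets`` has an entry for a transcript iff at least one retained
    site exists for it; ``universe`` records every miRNA id supplied to
    the prediction run (the hypergeometric universe downstream).
    """

    targets: dict[str, set[str]] = field(default_factory=dict)
    sites: dict[tuple[str, str], list[TargetSite]] = field(default_factory=dict)
    universe: tuple[str, ...] = ()

    def mirnas_targeting(self, transcript_id: str) -> set[str]:
        return set(self.targets.get(transcript_id, set()))

    def add_sites(self, transcript_id: str, mirna_id: str, sites: list[TargetSite]) -> None:
        if not sites:
            return
        self.targets.setdefault(transcript_id, set()).add(mirna_id)
        self.sites[(transcript_id, mirna_id)] = sorted(sites, key=lambda s: s.start)

    def site_table_rows(self) -> list[TargetSite]:
        rows: list[TargetSite] = []
        for key in sorted(self.sites):
            rows.extend(self.sites[key])
        return rows


def predict_targets(
    mirnas: Sequence[MiRNA],
    transcripts: Mapping[str, str] | str | Path,
    min_site_type: str = "7mer-m8",
    min_duplex_score: float = 50.0,
    weights: ScoringWeights = DEFAULT_WEIGHTS,
) -> TargetMap:
    """Scan every transcript with every miRNA and retain qualifying sites.

    A (transcript, miRNA) pair enters the map iff it has at least one
    site of class ``min_site_type`` or better with duplex score at least
    ``min_duplex_score``.  ``transcripts`` may be an id->sequence mapping
    or a FASTA path.  Thresholds are declared defaults: a perfect
    gapless 7mer-m8 seed pairing alone scores 70 under the default
    weights, so 50 admits any canonical 7mer/8mer site while discarding
    heavily degraded duplexes.
    """
    if not mirnas:
        raise ValueError("empty miRNA set")
    if min_site_type not in SITE_TYPE_RANK:
        raise ValueError(f"unknown site type {min_site_type!r}")
    if not isinstance(transcripts, Mapping):
        transcripts = read_fasta(transcripts)
    if not transcripts:
        raise ValueError("empty transcript set")
    min_rank = SITE_TYPE_RANK[min_site_type]
    tm = TargetMap(universe=tuple(m.id for m in mirnas))
    for tid, seq in transcripts.items():
        for mirna in mirnas:
            sites = [
                s
                for s in find_seed_sites(mirna, tid, seq, weights)
                if SITE_TYPE_RANK[s.site_type] >= min_rank
                and s.duplex_score >= min_duplex_score
            ]
            tm.add_sites(tid, mirna.id, sites)
    return tm


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id->sequence dict (RNA-normalized)."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        records[rec.id] = normalize_rna(str(rec.seq))
    return records


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 70) -> None:
    """Write sequences as FASTA wrapped at ``width`` columns (deterministic)."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_site_table(path: str | Path, targetmap: TargetMap) -> None:
    """Write the per-site TSV (one row per retained site)."""
    with open(path, "w") as fh:
        fh.write(
            "transcript_id\tmirna_id\tstart\tend\tsite_type\tduplex_score\tsite_sequence\n"
        )
        for s in targetmap.site_table_rows():
            fh.write(
                f"{s.transcript_id}\t{s.mirna_id}\t{s.start}\t{s.end}\t"
                f"{s.site_type}\t{s.duplex_score:.2f}\t{s.site_sequence}\n"
            )


def write_pair_table(path: str | Path, targetmap: TargetMap) -> None:
    """Write the TargetMap as a (transcript, miRNA) pair list TSV."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tmirna_id\n")
        for tid in sorted(targetmap.targets):
            for mid in sorted(targetmap.targets[tid]):
                fh.write(f"{tid}\t{mid}\n")
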