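"""Read demultiplexing, cleaning and per-run quality summaries.

The cleaning contract mirrors the original study's preprocessing: reads
missing the restriction-site residual at their start are dropped, reads are
trimmed to a fixed 110-nt tag, and reads whose trimmed tag contains more
than 10% unknown (N) bases are removed. Barcode (MID) assignment is exact,
with longest-match-wins to support variable-length MIDs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError, ValidationError


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: bases (may contain N) and per-base Phred scores."""

    read_id: str
    bases: str
    quals: tuple[int, ...]
    individual_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValidationError(
                f"read {self.read_id}: {len(self.bases)} bases vs "
                f"{len(self.quals)} quality scores")


@dataclass(frozen=True)
class MidTable:
    """Barcode table: (individual_id, phenotypic sex, MID) rows.

    MIDs must be unique but may differ in length (the study used 4-6 nt
    barcodes); nested MIDs are resolved by longest match at demultiplexing.
    """

    rows: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        mids = [mid for _, _, mid in self.rows]
        if len(set(mids)) != len(mids):
            raise ConfigurationError("duplicate MIDs in barcode table")
        ids = [i for i, _, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate individual ids in barcode table")
        for _, sex, _ in self.rows:
            if sex not in ("female", "male"):
                raise ConfigurationError(f"sex must be female/male, got {sex!r}")

    @property
    def mid_of(self) -> dict[str, str]:
        return {i: mid for i, _, mid in self.rows}

    @property
    def sex_of(self) -> dict[str, str]:
        return {i: sex for i, sex, _ in self.rows}


def demultiplex(
    reads: list[ReadRecord], mid_table: MidTable
) -> tuple[dict[str, list[ReadRecord]], list[ReadRecord]]:
    """Assign reads to individuals by exact MID prefix, longest match wins.

    The MID is stripped from assigned reads. Returns (per-individual
    streams, unassigned stream); the two partition the input.
    """
    by_len = sorted(mid_table.rows, key=lambda r: -len(r[2]))
    assigned: dict[str, list[ReadRecord]] = {i: [] for i, _, _ in mid_table.rows}
    unassigned: list[ReadRecord] = []
    for read in reads:
        for ind_id, _, mid in by_len:
            if read.bases.startswith(mid):
                assigned[ind_id].append(replace(
                    read,
                    bases=read.bases[len(mid):],
                    quals=read.quals[len(mid):],
                    individual_id=ind_id,
                ))
                break
        else:
            unassigned.append(read)
    return assigned, unassigned


def clean_reads(
    reads: list[ReadRecord],
    tag_length: int = 110,
    max_n_fraction: float = 0.10,
    residual_motif: str = "AATTC",
    keep_residual: bool = True,
) -> list[ReadRecord]:
    """Enforce the study's read-cleaning rules after MID removal.

    A read survives iff it starts with ``residual_motif`` (missing
    restriction site -> removed), is long enough to yield a full
    ``tag_length``-nt tag, and that trimmed tag has an N-fraction of at most
    ``max_n_fraction`` (strictly-greater fractions are removed). With
    ``keep_residual`` the tag starts at the residual (the usual RAD-tag
    convention), making the operation idempotent; otherwise the residual is
    stripped first.
    """
    if tag_length <= 0:
        raise ConfigurationError(f"tag_length must be > 0, got {tag_length}")
    res_len = len(residual_motif)
    offset = 0 if keep_residual else res_len
    out: list[ReadRecord] = []
    for read in reads:
        if residual_motif and not read.bases.startswith(residual_motif):
            continue
        if len(read.bases) < offset + tag_length:
            continue
        bases = read.bases[offset:offset + tag_length]
        if bases.count("N") / tag_length > max_n_fraction:
            continue
        out.append(replace(read, bases=bases,
                           quals=read.quals[offset:offset + tag_length]))
    return out


@dataclass(frozen=True)
class QualitySummary:
    """Counts and Q20/Q30 percentages for one read stream."""

    read_count: int
    base_count: int
    q20_pct: float
    q30_pct: float


def quality_summary(reads: list[ReadRecord]) -> QualitySummary:
    """Fraction of bases at or above Phred 20 / 30, as percentages."""
    if not reads:
        warnings.warn("quality_summary: empty read stream", stacklevel=2)
        return QualitySummary(0, 0, 0.0, 0.0)
    quals = np.concatenate([np.asarray(r.quals) for r in reads])
    total = quals.size
    return QualitySummary(
        read_count=len(reads),
        base_count=int(total),
        q20_pct=100.0 * int((quals >= 20).sum()) / total,
        q30_pct=100.0 * int((quals >= 30).sum()) / total,
    )
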