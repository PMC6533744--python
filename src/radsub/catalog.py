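"""Exact RAD-tag stacking and per-run summary statistics.

Identical cleaned reads are stacked into depth-annotated tags; because the
downstream subtractive screen works on exact 110-nt matches, no
mismatch-tolerant locus building is attempted. ``canonicalize`` collapses a
tag with its reverse complement so presence/absence comparisons are
strand-safe.

``summarize_run`` reproduces the derived columns of the study's
per-individual sequencing summary: mean tag depth = raw reads / distinct
tags, and sequence coverage = raw base pairs / genome size (the salamander
genome is ~50 Gb, hence the 5.0e10 default). Values are kept at full
precision internally and rounded half-up only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import pandas as pd

from .dna import canonical
from .errors import ValidationError
from .preprocess import ReadRecord

#: flow-cytometry genome-size estimate for Andrias davidianus, in bases
DEFAULT_GENOME_SIZE = 5.0e10


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (what the printed report tables use)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class TagCatalog:
    """Per-individual multiset of fixed-length tags."""

    individual_id: str
    counts: dict[str, int]
    reads_used: int

    @property
    def distinct_tags(self) -> int:
        return len(self.counts)

    @property
    def tag_set(self) -> set[str]:
        return set(self.counts)


def stack_tags(
    reads: Iterable[ReadRecord | str],
    individual_id: str = "",
    canonicalize: bool = False,
) -> TagCatalog:
    """Stack identical reads into a depth-annotated catalog.

    Accepts ReadRecords or bare sequences; all must be the same length.
    With ``canonicalize`` each sequence is replaced by the lexicographic
    minimum of itself and its reverse complement before stacking. Depth is
    conserved: sum(depths) == number of input reads.
    """
    counts: dict[str, int] = {}
    n = 0
    length: int | None = None
    for read in reads:
        seq = read if isinstance(read, str) else read.bases
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ValidationError(
                f"mixed-length input to stack_tags: {len(seq)} != {length}")
        if canonicalize:
            seq = canonical(seq)
        counts[seq] = counts.get(seq, 0) + 1
        n += 1
    return TagCatalog(individual_id=individual_id, counts=counts, reads_used=n)


@dataclass
class RunSummary:
    """One row of the per-individual sequencing summary."""

    individual_id: str
    sex: str
    reads: int
    base_pairs: int
    distinct_tags: int
    mean_depth: float
    coverage: float
    q20_pct: float
    q30_pct: float
    genome_size: float = DEFAULT_GENOME_SIZE


def summarize_run(
    catalog_or_tags: TagCatalog | int,
    raw_read_count: int,
    raw_base_count: int,
    q_summary=None,
    genome_size: float = DEFAULT_GENOME_SIZE,
    individual_id: str = "",
    sex: str = "",
) -> RunSummary:
    """Derive mean depth and coverage for one individual.

    ``catalog_or_tags`` is a TagCatalog or a bare distinct-tag count (so the
    published tag counts can be summarised without re-stacking). Mean depth
    is raw reads / distinct tags; a tagless run yields 0 with a warning.
    """
    import warnings

    if genome_size <= 0:
        raise ValidationError("genome_size must be > 0")
    if isinstance(catalog_or_tags, TagCatalog):
        tags = catalog_or_tags.distinct_tags
        individual_id = individual_id or catalog_or_tags.individual_id
    else:
        tags = int(catalog_or_tags)
    if tags == 0:
        warnings.warn("summarize_run: no tags; mean depth undefined, reporting 0",
                      stacklevel=2)
        depth = 0.0
    else:
        depth = raw_read_count / tags
    return RunSummary(
        individual_id=individual_id,
        sex=sex,
        reads=raw_read_count,
        base_pairs=raw_base_count,
        distinct_tags=tags,
        mean_depth=depth,
        coverage=raw_base_count / genome_size,
        q20_pct=getattr(q_summary, "q20_pct", float("nan")) if q_summary is not None else float("nan"),
        q30_pct=getattr(q_summary, "q30_pct", float("nan")) if q_summary is not None else float("nan"),
    )


def population_table(summaries: list[RunSummary]) -> pd.DataFrame:
    """Population report in the published layout: per-individual rows, then
    per-sex Subtotal/Subaverage rows, then Total/Average.

    Aggregates are computed from first principles over the per-row values
    (the published table's own aggregate rows are internally inconsistent,
    so they are recomputed rather than copied). Mean depth and coverage are
    rounded half-up to 1 and 2 decimals at this reporting boundary.
    """
    cols = ["individual_id", "sex", "reads", "base_pairs", "distinct_tags",
            "mean_depth", "coverage", "q20_pct", "q30_pct"]

    def row(s: RunSummary) -> dict:
        return {
            "individual_id": s.individual_id, "sex": s.sex, "reads": s.reads,
            "base_pairs": s.base_pairs, "distinct_tags": s.distinct_tags,
            "mean_depth": round_half_up(s.mean_depth, 1),
            "coverage": round_half_up(s.coverage, 2),
            "q20_pct": s.q20_pct, "q30_pct": s.q30_pct,
        }

    def agg(rows: list[RunSummary], label_sum: str, label_avg: str, sex: str) -> list[dict]:
        n = len(rows)
        if n == 0:
            return []
        sums = {
            "reads": sum(r.reads for r in rows),
            "base_pairs": sum(r.base_pairs for r in rows),
            "distinct_tags": sum(r.distinct_tags for r in rows),
            "mean_depth": sum(r.mean_depth for r in rows),
            "coverage": sum(r.coverage for r in rows),
        }
        subtotal = {"individual_id": label_sum, "sex": sex, **{
            k: (round_half_up(v, 2) if isinstance(v, float) else v)
            for k, v in sums.items()},
            "q20_pct": float("nan"), "q30_pct": float("nan")}
        subavg = {"individual_id": label_avg, "sex": sex,
                  "reads": round_half_up(sums["reads"] / n, 0),
                  "base_pairs": round_half_up(sums["base_pairs"] / n, 0),
                  "distinct_tags": round_half_up(sums["distinct_tags"] / n, 0),
                  "mean_depth": round_half_up(sums["mean_depth"] / n, 2),
                  "coverage": round_half_up(sums["coverage"] / n, 2),
                  "q20_pct": float("nan"), "q30_pct": float("nan")}
        return [subtotal, subavg]

    females = [s for s in summaries if s.sex == "female"]
    males = [s for s in summaries if s.sex == "male"]
    rows: list[dict] = [row(s) for s in females]
    rows += agg(females, "Subtotal", "Subaverage", "female")
    rows += [row(s) for s in males]
    rows += agg(males, "Subtotal", "Subaverage", "male")
    rows += agg(summaries, "Total", "Average", "all")
    return pd.DataFrame(rows, columns=cols)
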