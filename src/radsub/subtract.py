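"""The subtractive marker-discovery computation.

Two-stage presence/absence screen for sequences limited to the
heterogametic sex:

1. ``cross_sex_screen`` — every tag of the source sex is looked up, as an
   exact canonical 110-mer, in the tag sets of every opposite-sex
   individual; tags found nowhere in the opposite sex are *unmatched*.
   Unmatched tags seen in enough source individuals become candidates.
2. ``genome_filter`` — candidates are aligned (full-length, substitutions
   only) against the opposite sex's genome; candidates with no alignment at
   >= (1 - max_mismatch_fraction) identity on either strand are *unmapped*
   and constitute the final sex-specific markers.

Stage 2's search is an exact seed-and-extend: the query is split into
m + 1 disjoint seeds (m = allowed mismatches), so any qualifying alignment
contains at least one exact seed (pigeonhole) and the search provably finds
every hit the exhaustive Hamming scan would.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np

from .catalog import TagCatalog
from .dna import canonical, revcomp, validate_dna
from .errors import ConfigurationError, ValidationError


@dataclass(frozen=True)
class CandidateMarker:
    """A putative sex-specific tag and its filter status."""

    marker_id: str
    sequence: str
    source_sex: str
    n_source_individuals_present: int
    screen_status: str  # 'matched_opposite_reads' | 'unmatched'
    genome_status: str = "not_tested"  # 'mapped' | 'unmapped' | 'not_tested'

    def __post_init__(self) -> None:
        if self.genome_status != "not_tested" and self.screen_status != "unmatched":
            raise ValidationError(
                "only unmatched candidates may carry a genome status")


def _as_tag_sets(obj: Mapping[str, TagCatalog] | Mapping[str, Iterable[str]]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for ind, val in obj.items():
        out[ind] = set(val.counts) if isinstance(val, TagCatalog) else set(val)
    return out


def cross_sex_screen(
    source_catalogs: Mapping[str, TagCatalog],
    opposite_tagsets: Mapping[str, TagCatalog] | Mapping[str, Iterable[str]],
    source_sex: str = "female",
    min_source_individuals: int | None = None,
    min_depth: int = 1,
    canonicalize: bool = True,
) -> list[CandidateMarker]:
    """Screen one sex's tag universe against the other sex's reads.

    A tag is *matched* iff its (canonical) sequence occurs in any
    opposite-sex individual's tag set. Unmatched tags present at depth >=
    ``min_depth`` in at least ``min_source_individuals`` source individuals
    (default: all of them — a real sex-limited locus should be sequenced in
    every source animal) are returned as candidates, sorted by sequence.
    """
    if min_source_individuals is None:
        min_source_individuals = len(source_catalogs)

    def canon(s: str) -> str:
        return canonical(s) if canonicalize else s

    # per-source-individual canonical depth maps
    source_depths: dict[str, dict[str, int]] = {}
    lengths: set[int] = set()
    for ind, cat in source_catalogs.items():
        depths: dict[str, int] = {}
        for seq, d in cat.counts.items():
            lengths.add(len(seq))
            c = canon(seq)
            depths[c] = depths.get(c, 0) + d
        source_depths[ind] = depths

    opposite_union: set[str] = set()
    for ind, tags in _as_tag_sets(opposite_tagsets).items():
        for t in tags:
            lengths.add(len(t))
            opposite_union.add(canon(t))
    if len(lengths) > 1:
        raise ValidationError(
            f"tag lengths differ across catalogs: {sorted(lengths)}")

    universe: set[str] = set()
    for depths in source_depths.values():
        universe.update(depths)

    candidates: list[CandidateMarker] = []
    for seq in sorted(universe):
        n_present = sum(
            1 for depths in source_depths.values() if depths.get(seq, 0) >= min_depth)
        if seq in opposite_union:
            continue
        if n_present < min_source_individuals:
            continue
        candidates.append(CandidateMarker(
            marker_id="",  # assigned after sorting, below
            sequence=seq,
            source_sex=source_sex,
            n_source_individuals_present=n_present,
            screen_status="unmatched",
        ))
    prefix = {"female": "adf", "male": "adm"}.get(source_sex, source_sex[:1])
    return [replace(c, marker_id=f"{prefix}{i + 1:05d}")
            for i, c in enumerate(candidates)]


def _hamming_hit(genome: str, query: str, max_mm: int, seed_len: int,
                 index: dict[str, list[int]]) -> bool:
    """True iff *query* aligns somewhere in *genome* with <= max_mm
    substitutions, using m+1 disjoint exact seeds."""
    L = len(query)
    n_chunks = max_mm + 1
    stride = L // n_chunks
    for k in range(n_chunks):
        off = k * stride
        seed = query[off:off + seed_len]
        for pos in index.get(seed, ()):
            start = pos - off
            if start < 0 or start + L > len(genome):
                continue
            window = genome[start:start + L]
            mm = sum(a != b for a, b in zip(window, query))
            if mm <= max_mm:
                return True
    return False


def genome_filter(
    candidates: list[CandidateMarker],
    opposite_genome: str,
    max_mismatch_fraction: float = 0.10,
    seed_length: int = 20,
) -> list[CandidateMarker]:
    """Set each candidate's genome status against the opposite genome.

    A candidate is *mapped* iff it (or its reverse complement) aligns
    full-length to the genome with at most
    ``floor(max_mismatch_fraction * len)`` substitutions. ``seed_length``
    caps the exact-seed size; it is shrunk to ``len // (m + 1)`` when needed
    so the pigeonhole guarantee (and hence exactness of the search) holds.
    Unmapped candidates are the final sex-specific markers.
    """
    if not candidates:
        return []
    validate_dna(opposite_genome, "opposite_genome")
    L = len(candidates[0].sequence)
    if seed_length > L:
        raise ConfigurationError(
            f"seed_length {seed_length} exceeds tag length {L}")
    max_mm = int(max_mismatch_fraction * L)
    eff_seed = min(seed_length, L // (max_mm + 1))
    if eff_seed < 1:
        raise ConfigurationError("mismatch budget leaves no usable seed")

    index: dict[str, list[int]] = {}
    for i in range(len(opposite_genome) - eff_seed + 1):
        kmer = opposite_genome[i:i + eff_seed]
        index.setdefault(kmer, []).append(i)

    out: list[CandidateMarker] = []
    for cand in candidates:
        if cand.screen_status != "unmatched":
            out.append(cand)
            continue
        if len(cand.sequence) != L:
            raise ValidationError("candidates must share one tag length")
        hit = (_hamming_hit(opposite_genome, cand.sequence, max_mm, eff_seed, index)
               or _hamming_hit(opposite_genome, revcomp(cand.sequence), max_mm,
                               eff_seed, index))
        out.append(replace(cand, genome_status="mapped" if hit else "unmapped"))
    return out


def final_markers(candidates: list[CandidateMarker]) -> list[CandidateMarker]:
    """Candidates that survived both stages (genome-unmapped)."""
    return [c for c in candidates if c.genome_status == "unmapped"]


def select_candidates(
    markers: list[CandidateMarker], n: int, rng_seed: int
) -> list[CandidateMarker]:
    """Uniform without-replacement sample of min(n, len) markers,
    deterministic for a fixed seed, preserving original order."""
    if n <= 0:
        raise ConfigurationError(f"n must be > 0, got {n}")
    if n >= len(markers):
        return list(markers)
    rng = np.random.default_rng(rng_seed)
    idx = sorted(rng.choice(len(markers), size=n, replace=False))
    return [markers[i] for i in idx]
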