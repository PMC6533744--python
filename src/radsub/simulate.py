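"""Synthetic ddRAD population generator.

Emulates the sequencing design used for the salamander study population:
a large shared (autosomal + Z-like) genome carried by both sexes, plus a
small number of W-limited regions present only in females. Genomic DNA is
double-digested with an EcoRI-like and an NlaIII-like enzyme; fragments cut
once by each enzyme and falling in the gel window (400-600 bp including
75 bp of adapter) enter the library; each individual contributes 150 bp
paired-end reads whose read-1 starts with an inline MID barcode followed by
the EcoRI residual ``AATTC``.

Every W-limited region carries one engineered "cassette" — an EcoRI site, a
motif-free filler and an NlaIII site spaced so the resulting fragment passes
size selection — so the planted truth is discoverable downstream and usable
as a test oracle.

The model is single-stranded and coordinate-based. Because the EcoRI 5'
overhang cannot be represented by one cut coordinate for fragments whose
EcoRI end is on the right, each fragment also carries ``insert``: the
library insert oriented EcoRI-end first, including both restriction
residues (``AATTC ... CATG`` at the defaults). Reads are built from
``insert``; coordinates and size selection use the genomic slice.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .dna import find_occurrences, random_dna, revcomp, validate_dna, validate_motif
from .errors import ConfigurationError

#: MIDs used for the original eight salamanders, reused for small simulations
STUDY_FEMALE_MIDS = ("GCTAC", "CCTCT", "TAATC", "GGCTAC")
STUDY_MALE_MIDS = ("GCTTA", "TCCAC", "CTCC", "ACCTCT")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated ddRAD experiment.

    Lengths are in base pairs. ``select_min``/``select_max`` bound the *gel*
    fragment size, i.e. genomic insert + ``adapter_length``; at the defaults
    the retained insert window is 325-525 bp. ``mean_depth`` is the expected
    number of read pairs per size-selected fragment per individual
    (Poisson-distributed). ``error_rate`` is an i.i.d. per-base substitution
    probability applied to every emitted read base.
    """

    genome_length: int = 100_000
    n_females: int = 4
    n_males: int = 4
    n_w_regions: int = 3
    w_region_length: int = 2_000
    enzyme_a_site: str = "GAATTC"  # EcoRI, cuts G^AATTC
    enzyme_b_site: str = "CATG"    # NlaIII, cuts CATG^
    enzyme_a_cut: int = 1
    enzyme_b_cut: int = 4
    select_min: int = 400
    select_max: int = 600
    adapter_length: int = 75
    read_length: int = 150
    mean_depth: float = 5.0
    error_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("genome_length", "w_region_length", "select_min", "select_max",
                     "adapter_length", "read_length"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_females < 0 or self.n_males < 0 or self.n_w_regions < 0:
            raise ConfigurationError("counts must be non-negative")
        if self.select_min > self.select_max:
            raise ConfigurationError(
                f"select_min ({self.select_min}) must be <= select_max ({self.select_max})")
        if not (0.0 <= self.error_rate < 1.0):
            raise ConfigurationError(f"error_rate must be in [0, 1), got {self.error_rate}")
        if self.n_w_regions * self.w_region_length >= self.genome_length:
            raise ConfigurationError(
                "total W-region length must be smaller than the shared genome")
        validate_motif(self.enzyme_a_site, "enzyme_a_site")
        validate_motif(self.enzyme_b_site, "enzyme_b_site")
        if not (0 <= self.enzyme_a_cut <= len(self.enzyme_a_site)):
            raise ConfigurationError("enzyme_a_cut outside enzyme_a_site")
        if not (0 <= self.enzyme_b_cut <= len(self.enzyme_b_site)):
            raise ConfigurationError("enzyme_b_cut outside enzyme_b_site")
        if self.mean_depth <= 0:
            raise ConfigurationError("mean_depth must be > 0")


@dataclass(frozen=True)
class Individual:
    """One sequenced animal: id, genetic sex and inline barcode."""

    individual_id: str
    sex: str  # 'female' | 'male'
    mid: str

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ConfigurationError(f"sex must be 'female' or 'male', got {self.sex!r}")
        validate_motif(self.mid, f"MID of {self.individual_id}")


def default_individuals(config: SimConfig) -> list[Individual]:
    """n_females + n_males individuals with unique MIDs (the study barcodes
    for the first four of each sex, generated extensions beyond that)."""

    def mids(stock: tuple[str, ...], n: int, salt: int) -> list[str]:
        out = list(stock[:n])
        rng = np.random.default_rng(salt)
        while len(out) < n:
            cand = random_dna(rng, 6)
            if cand not in out:
                out.append(cand)
        return out

    females = [Individual(f"C{i + 1}", "female", m)
               for i, m in enumerate(mids(STUDY_FEMALE_MIDS, config.n_females, 101))]
    males = [Individual(f"X{i + 1}", "male", m)
             for i, m in enumerate(mids(STUDY_MALE_MIDS, config.n_males, 202))]
    all_mids = [ind.mid for ind in females + males]
    if len(set(all_mids)) != len(all_mids):
        raise ConfigurationError("generated MIDs collide; choose custom individuals")
    return females + males


@dataclass(frozen=True)
class Fragment:
    """A doubly-cut genomic fragment.

    ``start``/``end`` are 0-based half-open on ``source``;
    ``flank_left``/``flank_right`` are 'A' or 'B' (which enzyme produced
    each end); ``insert`` is the library insert oriented A-end first,
    including both restriction residues.
    """

    source: str
    start: int
    end: int
    sequence: str
    flank_left: str
    flank_right: str
    insert: str = ""

    def __post_init__(self) -> None:
        assert self.end - self.start == len(self.sequence)


@dataclass(frozen=True)
class WRegion:
    """Planted truth for one W-limited region."""

    region_id: str
    insertion_point: int     # offset in the shared genome (before insertion)
    sequence: str            # full W-region sequence
    cassette_fragment: str   # the A/B fragment the cassette digests to (A-end first)


@dataclass(frozen=True)
class GenomePair:
    """Male and female genomes sharing a backbone; females carry extras."""

    shared_sequence: str
    female_extra: tuple[tuple[int, str], ...]  # (insertion_point, sequence), increasing
    truth: tuple[WRegion, ...] = ()

    def __post_init__(self) -> None:
        points = [p for p, _ in self.female_extra]
        if points != sorted(points) or len(set(points)) != len(points):
            raise ConfigurationError("insertion points must be strictly increasing")

    @property
    def male_genome(self) -> str:
        return self.shared_sequence

    @property
    def female_genome(self) -> str:
        parts: list[str] = []
        prev = 0
        for point, seq in self.female_extra:
            parts.append(self.shared_sequence[prev:point])
            parts.append(seq)
            prev = point
        parts.append(self.shared_sequence[prev:])
        return "".join(parts)


def _motif_free_filler(rng: np.random.Generator, length: int, motifs: tuple[str, ...]) -> str:
    """Random DNA of *length* containing no occurrence of any motif."""
    for _ in range(1000):
        cand = random_dna(rng, length)
        if not any(m in cand for m in motifs):
            return cand
    raise ConfigurationError("could not draw a motif-free filler; motifs too dense")


def _build_cassette(rng: np.random.Generator, config: SimConfig) -> tuple[str, str]:
    """An enzyme-A..enzyme-B cassette whose single A/B fragment passes size
    selection. Returns (cassette, fragment_sequence)."""
    site_a, site_b = config.enzyme_a_site, config.enzyme_b_site
    lo = config.select_min - config.adapter_length
    hi = config.select_max - config.adapter_length
    residual_a = len(site_a) - config.enzyme_a_cut
    if lo > hi or hi < residual_a + config.enzyme_b_cut + 1:
        raise ConfigurationError("size-selection window admits no cassette fragment")
    lo = max(lo, residual_a + config.enzyme_b_cut + 1)
    for _ in range(1000):
        frag_len = int(rng.integers(lo, hi + 1))
        filler = _motif_free_filler(
            rng, frag_len - residual_a - config.enzyme_b_cut, (site_a, site_b))
        cassette = site_a + filler + site_b
        # junction-safety: the cassette must contain exactly one site of each
        # enzyme so it digests to a single clean A/B fragment
        if len(find_occurrences(cassette, site_a)) == 1 and \
           len(find_occurrences(cassette, site_b)) == 1:
            fragment = cassette[config.enzyme_a_cut:]
            return cassette, fragment
    raise ConfigurationError("could not build a clean cassette")


def build_genomes(config: SimConfig) -> GenomePair:
    """Generate the shared genome and plant ``n_w_regions`` W-limited
    regions, each carrying one size-selectable A/B cassette.

    Deterministic for a fixed ``rng_seed``. The returned ``truth`` records
    each region's insertion point, full sequence and the exact fragment its
    cassette digests to (EcoRI-end first), for downstream oracles.
    """
    rng = np.random.default_rng(config.rng_seed)
    shared = random_dna(rng, config.genome_length)

    margin = 10  # keep cassettes away from W-region edges (junction artefacts)
    extras: list[tuple[int, str]] = []
    truth: list[WRegion] = []
    if config.n_w_regions:
        points = np.sort(rng.choice(
            np.arange(1, config.genome_length - 1),
            size=config.n_w_regions, replace=False))
        for k, point in enumerate(points):
            cassette, fragment = _build_cassette(rng, config)
            pad = config.w_region_length - len(cassette)
            if pad < 2 * margin:
                raise ConfigurationError(
                    "w_region_length too small for a size-selectable cassette")
            left = int(rng.integers(margin, pad - margin + 1))
            region = (random_dna(rng, left) + cassette + random_dna(rng, pad - left))
            extras.append((int(point), region))
            truth.append(WRegion(f"W{k + 1}", int(point), region, fragment))
    return GenomePair(shared, tuple(extras), tuple(truth))


def digest_genome(
    sequence: str,
    site_a: str = "GAATTC",
    site_b: str = "CATG",
    cut_a: int = 1,
    cut_b: int = 4,
    source: str = "genome",
) -> list[Fragment]:
    """In-silico double digestion; returns only A/B-flanked fragments.

    Cut coordinates follow the enzymes' canonical offsets (EcoRI G^AATTC ->
    offset 1; NlaIII CATG^ -> offset 4). Fragments between two cuts of the
    same enzyme are real digestion products but never enter a ddRAD library
    (no adapter pair) and are excluded here; zero-length pieces between
    coincident cuts are likewise dropped.
    """
    validate_dna(sequence, "sequence")
    validate_motif(site_a, "site_a")
    validate_motif(site_b, "site_b")

    # Coincident cuts (e.g. CATGAATTC at the defaults) sort by how much of
    # the motif lies downstream of the cut: the enzyme whose motif sits
    # entirely upstream (NlaIII, residual 0) comes first, so the upstream
    # fragment keeps its B end and the downstream fragment its A end —
    # matching the chemistry of the two cut products.
    cuts_keyed = sorted(
        [(p + cut_a, len(site_a) - cut_a, "A")
         for p in find_occurrences(sequence, site_a)]
        + [(p + cut_b, len(site_b) - cut_b, "B")
           for p in find_occurrences(sequence, site_b)]
    )
    cuts = [(pos, lab) for pos, _, lab in cuts_keyed]
    frags: list[Fragment] = []
    for (c1, l1), (c2, l2) in zip(cuts, cuts[1:]):
        if l1 == l2 or c2 <= c1:
            continue
        seq = sequence[c1:c2]
        if l1 == "A":
            insert = seq  # starts with the A residual, ends with site_b
        else:
            # A end on the right: orient A-first and restore both residues
            # (the 4-nt A overhang and the B recognition bases flank the cut)
            ext = sequence[c1 - cut_b:c2 + (len(site_a) - cut_a - 1)]
            insert = revcomp(ext)
        frags.append(Fragment(source, c1, c2, seq, l1, l2, insert))
    return frags


def size_select(fragments: list[Fragment], config: SimConfig) -> list[Fragment]:
    """Gel size selection: keep fragments with
    select_min <= len(sequence) + adapter_length <= select_max (inclusive),
    preserving order."""
    lo = config.select_min - config.adapter_length
    hi = config.select_max - config.adapter_length
    return [f for f in fragments if lo <= len(f.sequence) <= hi]


@dataclass
class SimulatedRead:
    """One read pair as emitted by the sequencer model."""

    read_id: str
    individual_id: str
    bases1: str
    quals1: np.ndarray
    bases2: str
    quals2: np.ndarray


def _draw_quals(rng: np.random.Generator, n: int) -> np.ndarray:
    """Phred scores ~ round(N(36, 3)) clipped to [2, 40] — a crude but
    adequate stand-in for HiSeq base-quality profiles."""
    q = np.rint(rng.normal(36.0, 3.0, size=n)).astype(np.int64)
    return np.clip(q, 2, 40)


def _apply_errors(rng: np.random.Generator, bases: str, error_rate: float) -> str:
    if error_rate == 0.0:
        return bases
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < error_rate
    if hit.any():
        alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
        for i in np.nonzero(hit)[0]:
            choices = alphabet[alphabet != arr[i]]
            arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def _one_read(template: str, read_length: int) -> str:
    """Truncate/pad the template to the machine read length."""
    if len(template) >= read_length:
        return template[:read_length]
    return template + "A" * (read_length - len(template))  # adapter read-through


def simulate_reads(
    fragments: list[Fragment],
    individuals: list[Individual],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[SimulatedRead], dict[str, int]]:
    """Emit barcoded read pairs for every individual over *fragments*.

    Per fragment and individual the pair count is Poisson(mean_depth).
    Read-1 = MID + insert prefix (so it begins MID + 'AATTC' at the
    defaults); read-2 is the reverse complement end. Returns the reads in a
    deterministic order plus per-individual emitted counts.
    """
    mids = [ind.mid for ind in individuals]
    if len(set(mids)) != len(mids):
        raise ConfigurationError("duplicate MIDs across individuals")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 1)

    reads: list[SimulatedRead] = []
    counts: dict[str, int] = {ind.individual_id: 0 for ind in individuals}
    for ind in individuals:
        for fi, frag in enumerate(fragments):
            n = int(rng.poisson(config.mean_depth))
            for copy in range(n):
                b1 = _one_read(ind.mid + frag.insert, config.read_length)
                b2 = _one_read(revcomp(frag.insert), config.read_length)
                b1 = _apply_errors(rng, b1, config.error_rate)
                b2 = _apply_errors(rng, b2, config.error_rate)
                reads.append(SimulatedRead(
                    read_id=f"sim|{ind.individual_id}|frag{fi}|{copy}",
                    individual_id=ind.individual_id,
                    bases1=b1, quals1=_draw_quals(rng, len(b1)),
                    bases2=b2, quals2=_draw_quals(rng, len(b2)),
                ))
            counts[ind.individual_id] += n
    return reads, counts


@dataclass
class SimulatedPopulation:
    """Everything one simulation run produces, with planted truth."""

    config: SimConfig
    genomes: GenomePair
    individuals: list[Individual]
    male_fragments: list[Fragment] = field(default_factory=list)
    female_fragments: list[Fragment] = field(default_factory=list)
    reads: list[SimulatedRead] = field(default_factory=list)
    emitted_counts: dict[str, int] = field(default_factory=dict)

    @property
    def truth_tags(self) -> list[str]:
        """Planted cassette fragments as they appear after read trimming
        (first ``tag`` bases of the A-oriented fragment); full fragments
        returned — slice to the tag length downstream."""
        return [w.cassette_fragment for w in self.genomes.truth]


def simulate_population(
    config: SimConfig,
    individuals: list[Individual] | None = None,
) -> SimulatedPopulation:
    """End-to-end generator: genomes -> digestion -> size selection ->
    barcoded reads for every individual. Deterministic for fixed config."""
    if individuals is None:
        individuals = default_individuals(config)
    genomes = build_genomes(config)
    dig = dict(site_a=config.enzyme_a_site, site_b=config.enzyme_b_site,
               cut_a=config.enzyme_a_cut, cut_b=config.enzyme_b_cut)
    male_frags = size_select(
        digest_genome(genomes.male_genome, source="male", **dig), config)
    female_frags = size_select(
        digest_genome(genomes.female_genome, source="female", **dig), config)

    rng = np.random.default_rng(config.rng_seed + 1)
    females = [i for i in individuals if i.sex == "female"]
    males = [i for i in individuals if i.sex == "male"]
    f_reads, f_counts = simulate_reads(female_frags, females, config, rng)
    m_reads, m_counts = simulate_reads(male_frags, males, config, rng)
    return SimulatedPopulation(
        config=config, genomes=genomes, individuals=list(individuals),
        male_fragments=male_frags, female_fragments=female_frags,
        reads=f_reads + m_reads, emitted_counts={**f_counts, **m_counts},
    )
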