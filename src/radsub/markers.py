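"""Marker application: in-silico PCR, presence/absence genotyping, genetic
sex calls and reversal detection.

Under a ZW system a validated female-limited (W-linked) marker amplifies in
genetic females only, so a PCR band is read as genetic female and its
absence as genetic male; an XY male-limited marker is the mirror image.
Discordance between marker-inferred genetic sex and gonadal phenotypic sex
flags a sex-reversed individual (e.g. after rearing at elevated temperature
or 17beta-estradiol exposure).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .dna import revcomp, validate_dna, validate_motif
from .errors import ConfigurationError, ValidationError
from .subtract import CandidateMarker

MIN_PRIMER_LENGTH = 15


@dataclass(frozen=True)
class PrimerPair:
    """One validated marker's primer pair; temperatures are metadata only."""

    name: str
    forward_seq: str
    reverse_seq: str
    expected_product_bp: int
    forward_tm_c: float = float("nan")
    reverse_tm_c: float = float("nan")

    def __post_init__(self) -> None:
        for label, seq in (("forward", self.forward_seq), ("reverse", self.reverse_seq)):
            validate_motif(seq, f"{self.name} {label} primer")
            if len(seq) < MIN_PRIMER_LENGTH:
                raise ValidationError(
                    f"{self.name} {label} primer shorter than {MIN_PRIMER_LENGTH} nt")
        if self.expected_product_bp < len(self.forward_seq) + len(self.reverse_seq):
            raise ValidationError(
                f"{self.name}: product size smaller than the two primers")


@dataclass(frozen=True)
class PcrProduct:
    """One predicted amplicon, in plus-strand template coordinates."""

    start: int
    end: int  # half-open; product_length == end - start
    strand: str  # '+' if the forward primer sits on the plus strand

    @property
    def product_length(self) -> int:
        return self.end - self.start


def _match_with_3prime_anchor(template: str, primer: str, pos: int,
                              max_mm: int, anchor_last: bool) -> bool:
    """Does *primer* match template[pos:pos+len] with <= max_mm mismatches
    and an exact 3'-terminal base? The 3' base is the last primer base for a
    forward primer and maps to the *first* base of the reverse-complemented
    reverse primer."""
    window = template[pos:pos + len(primer)]
    if len(window) != len(primer):
        return False
    if anchor_last:
        if window[-1] != primer[-1]:
            return False
    else:
        if window[0] != primer[0]:
            return False
    mm = sum(a != b for a, b in zip(window, primer))
    return mm <= max_mm


def _scan_one_strand(template: str, forward: str, reverse: str,
                     max_product_bp: int, max_mm: int) -> list[tuple[int, int]]:
    lf, lr = len(forward), len(reverse)
    rev_rc = revcomp(reverse)
    fwd_pos = [i for i in range(len(template) - lf + 1)
               if _match_with_3prime_anchor(template, forward, i, max_mm, True)]
    rev_pos = [j for j in range(len(template) - lr + 1)
               if _match_with_3prime_anchor(template, rev_rc, j, max_mm, False)]
    hits = []
    for i in fwd_pos:
        for j in rev_pos:
            if j >= i + lf and (j + lr) - i <= max_product_bp:
                hits.append((i, j + lr))
    return hits


def insilico_pcr(
    primers: PrimerPair,
    template: str,
    max_product_bp: int = 2000,
    max_primer_mismatches: int = 0,
) -> list[PcrProduct]:
    """Predict every amplicon of *primers* on *template*.

    A product is an interval where the forward primer matches one strand and
    the reverse complement of the reverse primer matches downstream within
    ``max_product_bp``, each with at most ``max_primer_mismatches``
    substitutions and an exactly matching 3'-terminal base (extension
    chemistry tolerates internal mismatches far better than 3' ones). Both
    template strands are tested; coordinates are reported on the plus
    strand, duplicates merged, sorted by position.
    """
    validate_dna(template, "template")
    L = len(template)
    products: dict[tuple[int, int], PcrProduct] = {}
    for start, end in _scan_one_strand(template, primers.forward_seq,
                                       primers.reverse_seq, max_product_bp,
                                       max_primer_mismatches):
        products.setdefault((start, end), PcrProduct(start, end, "+"))
    rc = revcomp(template)
    for start, end in _scan_one_strand(rc, primers.forward_seq,
                                       primers.reverse_seq, max_product_bp,
                                       max_primer_mismatches):
        key = (L - end, L - start)
        products.setdefault(key, PcrProduct(L - end, L - start, "-"))
    return [products[k] for k in sorted(products)]


@dataclass
class GenotypeMatrix:
    """Complete individuals x markers presence grid (True = band)."""

    matrix: pd.DataFrame
    errors: dict[str, str] = field(default_factory=dict)

    def band(self, individual_id: str, marker: str) -> bool:
        return bool(self.matrix.loc[individual_id, marker])


def genotype_panel(
    individual_templates: Mapping[str, str | Iterable[str] | None],
    panel: list[PrimerPair],
    size_tolerance_bp: int = 5,
    max_product_bp: int = 2000,
    max_primer_mismatches: int = 0,
) -> GenotypeMatrix:
    """Genotype every individual against every panel marker.

    A template source is a genome/amplicon string or an iterable of tag
    sequences (each tried as a template). A band is called iff some product
    lands within ``size_tolerance_bp`` of the marker's expected size (the
    gel-resolution analog). Missing templates are recorded as errors and
    genotyped band-negative so the matrix stays complete.
    """
    ids = list(individual_templates)
    data: dict[str, list[bool]] = {p.name: [] for p in panel}
    errors: dict[str, str] = {}
    for ind in ids:
        source = individual_templates[ind]
        templates: list[str]
        if source is None:
            errors[ind] = "missing template"
            templates = []
        elif isinstance(source, str):
            templates = [source]
        else:
            templates = list(source)
        for primer in panel:
            band = False
            for tpl in templates:
                if len(tpl) < len(primer.forward_seq) + len(primer.reverse_seq):
                    continue
                for prod in insilico_pcr(primer, tpl, max_product_bp,
                                         max_primer_mismatches):
                    if abs(prod.product_length - primer.expected_product_bp) <= size_tolerance_bp:
                        band = True
                        break
                if band:
                    break
            data[primer.name].append(band)
    matrix = pd.DataFrame(data, index=pd.Index(ids, name="individual_id"),
                          columns=[p.name for p in panel])
    return GenotypeMatrix(matrix=matrix, errors=errors)


SEX_SYSTEMS = ("ZW_female_marker", "XY_male_marker")


def call_genetic_sex(
    genotypes: GenotypeMatrix | pd.DataFrame,
    system: str = "ZW_female_marker",
) -> dict[str, str]:
    """Call genetic sex per individual by majority vote across the panel.

    Under ``ZW_female_marker`` a band votes female and its absence male
    (mirror-image under ``XY_male_marker``); vote ties — including an empty
    panel — yield 'indeterminate'.
    """
    if system not in SEX_SYSTEMS:
        raise ConfigurationError(
            f"unknown sex system {system!r}; expected one of {SEX_SYSTEMS}")
    matrix = genotypes.matrix if isinstance(genotypes, GenotypeMatrix) else genotypes
    band_sex, no_band_sex = (("female", "male") if system == "ZW_female_marker"
                             else ("male", "female"))
    calls: dict[str, str] = {}
    for ind, row in matrix.iterrows():
        bands = int(row.sum())
        absences = len(row) - bands
        if bands > absences:
            calls[str(ind)] = band_sex
        elif absences > bands:
            calls[str(ind)] = no_band_sex
        else:
            calls[str(ind)] = "indeterminate"
    return calls


@dataclass(frozen=True)
class Reversal:
    individual_id: str
    direction: str  # 'female_to_male' | 'male_to_female' (genetic -> phenotypic)


@dataclass
class ReversalReport:
    """Cross-tabulation of phenotypic vs genetic sex plus discordant ids.

    ``direction`` reads genetic -> phenotypic: a genetic female with male
    gonads is a 'female_to_male' reversal.
    """

    crosstab: pd.DataFrame  # rows: phenotypic sex, cols: genetic sex
    reversals: list[Reversal]

    @property
    def n_female_to_male(self) -> int:
        return sum(1 for r in self.reversals if r.direction == "female_to_male")

    @property
    def n_male_to_female(self) -> int:
        return sum(1 for r in self.reversals if r.direction == "male_to_female")


def detect_reversals(
    genetic: Mapping[str, str], phenotypic: Mapping[str, str]
) -> ReversalReport:
    """Compare genetic and phenotypic sex over the same individuals.

    Indeterminate genetic calls appear in the cross-tab but are never
    listed as reversals. Counts are conserved: the cross-tab sums to the
    group size.
    """
    if set(genetic) != set(phenotypic):
        missing = set(genetic) ^ set(phenotypic)
        raise ValidationError(f"id sets differ between calls and phenotypes: {sorted(missing)}")
    ids = sorted(genetic)
    df = pd.DataFrame({
        "phenotypic": [phenotypic[i] for i in ids],
        "genetic": [genetic[i] for i in ids],
    }, index=ids)
    crosstab = pd.crosstab(df["phenotypic"], df["genetic"])
    reversals: list[Reversal] = []
    for ind in ids:
        g, p = genetic[ind], phenotypic[ind]
        if g == "indeterminate" or g == p:
            continue
        if g == "female" and p == "male":
            reversals.append(Reversal(ind, "female_to_male"))
        elif g == "male" and p == "female":
            reversals.append(Reversal(ind, "male_to_female"))
    return ReversalReport(crosstab=crosstab, reversals=reversals)


def markers_to_primers(
    markers: list[CandidateMarker], primer_length: int = 20
) -> list[PrimerPair]:
    """Derive a naive primer pair from each discovered marker: forward =
    first ``primer_length`` nt, reverse = revcomp of the last
    ``primer_length`` nt, expected product = the full tag length."""
    panel: list[PrimerPair] = []
    for m in markers:
        if len(m.sequence) < 2 * primer_length:
            raise ConfigurationError(
                f"marker {m.marker_id} shorter than two primer lengths")
        panel.append(PrimerPair(
            name=m.marker_id,
            forward_seq=m.sequence[:primer_length],
            reverse_seq=revcomp(m.sequence[-primer_length:]),
            expected_product_bp=len(m.sequence),
        ))
    return panel
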