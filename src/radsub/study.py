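"""Published study inputs for the Andrias davidianus marker panel.

Three small data sets printed in the original report are shipped with the
package as TSV resources and dictionaries:

* the per-individual sequencing summary for the eight RAD-sequenced
  salamanders (reads, base pairs, MIDs, distinct tags, derived statistics);
* the four validated female-specific primer pairs (adf225/adf318/adf340/
  adf431) with expected product sizes;
* the band patterns of the two sex-reversal experiments — 12 females + 12
  males reared at elevated temperature scored with adf340, and 20 females +
  3 males exposed to 17beta-estradiol scored with adf431.

Individual identities within each reversal group were not published; ids
here are synthetic labels, only the per-group counts are real.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .dna import random_dna, revcomp
from .markers import PrimerPair, insilico_pcr


def sequencing_summary() -> pd.DataFrame:
    """Per-individual sequencing summary of the eight study animals, as
    printed (derived columns included verbatim, inconsistencies and all)."""
    with resources.files("radsub.data").joinpath("sequencing_summary.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def primer_panel() -> dict[str, PrimerPair]:
    """The four validated female-specific primer pairs, keyed by marker."""
    with resources.files("radsub.data").joinpath("primer_panel.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return {
        row.marker: PrimerPair(
            name=row.marker,
            forward_seq=row.forward_seq,
            reverse_seq=row.reverse_seq,
            expected_product_bp=int(row.product_bp),
            forward_tm_c=float(row.forward_tm_c),
            reverse_tm_c=float(row.reverse_tm_c),
        )
        for row in df.itertuples()
    }


def temperature_group() -> tuple[dict[str, bool], dict[str, str], str]:
    """Elevated-temperature experiment: (band by id, phenotypic sex by id,
    marker name). All 12 phenotypic females banded with adf340; 3 of 12
    phenotypic males banded (genetic females reversed to male)."""
    bands: dict[str, bool] = {}
    phenotype: dict[str, str] = {}
    for i in range(1, 13):
        bands[f"T_F{i:02d}"] = True
        phenotype[f"T_F{i:02d}"] = "female"
    for i in range(1, 13):
        bands[f"T_M{i:02d}"] = i <= 3
        phenotype[f"T_M{i:02d}"] = "male"
    return bands, phenotype, "adf340"


def estradiol_group() -> tuple[dict[str, bool], dict[str, str], str]:
    """17beta-estradiol experiment: 13 of 20 phenotypic females showed no
    adf431 band (genetic males reversed to female); the 3 phenotypic males
    showed none."""
    bands: dict[str, bool] = {}
    phenotype: dict[str, str] = {}
    for i in range(1, 21):
        bands[f"E_F{i:02d}"] = i <= 7  # 7 banded, 13 band-negative
        phenotype[f"E_F{i:02d}"] = "female"
    for i in range(1, 4):
        bands[f"E_M{i:02d}"] = False
        phenotype[f"E_M{i:02d}"] = "male"
    return bands, phenotype, "adf431"


def synthetic_group_templates(
    bands: dict[str, bool],
    primer: PrimerPair,
    rng: np.random.Generator,
    flank: int = 60,
    negative_length: int = 400,
) -> dict[str, str]:
    """Synthetic per-individual DNA templates reproducing a band pattern.

    Band-positive individuals receive a random template embedding the
    marker's amplicon (forward primer + random core + revcomp(reverse
    primer), flanked by random DNA); band-negative individuals receive
    random DNA verified to yield no product. Purely a stand-in for the
    unpublished genomic DNA of the experimental animals.
    """
    core_len = primer.expected_product_bp - len(primer.forward_seq) - len(primer.reverse_seq)
    templates: dict[str, str] = {}
    for ind in bands:
        if bands[ind]:
            amplicon = (primer.forward_seq + random_dna(rng, core_len)
                        + revcomp(primer.reverse_seq))
            templates[ind] = (random_dna(rng, flank) + amplicon
                              + random_dna(rng, flank))
        else:
            for _ in range(100):
                cand = random_dna(rng, negative_length)
                if not insilico_pcr(primer, cand):
                    templates[ind] = cand
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError("could not draw a product-free template")
    return templates
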