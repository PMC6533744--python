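"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (regex scans, all-pairs loops, full
sliding-window comparisons) and shares no code with the package internals
it checks.
"""

from __future__ import annotations

import re

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def ham(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def digest_oracle(seq: str, site_a: str = "GAATTC", site_b: str = "CATG",
                  cut_a: int = 1, cut_b: int = 4) -> list[tuple[int, int, str, str]]:
    """All A/B-flanked fragments via an exhaustive all-pairs scan.

    A fragment [c1, c2) is valid iff c1 and c2 come from different enzymes,
    c2 > c1, and no cut falls strictly inside. Coincident cuts of the two
    enzymes are ordered by the length of motif remaining downstream of the
    cut (the enzyme whose motif lies upstream cuts 'first').
    """
    cuts = []
    for motif, off, lab in ((site_a, cut_a, "A"), (site_b, cut_b, "B")):
        for m in re.finditer(f"(?={motif})", seq):
            cuts.append((m.start() + off, len(motif) - off, lab))
    frags = []
    for c1, r1, l1 in cuts:
        for c2, r2, l2 in cuts:
            if l1 == l2 or c2 <= c1:
                continue
            if any(c1 < p < c2 for p, _, _ in cuts):
                continue
            # coincident-cut adjacency: nothing may sort between the two
            if any(p == c1 and (r, l) > (r1, l1) for p, r, l in cuts if l != l1):
                continue
            if any(p == c2 and (r, l) < (r2, l2) for p, r, l in cuts if l != l2):
                continue
            frags.append((c1, c2, l1, l2))
    return sorted(frags)


def hamming_scan_min(genome: str, query: str) -> int:
    """Minimum Hamming distance of *query* over every plus-strand offset."""
    L = len(query)
    if len(genome) < L:
        return L + 1
    g = np.frombuffer(genome.encode(), dtype=np.uint8)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(g, L)
    return int((windows != q).sum(axis=1).min())


def maps_oracle(genome: str, query: str, max_mm: int) -> bool:
    """True iff query or its reverse complement aligns with <= max_mm
    substitutions anywhere in the genome (exhaustive scan)."""
    return (hamming_scan_min(genome, query) <= max_mm
            or hamming_scan_min(genome, rc(query)) <= max_mm)


def pcr_oracle(forward: str, reverse: str, template: str,
               max_product_bp: int = 2000, max_mm: int = 0) -> set[tuple[int, int]]:
    """Every amplicon interval on the plus strand, via a full sliding-window
    scan of both strands with the 3'-terminal-base exactness rule."""
    out: set[tuple[int, int]] = set()
    L = len(template)
    rev = rc(reverse)
    for strand, seq in (("+", template), ("-", rc(template))):
        fpos = [i for i in range(L - len(forward) + 1)
                if seq[i + len(forward) - 1] == forward[-1]
                and ham(seq[i:i + len(forward)], forward) <= max_mm]
        rpos = [j for j in range(L - len(rev) + 1)
                if seq[j] == rev[0] and ham(seq[j:j + len(rev)], rev) <= max_mm]
        for i in fpos:
            for j in rpos:
                if j >= i + len(forward) and j + len(rev) - i <= max_product_bp:
                    s, e = i, j + len(rev)
                    out.add((s, e) if strand == "+" else (L - e, L - s))
    return out
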