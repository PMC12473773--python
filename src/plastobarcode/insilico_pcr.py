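"""In-silico PCR: primer site location, amplicon extraction, amplification rates.

Pure string matching on linear templates: a primer anneals where it matches
with at most ``max_mismatch`` mismatches and perfectly over its 3'-terminal
``three_prime_exact`` bases (polymerase extension is 3'-critical). A primer
base matches a template IUPAC code iff the base belongs to the code's set.
No thermodynamic modelling.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .plastome_structure import revcomp

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

DEFAULT_MAX_MISMATCH = 2
DEFAULT_THREE_PRIME_EXACT = 3
DEFAULT_MAX_PRODUCT = 5000


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str
    reverse: str
    max_mismatch: int = DEFAULT_MAX_MISMATCH
    three_prime_exact: int = DEFAULT_THREE_PRIME_EXACT
    max_product: int = DEFAULT_MAX_PRODUCT

    def __post_init__(self):
        for primer in (self.forward, self.reverse):
            if len(primer) < 10:
                raise ValueError("primers must be at least 10 bases")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if self.three_prime_exact > min(len(self.forward), len(self.reverse)):
            raise ValueError("three_prime_exact exceeds primer length")


#: Published Phoebe-specific primer pairs for the two best barcode loci.
PHOEBE_PRIMERS: dict[str, PrimerPair] = {
    "rpl32-trnL": PrimerPair(
        "rpl32-trnL", forward="GCGAGATGGGGGTTGTAACT", reverse="AGTATCATGGCAGGGGGTCA"
    ),
    "ycf1": PrimerPair(
        "ycf1", forward="TGACCCCTTAACCAGTTTTTCCA", reverse="CTGAAACCCTGGCGCAAATC"
    ),
}


@dataclass(frozen=True)
class PrimerSite:
    start: int
    strand: str  # '+' or '-'
    n_mismatch: int

    @property
    def interval(self) -> tuple[int, int]:
        raise AttributeError("length unknown at site level; see amplify")


def _match_matrix(template: str, primer: str) -> np.ndarray:
    """mismatch[k, t]: primer base k mismatches template position t."""
    tmpl = np.frombuffer(template.upper().encode("ascii"), dtype=np.uint8)
    out = np.empty((len(primer), len(template)), dtype=bool)
    for k, base in enumerate(primer.upper()):
        allowed = np.zeros(256, dtype=bool)
        for code, members in IUPAC_SETS.items():
            if base in members:
                allowed[ord(code)] = True
        out[k] = ~allowed[tmpl]
    return out


def _scan(template: str, primer: str, max_mismatch: int, exact_idx: range) -> list[tuple[int, int]]:
    """(offset, n_mismatch) for each admissible placement of ``primer``."""
    m, n = len(primer), len(template)
    if n < m:
        return []
    mis = _match_matrix(template, primer)
    n_off = n - m + 1
    total = np.zeros(n_off, dtype=np.int32)
    exact = np.zeros(n_off, dtype=np.int32)
    for k in range(m):
        col = mis[k, k : k + n_off]
        total += col
        if k in exact_idx:
            exact += col
    hits = np.flatnonzero((total <= max_mismatch) & (exact == 0))
    return [(int(o), int(total[o])) for o in hits]


def find_primer_sites(
    template: str,
    primer: str,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    three_prime_exact: int = DEFAULT_THREE_PRIME_EXACT,
) -> list[PrimerSite]:
    """All annealing sites of the primer on either strand, sorted by start.

    On the plus strand the primer's 3' end is the rightmost matched base; on
    the minus strand (the reverse complement is matched against the template)
    it is the leftmost, so the exact-match window flips accordingly.
    """
    if len(template) < len(primer):
        raise ValueError("template shorter than primer")
    m = len(primer)
    k = min(three_prime_exact, m)
    sites = [
        PrimerSite(off, "+", nm)
        for off, nm in _scan(template, primer, max_mismatch, range(m - k, m))
    ]
    sites += [
        PrimerSite(off, "-", nm)
        for off, nm in _scan(template, revcomp(primer), max_mismatch, range(0, k))
    ]
    return sorted(sites, key=lambda s: (s.start, s.strand))


def amplify(template: str, pair: PrimerPair) -> list[tuple[int, int]]:
    """Amplicon intervals (inclusive of both primer footprints), 0-based half-open.

    A product forms from a plus-strand forward site and a minus-strand reverse
    site whose footprints do not overlap (forward 3' end upstream of the
    reverse 3' end) with total length at most ``max_product``.
    """
    fwd = [
        s for s in find_primer_sites(template, pair.forward, pair.max_mismatch, pair.three_prime_exact)
        if s.strand == "+"
    ]
    rev = [
        s for s in find_primer_sites(template, pair.reverse, pair.max_mismatch, pair.three_prime_exact)
        if s.strand == "-"
    ]
    lf, lr = len(pair.forward), len(pair.reverse)
    products = []
    for f in fwd:
        for r in rev:
            if f.start + lf > r.start:
                continue
            length = r.start + lr - f.start
            if length <= pair.max_product:
                products.append((f.start, r.start + lr))
    return sorted(products, key=lambda iv: (iv[0], iv[1] - iv[0]))


@dataclass(frozen=True)
class AmplificationRate:
    rate: float
    n_amplified: int
    n_templates: int


def amplification_rate(templates: Sequence[str], pair: PrimerPair) -> AmplificationRate:
    """Fraction of templates yielding at least one product."""
    if not templates:
        raise ValueError("no templates")
    n_ok = sum(1 for t in templates if amplify(t, pair))
    return AmplificationRate(n_ok / len(templates), n_ok, len(templates))


def extract_amplicons(template: str, pair: PrimerPair) -> list[str]:
    return [template[s:e] for s, e in amplify(template, pair)]
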