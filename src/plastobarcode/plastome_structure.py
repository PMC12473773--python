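"""Quadripartite plastome structure: IR detection, junctions, summaries.

Plastomes are organised as LSC | IRb | SSC | IRa, where the two inverted
repeats are exact reverse complements of each other. Detection works on the
linear sequence as given (NCBI plastomes are conventionally rotated so both
IRs are internal); wrap-around repeats raise an explicit error.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

from .seq_io import Feature

Interval = tuple[int, int]

_RC_TABLE = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


@dataclass(frozen=True)
class QuadripartiteAnnotation:
    lsc: Interval
    irb: Interval
    ssc: Interval
    ira: Interval
    ir_length: int

    def __post_init__(self):
        if self.ira[1] - self.ira[0] != self.ir_length or self.irb[1] - self.irb[0] != self.ir_length:
            raise ValueError("IR intervals inconsistent with ir_length")
        if self._len(self.lsc) < self._len(self.ssc):
            raise ValueError("LSC shorter than SSC")

    @staticmethod
    def _len(iv: Interval) -> int:
        return iv[1] - iv[0]

    @property
    def lsc_length(self) -> int:
        return self._len(self.lsc)

    @property
    def ssc_length(self) -> int:
        return self._len(self.ssc)

    @property
    def genome_length(self) -> int:
        return self.lsc_length + self.ssc_length + 2 * self.ir_length


@dataclass(frozen=True)
class PlastomeSummary:
    length_bp: int
    gc_fraction: float
    n_cds: int
    n_trna: int
    n_rrna: int


def gc_content(sequence: str) -> float:
    """(G+C) / (A+C+G+T); ambiguity codes and gaps are excluded entirely."""
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("no unambiguous bases in sequence")
    return gc / (gc + at)


# ----------------------------------------------------------------- IR search

def _hash_positions(seq: str, length: int, base: int, mod: int) -> dict[int, list[int]]:
    """Rolling-hash positions of every substring of ``length`` in ``seq``."""
    n = len(seq)
    out: dict[int, list[int]] = {}
    if length > n:
        return out
    h = 0
    power = pow(base, length - 1, mod)
    vals = [ord(c) for c in seq]
    for i in range(length):
        h = (h * base + vals[i]) % mod
    out.setdefault(h, []).append(0)
    for i in range(1, n - length + 1):
        h = ((h - vals[i - 1] * power) * base + vals[i + length - 1]) % mod
        out.setdefault(h, []).append(i)
    return out


def _disjoint(a: Interval, b: Interval) -> bool:
    return a[1] <= b[0] or b[1] <= a[0]


def _pairs_at_length(genome: str, rc: str, length: int, first_only: bool) -> list[tuple[Interval, Interval]]:
    """All (earlier, later) disjoint interval pairs that are reverse complements."""
    n = len(genome)
    base, mod = 1_000_003, (1 << 61) - 1
    table = _hash_positions(genome, length, base, mod)
    pairs: set[tuple[Interval, Interval]] = set()
    h = 0
    power = pow(base, length - 1, mod)
    vals = [ord(c) for c in rc]
    for i in range(length):
        h = (h * base + vals[i]) % mod
    for p in range(0, n - length + 1):
        if p > 0:
            h = ((h - vals[p - 1] * power) * base + vals[p + length - 1]) % mod
        # rc[p:p+length] corresponds to genome interval [n-p-length, n-p)
        j0 = n - p - length
        b: Interval = (j0, j0 + length)
        for i in table.get(h, ()):
            a: Interval = (i, i + length)
            if not _disjoint(a, b):
                continue
            first, second = (a, b) if a[0] < b[0] else (b, a)
            # verify (guards against hash collisions)
            if genome[second[0] : second[1]] != revcomp(genome[first[0] : first[1]]):
                continue
            pairs.add((first, second))
            if first_only:
                return [(first, second)]
    return sorted(pairs)


def detect_inverted_repeat(
    genome: str, min_len: int = 1000
) -> tuple[Interval, Interval]:
    """Longest pair of disjoint intervals that are exact reverse complements.

    Returns ``(irb, ira)``: if the gap between the repeats is the shorter
    single-copy region the earlier repeat is IRb (the canonical
    LSC-IRb-SSC-IRa layout), otherwise labels follow position order.
    Ties at the maximal length break leftmost-longest.
    """
    genome = genome.upper()
    n = len(genome)
    if n < 2 * min_len:
        raise ValueError("genome shorter than twice min_len")
    rc = revcomp(genome)
    if not _pairs_at_length(genome, rc, min_len, first_only=True):
        raise ValueError(f"no inverted repeat of length >= {min_len} found")
    lo, hi = min_len, n // 2
    # binary search the largest length with at least one disjoint rc-pair
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _pairs_at_length(genome, rc, mid, first_only=True):
            lo = mid
        else:
            hi = mid - 1
    candidates = _pairs_at_length(genome, rc, lo, first_only=False)
    # leftmost-longest tie-break; earlier repeat is IRb in the canonical
    # LSC-IRb-SSC-IRa layout, and labels follow position order otherwise
    first, second = min(candidates)
    return first, second


def partition_quadripartite(
    genome_length: int, irb: Interval, ira: Interval
) -> QuadripartiteAnnotation:
    """Label the two single-copy gaps between the IRs as LSC (longer) and SSC."""
    first, second = sorted([tuple(irb), tuple(ira)])
    if not _disjoint(first, second):
        raise ValueError("overlapping IR intervals")
    if not (0 <= first[0] and second[1] <= genome_length):
        raise ValueError("IR intervals outside genome")
    head = (0, first[0])
    middle = (first[1], second[0])
    tail = (second[1], genome_length)
    head_len = head[1] - head[0]
    tail_len = tail[1] - tail[0]
    if head_len > 0 and tail_len > 0:
        raise ValueError(
            "single-copy region wraps the origin; rotate genome first"
        )
    outer = head if head_len > 0 else tail
    gaps = [outer, middle]
    lens = [g[1] - g[0] for g in gaps]
    if lens[0] == lens[1]:
        warnings.warn("equal-length single-copy regions; gap containing position 0 labelled LSC")
        lsc, ssc = (gaps[0], gaps[1]) if gaps[0][0] == 0 else (gaps[1], gaps[0])
    elif lens[0] > lens[1]:
        lsc, ssc = gaps[0], gaps[1]
    else:
        lsc, ssc = gaps[1], gaps[0]
    # the earlier repeat is IRb (it precedes the SSC in the canonical layout;
    # when the outer gap is the SSC, labels simply follow position order)
    out_irb, out_ira = first, second
    ir_length = first[1] - first[0]
    if second[1] - second[0] != ir_length:
        raise ValueError("IR intervals of unequal length")
    return QuadripartiteAnnotation(lsc=lsc, irb=out_irb, ssc=ssc, ira=out_ira, ir_length=ir_length)


Junction = Literal["IRb/LSC", "IRb/SSC", "SSC/IRa", "IRa/LSC"]

_JUNCTION_REGIONS: dict[str, tuple[str, str]] = {
    "IRb/LSC": ("irb", "lsc"),
    "IRb/SSC": ("irb", "ssc"),
    "SSC/IRa": ("ssc", "ira"),
    "IRa/LSC": ("ira", "lsc"),
}


def junction_coordinate(annotation: QuadripartiteAnnotation, junction: str) -> int:
    """The genome coordinate of a named region boundary.

    For the IRa/LSC junction of a genome starting with the LSC the adjacency
    is circular; the boundary is then reported at the genome end.
    """
    if junction not in _JUNCTION_REGIONS:
        raise ValueError(f"unknown junction {junction!r}")
    ra, rb = _JUNCTION_REGIONS[junction]
    a: Interval = getattr(annotation, ra)
    b: Interval = getattr(annotation, rb)
    if a[1] == b[0]:
        return a[1]
    if b[1] == a[0]:
        return b[1]
    # circular adjacency: one region ends where the genome does, the other starts at 0
    n = annotation.genome_length
    if (a[1] == n and b[0] == 0) or (b[1] == n and a[0] == 0):
        return n
    raise ValueError(f"regions {ra} and {rb} are not adjacent in this annotation")


def junction_distance(
    feature: Feature, annotation: QuadripartiteAnnotation, junction: str
) -> int:
    """Signed distance from the feature edge nearest the junction.

    Positive when the feature lies clear of the junction, zero when an edge
    coincides with it, and negative (the overlap depth) when the feature spans
    the junction. Circular adjacency (IRa/LSC at the origin) is evaluated at
    both coordinate images and the smaller magnitude is returned.
    """
    j = junction_coordinate(annotation, junction)
    images = [j]
    if j == annotation.genome_length:
        images.append(0)

    def _signed(jc: int) -> int:
        if feature.start < jc < feature.end:
            return -min(jc - feature.start, feature.end - jc)
        if jc <= feature.start:
            return feature.start - jc
        return jc - feature.end

    return min((_signed(jc) for jc in images), key=abs)


def summarize_plastome(sequence: str, features: list[Feature]) -> PlastomeSummary:
    kinds = [f.kind for f in features]
    return PlastomeSummary(
        length_bp=len(sequence),
        gc_fraction=gc_content(sequence),
        n_cds=kinds.count("CDS"),
        n_trna=kinds.count("tRNA"),
        n_rrna=kinds.count("rRNA"),
    )
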