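"""K2P distances, barcoding-gap summaries and identification success rates.

The Kimura two-parameter distance is d = -1/2 ln((1-2P-Q) sqrt(1-2Q)) with
P and Q the transition and transversion proportions over comparable sites.
Saturated pairs (log argument <= 0) carry an explicit undefined flag rather
than a number. The identification success rate (ISR) is reported under two
criteria: strict nearest-neighbour best match, and tree monophyly.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import phylo
from .diversity_scan import usable_columns
from .seq_io import LabelledAlignment, concat_loci

Masking = Literal["complete", "pairwise"]
SingletonPolicy = Literal["exclude", "count_fail"]


@dataclass(frozen=True)
class SitePairCounts:
    n: int
    ts: int
    tv: int

    def __post_init__(self):
        if self.ts + self.tv > self.n or min(self.n, self.ts, self.tv) < 0:
            raise ValueError("inconsistent site-pair counts")


def classify_site_pairs(
    a: str,
    b: str,
    masking: Masking = "pairwise",
    usable: np.ndarray | Sequence[int] | None = None,
) -> SitePairCounts:
    """Count comparable sites, transitions (A<->G, C<->T) and transversions.

    With ``masking='complete'`` the caller supplies the globally usable column
    set via ``usable`` (a pair in isolation cannot know it).
    """
    if len(a) != len(b):
        raise ValueError("sequences of unequal length")
    from .seq_io import _CODE_TABLE

    ca = _CODE_TABLE[np.frombuffer(a.upper().encode("ascii"), dtype=np.uint8)]
    cb = _CODE_TABLE[np.frombuffer(b.upper().encode("ascii"), dtype=np.uint8)]
    ok = (ca < 4) & (cb < 4)
    if masking == "complete":
        if usable is None:
            raise ValueError("complete masking requires the global usable-column set")
        sel = np.zeros(len(a), dtype=bool)
        sel[np.asarray(usable)] = True
        ok &= sel
    return _count_pairs(ca, cb, ok)


def _count_pairs(ca: np.ndarray, cb: np.ndarray, ok: np.ndarray) -> SitePairCounts:
    # with A,C,G,T coded 0..3, a substitution is a transition iff |a-b| == 2
    da = np.abs(ca[ok].astype(np.int8) - cb[ok].astype(np.int8))
    return SitePairCounts(n=int(ok.sum()), ts=int((da == 2).sum()), tv=int((da % 2 == 1).sum()))


def k2p_distance(counts: SitePairCounts) -> float | None:
    """K2P distance, or None when the pair is saturated or has no sites."""
    if counts.n == 0:
        return None
    # integer arithmetic first so exact saturation (1-2P-Q == 0) is detected
    w1 = (counts.n - 2 * counts.ts - counts.tv) / counts.n
    w2 = (counts.n - 2 * counts.tv) / counts.n
    if w1 <= 0.0 or w2 <= 0.0:
        return None
    return -0.5 * math.log(w1 * math.sqrt(w2))


@dataclass(frozen=True)
class DistanceMatrix:
    sample_ids: tuple[str, ...]
    d: np.ndarray
    defined: np.ndarray

    def __post_init__(self):
        n = len(self.sample_ids)
        if self.d.shape != (n, n) or self.defined.shape != (n, n):
            raise ValueError("matrix shape does not match sample ids")
        if not np.allclose(self.d[self.defined], self.d.T[self.defined]):
            raise ValueError("distance matrix not symmetric")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def all_defined(self) -> bool:
        off = ~np.eye(self.n, dtype=bool)
        return bool(self.defined[off].all())

    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(self.n, k=1)
        return int((~self.defined[iu]).sum())


def distance_matrix(alignment: LabelledAlignment, masking: Masking = "complete") -> DistanceMatrix:
    """All-pairs K2P matrix; complete deletion by default (toolchain default)."""
    codes = alignment.to_codes()
    n = codes.shape[0]
    if masking == "complete":
        global_ok = usable_columns(codes)
    d = np.zeros((n, n))
    defined = np.ones((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            ok = (codes[i] < 4) & (codes[j] < 4)
            if masking == "complete":
                ok &= global_ok
            dist = k2p_distance(_count_pairs(codes[i], codes[j], ok))
            if dist is None:
                defined[i, j] = defined[j, i] = False
                d[i, j] = d[j, i] = np.nan
            else:
                d[i, j] = d[j, i] = dist
    return DistanceMatrix(tuple(alignment.sample_ids), d, defined)


@dataclass(frozen=True)
class DistanceSummary:
    intra_min: float | None
    intra_max: float | None
    intra_mean: float | None
    inter_min: float | None
    inter_max: float | None
    inter_mean: float | None

    @property
    def gap_margin(self) -> float | None:
        """inter_min - intra_max; positive means a clean barcoding gap."""
        if self.inter_min is None or self.intra_max is None:
            return None
        return self.inter_min - self.intra_max


def intra_inter_summary(D: DistanceMatrix, partition: Mapping[str, str]) -> DistanceSummary:
    """Min/max/mean of within- and between-species distances (defined pairs only)."""
    species = [partition[s] for s in D.sample_ids]
    intra, inter = [], []
    for i in range(D.n):
        for j in range(i + 1, D.n):
            if not D.defined[i, j]:
                continue
            (intra if species[i] == species[j] else inter).append(D.d[i, j])

    def _stats(vals: list[float]) -> tuple[float | None, float | None, float | None]:
        if not vals:
            return None, None, None
        return float(min(vals)), float(max(vals)), float(np.mean(vals))

    if not intra:
        warnings.warn("no intraspecific pairs; intra fields undefined")
    if not inter:
        warnings.warn("no interspecific pairs; inter fields undefined")
    i_min, i_max, i_mean = _stats(intra)
    e_min, e_max, e_mean = _stats(inter)
    return DistanceSummary(i_min, i_max, i_mean, e_min, e_max, e_mean)


@dataclass(frozen=True)
class ISRResult:
    isr: float | None
    n_identified: int
    n_evaluated: int
    per_sample: dict


def isr_nearest_neighbor(
    D: DistanceMatrix,
    partition: Mapping[str, str],
    singleton_policy: SingletonPolicy = "exclude",
) -> ISRResult:
    """Strict best-match ISR: a sample is identified iff every sample at its
    minimum defined distance is conspecific. Ties with a heterospecific fail."""
    species = [partition[s] for s in D.sample_ids]
    counts: dict[str, int] = {}
    for sp in species:
        counts[sp] = counts.get(sp, 0) + 1
    per_sample: dict[str, bool | None] = {}
    n_ident = n_eval = 0
    for i, sid in enumerate(D.sample_ids):
        if counts[species[i]] == 1:
            if singleton_policy == "exclude":
                per_sample[sid] = None
                continue
            per_sample[sid] = False
            n_eval += 1
            continue
        mask = D.defined[i].copy()
        mask[i] = False
        n_eval += 1
        if not mask.any():
            per_sample[sid] = False  # no defined distance to anything
            continue
        row = np.where(mask, D.d[i], np.inf)
        best = row.min()
        hits = np.flatnonzero(row == best)
        ok = all(species[j] == species[i] for j in hits)
        per_sample[sid] = ok
        n_ident += int(ok)
    isr = n_ident / n_eval if n_eval else None
    return ISRResult(isr, n_ident, n_eval, per_sample)


def isr_tree_monophyly(
    tree,
    partition: Mapping[str, str],
    singleton_policy: SingletonPolicy = "exclude",
) -> ISRResult:
    """Per-individual ISR under the tree criterion: all individuals of a
    species that forms an exclusive clade count as identified."""
    leaf_names = set(tree.leaf_names())
    if leaf_names != set(partition):
        raise ValueError("tree leaves do not match the species partition")
    by_species: dict[str, set[str]] = {}
    for sid, sp in partition.items():
        by_species.setdefault(sp, set()).add(sid)
    per_species: dict[str, bool | None] = {}
    n_ident = n_eval = 0
    for sp, members in sorted(by_species.items()):
        if len(members) == 1:
            if singleton_policy == "exclude":
                per_species[sp] = None
                continue
            per_species[sp] = False
            n_eval += 1
            continue
        mono = phylo.is_monophyletic(tree, members)
        per_species[sp] = mono
        n_eval += len(members)
        n_ident += len(members) if mono else 0
    isr = n_ident / n_eval if n_eval else None
    return ISRResult(isr, n_ident, n_eval, per_species)


def evaluate_combinations(
    loci: Mapping[str, LabelledAlignment],
    partition: Mapping[str, str],
    masking: Masking = "complete",
    isr: Literal["nn", "tree", "both"] = "both",
    singleton_policy: SingletonPolicy = "exclude",
) -> pd.DataFrame:
    """One row per non-empty locus subset (2^k - 1 rows), Table-1 style.

    Rows are ordered by subset size then by the position of each locus as
    provided. Columns: combination, n_loci, intra/inter min-max-mean,
    gap_margin, isr_nn, isr_tree, n_undefined.
    """
    names = list(loci)
    rows = []
    for size in range(1, len(names) + 1):
        for subset in itertools.combinations(range(len(names)), size):
            order = [names[k] for k in subset]
            aln, _ = concat_loci(loci, order)
            D = distance_matrix(aln, masking=masking)
            summary = intra_inter_summary(D, partition)
            row: dict = {
                "combination": " + ".join(order),
                "n_loci": size,
                "intra_min": summary.intra_min,
                "intra_max": summary.intra_max,
                "intra_mean": summary.intra_mean,
                "inter_min": summary.inter_min,
                "inter_max": summary.inter_max,
                "inter_mean": summary.inter_mean,
                "gap_margin": summary.gap_margin,
                "isr_nn": None,
                "isr_tree": None,
                "n_undefined": D.n_undefined_pairs(),
            }
            if isr in ("nn", "both"):
                row["isr_nn"] = isr_nearest_neighbor(D, partition, singleton_policy).isr
            if isr in ("tree", "both") and D.all_defined and D.n >= 3:
                tree = phylo.bionj(D)
                row["isr_tree"] = isr_tree_monophyly(tree, partition, singleton_policy).isr
            rows.append(row)
    return pd.DataFrame(rows)
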