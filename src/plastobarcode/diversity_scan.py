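"""Sliding-window nucleotide diversity (Pi) and divergence-hotspot calling.

Pi here is the uncorrected average pairwise difference proportion (Nei's
nucleotide diversity as DnaSP reports it, without multiple-hit correction).
The default masking policy is complete deletion: an alignment column is
excluded for everyone if any sequence carries a gap or ambiguity there.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .seq_io import Feature, LabelledAlignment

Masking = Literal["complete", "pairwise"]

DEFAULT_WINDOW = 800
DEFAULT_STEP = 100
DEFAULT_PI_THRESHOLD = 0.005


@dataclass(frozen=True)
class Window:
    start: int
    end: int
    midpoint: int
    pi: float
    n_sites_used: int
    defined: bool = True


@dataclass(frozen=True)
class DiversityProfile:
    windows: tuple[Window, ...]
    window: int
    step: int
    masking: Masking = "complete"


@dataclass(frozen=True)
class Hotspot:
    start: int
    end: int
    peak_pi: float
    mean_pi: float
    name: str = ""


def usable_columns(codes: np.ndarray, masking: Masking = "complete") -> np.ndarray:
    """Boolean mask of columns usable under complete deletion."""
    if masking != "complete":
        raise ValueError("column-level usability is only defined for complete deletion")
    return (codes < 4).all(axis=0)


def pairwise_diff_fraction(
    a: str, b: str, usable: Sequence[int] | np.ndarray | None = None
) -> float | None:
    """Proportion of differing sites among columns where both bases are A/C/G/T.

    ``usable`` restricts the comparison to the given columns (e.g. the globally
    usable set under complete deletion); ``None`` means pairwise deletion.
    Returns None when no usable column remains.
    """
    if len(a) != len(b):
        raise ValueError("sequences of unequal length")
    xa = np.frombuffer(a.upper().encode("ascii"), dtype=np.uint8)
    xb = np.frombuffer(b.upper().encode("ascii"), dtype=np.uint8)
    from .seq_io import _CODE_TABLE

    ca, cb = _CODE_TABLE[xa], _CODE_TABLE[xb]
    ok = (ca < 4) & (cb < 4)
    if usable is not None:
        sel = np.zeros(len(a), dtype=bool)
        sel[np.asarray(usable)] = True
        ok &= sel
    n = int(ok.sum())
    if n == 0:
        return None
    return int((ca[ok] != cb[ok]).sum()) / n


def nucleotide_diversity(
    alignment: LabelledAlignment,
    columns: Sequence[int] | np.ndarray | None = None,
    masking: Masking = "complete",
) -> float | None:
    """Average pairwise difference proportion over all unordered pairs.

    Deliberately computed pair by pair (the reference route); the windowed
    scanner uses an allele-count shortcut and is cross-checked against this.
    """
    codes = alignment.to_codes()
    n, L = codes.shape
    sel = np.ones(L, dtype=bool)
    if columns is not None:
        sel = np.zeros(L, dtype=bool)
        sel[np.asarray(columns)] = True
    if masking == "complete":
        sel &= usable_columns(codes)
        sub = codes[:, sel]
        n_sites = sub.shape[1]
        if n_sites == 0:
            return None
        total = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                total += int((sub[i] != sub[j]).sum()) / n_sites
        return total / (n * (n - 1) / 2)
    # pairwise deletion: each pair uses its own usable set
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            ok = (codes[i] < 4) & (codes[j] < 4) & sel
            m = int(ok.sum())
            if m:
                vals.append(int((codes[i, ok] != codes[j, ok]).sum()) / m)
    if not vals:
        return None
    return float(np.mean(vals))


def _per_column_diff_pairs(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(differing-pair count per column, usable-column mask), complete deletion."""
    n = codes.shape[0]
    ok = usable_columns(codes)
    counts = np.stack([(codes == b).sum(axis=0) for b in range(4)])
    diff_pairs = (n * n - (counts.astype(np.int64) ** 2).sum(axis=0)) / 2.0
    diff_pairs[~ok] = 0.0
    return diff_pairs, ok


def sliding_window_pi(
    alignment: LabelledAlignment,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    masking: Masking = "complete",
) -> DiversityProfile:
    """Pi in windows starting at 0, step, 2*step, ...; only full windows emitted."""
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    L = alignment.length
    codes = alignment.to_codes()
    n = codes.shape[0]
    n_pairs = n * (n - 1) / 2
    if masking == "complete":
        diff_pairs, ok = _per_column_diff_pairs(codes)
        cum_diff = np.concatenate([[0.0], np.cumsum(diff_pairs)])
        cum_ok = np.concatenate([[0], np.cumsum(ok)])

        def _window_pi(s: int, e: int) -> tuple[float, int, bool]:
            used = int(cum_ok[e] - cum_ok[s])
            if used == 0:
                return 0.0, 0, False
            return float((cum_diff[e] - cum_diff[s]) / (n_pairs * used)), used, True

    else:

        def _window_pi(s: int, e: int) -> tuple[float, int, bool]:
            pi = nucleotide_diversity(alignment, columns=range(s, e), masking="pairwise")
            if pi is None:
                return 0.0, 0, False
            # report the union of per-pair usable sites as column count
            used = int(((codes[:, s:e] < 4).sum(axis=0) >= 2).sum())
            return pi, used, True

    windows: list[Window] = []
    if L < window:
        warnings.warn(
            f"alignment length {L} shorter than window {window}; emitting one full-length window"
        )
        pi, used, defined = _window_pi(0, L)
        windows.append(Window(0, L, L // 2, pi, used, defined))
    else:
        for s in range(0, L - window + 1, step):
            pi, used, defined = _window_pi(s, s + window)
            windows.append(Window(s, s + window, s + window // 2, pi, used, defined))
    return DiversityProfile(tuple(windows), window=window, step=step, masking=masking)


def mean_pi(alignment: LabelledAlignment, masking: Masking = "complete") -> float | None:
    """Whole-alignment nucleotide diversity under the masking policy."""
    return nucleotide_diversity(alignment, masking=masking)


def call_hotspots(
    profile: DiversityProfile, threshold: float = DEFAULT_PI_THRESHOLD
) -> list[Hotspot]:
    """Merge super-threshold windows (pi > threshold) into maximal intervals."""
    if not profile.windows:
        raise ValueError("empty diversity profile")
    selected = [w for w in profile.windows if w.defined and w.pi > threshold]
    hotspots: list[Hotspot] = []
    group: list[Window] = []

    def _flush():
        if group:
            hotspots.append(
                Hotspot(
                    start=group[0].start,
                    end=group[-1].end,
                    peak_pi=max(w.pi for w in group),
                    mean_pi=float(np.mean([w.pi for w in group])),
                )
            )

    for w in selected:
        if group and w.start <= group[-1].end:
            group.append(w)
        else:
            _flush()
            group = [w]
    _flush()
    return hotspots


def name_hotspots(hotspots: Sequence[Hotspot], features: Sequence[Feature]) -> list[Hotspot]:
    """Name hotspots from overlapping genes, or flanking genes for intergenic spans."""
    named = []
    feats = sorted(features, key=lambda f: (f.start, f.end))
    for k, h in enumerate(hotspots, start=1):
        overlapping = [f.gene for f in feats if f.start < h.end and f.end > h.start]
        if overlapping:
            seen: list[str] = []
            for g in overlapping:
                if g not in seen:
                    seen.append(g)
            name = "-".join(seen)
        elif feats:
            left = [f.gene for f in feats if f.end <= h.start]
            right = [f.gene for f in feats if f.start >= h.end]
            parts = ([left[-1]] if left else []) + ([right[0]] if right else [])
            name = "-".join(parts) if parts else f"hotspot_{k}"
        else:
            name = f"hotspot_{k}"
        named.append(replace(h, name=name))
    return named
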