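"""Genome masks: interval algebra, mappability and low-complexity masking.

A :class:`GenomeMask` is a per-sequence set of sorted, disjoint, 0-based
half-open intervals.  Two masks matter downstream of variant calling here:

* the *low-mappability* mask — positions where fewer than half of the
  covering read-length k-mers occur uniquely in the reference, where
  "unique" means the canonical k-mer sequence occurs exactly once in the
  canonical k-mer multiset of the whole reference;
* the *low-complexity* mask — homopolymer runs of 7 bp or longer, merged
  with windows flagged by a DUST-style trinucleotide score and any external
  repeat annotation supplied as BED, every interval extended by 10 bp flanks.

Long-indel calls overlapping the union of the two are discarded.
"""

from __future__ import annotations

import os
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

Interval = tuple[int, int]

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def canonical(seq: str) -> str:
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def _merge(intervals: list[Interval]) -> list[Interval]:
    """Sort and merge overlapping or touching intervals."""
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if e <= s:
            continue
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class GenomeMask:
    intervals: dict[str, list[Interval]] = field(default_factory=dict)
    label: str = "mask"

    def __post_init__(self) -> None:
        self.intervals = {c: _merge(list(ivs)) for c, ivs in self.intervals.items()}

    def add(self, chrom: str, start: int, end: int) -> None:
        ivs = self.intervals.setdefault(chrom, [])
        ivs.append((start, end))
        self.intervals[chrom] = _merge(ivs)

    def contains(self, chrom: str, pos: int) -> bool:
        return self.overlaps(chrom, pos, pos + 1)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        ivs = self.intervals.get(chrom, [])
        if not ivs:
            return False
        starts = [s for s, _ in ivs]
        i = int(np.searchsorted(starts, end)) - 1
        for j in range(max(i, 0), -1, -1):
            s, e = ivs[j]
            if e <= start:
                break
            if s < end and start < e:
                return True
        return False

    def total_bp(self) -> int:
        return sum(e - s for ivs in self.intervals.values() for s, e in ivs)

    def union(self, other: "GenomeMask", label: str = "merged") -> "GenomeMask":
        merged: dict[str, list[Interval]] = {}
        for c in set(self.intervals) | set(other.intervals):
            merged[c] = _merge(self.intervals.get(c, []) + other.intervals.get(c, []))
        return GenomeMask(merged, label=label)

    def subtract(self, other: "GenomeMask", label: str | None = None) -> "GenomeMask":
        out: dict[str, list[Interval]] = {}
        for c, ivs in self.intervals.items():
            cut = other.intervals.get(c, [])
            kept: list[Interval] = []
            for s, e in ivs:
                pieces = [(s, e)]
                for cs, ce in cut:
                    nxt: list[Interval] = []
                    for ps, pe in pieces:
                        if ce <= ps or cs >= pe:
                            nxt.append((ps, pe))
                            continue
                        if ps < cs:
                            nxt.append((ps, cs))
                        if ce < pe:
                            nxt.append((ce, pe))
                    pieces = nxt
                kept.extend(pieces)
            if kept:
                out[c] = _merge(kept)
        return GenomeMask(out, label=label or self.label)

    def to_bed(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals):
                for s, e in self.intervals[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{self.label}\n")

    @classmethod
    def from_bed(cls, path: str | os.PathLike, label: str = "bed") -> "GenomeMask":
        ivs: dict[str, list[Interval]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                ivs.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
        return cls(ivs, label=label)


def merge_masks(*masks: GenomeMask, label: str = "merged") -> GenomeMask:
    out = GenomeMask({}, label=label)
    for m in masks:
        out = out.union(m, label=label)
    return out


def mappability_mask(reference: dict[str, str], read_len: int = 151,
                     min_unique_ratio: float = 0.5) -> GenomeMask:
    """Mask positions where < ``min_unique_ratio`` of covering k-mers are unique.

    Every ``read_len``-mer of the reference is counted in canonical form
    (lexicographic min of the k-mer and its reverse complement) over all
    sequences jointly; a k-mer is unique iff its canonical count is exactly 1.
    The per-position ratio divides by the number of k-mers actually covering
    the position, which shrinks toward sequence ends.
    """
    k = read_len
    counts: Counter[str] = Counter()
    for seq in reference.values():
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            counts[canonical(seq[i:i + k])] += 1

    mask = GenomeMask({}, label="mappability")
    for chrom, seq in reference.items():
        seq = seq.upper()
        n = len(seq)
        if n < k:
            warnings.warn(f"{chrom}: shorter than {k} bp, wholly masked")
            mask.add(chrom, 0, n)
            continue
        nstart = n - k + 1
        unique = np.fromiter(
            (counts[canonical(seq[i:i + k])] == 1 for i in range(nstart)),
            dtype=np.int64, count=nstart)
        cum = np.concatenate(([0], np.cumsum(unique)))
        pos = np.arange(n)
        lo = np.maximum(pos - k + 1, 0)
        hi = np.minimum(pos, nstart - 1)
        total = hi - lo + 1
        uniq = cum[hi + 1] - cum[lo]
        bad = (uniq / total) < min_unique_ratio
        for s, e in _runs(bad):
            mask.add(chrom, s, e)
    return mask


def _runs(flags: np.ndarray) -> list[Interval]:
    """Maximal runs of True as 0-based half-open intervals."""
    if not flags.any():
        return []
    padded = np.concatenate(([False], flags, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def dust_score(window: str) -> float:
    """DUST-style low-complexity score from trinucleotide counts.

    score = sum_t c_t (c_t - 1) / 2 / (n_triplets - 1); perfectly periodic
    sequence scores high, random sequence stays near 0.5.
    """
    n = len(window) - 2
    if n < 2:
        return 0.0
    c = Counter(window[i:i + 3] for i in range(n))
    return sum(v * (v - 1) / 2 for v in c.values()) / (n - 1)


def low_complexity_mask(reference: dict[str, str], flank: int = 10,
                        min_homopolymer: int = 7,
                        dust_window: int = 64, dust_step: int = 32,
                        dust_threshold: float = 2.0,
                        repeat_bed: GenomeMask | None = None) -> GenomeMask:
    """Homopolymers >= 7 bp, DUST-flagged windows and optional external repeat
    annotation, each interval extended by ``flank`` bp and merged."""
    core: dict[str, list[Interval]] = {}
    homo_re = re.compile(r"A{%d,}|C{%d,}|G{%d,}|T{%d,}" % ((min_homopolymer,) * 4))
    for chrom, seq in reference.items():
        seq = seq.upper()
        ivs: list[Interval] = [m.span() for m in homo_re.finditer(seq)]
        for start in range(0, max(len(seq) - 2, 1), dust_step):
            win = seq[start:start + dust_window]
            if len(win) < 3:
                break
            if dust_score(win) > dust_threshold:
                ivs.append((start, start + len(win)))
        if ivs:
            core[chrom] = _merge(ivs)
    if repeat_bed is not None:
        for chrom, ivs in repeat_bed.intervals.items():
            core.setdefault(chrom, []).extend(ivs)

    lengths = {c: len(s) for c, s in reference.items()}
    flanked: dict[str, list[Interval]] = {}
    for chrom, ivs in core.items():
        n = lengths.get(chrom)
        out = []
        for s, e in ivs:
            s2 = max(0, s - flank)
            e2 = e + flank if n is None else min(n, e + flank)
            out.append((s2, e2))
        flanked[chrom] = _merge(out)
    return GenomeMask(flanked, label="complexity")
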