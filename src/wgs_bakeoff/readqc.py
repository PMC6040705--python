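"""Raw-read quality control from the 23-mer spectrum.

Five parameters summarize a run: the fraction of read pairs free of adapters
and Ns, the fraction of pairs with both mates retained at mean Q >= 20, the
fraction of erroneous 23-mers, the estimated mean coverage of the
non-repetitive genome, and the variance coefficient of coverage (sd/mean).
A sample passes the inclusion gate iff

    frac_pairs_clean >= 0.95,  frac_pairs_retained >= 0.95,
    frac_kmers_error <= 0.15,  coverage_mode >= 27.

Coverage is estimated from the canonical k-mer multiplicity histogram: the
low-multiplicity error peak is cut at the first local minimum m, the main
peak M = argmax above m tracks the k-mer coverage, and moments over the
symmetric window (m, 2M - m] estimate the mean and spread of coverage in
non-repetitive sequence.  K-mer coverage converts to base coverage by
L / (L - k + 1): a read of length L contributes L - k + 1 k-mers.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from .synth import ReadPair, TRUSEQ_ADAPTER

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i


@dataclass
class KmerSpectrum:
    k: int
    counts: dict[int, int]  # multiplicity -> number of distinct canonical k-mers

    @property
    def total_kmers(self) -> int:
        return sum(m * c for m, c in self.counts.items())

    @property
    def total_distinct(self) -> int:
        return sum(self.counts.values())

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        mults = np.array(sorted(self.counts), dtype=np.int64)
        return mults, np.array([self.counts[int(m)] for m in mults], dtype=np.int64)

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("multiplicity\tdistinct_kmers\n")
            for m in sorted(self.counts):
                fh.write(f"{m}\t{self.counts[m]}\n")


@dataclass
class RawReadQCReport:
    frac_pairs_clean: float
    frac_pairs_retained: float
    frac_kmers_error: float
    est_mean_coverage: float
    coverage_mode: float
    variance_coefficient: float
    passed: bool = False
    failed_criteria: list[str] = field(default_factory=list)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _read_kmer_codes(seq: str, k: int) -> np.ndarray:
    """Canonical k-mer integer codes of one read; N-containing windows skipped."""
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = win @ powers
    rc = (3 - win)[:, ::-1] @ powers
    return np.minimum(fwd, rc)[valid]


def count_kmers(reads: Iterable[str], k: int = 23) -> KmerSpectrum:
    """Canonical k-mer multiplicity spectrum over a collection of reads."""
    chunks: list[np.ndarray] = []
    short_warned = False
    for seq in reads:
        if len(seq) < k and not short_warned:
            warnings.warn(f"reads shorter than k={k}: empty contribution")
            short_warned = True
        chunks.append(_read_kmer_codes(seq, k))
    if not chunks:
        return KmerSpectrum(k=k, counts={})
    allc = np.concatenate(chunks)
    if allc.size == 0:
        return KmerSpectrum(k=k, counts={})
    _, mult = np.unique(allc, return_counts=True)
    ms, cs = np.unique(mult, return_counts=True)
    return KmerSpectrum(k=k, counts={int(m): int(c) for m, c in zip(ms, cs)})


def error_boundary(spectrum: KmerSpectrum) -> int:
    """First local minimum m of the spectrum, scanning multiplicity upward.

    The boundary separates the low-multiplicity error peak from the coverage
    peak; counts at absent multiplicities are zero and the left neighbor of
    multiplicity 1 is treated as infinite.
    """
    if not spectrum.counts:
        raise ValueError("empty spectrum")
    max_m = max(spectrum.counts)
    c = np.zeros(max_m + 2, dtype=np.int64)
    for m, v in spectrum.counts.items():
        c[m] = v
    for i in range(1, max_m + 1):
        left = np.inf if i == 1 else c[i - 1]
        if c[i] <= left and c[i] < c[i + 1]:
            return i
    return 0


def estimate_coverage_stats(spectrum: KmerSpectrum, read_length: int,
                            ) -> tuple[float, float, float]:
    """(coverage_mode, est_mean_coverage, variance_coefficient) in base space."""
    if not spectrum.counts:
        raise ValueError("empty spectrum")
    m = error_boundary(spectrum)
    mults, counts = spectrum.as_arrays()
    above = mults > m
    if not above.any():
        raise ValueError("no coverage peak above the error boundary: "
                         "uninterpretable spectrum")
    peak_mults, peak_counts = mults[above], counts[above]
    M = int(peak_mults[np.argmax(peak_counts)])
    if m == 0 and M == int(mults.min()):
        # monotone-decreasing spectrum: errors only, no coverage peak
        raise ValueError("no coverage peak above the error boundary: "
                         "uninterpretable spectrum")
    window = (mults > m) & (mults <= 2 * M - m)
    w_m = mults[window].astype(float)
    w_c = counts[window].astype(float)
    mean_k = float(np.average(w_m, weights=w_c))
    sd_k = float(np.sqrt(np.average((w_m - mean_k) ** 2, weights=w_c)))
    factor = read_length / (read_length - spectrum.k + 1)
    # Erroneous k-mers still came from sequenced bases of the genome: scale
    # the error-free peak mean back up by the retained-instance fraction so
    # the estimate tracks total coverage rather than error-free coverage.
    total = spectrum.total_kmers
    err = sum(mult * c for mult, c in spectrum.counts.items() if mult <= m)
    retained_frac = 1.0 - err / total if total else 1.0
    mean_cov = mean_k * factor / retained_frac if retained_frac > 0 else mean_k * factor
    return M * factor, mean_cov, (sd_k / mean_k if mean_k > 0 else 0.0)


def kmer_error_fraction(spectrum: KmerSpectrum) -> float:
    """Fraction of k-mer instances at multiplicities at or below the error
    boundary — an estimate of the sequencing error rate's k-mer footprint."""
    if not spectrum.counts:
        raise ValueError("empty spectrum")
    m = error_boundary(spectrum)
    total = spectrum.total_kmers
    err = sum(mult * c for mult, c in spectrum.counts.items() if mult <= m)
    return err / total if total else 0.0


def _has_adapter(seq: str, adapters: Sequence[str], min_tail: int = 12) -> bool:
    # full adapter anywhere, or an adapter prefix >= min_tail bp at the 3' end
    for ad in adapters:
        if ad in seq:
            return True
        for ln in range(len(ad) - 1, min_tail - 1, -1):
            if seq.endswith(ad[:ln]):
                return True
    return False


def scan_adapters_and_ns(pairs: Iterable[ReadPair],
                         adapters: Sequence[str] = (TRUSEQ_ADAPTER,),
                         ) -> tuple[float, int, int]:
    """Fraction of pairs free of adapters and Ns (adapters are detected, not
    removed).  Returns (frac_clean, n_pairs, n_unclean)."""
    if not adapters:
        raise ValueError("adapter list must be non-empty")
    n = unclean = 0
    for p in pairs:
        n += 1
        if ("N" in p.seq1 or "N" in p.seq2
                or _has_adapter(p.seq1, adapters)
                or _has_adapter(p.seq2, adapters)):
            unclean += 1
    return (1.0 if n == 0 else (n - unclean) / n), n, unclean


def mean_quality(qual: str) -> float:
    arr = np.frombuffer(qual.encode(), dtype=np.uint8).astype(float) - 33.0
    if (arr < 0).any() or (arr > 60).any():
        raise ValueError("malformed Phred+33 quality string")
    return float(arr.mean())


def quality_filter_pairs(pairs: Sequence[ReadPair], min_mean_q: float = 20.0,
                         ) -> tuple[list[ReadPair], float]:
    """Retain reads with mean Phred >= min_mean_q; a pair counts as retained
    only when BOTH mates pass."""
    retained = []
    for p in pairs:
        if mean_quality(p.qual1) >= min_mean_q and mean_quality(p.qual2) >= min_mean_q:
            retained.append(p)
    frac = 1.0 if not pairs else len(retained) / len(pairs)
    return retained, frac


GATE_RULES = {
    "frac_pairs_clean": (">=", 0.95),
    "frac_pairs_retained": (">=", 0.95),
    "frac_kmers_error": ("<=", 0.15),
    "coverage_mode": (">=", 27.0),
}


def qc_gate(report: RawReadQCReport) -> RawReadQCReport:
    """Apply the four sample-inclusion criteria; a failing sample requires
    additional sequencing.  Thresholds are inclusive exactly as stated."""
    failed = []
    for name, (op, thr) in GATE_RULES.items():
        v = getattr(report, name)
        ok = v >= thr if op == ">=" else v <= thr
        if not ok:
            failed.append(name)
    report.failed_criteria = failed
    report.passed = not failed
    return report


def run_read_qc(pairs: Sequence[ReadPair], read_length: int | None = None,
                adapters: Sequence[str] = (TRUSEQ_ADAPTER,), k: int = 23,
                ) -> tuple[RawReadQCReport, KmerSpectrum]:
    """Full raw-read QC: all five parameters plus the inclusion gate."""
    if read_length is None:
        read_length = len(pairs[0].seq1)
    frac_clean, _, _ = scan_adapters_and_ns(pairs, adapters)
    _, frac_retained = quality_filter_pairs(pairs)
    reads = [s for p in pairs for s in (p.seq1, p.seq2)]
    spectrum = count_kmers(reads, k=k)
    mode, mean, vc = estimate_coverage_stats(spectrum, read_length)
    report = RawReadQCReport(
        frac_pairs_clean=frac_clean,
        frac_pairs_retained=frac_retained,
        frac_kmers_error=kmer_error_fraction(spectrum),
        est_mean_coverage=mean,
        coverage_mode=mode,
        variance_coefficient=vc,
    )
    return qc_gate(report), spectrum
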