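"""Variant normalization and the hard filters.

Normalization splits multiallelic records into biallelic ones (re-indexing
per-sample genotypes), left-aligns indels to their minimal leftmost
representation against the reference, and drops records whose reference
allele disagrees with the reference sequence.

Two filter chains operate on normalized call sets:

* the SNV hard filter — QUAL > 40, per-sample GQ > 20, DP > 10, SP < 20
  (strict inequalities exactly as stated), then removal of variants in
  annotated repeat regions;
* the long-indel chain — caller PASS flag, successful normalization, an
  absolute ref/alt length difference of 20..100 bp inclusive, QUAL > 40,
  minimum per-sample GQ > 20, and no overlap with the merged low-complexity
  and low-mappability mask.

Every chain returns a ledger recording the record count entering and
leaving each step.
"""

from __future__ import annotations

from dataclasses import dataclass

from .masks import GenomeMask
from .variants import CallSet, VariantKey, VariantRecord


@dataclass
class FilterLedgerEntry:
    step: str
    n_in: int
    n_out: int
    rule: str


def check_ledger(ledger: list[FilterLedgerEntry]) -> None:
    for prev, cur in zip(ledger, ledger[1:]):
        if cur.n_in != prev.n_out:
            raise AssertionError(f"ledger break between {prev.step} and {cur.step}")


# ---------------------------------------------------------------------------
# Normalization


def _left_align(seq: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal leftmost representation of one allele pair.

    pos is 1-based; trailing shared bases are trimmed (extending left into
    the reference when an allele would empty), then leading shared bases are
    trimmed down to a single anchor base for indels.
    """
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            if (len(ref) == 1 or len(alt) == 1) and pos > 1:
                pad = seq[pos - 2]
                ref, alt, pos = pad + ref, pad + alt, pos - 1
            elif len(ref) == 1 or len(alt) == 1:
                break  # at contig start: cannot extend further
            ref, alt = ref[:-1], alt[:-1]
            continue
        break
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    return pos, ref, alt


def split_multiallelic(rec: VariantRecord) -> list[VariantRecord]:
    """One biallelic record per alternative allele; genotype indices of other
    alternatives collapse to the reference (0)."""
    if rec.is_biallelic:
        return [rec.copy()]
    out = []
    for ai, alt in enumerate(rec.alts, start=1):
        new = rec.copy()
        new.alts = (alt,)
        new.genotypes = [
            None if gt is None else tuple(sorted(1 if a == ai else 0 for a in gt))
            for gt in rec.genotypes]
        out.append(new)
    return out


def normalize_variant(rec: VariantRecord, reference: dict[str, str],
                      ) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Split + left-align one record against the reference.

    Returns (normalized records, dropped records); a record is dropped when
    its reference allele mismatches the reference sequence at its position.
    """
    if rec.chrom not in reference:
        raise KeyError(f"sequence {rec.chrom!r} absent from reference")
    seq = reference[rec.chrom].upper()
    normalized, dropped = [], []
    for r in split_multiallelic(rec):
        if seq[r.pos - 1: r.pos - 1 + len(r.ref)] != r.ref.upper():
            dropped.append(r)
            continue
        if r.ref.upper() == r.alts[0].upper():
            dropped.append(r)  # degenerate after the split: no variation left
            continue
        pos, ref, alt = _left_align(seq, r.pos, r.ref.upper(), r.alts[0].upper())
        r.pos, r.ref, r.alts = pos, ref, (alt,)
        normalized.append(r)
    return normalized, dropped


def normalize_callset(cs: CallSet, reference: dict[str, str],
                      ) -> tuple[CallSet, list[VariantRecord]]:
    normalized, dropped = [], []
    for rec in cs.records:
        ok, bad = normalize_variant(rec, reference)
        normalized.extend(ok)
        dropped.extend(bad)
    return CallSet(cs.samples, normalized).sorted(), dropped


# ---------------------------------------------------------------------------
# SNV hard filter


def _format_pass(values, threshold, op, mode) -> bool:
    """Per-sample FORMAT criterion over non-missing samples."""
    checks = []
    for v in values:
        if v is None:
            continue
        checks.append(v > threshold if op == ">" else v < threshold)
    if not checks:
        return False  # FORMAT field absent everywhere: fail the criterion
    return all(checks) if mode == "all" else any(checks)


def snv_hard_filter(cs: CallSet, repeat_mask: GenomeMask | None = None,
                    mode: str = "all",
                    ) -> tuple[CallSet, list[FilterLedgerEntry]]:
    """QUAL > 40, GQ > 20, DP > 10, SP < 20, then repeat-region removal.

    ``mode`` decides whether every non-missing sample must pass the
    per-sample FORMAT thresholds ("all", the default) or at least one
    ("any").
    """
    if mode not in ("all", "any"):
        raise ValueError("mode must be 'all' or 'any'")
    ledger: list[FilterLedgerEntry] = []
    recs = list(cs.records)

    def step(name: str, rule: str, keep) -> None:
        nonlocal recs
        n_in = len(recs)
        recs = [r for r in recs if keep(r)]
        ledger.append(FilterLedgerEntry(name, n_in, len(recs), rule))

    step("snv_only", "biallelic single-nucleotide records", lambda r: r.is_snv)
    step("qual", "QUAL > 40", lambda r: r.qual is not None and r.qual > 40)
    step("gq", "FORMAT/GQ > 20",
         lambda r: _format_pass(r.gq, 20, ">", mode))
    step("dp", "FORMAT/DP > 10",
         lambda r: _format_pass(r.dp, 10, ">", mode))
    step("sp", "FORMAT/SP < 20",
         lambda r: _format_pass(r.sp, 20, "<", mode))
    if repeat_mask is not None:
        step("repeat_mask", "outside annotated repeat regions",
             lambda r: not repeat_mask.overlaps(r.chrom, *r.span()))
    return CallSet(cs.samples, recs), ledger


# ---------------------------------------------------------------------------
# Long-indel chain


def indel_length(rec: VariantRecord) -> int:
    return abs(len(rec.ref) - len(rec.alts[0]))


def long_indel_filter(cs: CallSet, mask: GenomeMask | None = None,
                      reference: dict[str, str] | None = None,
                      qual_min: float = 40.0, gq_min: int = 20,
                      len_range: tuple[int, int] = (20, 100),
                      ) -> tuple[CallSet, list[FilterLedgerEntry]]:
    """The six-step long-indel selection.

    When a reference is supplied the call set is re-normalized in step 2
    (records failing the reference check drop out there); otherwise the
    input is assumed normalized and step 2 passes everything through.
    """
    lo, hi = len_range
    ledger: list[FilterLedgerEntry] = []
    recs = list(cs.records)

    n_in = len(recs)
    recs = [r for r in recs if r.filter == "PASS"]
    ledger.append(FilterLedgerEntry("caller_pass", n_in, len(recs),
                                    "FILTER field is PASS"))

    n_in = len(recs)
    if reference is not None:
        normalized = []
        for r in recs:
            ok, _ = normalize_variant(r, reference)
            normalized.extend(ok)
        recs = normalized
    ledger.append(FilterLedgerEntry("normalized", n_in, len(recs),
                                    "split + left-aligned, reference allele verified"))

    def step(name: str, rule: str, keep) -> None:
        nonlocal recs
        n = len(recs)
        recs = [r for r in recs if keep(r)]
        ledger.append(FilterLedgerEntry(name, n, len(recs), rule))

    step("length", f"|len(ref) - len(alt)| in [{lo}, {hi}]",
         lambda r: r.is_biallelic and lo <= indel_length(r) <= hi)
    step("qual", f"QUAL > {qual_min:g}",
         lambda r: r.qual is not None and r.qual > qual_min)
    step("gq", f"minimum per-sample GQ > {gq_min}",
         lambda r: _format_pass(r.gq, gq_min, ">", "all"))
    if mask is not None:
        step("masks", "outside low-complexity and low-mappability regions",
             lambda r: not mask.overlaps(r.chrom, *r.span()))
    return CallSet(cs.samples, recs), ledger


# ---------------------------------------------------------------------------
# Cross-center overlap


def callset_overlap(sets: dict[str, set[VariantKey]],
                    ) -> tuple[dict[frozenset, int], dict[str, dict[str, float]]]:
    """Venn-region counts for 2 or 3 variant-key sets.

    Returns (region counts keyed by the frozenset of member names, and
    per-set percentages of shared-by-all and unique keys).
    """
    if len(sets) < 2:
        raise ValueError("need >= 2 call sets to overlap")
    names = list(sets)
    union = set().union(*sets.values())
    regions: dict[frozenset, int] = {}
    for key in union:
        members = frozenset(n for n in names if key in sets[n])
        regions[members] = regions.get(members, 0) + 1
    pct = {}
    all_names = frozenset(names)
    for n in names:
        total = len(sets[n])
        shared = regions.get(all_names, 0)
        unique = regions.get(frozenset([n]), 0)
        pct[n] = {"shared_all": 100.0 * shared / total if total else 0.0,
                  "unique": 100.0 * unique / total if total else 0.0}
    return regions, pct
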