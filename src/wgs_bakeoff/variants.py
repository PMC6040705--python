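"""Variant records, call sets and VCF round-trip.

The in-memory unit of every concordance and filtering computation is a
:class:`CallSet`: a list of normalized-or-raw :class:`VariantRecord` objects
plus a shared sample list.  Genotypes are unphased allele-index pairs
(``(0, 1)``), ``None`` where the call is missing (``./.``).  Positions are
1-based as in VCF; interval arithmetic converts to 0-based half-open at the
mask boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import pysam

Genotype = Optional[tuple[int, int]]


@dataclass(frozen=True)
class VariantKey:
    """Identity of a (normalized, biallelic) variant."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: Optional[float] = None
    filter: str = "PASS"
    genotypes: list[Genotype] = field(default_factory=list)  # parallel to CallSet.samples
    gq: list[Optional[int]] = field(default_factory=list)
    dp: list[Optional[int]] = field(default_factory=list)
    sp: list[Optional[int]] = field(default_factory=list)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    @property
    def is_snv(self) -> bool:
        return self.is_biallelic and len(self.ref) == 1 and len(self.alts[0]) == 1

    @property
    def is_indel(self) -> bool:
        return self.is_biallelic and len(self.ref) != len(self.alts[0])

    def key(self) -> VariantKey:
        if not self.is_biallelic:
            raise ValueError("key() requires a biallelic record; split first")
        return VariantKey(self.chrom, self.pos, self.ref, self.alts[0])

    def span(self) -> tuple[int, int]:
        """0-based half-open interval covered by the reference allele."""
        return self.pos - 1, self.pos - 1 + len(self.ref)

    def copy(self) -> "VariantRecord":
        return replace(
            self,
            alts=tuple(self.alts),
            genotypes=list(self.genotypes),
            gq=list(self.gq),
            dp=list(self.dp),
            sp=list(self.sp),
        )


class CallSet:
    """An ordered collection of variant records over a fixed sample list."""

    def __init__(self, samples: Sequence[str], records: Iterable[VariantRecord] = ()):
        self.samples = list(samples)
        self.records: list[VariantRecord] = list(records)
        for rec in self.records:
            self._check(rec)

    def _check(self, rec: VariantRecord) -> None:
        n = len(self.samples)
        for name in ("genotypes", "gq", "dp", "sp"):
            vals = getattr(rec, name)
            if len(vals) not in (0, n):
                raise ValueError(f"{name} length {len(vals)} != {n} samples")

    def add(self, rec: VariantRecord) -> None:
        self._check(rec)
        self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in call set") from None

    def genotype(self, rec: VariantRecord, sample: str) -> Genotype:
        return rec.genotypes[self.sample_index(sample)]

    def by_key(self) -> dict[VariantKey, VariantRecord]:
        return {rec.key(): rec for rec in self.records if rec.is_biallelic}

    def sorted(self) -> "CallSet":
        recs = sorted(self.records, key=lambda r: (r.chrom, r.pos, r.ref, r.alts))
        return CallSet(self.samples, [r.copy() for r in recs])

    def copy(self) -> "CallSet":
        return CallSet(self.samples, [r.copy() for r in self.records])


def parse_genotype(text: str, allele_offset: int = 0) -> Genotype:
    """Parse an unphased genotype string like ``0/1`` into allele indices.

    ``allele_offset=1`` accepts the legacy 1-based coding used in clinical
    genotype tables (1 = reference allele, 2 = alternative allele), mapping
    it onto the VCF convention.
    """
    text = text.strip()
    if text in (".", "./.", ".|."):
        return None
    sep = "|" if "|" in text else "/"
    a, b = (int(x) - allele_offset for x in text.split(sep))
    if a < 0 or b < 0:
        raise ValueError(f"genotype {text!r} invalid for offset {allele_offset}")
    return tuple(sorted((a, b)))


def _fmt_gt(gt: Genotype) -> tuple:
    return (None, None) if gt is None else tuple(sorted(gt))


def write_vcf(callset: CallSet, path: str | os.PathLike,
              contigs: dict[str, int]) -> None:
    """Write a CallSet as VCF v4.2 with FORMAT GT:GQ:DP:SP."""
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("SP", 1, "Integer", "Strand bias Phred score")
    for s in callset.samples:
        header.add_sample(s)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for rec in sorted(callset.records, key=lambda r: (r.chrom, r.pos)):
            vrec = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(rec.ref, *rec.alts),
            )
            vrec.qual = rec.qual
            if rec.filter:
                vrec.filter.add(rec.filter)
            for i, s in enumerate(callset.samples):
                vs = vrec.samples[s]
                vs["GT"] = _fmt_gt(rec.genotypes[i] if rec.genotypes else None)
                vs.phased = False
                for tag, vals in (("GQ", rec.gq), ("DP", rec.dp), ("SP", rec.sp)):
                    if vals and vals[i] is not None:
                        vs[tag] = vals[i]
            out.write(vrec)


def read_vcf(path: str | os.PathLike) -> CallSet:
    with pysam.VariantFile(os.fspath(path)) as vcf:
        samples = list(vcf.header.samples)
        cs = CallSet(samples)
        for vrec in vcf:
            gts: list[Genotype] = []
            gq: list[Optional[int]] = []
            dp: list[Optional[int]] = []
            sp: list[Optional[int]] = []
            for s in samples:
                vs = vrec.samples[s]
                gt = vs.get("GT")
                if gt is None or any(a is None for a in gt):
                    gts.append(None)
                else:
                    gts.append(tuple(sorted(gt)))  # unphased
                gq.append(vs.get("GQ"))
                dp.append(vs.get("DP"))
                sp.append(vs.get("SP"))
            filt = list(vrec.filter.keys())
            cs.add(VariantRecord(
                chrom=vrec.chrom,
                pos=vrec.pos,
                ref=vrec.ref,
                alts=tuple(vrec.alts or ()),
                qual=vrec.qual,
                filter=filt[0] if filt else "PASS",
                genotypes=gts, gq=gq, dp=dp, sp=sp,
            ))
    return cs
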