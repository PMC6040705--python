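"""Synthetic inputs for the whole pipeline.

Everything the bake-off consumes can be generated here with known truth:
a reference with planted repeats and homopolymers, paired-end reads with
controlled error/adapter/N/low-quality injection, a cohort call set with a
trio and per-center corrupted replicates, a microarray subset, window
read-depth profiles with planted segmental duplications, a per-variant
annotation table with one planted rare loss-of-function causal variant, and
paired HLA typing tables with planted mismatches.

Defaults emulate the study conditions: ~150 bp paired reads at 30x with
~400 bp inserts, a 10-sample cohort of 8 cases including one parent-offspring
trio, and a causal insertion carried homozygously by the trio case (inherited
from the carrier mother, absent in the father — a spontaneous second allele)
plus one unrelated heterozygous case.

Every draw flows from one ``numpy`` Generator seeded from ``config.seed``, so
identical configurations give byte-identical outputs; every corruption is
logged so tests can reconcile observed discrepancies against the injection
log exactly.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortDesign, default_design
from .masks import GenomeMask
from .variants import CallSet, VariantRecord

# TruSeq read-through adapter, the default query of the adapter scan.
TRUSEQ_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i
_CODE[ord("N")] = 4
_CODE[ord("n")] = 4

# Default planted carrier pattern over the 10-sample design: trio case
# homozygous, mother heterozygous, father non-carrier, one unrelated
# heterozygous case.
DEFAULT_CAUSAL_PATTERN: dict[str, tuple[int, int]] = {
    "trio_case1": (1, 1),
    "trio_father": (0, 0),
    "trio_mother": (0, 1),
    "case2": (0, 1),
    **{f"case{i}": (0, 0) for i in range(3, 9)},
}


@dataclass
class SimulationConfig:
    genome_length: int = 100_000
    n_chromosomes: int = 1
    seed: int = 0
    read_length: int = 150
    insert_size_mean: float = 400.0
    insert_size_sd: float = 30.0
    coverage: float = 30.0
    base_error_rate: float = 0.003
    adapter_rate: float = 0.005
    n_rate: float = 0.001
    low_quality_rate: float = 0.0055   # per-read probability of a mean-Q<20 read
    n_cases: int = 8
    trio: tuple[str, str, str] = ("trio_case1", "trio_father", "trio_mother")
    n_variant_sites: int = 2_000
    per_center_discordance: float = 0.01
    drop_rate: float = 0.0
    extra_rate: float = 0.0
    mendel_error_rate: float = 0.003
    array_fraction: float = 0.10
    array_error_rate: float = 0.0
    lof_fraction: float = 0.05
    window_size: int = 1_000
    cn_dispersion: float = 0.15
    planted_sds: list[tuple[str, int, int, float]] = field(default_factory=list)
    planted_causal: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_CAUSAL_PATTERN))

    def validate(self) -> None:
        if self.genome_length < 10 * self.read_length:
            raise ValueError("genome_length must be >= 10 * read_length")
        for name in ("base_error_rate", "adapter_rate", "n_rate",
                     "low_quality_rate", "per_center_discordance",
                     "mendel_error_rate", "array_fraction", "array_error_rate",
                     "lof_fraction", "drop_rate", "extra_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.insert_size_mean < self.read_length:
            raise ValueError("insert_size_mean below read_length: invalid geometry")
        for chrom, start, end, cn in self.planted_sds:
            if not (0 <= start < end <= self.genome_length):
                raise ValueError(f"planted SD {chrom}:{start}-{end} out of bounds")
            if cn < 0:
                raise ValueError("planted SD copy number must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# Reference


@dataclass
class ReferenceTruth:
    duplications: GenomeMask
    homopolymers: GenomeMask


def make_reference(config: SimulationConfig,
                   dup_length: int | None = None,
                   homopolymer_length: int = 10,
                   ) -> tuple[dict[str, str], ReferenceTruth]:
    """Random reference with one exact duplicated segment and one homopolymer.

    The duplication (>= 2 read lengths) exercises the mappability mask; the
    homopolymer exercises the low-complexity mask.  Truth intervals of both
    are returned alongside the sequences.
    """
    config.validate()
    dup_length = dup_length or 2 * config.read_length
    per_chrom = config.genome_length // config.n_chromosomes
    if per_chrom < 2 * dup_length + homopolymer_length + 100:
        raise ValueError("genome too short to host the planted features")
    rng = np.random.default_rng(config.seed)
    reference: dict[str, str] = {}
    dups = GenomeMask({}, label="duplication")
    homos = GenomeMask({}, label="homopolymer")
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        codes = rng.integers(0, 4, size=per_chrom)
        # plant an exact duplicate: copy [src, src+dup) onto [dst, dst+dup)
        src = per_chrom // 8
        dst = per_chrom // 2
        codes[dst:dst + dup_length] = codes[src:src + dup_length]
        # plant a homopolymer run clear of the duplicate
        hstart = per_chrom // 4 * 3
        codes[hstart:hstart + homopolymer_length] = 0  # poly-A
        # ensure the run is maximal
        if hstart > 0:
            codes[hstart - 1] = 1
        if hstart + homopolymer_length < per_chrom:
            codes[hstart + homopolymer_length] = 1
        reference[chrom] = _BASES[codes].tobytes().decode("ascii")
        dups.add(chrom, src, src + dup_length)
        dups.add(chrom, dst, dst + dup_length)
        homos.add(chrom, hstart, hstart + homopolymer_length)
    return reference, ReferenceTruth(duplications=dups, homopolymers=homos)


def write_fasta(reference: dict[str, str], path: str | os.PathLike,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Reads


@dataclass
class ReadPair:
    name: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


@dataclass
class ReadSimLog:
    n_pairs: int
    adapter_pairs: set[int]
    n_pairs_with_n: set[int]
    low_quality_reads: set[tuple[int, int]]  # (pair index, mate 0/1)
    n_error_bases: int = 0


_Q_HIGH = chr(33 + 35)
_Q_LOW = chr(33 + 12)


def simulate_read_pairs(reference: dict[str, str], config: SimulationConfig,
                        adapter: str = TRUSEQ_ADAPTER,
                        ) -> tuple[list[ReadPair], ReadSimLog]:
    """Paired reads at ``config.coverage`` with controlled injections.

    Adapter read-through is simulated by drawing a short insert for the
    affected pair so that both mates run into adapter sequence; qualities
    are two-state (mean Q35 high / Q12 low) because only the mean-Q >= 20
    retention gate matters downstream.
    """
    config.validate()
    if not reference:
        raise ValueError("empty reference")
    rng = np.random.default_rng(config.seed + 1)
    L = config.read_length
    chroms = list(reference)
    lengths = np.array([len(reference[c]) for c in chroms], dtype=float)
    total = lengths.sum()
    n_pairs = int(round(config.coverage * total / (2 * L)))
    codes = {c: _CODE[np.frombuffer(reference[c].upper().encode(), dtype=np.uint8)]
             .astype(np.int64) for c in chroms}
    adapter_codes = _CODE[np.frombuffer(adapter.encode(), dtype=np.uint8)].astype(np.int64)

    chrom_idx = rng.choice(len(chroms), size=n_pairs, p=lengths / total)
    is_adapter = rng.random(n_pairs) < config.adapter_rate
    has_n = rng.random(n_pairs) < config.n_rate
    low_q = rng.random((n_pairs, 2)) < config.low_quality_rate
    inserts = np.rint(rng.normal(config.insert_size_mean, config.insert_size_sd,
                                 size=n_pairs)).astype(int)
    # adapter pairs: insert shorter than the read so both mates read through
    short = rng.integers(L // 3, L - len(adapter) + 1, size=n_pairs)
    inserts = np.where(is_adapter, short, np.clip(inserts, L, None))

    log = ReadSimLog(n_pairs=n_pairs, adapter_pairs=set(),
                     n_pairs_with_n=set(), low_quality_reads=set())
    pairs: list[ReadPair] = []
    for i in range(n_pairs):
        chrom = chroms[chrom_idx[i]]
        arr = codes[chrom]
        ins = min(int(inserts[i]), len(arr))
        start = int(rng.integers(0, len(arr) - ins + 1))
        frag = arr[start:start + ins]
        if ins >= L:
            r1 = frag[:L].copy()
            r2 = (3 - frag[::-1])[:L].copy()
        else:
            pad = L - ins
            tail = adapter_codes[:pad]
            if tail.size < pad:  # read runs past the adapter into noise
                tail = np.concatenate(
                    [tail, rng.integers(0, 4, size=pad - tail.size)])
            r1 = np.concatenate([frag, tail])
            r2 = np.concatenate([3 - frag[::-1], tail])
            log.adapter_pairs.add(i)
        for r in (r1, r2):
            if config.base_error_rate > 0:
                err = np.flatnonzero(rng.random(L) < config.base_error_rate)
                if err.size:
                    r[err] = (r[err] + rng.integers(1, 4, size=err.size)) % 4
                    log.n_error_bases += int(err.size)
        if has_n[i]:
            k = int(rng.integers(1, 4))
            r1[rng.integers(0, L, size=k)] = 4
            log.n_pairs_with_n.add(i)
        q1 = _Q_LOW * L if low_q[i, 0] else _Q_HIGH * L
        q2 = _Q_LOW * L if low_q[i, 1] else _Q_HIGH * L
        for m in (0, 1):
            if low_q[i, m]:
                log.low_quality_reads.add((i, m))
        pairs.append(ReadPair(
            name=f"pair_{i}",
            seq1=_BASES[r1].tobytes().decode("ascii"), qual1=q1,
            seq2=_BASES[r2].tobytes().decode("ascii"), qual2=q2,
        ))
    return pairs, log


def write_fastq_pair(pairs: Iterable[ReadPair], r1_path: str | os.PathLike,
                     r2_path: str | os.PathLike) -> None:
    """Write mates as gzipped Phred+33 FASTQ."""
    with gzip.open(r1_path, "wt") as f1, gzip.open(r2_path, "wt") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{p.qual2}\n")


def read_fastq_pair(r1_path: str | os.PathLike, r2_path: str | os.PathLike,
                    ) -> list[ReadPair]:
    import pysam

    pairs = []
    with pysam.FastxFile(os.fspath(r1_path)) as f1, \
            pysam.FastxFile(os.fspath(r2_path)) as f2:
        for e1, e2 in zip(f1, f2):
            pairs.append(ReadPair(e1.name, e1.sequence, e1.quality,
                                  e2.sequence, e2.quality))
    return pairs


# ---------------------------------------------------------------------------
# Call sets


_GTS = [(0, 0), (0, 1), (1, 1)]


@dataclass
class CallSetTruth:
    truth: CallSet
    replicates: list[CallSet]
    array: pd.DataFrame
    corruption_log: pd.DataFrame     # center, chrom, pos, sample, truth_gt, observed_gt
    mendel_violation_sites: list[int]  # positions where a violating child gt was planted
    causal_pos: int | None


def _mendel_consistent(child, father, mother) -> bool:
    a, b = child
    return ((a in father and b in mother) or (b in father and a in mother))


def simulate_center_callsets(reference: dict[str, str],
                             design: CohortDesign | None,
                             config: SimulationConfig,
                             n_centers: int = 3,
                             per_center_discordance: Sequence[float] | None = None,
                             plant_causal: bool = True,
                             ) -> CallSetTruth:
    """One truth call set, per-center corrupted replicates, and an array subset.

    The trio child's genotypes follow Mendel transmission except at
    ``mendel_error_rate``, where a genotype violating the parental pair is
    planted (sites where every genotype is consistent are left untouched).
    Replicates equal truth except genotypes corrupted independently at the
    per-center rate; the planted causal site is never corrupted, matching a
    fully replicating causal variant.  Every corruption is logged.
    """
    config.validate()
    design = design or default_design()
    if config.mendel_error_rate > 0 and design.trio is None:
        raise ValueError("mendel_error_rate > 0 requires a trio in the design")
    rates = list(per_center_discordance if per_center_discordance is not None
                 else [config.per_center_discordance] * n_centers)
    rng = np.random.default_rng(config.seed + 2)
    samples = design.samples
    chrom = next(iter(reference))
    seq = reference[chrom].upper()
    glen = len(seq)

    n_sites = min(config.n_variant_sites, glen - 2)
    positions = np.sort(rng.choice(np.arange(1, glen - 1), size=n_sites + 1,
                                   replace=False))  # 0-based, spare one for causal
    causal_pos0 = int(positions[len(positions) // 2]) if plant_causal else None
    site_pos = [int(p) for p in positions if p != causal_pos0][:n_sites]

    child = father = mother = None
    if design.trio:
        child, father, mother = design.trio
    founders = [s for s in samples if s != child]

    truth = CallSet(samples)
    mendel_sites: list[int] = []
    afs = rng.beta(0.5, 2.0, size=len(site_pos))
    for pos0, af in zip(site_pos, afs):
        ref_base = seq[pos0]
        if ref_base == "N":
            ref_base = "A"
        alt_base = "ACGT"[(("ACGT".index(ref_base)) + int(rng.integers(1, 4))) % 4]
        gts: dict[str, tuple[int, int]] = {}
        for s in founders:
            gts[s] = tuple(sorted(int(rng.random() < af) for _ in range(2)))
        if child is not None:
            fa, mo = gts[father], gts[mother]
            cg = tuple(sorted((fa[rng.integers(0, 2)], mo[rng.integers(0, 2)])))
            if rng.random() < config.mendel_error_rate:
                violating = [g for g in _GTS if not _mendel_consistent(g, fa, mo)]
                if violating:
                    cg = violating[int(rng.integers(0, len(violating)))]
                    mendel_sites.append(pos0 + 1)
            gts[child] = cg
        if all(g == (0, 0) for g in gts.values()):
            # keep the site polymorphic: seed one heterozygote
            gts[founders[int(rng.integers(0, len(founders)))]] = (0, 1)
        truth.add(VariantRecord(
            chrom=chrom, pos=pos0 + 1, ref=ref_base, alts=(alt_base,),
            qual=float(np.round(rng.uniform(45, 900), 1)),
            genotypes=[gts[s] for s in samples],
            gq=[int(rng.integers(25, 100)) for _ in samples],
            dp=[int(rng.poisson(config.coverage)) for _ in samples],
            sp=[int(rng.integers(0, 16)) for _ in samples],
        ))

    causal_pos = None
    if plant_causal:
        pattern = config.planted_causal
        missing = set(samples) - set(pattern)
        if missing:
            raise ValueError(f"planted_causal lacks samples: {sorted(missing)}")
        ref_base = seq[causal_pos0]
        if ref_base == "N":
            ref_base = "G"
        causal_pos = causal_pos0 + 1
        truth.add(VariantRecord(
            chrom=chrom, pos=causal_pos, ref=ref_base, alts=(ref_base + "C",),
            qual=850.0,
            genotypes=[tuple(sorted(pattern[s])) for s in samples],
            gq=[99] * len(samples),
            dp=[int(rng.poisson(config.coverage)) for _ in samples],
            sp=[int(rng.integers(0, 10)) for _ in samples],
        ))
    truth = truth.sorted()

    log_rows = []
    replicates = []
    for ci, rate in enumerate(rates):
        rep = truth.copy()
        kept = []
        for rec in rep.records:
            is_causal = causal_pos is not None and rec.pos == causal_pos
            if not is_causal and config.drop_rate > 0 and rng.random() < config.drop_rate:
                continue
            if not is_causal and rate > 0:
                for si, s in enumerate(samples):
                    if rng.random() < rate:
                        old = rec.genotypes[si]
                        others = [g for g in _GTS if g != old]
                        new = others[int(rng.integers(0, len(others)))]
                        rec.genotypes[si] = new
                        log_rows.append({"center": f"center{ci + 1}",
                                         "chrom": rec.chrom, "pos": rec.pos,
                                         "sample": s,
                                         "truth_gt": f"{old[0]}/{old[1]}",
                                         "observed_gt": f"{new[0]}/{new[1]}"})
            kept.append(rec)
        if config.extra_rate > 0:
            n_extra = rng.binomial(len(truth), config.extra_rate)
            used = {r.pos for r in truth.records}
            for _ in range(n_extra):
                pos0 = int(rng.integers(1, glen - 1))
                if pos0 + 1 in used:
                    continue
                rb = seq[pos0] if seq[pos0] != "N" else "A"
                ab = "ACGT"[("ACGT".index(rb) + 1) % 4]
                gts = [(0, 0)] * len(samples)
                gts[int(rng.integers(0, len(samples)))] = (0, 1)
                kept.append(VariantRecord(
                    chrom=chrom, pos=pos0 + 1, ref=rb, alts=(ab,),
                    qual=float(np.round(rng.uniform(45, 200), 1)),
                    genotypes=gts, gq=[60] * len(samples),
                    dp=[30] * len(samples), sp=[2] * len(samples)))
        replicates.append(CallSet(samples, kept).sorted())

    snv_recs = [r for r in truth.records if r.is_snv]
    n_array = max(1, int(round(config.array_fraction * len(snv_recs))))
    array_idx = rng.choice(len(snv_recs), size=min(n_array, len(snv_recs)),
                           replace=False)
    arr_rows = []
    for i in np.sort(array_idx):
        rec = snv_recs[int(i)]
        row = {"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
               "alt": rec.alts[0]}
        for si, s in enumerate(samples):
            gt = rec.genotypes[si]
            if config.array_error_rate > 0 and rng.random() < config.array_error_rate:
                gt = _GTS[int(rng.integers(0, 3))]
            row[s] = "./." if gt is None else f"{gt[0]}/{gt[1]}"
        arr_rows.append(row)
    array = pd.DataFrame(arr_rows)

    log = pd.DataFrame(log_rows, columns=["center", "chrom", "pos", "sample",
                                          "truth_gt", "observed_gt"])
    return CallSetTruth(truth=truth, replicates=replicates, array=array,
                        corruption_log=log,
                        mendel_violation_sites=mendel_sites,
                        causal_pos=causal_pos)


# ---------------------------------------------------------------------------
# Copy-number depth profiles


def simulate_cn_profile(genome_length: int, samples: Sequence[str],
                        planted: dict[str, list[tuple[str, int, int, float]]],
                        coverage: float = 30.0, window_size: int = 1_000,
                        dispersion: float = 0.15, seed: int = 0,
                        chrom: str = "chr1") -> pd.DataFrame:
    """Per-sample, per-window read depth with planted duplications.

    The expected depth of a window is the diploid coverage scaled by
    copy_number / 2; window-to-window noise is technical (GC, residual
    mappability) and is drawn at a fixed magnitude ``dispersion`` relative
    to the diploid depth, independent of copy number.  Returns columns
    sample, chrom, start, end, depth, true_cn.
    """
    rng = np.random.default_rng(seed + 3)
    starts = np.arange(0, genome_length - window_size + 1, window_size)
    rows = []
    for s in samples:
        cn = np.full(starts.size, 2.0)
        for pchrom, pstart, pend, pcn in planted.get(s, []):
            if pchrom != chrom:
                continue
            sel = (starts >= pstart) & (starts + window_size <= pend)
            cn[sel] = pcn
        noise = rng.normal(0.0, dispersion, size=starts.size) if dispersion > 0 \
            else np.zeros(starts.size)
        depth = np.clip(coverage * (cn / 2.0) + coverage * noise, 0.0, None)
        for w, st in enumerate(starts):
            rows.append({"sample": s, "chrom": chrom, "start": int(st),
                         "end": int(st + window_size),
                         "depth": float(depth[w]), "true_cn": float(cn[w])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Annotation table


_CONSEQUENCES = ["stop_gained", "frameshift_variant", "splice_donor_variant",
                 "missense_variant", "synonymous_variant", "intron_variant"]


def simulate_annotation_table(call_set: CallSet, design: CohortDesign,
                              config: SimulationConfig,
                              causal_pos: int | None = None) -> pd.DataFrame:
    """Per-variant annotation with LoF flags and population frequencies.

    The planted causal variant is annotated as high-confidence LoF, absent
    from two frequency databases and rare (0.006) in the third.  Background
    variants are given rare frequencies only where a parent carries the
    alternative allele; any other background variant carries a common
    frequency, so the causal variant is the unique prioritizable signal by
    construction.
    """
    if len(call_set) == 0:
        raise ValueError("empty call set")
    rng = np.random.default_rng(config.seed + 4)
    parent_idx = [call_set.sample_index(s) for s in design.parents]
    child_idx = (call_set.sample_index(design.trio[0])
                 if design.trio is not None else None)
    rows = []
    for vi, rec in enumerate(call_set.records):
        is_causal = causal_pos is not None and rec.pos == causal_pos

        def carries(i: int) -> bool:
            return rec.genotypes[i] is not None and 1 in rec.genotypes[i]

        # Rare background frequencies go only where a parent carries the
        # allele and the trio child does not, so the parental-zero rule
        # (not its child-carrier relaxation) removes every background
        # variant and the planted causal is the unique prioritizable signal.
        parent_carried = (any(carries(i) for i in parent_idx)
                          and not (child_idx is not None and carries(child_idx)))
        if is_causal:
            lof = "high"
            maf_1000g = maf_exac = np.nan
            maf_gnomad = 0.006
            gene, csq = "FTCD", "frameshift_variant"
            rsid, novelty, gavin = ".", "novel", "Pathogenic"
            liver = True
        else:
            u = rng.random()
            lof = ("high" if u < config.lof_fraction
                   else "low" if u < 2 * config.lof_fraction else "none")
            if parent_carried:
                maf_gnomad = (np.nan if rng.random() < 0.5
                              else float(np.round(rng.uniform(1e-4, 0.009), 6)))
                lo, hi = 1e-4, 0.009
            else:
                maf_gnomad = float(np.round(rng.uniform(0.02, 0.5), 6))
                lo, hi = 0.02, 0.5
            maf_1000g = (float(np.round(rng.uniform(lo, hi), 6))
                         if rng.random() < 0.8 else np.nan)
            maf_exac = (float(np.round(rng.uniform(lo, hi), 6))
                        if rng.random() < 0.8 else np.nan)
            gene = f"GENE{vi // 5:04d}"
            csq = _CONSEQUENCES[int(rng.integers(0, len(_CONSEQUENCES)))]
            known = rng.random() < 0.8
            rsid = f"rs{int(rng.integers(10**6, 10**8))}" if known else "."
            novelty = "known" if known else "novel"
            gavin = ["Benign", "VOUS", "Pathogenic"][int(rng.integers(0, 3))]
            liver = bool(rng.random() < 0.4)
        rows.append({
            "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
            "alt": rec.alts[0], "rsid": rsid, "gene": gene,
            "consequence": csq,
            "n_transcripts": int(rng.integers(1, 12)),
            "lof_confidence": lof,
            "maf_1000g": maf_1000g, "maf_exac": maf_exac,
            "maf_gnomad": maf_gnomad,
            "novelty": novelty, "liver_expression": liver,
            "associations": ".", "gavin": gavin,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# HLA typings

_HLA_POOL = {
    "HLA-A": ["01:01", "02:01", "03:01", "11:01", "24:02", "26:01"],
    "HLA-B": ["07:02", "08:01", "15:01", "35:01", "44:02", "51:01"],
    "HLA-C": ["03:04", "04:01", "06:02", "07:01", "07:02", "12:03"],
    "HLA-DRB1": ["03:01", "04:05", "07:01", "10:01", "11:01", "13:01",
                 "14:54", "15:01", "15:03"],
}


def simulate_hla_typings(design: CohortDesign, seed: int = 0,
                         n_planted_mismatches: int = 4,
                         genes: Sequence[str] = tuple(_HLA_POOL),
                         ) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Two typing tables (molecular vs sequence-derived) with planted
    single-allele mismatches; returns (table_a, table_b, n_planted)."""
    rng = np.random.default_rng(seed + 5)
    rows = []
    for s in design.samples:
        for g in genes:
            pool = _HLA_POOL[g]
            a1, a2 = rng.choice(pool, size=2, replace=True)
            rows.append({"sample": s, "gene": g, "allele1": str(a1),
                         "allele2": str(a2)})
    a = pd.DataFrame(rows)
    b = a.copy(deep=True)
    slots = rng.choice(len(b), size=min(n_planted_mismatches, len(b)),
                       replace=False)
    planted = 0
    for slot in slots:
        g = b.at[slot, "gene"]
        pair = {b.at[slot, "allele1"], b.at[slot, "allele2"]}
        candidates = [x for x in _HLA_POOL[g] if x not in pair]
        if not candidates:
            continue
        which = "allele1" if rng.random() < 0.5 else "allele2"
        b.at[slot, which] = candidates[int(rng.integers(0, len(candidates)))]
        planted += 1
    return a, b, planted
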