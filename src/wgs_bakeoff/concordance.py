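"""Genotype-level comparisons: cross-center concordance, microarray
agreement, Mendel inheritance errors, allele-count spectra and HLA typing
mismatch counting.

The matching unit everywhere is the normalized biallelic variant key
(chrom, pos, ref, alt) together with the unphased diploid genotype of one
sample: a variant "replicates" between two call sets for a sample iff the
key and the genotype are both identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .variants import CallSet, Genotype, VariantKey


@dataclass
class ConcordanceResult:
    n_baseline: int
    n_query: int
    n_genotype_match: int

    @property
    def precision(self) -> float:
        return self.n_genotype_match / self.n_query if self.n_query else 1.0

    @property
    def sensitivity(self) -> float:
        return self.n_genotype_match / self.n_baseline if self.n_baseline else 1.0

    @property
    def f_measure(self) -> float:
        p, s = self.precision, self.sensitivity
        return 2 * p * s / (p + s) if p + s else 0.0


def _carried(cs: CallSet) -> dict[str, dict[VariantKey, tuple[int, int]]]:
    """Per sample: keys where the sample carries >= 1 alternative allele."""
    out: dict[str, dict[VariantKey, tuple[int, int]]] = {s: {} for s in cs.samples}
    for rec in cs.records:
        if not rec.is_biallelic:
            continue
        key = rec.key()
        for i, s in enumerate(cs.samples):
            gt = rec.genotypes[i]
            if gt is not None and 1 in gt:
                out[s][key] = gt
    return out


def genotype_concordance(baseline: CallSet, query: CallSet,
                         samples: list[str] | None = None,
                         ) -> tuple[ConcordanceResult, pd.DataFrame]:
    """Precision / sensitivity / F over variants carried per sample.

    A baseline (query) unit is a (variant key, sample) pair at which the
    sample carries the alternative allele; a unit matches iff the other call
    set carries the identical key with the identical unphased genotype.
    Missing genotypes never match.
    """
    if samples is None:
        samples = [s for s in baseline.samples if s in query.samples]
    if not samples:
        raise ValueError("no shared samples between call sets")
    bc, qc = _carried(baseline), _carried(query)
    rows = []
    nb = nq = nm = 0
    for s in samples:
        b, q = bc[s], qc[s]
        match = sum(1 for k, gt in b.items() if q.get(k) == gt)
        rows.append({"sample": s, "n_baseline": len(b), "n_query": len(q),
                     "n_match": match,
                     "precision": match / len(q) if q else 1.0,
                     "sensitivity": match / len(b) if b else 1.0})
        nb += len(b)
        nq += len(q)
        nm += match
    return ConcordanceResult(nb, nq, nm), pd.DataFrame(rows)


def array_concordance(call_set: CallSet, array: pd.DataFrame,
                      samples: list[str] | None = None,
                      absent_as_ref: bool = False,
                      ) -> tuple[float, pd.Series]:
    """Fraction of microarray SNP sites genotyped identically in the call set.

    A site absent from the call set counts as discordant (detection failure);
    with ``absent_as_ref`` the call set is instead assumed homozygous
    reference there, concordant iff the array genotype is 0/0.
    """
    if samples is None:
        samples = call_set.samples
    sample_cols = [c for c in array.columns
                   if c not in ("chrom", "pos", "ref", "alt")]
    for s in samples:
        if s not in sample_cols:
            raise ValueError(f"sample {s!r} absent from array table")
        call_set.sample_index(s)  # raises if absent
    by_key = call_set.by_key()
    per_sample: dict[str, list[int]] = {s: [0, 0] for s in samples}  # conc, total
    for row in array.itertuples(index=False):
        key = VariantKey(row.chrom, int(row.pos), row.ref, row.alt)
        rec = by_key.get(key)
        for s in samples:
            agt = getattr(row, s)
            if agt in (".", "./."):
                continue
            a, b = agt.split("/")
            array_gt = tuple(sorted((int(a), int(b))))
            if rec is None:
                wgs_gt: Genotype = (0, 0) if absent_as_ref else None
            else:
                wgs_gt = call_set.genotype(rec, s)
            per_sample[s][1] += 1
            if wgs_gt is not None and wgs_gt == array_gt:
                per_sample[s][0] += 1
    fracs = pd.Series({s: (c / t if t else float("nan"))
                       for s, (c, t) in per_sample.items()})
    conc = sum(c for c, _ in per_sample.values())
    tot = sum(t for _, t in per_sample.values())
    return (conc / tot if tot else float("nan")), fracs


def is_mendel_error(child: Genotype, father: Genotype, mother: Genotype) -> bool:
    """True iff no assignment of one child allele to each parent is
    consistent with the parental genotypes.  Missing genotypes are never
    errors (the site is untestable)."""
    if child is None or father is None or mother is None:
        return False
    a, b = child
    return not ((a in father and b in mother) or (b in father and a in mother))


def mendel_errors(call_set: CallSet, trio: tuple[str, str, str],
                  ) -> tuple[int, int, float]:
    """Count trio sites violating Mendel transmission.

    Returns (n_errors, n_tested, rate); sites with any missing genotype are
    excluded from the tested denominator.  Multiallelic records are handled
    directly on allele indices.
    """
    child, father, mother = trio
    ci = call_set.sample_index(child)
    fi = call_set.sample_index(father)
    mi = call_set.sample_index(mother)
    n_err = n_tested = 0
    for rec in call_set.records:
        c, f, m = rec.genotypes[ci], rec.genotypes[fi], rec.genotypes[mi]
        if c is None or f is None or m is None:
            continue
        n_tested += 1
        if is_mendel_error(c, f, m):
            n_err += 1
    return n_err, n_tested, (n_err / n_tested if n_tested else 0.0)


def allele_count_spectrum(call_set: CallSet) -> dict[int, int]:
    """Histogram of per-variant alternative-allele counts over samples.

    Multiallelic records are excluded; counts range over 1..2N.
    """
    spectrum: dict[int, int] = {}
    for rec in call_set.records:
        if not rec.is_biallelic:
            continue
        ac = sum(gt.count(1) for gt in rec.genotypes if gt is not None)
        if ac >= 1:
            spectrum[ac] = spectrum.get(ac, 0) + 1
    return dict(sorted(spectrum.items()))


def _truncate_allele(allele: str, resolution: int = 2) -> str:
    return ":".join(str(allele).split(":")[:resolution])


def pair_mismatches(pair_a: tuple[str, str], pair_b: tuple[str, str],
                    resolution: int = 2) -> int:
    """2 minus the maximum matching between two unordered allele pairs,
    compared at the given field resolution."""
    a1, a2 = (_truncate_allele(x, resolution) for x in pair_a)
    b1, b2 = (_truncate_allele(x, resolution) for x in pair_b)
    best = max((a1 == b1) + (a2 == b2), (a1 == b2) + (a2 == b1))
    return 2 - best


def hla_mismatch_count(typing_a: pd.DataFrame, typing_b: pd.DataFrame,
                       resolution: int = 2,
                       ) -> tuple[pd.DataFrame, pd.Series, int]:
    """Per-(sample, gene) mismatches between two HLA typing tables.

    Tables carry columns sample, gene, allele1, allele2; alleles are
    truncated to ``resolution`` fields before maximum matching.  Returns
    (per-slot table, per-gene totals, grand total).
    """
    a = typing_a.set_index(["sample", "gene"])
    b = typing_b.set_index(["sample", "gene"])
    common = a.index.intersection(b.index)
    if common.empty:
        raise ValueError("no shared (sample, gene) slots between typings")
    rows = []
    for sample, gene in common:
        ra, rb = a.loc[(sample, gene)], b.loc[(sample, gene)]
        mm = pair_mismatches((ra["allele1"], ra["allele2"]),
                             (rb["allele1"], rb["allele2"]), resolution)
        rows.append({"sample": sample, "gene": gene, "mismatches": mm})
    table = pd.DataFrame(rows)
    per_gene = table.groupby("gene")["mismatches"].sum()
    return table, per_gene, int(table["mismatches"].sum())
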