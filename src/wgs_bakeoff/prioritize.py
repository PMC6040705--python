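"""Replication-based prioritization of rare loss-of-function variants.

In a small case cohort with sequenced healthy parents, candidate causal
variants are shortlisted by a fixed filter chain, each step recording how
many variants it removed:

1. high-confidence loss-of-function annotation;
2. rarity — every population frequency present in the databases is at most
   ``maf_max`` (a variant absent from a database counts as rare);
3. case occurrence — at least ``min_case_alt_alleles`` alternative alleles
   over the case samples, or any case homozygous for the alternative;
4. parental zero — no alternative allele in the healthy parents, relaxed to
   at most two parental alleles when the trio child itself carries the
   variant (a transmitted allele is expected in a parent);
5. replication — genotypes concordant in at least ``concordance_min`` of
   replicate-pair comparisons pooled over individuals.

Exclusion reasons use first-failing-step attribution so the ledger is
reproducible: retained + sum over reasons = input count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .cohort import CohortDesign
from .concordance import is_mendel_error
from .variants import CallSet, VariantKey

STEP_ORDER = ["lof", "maf", "case_occurrence", "parental", "replication"]


@dataclass
class PrioritizationResult:
    retained: pd.DataFrame                 # diagnostics of retained variants
    excluded: pd.DataFrame                 # key columns + reason
    ledger: dict[str, int] = field(default_factory=dict)  # reason -> n excluded

    @property
    def n_input(self) -> int:
        return len(self.retained) + len(self.excluded)


def replicate_concordance(key: VariantKey, replicates: list[CallSet],
                          samples: list[str] | None = None) -> float:
    """Fraction of concordant unordered replicate-pair genotype comparisons.

    Pooled over all individuals present in >= 2 replicates; missing
    genotypes (and replicates lacking the variant) contribute no pairs.
    """
    if len(replicates) < 2:
        raise ValueError("need >= 2 replicate call sets")
    if samples is None:
        samples = replicates[0].samples
    per_rep = []
    found = False
    for rep in replicates:
        rec = rep.by_key().get(key)
        if rec is None:
            per_rep.append({s: None for s in samples})
        else:
            found = True
            per_rep.append({s: rep.genotype(rec, s) for s in samples})
    if not found:
        raise ValueError(f"variant {key} absent from every replicate")
    conc = total = 0
    for s in samples:
        gts = [r[s] for r in per_rep if r[s] is not None]
        for a, b in combinations(gts, 2):
            total += 1
            conc += a == b
    return conc / total if total else 1.0


def _alt_count(gt) -> int:
    return 0 if gt is None else list(gt).count(1)


def prioritize_lof(annotations: pd.DataFrame, replicates: list[CallSet],
                   design: CohortDesign, maf_max: float = 0.01,
                   min_case_alt_alleles: int = 2,
                   concordance_min: float = 0.98,
                   parent_relaxed_max: int = 2,
                   genotype_source: CallSet | None = None,
                   ) -> PrioritizationResult:
    """Run the five-step filter chain over an annotation table.

    ``annotations`` carries one row per variant with columns chrom, pos,
    ref, alt, lof_confidence, maf_1000g, maf_exac, maf_gnomad (NaN = absent
    from the database).  Genotypes for the occurrence and parental rules are
    taken from ``genotype_source`` (default: the first replicate).
    """
    source = genotype_source if genotype_source is not None else replicates[0]
    for s in design.samples:
        source.sample_index(s)  # raises on unknown sample role binding
    by_key = source.by_key()
    maf_cols = [c for c in ("maf_1000g", "maf_exac", "maf_gnomad")
                if c in annotations.columns]
    child = design.trio[0] if design.trio else None

    kept_rows, excl_rows = [], []
    ledger = {step: 0 for step in STEP_ORDER}
    for row in annotations.itertuples(index=False):
        key = VariantKey(row.chrom, int(row.pos), row.ref, row.alt)
        diag = {"chrom": key.chrom, "pos": key.pos, "ref": key.ref,
                "alt": key.alt}

        def exclude(reason: str) -> None:
            ledger[reason] += 1
            excl_rows.append({**diag, "reason": reason})

        if getattr(row, "lof_confidence", "none") != "high":
            exclude("lof")
            continue
        mafs = [getattr(row, c) for c in maf_cols]
        if any(m is not None and not pd.isna(m) and m > maf_max for m in mafs):
            exclude("maf")
            continue

        rec = by_key.get(key)
        gts = ({} if rec is None
               else {s: source.genotype(rec, s) for s in design.samples})
        case_alt = sum(_alt_count(gts.get(s)) for s in design.cases)
        hom_case = any(gts.get(s) == (1, 1) for s in design.cases)
        diag.update(case_alt_alleles=case_alt, hom_alt_case=hom_case)
        if not (case_alt >= min_case_alt_alleles or hom_case):
            exclude("case_occurrence")
            continue

        parent_alt = sum(_alt_count(gts.get(s)) for s in design.parents)
        child_carries = child is not None and _alt_count(gts.get(child)) >= 1
        limit = parent_relaxed_max if child_carries else 0
        diag.update(parent_alt_alleles=parent_alt, child_carries=child_carries)
        if parent_alt > limit:
            exclude("parental")
            continue

        try:
            conc = replicate_concordance(key, replicates, design.samples)
        except ValueError:
            conc = 0.0
        diag["replicate_concordance"] = conc
        if conc < concordance_min:
            exclude("replication")
            continue
        kept_rows.append(diag)

    retained = pd.DataFrame(kept_rows, columns=[
        "chrom", "pos", "ref", "alt", "case_alt_alleles", "hom_alt_case",
        "parent_alt_alleles", "child_carries", "replicate_concordance"])
    excluded = pd.DataFrame(excl_rows, columns=["chrom", "pos", "ref", "alt",
                                                "reason"])
    return PrioritizationResult(retained=retained, excluded=excluded,
                                ledger=ledger)


REPORT_COLUMNS = ["chrom", "pos", "rsid", "ref_alt", "n_transcripts",
                  "consequence", "novelty", "mendel_error",
                  "liver_expression", "associations", "pathogenicity"]


def shortlist_report(result: PrioritizationResult, annotations: pd.DataFrame,
                     call_set: CallSet,
                     design: CohortDesign) -> pd.DataFrame:
    """One row per retained variant with the standard 11 report columns.

    The Mendel-error flag is recomputed from the trio genotypes at each
    retained site; annotation fields missing for a variant are emitted as
    explicit '.' markers.
    """
    ann = annotations.set_index(["chrom", "pos", "ref", "alt"])
    by_key = call_set.by_key()
    rows = []
    for r in result.retained.itertuples(index=False):
        idx = (r.chrom, r.pos, r.ref, r.alt)
        a = ann.loc[idx] if idx in ann.index else None

        def get(col: str):
            if a is None or col not in a.index or pd.isna(a[col]):
                return "."
            return a[col]

        mend = False
        rec = by_key.get(VariantKey(*idx))
        if rec is not None and design.trio is not None:
            c, f, m = (call_set.genotype(rec, s) for s in design.trio)
            mend = is_mendel_error(c, f, m)
        rows.append({
            "chrom": r.chrom, "pos": r.pos, "rsid": get("rsid"),
            "ref_alt": f"{r.ref}>{r.alt}",
            "n_transcripts": get("n_transcripts"),
            "consequence": get("consequence"), "novelty": get("novelty"),
            "mendel_error": mend,
            "liver_expression": get("liver_expression"),
            "associations": get("associations"),
            "pathogenicity": get("gavin"),
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
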