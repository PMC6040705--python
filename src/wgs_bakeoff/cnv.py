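"""Window copy-number estimation and segmental-duplication calling.

Read depth is summarized in non-overlapping windows of 1 kbp of unmasked
sequence.  Copy number is depth scaled so that control (non-duplicated,
unmasked) windows average exactly 2, the diploid state.  A segmental
duplication is a run of consecutive windows whose copy number exceeds the
control mean plus ``k_sigma`` control standard deviations (the dispersion
correction), spanning at least ``min_span`` genomic bp; gaps of masked
sequence up to one window wide are bridged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortDesign
from .masks import GenomeMask, _merge


@dataclass
class CopyNumberProfile:
    windows: pd.DataFrame           # sample-free: chrom, start, end, depth, cn, is_control
    mean_cn: float
    sd_cn: float


@dataclass
class SegmentalDuplication:
    chrom: str
    start: int
    end: int
    mean_cn: float
    n_windows: int

    @property
    def span(self) -> int:
        return self.end - self.start


def compute_cn(windows: pd.DataFrame, control: np.ndarray | pd.Series | None = None,
               ) -> CopyNumberProfile:
    """Scale window depths to copy number against the control windows.

    ``control`` is a boolean vector marking the control (non-duplicated)
    windows; all windows are control when omitted.  cn = 2 * depth /
    mean(control depth), so the control mean copy number is 2 exactly.
    """
    df = windows.copy().reset_index(drop=True)
    if control is None:
        ctrl = np.ones(len(df), dtype=bool)
    else:
        ctrl = np.asarray(control, dtype=bool)
    if not ctrl.any():
        raise ValueError("control window set is empty")
    mean_depth = float(df.loc[ctrl, "depth"].mean())
    if mean_depth == 0:
        raise ValueError("zero mean control depth")
    df["cn"] = 2.0 * df["depth"] / mean_depth
    df["is_control"] = ctrl
    mean_cn = float(df.loc[ctrl, "cn"].mean())
    sd_cn = float(df.loc[ctrl, "cn"].std(ddof=0))
    return CopyNumberProfile(windows=df, mean_cn=mean_cn, sd_cn=sd_cn)


def call_segmental_duplications(profile: CopyNumberProfile,
                                min_span: int = 10_000,
                                k_sigma: float = 3.0,
                                bridge_windows: int = 1,
                                ) -> list[SegmentalDuplication]:
    """Merge consecutive above-threshold windows into duplications.

    Threshold = control mean + k_sigma * control sd.  Windows separated by
    missing (masked) genomic sequence up to ``bridge_windows`` windows wide
    are merged; an evaluated window below threshold always breaks a run.
    Runs shorter than ``min_span`` genomic bp are discarded.
    """
    thr = profile.mean_cn + k_sigma * profile.sd_cn
    df = profile.windows.sort_values(["chrom", "start"]).reset_index(drop=True)
    out: list[SegmentalDuplication] = []
    cur: list[pd.Series] = []

    def flush() -> None:
        nonlocal cur
        if cur:
            start, end = int(cur[0]["start"]), int(cur[-1]["end"])
            if end - start >= min_span:
                out.append(SegmentalDuplication(
                    chrom=str(cur[0]["chrom"]), start=start, end=end,
                    mean_cn=float(np.mean([w["cn"] for w in cur])),
                    n_windows=len(cur)))
        cur = []

    prev = None
    for _, w in df.iterrows():
        hot = w["cn"] > thr
        if prev is not None and cur:
            same = w["chrom"] == prev["chrom"]
            window_size = int(prev["end"] - prev["start"])
            gap = int(w["start"] - prev["end"])
            if not same or gap > bridge_windows * window_size:
                flush()
        if hot:
            cur.append(w)
        else:
            flush()
        prev = w
    flush()
    return out


def case_specific_sds(sd_lists: dict[str, list[SegmentalDuplication]],
                      design: CohortDesign, min_cases: int = 2,
                      ) -> list[tuple[str, int, int, int]]:
    """Regions duplicated in >= min_cases cases and in no healthy sample.

    Overlap means any shared base: a candidate shared-case region touching
    any healthy-sample duplication is excluded entirely.  Returns
    (chrom, start, end, n_cases) tuples.
    """
    if not design.parents:
        raise ValueError("design has no healthy samples to compare against")
    case_ivs: dict[str, list[tuple[int, int, str]]] = {}
    for s in design.cases:
        for sd in sd_lists.get(s, []):
            case_ivs.setdefault(sd.chrom, []).append((sd.start, sd.end, s))
    healthy = GenomeMask({}, label="healthy_sd")
    for s in design.parents:
        for sd in sd_lists.get(s, []):
            healthy.add(sd.chrom, sd.start, sd.end)

    out = []
    for chrom, ivs in case_ivs.items():
        # sweep line over case coverage
        events: list[tuple[int, int]] = []
        for s, e, _ in ivs:
            events.append((s, 1))
            events.append((e, -1))
        events.sort()
        depth = 0
        seg_start = None
        regions: list[tuple[int, int]] = []
        for x, d in events:
            new_depth = depth + d
            if depth < min_cases <= new_depth:
                seg_start = x
            elif new_depth < min_cases <= depth and seg_start is not None:
                regions.append((seg_start, x))
                seg_start = None
            depth = new_depth
        for s, e in _merge(regions):
            if not healthy.overlaps(chrom, s, e):
                n = len({smp for (a, b, smp) in ivs if a < e and s < b})
                out.append((chrom, s, e, n))
    return sorted(out)


def sd_jaccard(called: list[SegmentalDuplication],
               truth: list[tuple[str, int, int]]) -> float:
    """Interval Jaccard index between called and true duplicated regions."""
    a = GenomeMask({}, label="called")
    for sd in called:
        a.add(sd.chrom, sd.start, sd.end)
    b = GenomeMask({}, label="truth")
    for chrom, s, e in truth:
        b.add(chrom, s, e)
    inter = a.total_bp() + b.total_bp() - a.union(b).total_bp()
    union = a.union(b).total_bp()
    return inter / union if union else 1.0
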