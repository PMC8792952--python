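"""Runs-of-homozygosity detection and ROH-based inbreeding statistics.

The detector is a consecutive-runs scan: per sample and chromosome it finds
maximal windows of SNPs containing at most one heterozygote and one missing
call, never spanning an inter-SNP gap above ``max_gap_bp`` and never starting
or ending on a non-homozygous SNP, then filters them by minimum SNP count,
minimum length and SNP density, and finally selects non-overlapping windows
greedily from the left.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genotype_qc import GenotypePanel, GenotypeError

__all__ = [
    "ROHParams",
    "ROHSegment",
    "detect_roh",
    "segments_to_frame",
    "compute_froh",
    "froh_by_length_class",
    "inbreeding_summary",
    "DEFAULT_CLASS_EDGES_MBP",
]

#: length-class edges in Mbp; classes are half-open (lower, upper]
DEFAULT_CLASS_EDGES_MBP = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0, np.inf)


@dataclass(frozen=True)
class ROHParams:
    min_snps: int = 15
    min_length_bp: int = 1_000_000
    max_gap_bp: int = 500_000
    min_density: float = 1e-5  # SNPs per bp
    max_het: int = 1
    max_missing: int = 1


@dataclass(frozen=True)
class ROHSegment:
    sample_id: str
    chrom: int
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def _chrom_runs(
    pos: np.ndarray, dosage: np.ndarray, params: ROHParams
) -> list[tuple[int, int]]:
    """Selected run windows [i, j] (inclusive SNP indexes) on one chromosome."""
    n = len(pos)
    het = dosage == 1
    miss = dosage < 0
    hom = ~het & ~miss
    cum_het = np.concatenate(([0], np.cumsum(het)))
    cum_miss = np.concatenate(([0], np.cumsum(miss)))

    # blocks split at gaps > max_gap (a window may never span such a gap)
    big_gap = np.flatnonzero(np.diff(pos) > params.max_gap_bp)
    block_bounds = np.concatenate(([0], big_gap + 1, [n]))

    candidates: list[tuple[int, int]] = []
    for b in range(len(block_bounds) - 1):
        lo, hi = block_bounds[b], block_bounds[b + 1]  # [lo, hi)
        j = lo
        prev_jt = -1
        for i in range(lo, hi):
            if not hom[i]:
                continue
            if j < i:
                j = i
            # extend composition-feasible right edge (monotone two-pointer)
            while (
                j + 1 < hi
                and cum_het[j + 2] - cum_het[i] <= params.max_het
                and cum_miss[j + 2] - cum_miss[i] <= params.max_missing
            ):
                j += 1
            # trim right end to a homozygous SNP
            jt = j
            while jt >= i and not hom[jt]:
                jt -= 1
            if jt < i:
                continue
            # keep only the leftmost window reaching each right edge:
            # later i with the same jt is strictly contained
            if jt > prev_jt:
                candidates.append((i, jt))
                prev_jt = jt

    # criteria filters on whole candidate segments
    filtered = []
    for i, j in candidates:
        n_snps = j - i + 1
        length = int(pos[j] - pos[i])
        if n_snps < params.min_snps:
            continue
        if length < params.min_length_bp:
            continue
        if length > 0 and n_snps / length < params.min_density:
            continue
        filtered.append((i, j))

    # greedy left-to-right selection of non-overlapping windows
    selected: list[tuple[int, int]] = []
    last_end = -1
    for i, j in filtered:
        if i > last_end:
            selected.append((i, j))
            last_end = j
    return selected


def detect_roh(panel: GenotypePanel, params: ROHParams = ROHParams()) -> list[ROHSegment]:
    """Detect ROH segments for every sample in the panel.

    Deterministic; raises on an unsorted map (enforced by the panel itself).
    """
    segments: list[ROHSegment] = []
    chrom_arr = panel.snps["chrom"].to_numpy()
    bp_arr = panel.snps["bp"].to_numpy()
    for chrom in np.unique(chrom_arr):
        sel = chrom_arr == chrom
        pos = bp_arr[sel]
        if not np.all(np.diff(pos) > 0):
            raise GenotypeError(f"map not sorted on chromosome {chrom}")
        calls = panel.calls[:, sel]
        for s, sample_id in enumerate(panel.sample_ids):
            dosage = calls[s]
            for i, j in _chrom_runs(pos, dosage, params):
                window = dosage[i : j + 1]
                segments.append(
                    ROHSegment(
                        sample_id=sample_id,
                        chrom=int(chrom),
                        start_bp=int(pos[i]),
                        end_bp=int(pos[j]),
                        n_snps=j - i + 1,
                        n_het=int((window == 1).sum()),
                        n_missing=int((window < 0).sum()),
                    )
                )
    segments.sort(key=lambda s: (s.sample_id, s.chrom, s.start_bp))
    return segments


def segments_to_frame(segments: Iterable[ROHSegment]) -> pd.DataFrame:
    rows = [
        (s.sample_id, s.chrom, s.start_bp, s.end_bp, s.n_snps, s.n_het,
         s.n_missing, s.length_bp)
        for s in segments
    ]
    return pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "start_bp", "end_bp", "n_snps",
                 "n_het", "n_missing", "length_bp"],
    )


def compute_froh(
    segments: Iterable[ROHSegment],
    l_auto: float,
    sample_ids: Sequence[str],
    bounds: Optional[Mapping[int, tuple[int, int]]] = None,
) -> pd.Series:
    """F_ROH per sample: total ROH length / autosome length covered by SNPs.

    Samples without segments report 0.  If ``bounds`` (chrom -> (first_bp,
    last_bp)) is given, a segment outside them is a hard error.
    """
    if l_auto <= 0:
        raise ValueError("l_auto must be positive")
    totals = dict.fromkeys(sample_ids, 0.0)
    for s in segments:
        if bounds is not None:
            lo, hi = bounds[s.chrom]
            if s.start_bp < lo or s.end_bp > hi:
                raise ValueError(
                    f"segment {s.sample_id} chr{s.chrom}:{s.start_bp}-{s.end_bp} "
                    "outside map bounds"
                )
        if s.sample_id not in totals:
            raise ValueError(f"segment for unknown sample {s.sample_id!r}")
        totals[s.sample_id] += s.length_bp
    return pd.Series(
        {sid: totals[sid] / l_auto for sid in sample_ids}, name="F_ROH"
    )


def froh_by_length_class(
    segments: Iterable[ROHSegment],
    l_auto: float,
    cohorts: Mapping[str, object],
    class_edges_mbp: Sequence[float] = DEFAULT_CLASS_EDGES_MBP,
) -> pd.DataFrame:
    """Per cohort x length class: mean/SD of class F_ROH and mean segment count.

    ``cohorts`` maps every sample id to its cohort label; samples without
    segments in a class contribute zeros.  Classes are half-open intervals
    (edge_k, edge_{k+1}] over segment length in Mbp.
    """
    edges = [float(e) for e in class_edges_mbp]
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f">{lo:g}-{hi:g}" if np.isfinite(hi) else f">{lo:g}")
    samples = list(cohorts)
    s_index = {sid: k for k, sid in enumerate(samples)}
    froh = np.zeros((len(samples), len(labels)))
    counts = np.zeros((len(samples), len(labels)))
    for s in segments:
        if s.sample_id not in s_index:
            continue
        mbp = s.length_bp / 1e6
        cls = np.searchsorted(edges, mbp, side="left") - 1
        cls = min(max(cls, 0), len(labels) - 1)
        froh[s_index[s.sample_id], cls] += s.length_bp / l_auto
        counts[s_index[s.sample_id], cls] += 1

    df = pd.DataFrame(froh, columns=labels)
    df["cohort"] = [cohorts[sid] for sid in samples]
    rows = []
    for cohort, grp in df.groupby("cohort", sort=True):
        idx = grp.index.to_numpy()
        for k, label in enumerate(labels):
            rows.append(
                {
                    "cohort": cohort,
                    "length_class_mbp": label,
                    "mean_froh": froh[idx, k].mean(),
                    "sd_froh": froh[idx, k].std(ddof=1) if len(idx) > 1 else np.nan,
                    "mean_n_segments": counts[idx, k].mean(),
                    "n_animals": len(idx),
                }
            )
        rows.append(
            {
                "cohort": cohort,
                "length_class_mbp": "total",
                "mean_froh": froh[idx].sum(axis=1).mean(),
                "sd_froh": froh[idx].sum(axis=1).std(ddof=1) if len(idx) > 1 else np.nan,
                "mean_n_segments": counts[idx].sum(axis=1).mean(),
                "n_animals": len(idx),
            }
        )
    return pd.DataFrame(rows)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def inbreeding_summary(
    fped: Sequence[float],
    froh: Sequence[float],
    birth_years: Optional[Sequence] = None,
    cge: Optional[Sequence[float]] = None,
    cge_split: float = 10.0,
) -> dict:
    """Joint summary of pedigree and genomic inbreeding.

    Reports per-coefficient mean/SD/min/max/CV, Pearson r (overall, per
    birth year, and per CGE subgroup at ``cge_split``), mean+3SD
    highly-inbred thresholds and flag counts, and the overlap of the two
    flag sets as both Jaccard (|A&B|/|A|B|) and |A&B|/min(|A|,|B|).
    """
    fped = np.asarray(fped, dtype=float)
    froh = np.asarray(froh, dtype=float)
    if fped.shape != froh.shape:
        raise ValueError("fped and froh must be aligned")

    def stats(v: np.ndarray) -> dict:
        mean, sd = float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0
        return {
            "mean": mean,
            "sd": sd,
            "min": float(v.min()),
            "max": float(v.max()),
            "cv": sd / mean if mean != 0 else np.nan,
            "high_threshold": mean + 3.0 * sd,
        }

    out = {"F_ped": stats(fped), "F_ROH": stats(froh)}
    r = _pearson(fped, froh)
    if np.isnan(r):
        import warnings

        warnings.warn("correlation undefined (zero variance or n<3)", stacklevel=2)
    out["r_overall"] = r

    if birth_years is not None:
        by = np.asarray(birth_years)
        per_year = {}
        for y in np.unique(by[~pd.isna(by)]):
            m = by == y
            if m.sum() >= 3:
                per_year[int(y)] = _pearson(fped[m], froh[m])
        out["r_per_year"] = per_year
    if cge is not None:
        cge = np.asarray(cge, dtype=float)
        lo, hi = cge <= cge_split, cge > cge_split
        out["r_by_cge"] = {
            f"cge_le_{cge_split:g}": _pearson(fped[lo], froh[lo]),
            f"cge_gt_{cge_split:g}": _pearson(fped[hi], froh[hi]),
        }

    flag_ped = fped > out["F_ped"]["high_threshold"]
    flag_roh = froh > out["F_ROH"]["high_threshold"]
    inter = int((flag_ped & flag_roh).sum())
    union = int((flag_ped | flag_roh).sum())
    smaller = min(int(flag_ped.sum()), int(flag_roh.sum()))
    out["highly_inbred"] = {
        "n_fped": int(flag_ped.sum()),
        "n_froh": int(flag_roh.sum()),
        "n_common": inter,
        "overlap_jaccard": inter / union if union else np.nan,
        "overlap_min": inter / smaller if smaller else np.nan,
    }
    return out
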