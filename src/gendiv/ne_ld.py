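"""LD-based historical effective population size.

Pairwise squared dosage correlations within a distance cap are binned onto a
generations-ago grid via c = 1/(2t) (distance converted to recombination
fraction with a configurable map function), corrected for sample size, and
inverted to Ne(t) = (1/(4c)) * (1/r2_adj - alpha).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_qc import GenotypePanel

__all__ = [
    "pairwise_r2",
    "bp_to_recomb",
    "bin_pairs_by_generation",
    "estimate_ne",
    "ld_ne_pipeline",
]

log = logging.getLogger(__name__)


def pairwise_r2(
    panel: GenotypePanel,
    max_distance_bp: int,
    min_maf: float = 0.05,
) -> pd.DataFrame:
    """All intra-chromosomal SNP pairs within ``max_distance_bp``.

    r2 is the squared Pearson correlation of dosages over samples with both
    calls present (unphased genotype convention).  Pairs where either SNP has
    MAF < ``min_maf`` (among the shared samples each SNP's overall MAF is
    used), fewer than 2 informative samples, or zero variance are skipped;
    skip counts are logged.  Columns: chrom, distance_bp, r2.
    """
    maf = panel.maf()
    chrom_arr = panel.snps["chrom"].to_numpy()
    bp_arr = panel.snps["bp"].to_numpy()
    calls = panel.calls.astype(np.float64)
    missing = panel.calls < 0
    calls[missing] = np.nan

    rows_chrom, rows_dist, rows_r2 = [], [], []
    n_skipped = 0
    for chrom in np.unique(chrom_arr):
        sel = np.flatnonzero(chrom_arr == chrom)
        if maf is not None:
            sel = sel[np.nan_to_num(maf[sel]) >= min_maf]
        if len(sel) < 2:
            continue
        pos = bp_arr[sel]
        X = calls[:, sel]  # n_samples x m
        m = len(sel)
        for a in range(m - 1):
            b_hi = np.searchsorted(pos, pos[a] + max_distance_bp, side="right")
            if b_hi <= a + 1:
                continue
            xa = X[:, a]
            Xb = X[:, a + 1 : b_hi]
            both = ~np.isnan(xa[:, None]) & ~np.isnan(Xb)
            n = both.sum(axis=0)
            xa_f = np.where(both, xa[:, None], 0.0)
            xb_f = np.where(both, Xb, 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                sa = xa_f.sum(axis=0)
                sb = xb_f.sum(axis=0)
                saa = (xa_f**2).sum(axis=0)
                sbb = (xb_f**2).sum(axis=0)
                sab = (xa_f * xb_f).sum(axis=0)
                cov = sab - sa * sb / n
                va = saa - sa**2 / n
                vb = sbb - sb**2 / n
                r2 = cov**2 / (va * vb)
            ok = (n >= 2) & (va > 0) & (vb > 0)
            n_skipped += int((~ok).sum())
            dist = pos[a + 1 : b_hi] - pos[a]
            rows_chrom.append(np.full(ok.sum(), chrom))
            rows_dist.append(dist[ok])
            rows_r2.append(r2[ok])
    if n_skipped:
        log.info("skipped %d uninformative/monomorphic pairs", n_skipped)
    if not rows_chrom:
        return pd.DataFrame(columns=["chrom", "distance_bp", "r2"])
    return pd.DataFrame(
        {
            "chrom": np.concatenate(rows_chrom),
            "distance_bp": np.concatenate(rows_dist),
            "r2": np.clip(np.concatenate(rows_r2), 0.0, 1.0),
        }
    )


def bp_to_recomb(
    distance_bp: np.ndarray,
    mapping: str = "linear",
    cm_per_mb: float = 1.0,
) -> np.ndarray:
    """Convert physical distance to recombination fraction.

    ``linear``: c = d (Morgans, capped at 0.5); ``haldane``:
    c = (1 - exp(-2d))/2; ``sved_feldman``: c = d/(1 + 2d), the hyperbolic
    map that agrees with linear to first order.
    """
    d = np.asarray(distance_bp, dtype=float) * cm_per_mb / 100.0 / 1e6
    if mapping == "linear":
        return np.minimum(d, 0.5)
    if mapping == "haldane":
        return 0.5 * (1.0 - np.exp(-2.0 * d))
    if mapping == "sved_feldman":
        return d / (1.0 + 2.0 * d)
    raise ValueError(f"unknown mapping {mapping!r}")


def bin_pairs_by_generation(
    pairs: pd.DataFrame,
    generations: Sequence[int] = tuple(range(1, 31)),
    mapping: str = "linear",
    cm_per_mb: float = 1.0,
    min_pairs: int = 20,
) -> pd.DataFrame:
    """Assign pairs to generations-ago bins and average r2 within each.

    Each target t corresponds to c_t = 1/(2t); a pair's recombination
    fraction is bracketed by the midpoints between consecutive c_t values.
    Empty (or under-populated) bins are omitted with a log entry.
    """
    gens = np.asarray(sorted(generations))
    if np.any(gens <= 0):
        raise ValueError("generations must be positive")
    c_targets = 1.0 / (2.0 * gens)  # decreasing in t
    # bin edges over c, descending order of c == ascending t
    mids = 0.5 * (c_targets[:-1] + c_targets[1:])
    edges = np.concatenate(([np.inf], mids, [0.0]))  # edges[k] > c >= edges[k+1] -> t_k

    c = bp_to_recomb(pairs["distance_bp"].to_numpy(), mapping, cm_per_mb)
    rows = []
    for k, t in enumerate(gens):
        in_bin = (c <= edges[k]) & (c > edges[k + 1])
        n = int(in_bin.sum())
        if n < min_pairs:
            log.info("generation bin t=%d omitted (%d pairs < %d)", t, n, min_pairs)
            continue
        rows.append(
            {
                "t": int(t),
                "c": 1.0 / (2.0 * t),
                "mean_distance_bp": float(pairs["distance_bp"].to_numpy()[in_bin].mean()),
                "mean_r2": float(pairs["r2"].to_numpy()[in_bin].mean()),
                "n_pairs": n,
            }
        )
    return pd.DataFrame(rows, columns=["t", "c", "mean_distance_bp", "mean_r2",
                                       "n_pairs"])


def estimate_ne(
    binned: pd.DataFrame,
    alpha: float = 2.2,
    n_samples: int = 0,
    correction: str = "1/n",
) -> pd.DataFrame:
    """Invert binned mean r2 to an Ne series.

    r2_adj = mean r2 - correction term ("none", "1/n" or "1/(2n)");
    Ne(t) = (1/(4 c_t)) * (1/r2_adj - alpha).  Rows where r2_adj <= 0 or
    Ne <= 0 are emitted with a flag instead of a value.
    """
    if binned.empty:
        raise ValueError("no generation bins to estimate Ne from")
    if correction == "none":
        corr = 0.0
    elif correction == "1/n":
        if n_samples < 2:
            raise ValueError("n_samples >= 2 required for 1/n correction")
        corr = 1.0 / n_samples
    elif correction == "1/(2n)":
        if n_samples < 2:
            raise ValueError("n_samples >= 2 required for 1/(2n) correction")
        corr = 1.0 / (2.0 * n_samples)
    else:
        raise ValueError(f"unknown correction {correction!r}")

    rows = []
    for rec in binned.itertuples(index=False):
        r2_adj = rec.mean_r2 - corr
        flag = ""
        ne = np.nan
        if r2_adj <= 0:
            flag = "nonpositive_adjusted_r2"
        else:
            ne = (1.0 / (4.0 * rec.c)) * (1.0 / r2_adj - alpha)
            if ne <= 0:
                flag = "nonpositive_ne"
                ne = np.nan
        rows.append(
            {
                "t": rec.t,
                "mean_distance_bp": rec.mean_distance_bp,
                "mean_r2_adj": r2_adj,
                "n_pairs": rec.n_pairs,
                "ne": ne,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows).sort_values("t", ignore_index=True)


def ld_ne_pipeline(
    panel: GenotypePanel,
    max_distance_bp: int = 10_000_000,
    min_maf: float = 0.05,
    generations: Sequence[int] = tuple(range(1, 31)),
    mapping: str = "linear",
    cm_per_mb: float = 1.0,
    alpha: float = 2.2,
    correction: str = "1/n",
    min_pairs: int = 20,
) -> pd.DataFrame:
    """pairwise_r2 -> bin_pairs_by_generation -> estimate_ne in one call."""
    pairs = pairwise_r2(panel, max_distance_bp, min_maf)
    binned = bin_pairs_by_generation(pairs, generations, mapping, cm_per_mb,
                                     min_pairs)
    return estimate_ne(binned, alpha=alpha, n_samples=panel.n_samples,
                       correction=correction)
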