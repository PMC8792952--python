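"""Genotype container, PLINK text I/O, and four-criterion SNP quality control.

Genotypes are held as a sample x SNP dosage matrix (int8; 0/1/2 copies of the
lexicographically smaller observed allele, -1 for missing) alongside a sorted
genomic map restricted to autosomes 1-29.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "MISSING",
    "GenotypePanel",
    "GenotypeError",
    "QCThresholds",
    "read_plink",
    "write_plink",
    "hwe_exact_test",
    "mendel_mismatch_rates",
    "qc_filter",
]

log = logging.getLogger(__name__)

MISSING = -1
AUTOSOMES = frozenset(range(1, 30))


class GenotypeError(ValueError):
    """Malformed genotype input."""


@dataclass
class GenotypePanel:
    """Sample x SNP dosage matrix plus map.

    ``snps`` has columns ``snp_id``, ``chrom`` (int, 1-29), ``bp`` (1-based
    int), ``a1``, ``a2`` where ``a1`` is the counted (lexicographically
    smaller) allele.  ``calls`` is int8 with -1 for missing.
    """

    sample_ids: list[str]
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.snps)):
            raise GenotypeError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        self.snps = self.snps.reset_index(drop=True)
        chrom = self.snps["chrom"].to_numpy()
        bp = self.snps["bp"].to_numpy()
        for c in np.unique(chrom):
            pos = bp[chrom == c]
            if not np.all(np.diff(pos) > 0):
                raise GenotypeError(
                    f"positions on chromosome {c} not strictly increasing"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset_snps(self, mask: np.ndarray) -> "GenotypePanel":
        mask = np.asarray(mask, dtype=bool)
        return GenotypePanel(
            sample_ids=list(self.sample_ids),
            snps=self.snps.loc[mask].reset_index(drop=True),
            calls=self.calls[:, mask].copy(),
        )

    def autosome_length(self) -> int:
        """Total bp spanned by SNPs: sum over chromosomes of last - first."""
        g = self.snps.groupby("chrom")["bp"]
        return int((g.max() - g.min()).sum())

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele per SNP (NaN if all missing)."""
        obs = self.calls >= 0
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(obs, self.calls, 0).sum(axis=0) / np.where(
                n > 0, 2.0 * n, np.nan
            )

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return (self.calls >= 0).mean(axis=0)


def read_plink(ped_path, map_path) -> GenotypePanel:
    """Read PLINK text PED/MAP into a :class:`GenotypePanel`.

    Alleles are recoded to dosage of the lexicographically smaller observed
    allele; ``0 0`` (or any half-missing pair) becomes missing.  MAP rows on
    chromosomes outside 1-29 are dropped (count logged).  A SNP with more
    than two observed alleles is a hard error.
    """
    snp_map = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "bp"],
        dtype={"chrom": str, "snp_id": str, "bp": int},
    )
    chrom_num = pd.to_numeric(snp_map["chrom"], errors="coerce")
    keep = chrom_num.isin(list(AUTOSOMES))
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("dropped %d non-autosomal MAP row(s)", n_dropped)
    n_total = len(snp_map)

    sample_ids: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_total:
                raise GenotypeError(
                    f"ragged PED row {ln}: {len(fields)} fields, "
                    f"expected {6 + 2 * n_total}"
                )
            sample_ids.append(fields[1])
            allele_rows.append(np.array(fields[6:], dtype=object))
    alleles = (
        np.array(allele_rows, dtype=object).reshape(len(sample_ids), n_total, 2)
        if sample_ids else np.empty((0, n_total, 2), dtype=object)
    )

    keep_idx = np.flatnonzero(keep.to_numpy())
    snps = snp_map.iloc[keep_idx][["snp_id", "bp"]].copy()
    snps["chrom"] = chrom_num.iloc[keep_idx].astype(int).to_numpy()
    alleles = alleles[:, keep_idx, :]

    n_snps = len(snps)
    calls = np.full((len(sample_ids), n_snps), MISSING, dtype=np.int8)
    a1_list, a2_list = [], []
    for j in range(n_snps):
        pair = alleles[:, j, :]
        miss = (pair == "0").any(axis=1)
        observed = sorted(set(pair[~miss].ravel().tolist()))
        if len(observed) > 2:
            raise GenotypeError(
                f"SNP {snps['snp_id'].iloc[j]!r} has >2 alleles: {observed}"
            )
        a1 = observed[0] if observed else "0"
        a2 = observed[1] if len(observed) > 1 else a1
        a1_list.append(a1)
        a2_list.append(a2)
        if observed:
            calls[~miss, j] = (pair[~miss] == a1).sum(axis=1)
    snps["a1"] = a1_list
    snps["a2"] = a2_list
    snps = snps[["snp_id", "chrom", "bp", "a1", "a2"]]
    order = np.lexsort((snps["bp"].to_numpy(), snps["chrom"].to_numpy()))
    snps = snps.iloc[order].reset_index(drop=True)
    calls = calls[:, order]
    return GenotypePanel(sample_ids=sample_ids, snps=snps, calls=calls)


def write_plink(panel: GenotypePanel, ped_path, map_path) -> None:
    """Write a panel back to PLINK text PED/MAP (cM emitted as 0)."""
    with open(map_path, "w") as fh:
        for row in panel.snps.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.bp}\n")
    a1 = panel.snps["a1"].to_numpy()
    a2 = panel.snps["a2"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(panel.sample_ids):
            out = [sid, sid, "0", "0", "0", "-9"]
            row = panel.calls[i]
            for j, d in enumerate(row):
                if d < 0:
                    out += ["0", "0"]
                elif d == 0:
                    out += [a2[j], a2[j]]
                elif d == 1:
                    out += [a1[j], a2[j]]
                else:
                    out += [a1[j], a1[j]]
            fh.write(" ".join(out) + "\n")


def hwe_exact_test(n_aa_hom1: int, n_het: int, n_hom2: int,
                   midp: bool = False) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Probability-ordering convention: the p-value is the total probability of
    heterozygote counts (conditional on allele counts) no more likely than
    the observed one.  Monomorphic input returns 1.0.  ``midp=True`` gives
    the mid-p variant (half weight on the observed outcome's probability).
    """
    if min(n_aa_hom1, n_het, n_hom2) < 0:
        raise ValueError("negative genotype count")
    n = n_aa_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("empty sample")
    n_rare = 2 * min(n_aa_hom1, n_hom2) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    # distribution of het count over {n_rare mod 2, ..., <= min(n_rare, 2n-n_rare)}
    het_max = min(n_rare, 2 * n - n_rare)
    hets = np.arange(n_rare % 2, het_max + 1, 2)
    # unnormalized log-probabilities via the hypergeometric-like closed form
    from scipy.special import gammaln

    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1.0)
        - gammaln(rare_hom + 1.0)
        - gammaln(common_hom + 1.0)
        + hets * np.log(2.0)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs_prob = probs[np.searchsorted(hets, n_het)]
    le = probs <= obs_prob * (1 + 1e-12)  # guard float ties
    p = probs[le].sum()
    if midp:
        p -= 0.5 * obs_prob
    return float(min(1.0, p))


def mendel_mismatch_rates(
    panel: GenotypePanel, pedigree: Pedigree
) -> np.ndarray:
    """Per-SNP opposing-homozygote rate over genotyped parent-offspring pairs.

    Each genotyped parent contributes one pair per genotyped offspring (an
    animal with two genotyped parents yields two pairs).  The rate is
    opposing homozygotes / pairs with both calls present; NaN where no pair
    is informative.  With no genotyped pairs at all, every SNP is NaN and a
    warning is raised.
    """
    sample_index = {s: i for i, s in enumerate(panel.sample_ids)}
    off_rows, par_rows = [], []
    for animal in panel.sample_ids:
        if animal not in pedigree:
            continue
        for pid in pedigree.parents(animal):
            if pid is not None and pid in sample_index:
                off_rows.append(sample_index[animal])
                par_rows.append(sample_index[pid])
    if not off_rows:
        warnings.warn("no genotyped parent-offspring pairs; Mendel rates all NA",
                      stacklevel=2)
        return np.full(panel.n_snps, np.nan)
    off = panel.calls[off_rows]
    par = panel.calls[par_rows]
    valid = (off >= 0) & (par >= 0)
    opposing = valid & (np.abs(off.astype(np.int16) - par) == 2)
    denom = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, opposing.sum(axis=0) / denom, np.nan)


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion bounds; a SNP is dropped when it crosses any of them."""

    min_call_rate: float = 0.95
    max_mendel_mismatch: float = 0.01
    min_maf: float = 0.01
    min_genotype_freq: float = 0.001
    min_hwe_p: float = 0.005


# fixed evaluation order; first failing criterion is the recorded reason
_CRITERIA = ("call_rate", "mendel", "maf", "genotype_freq", "hwe")


def qc_filter(
    panel: GenotypePanel,
    pedigree: Optional[Pedigree] = None,
    thresholds: QCThresholds = QCThresholds(),
    hwe_midp: bool = False,
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Apply the SNP QC criteria; returns (filtered panel, per-SNP report).

    Criteria in fixed order: call rate, parent-offspring mismatch, MAF,
    minimum observed genotype-class frequency, HWE exact test.  Samples are
    never removed.  SNPs with no informative Mendel pairs pass that
    criterion (rate NA).  An empty surviving panel is a hard error.
    """
    t = thresholds
    call_rate = panel.call_rate()
    maf = panel.maf()
    if pedigree is not None:
        mendel = mendel_mismatch_rates(panel, pedigree)
    else:
        mendel = np.full(panel.n_snps, np.nan)

    n_hom_a = (panel.calls == 2).sum(axis=0)
    n_het = (panel.calls == 1).sum(axis=0)
    n_hom_b = (panel.calls == 0).sum(axis=0)
    n_obs = n_hom_a + n_het + n_hom_b

    geno_freq = np.full(panel.n_snps, np.nan)
    hwe_p = np.full(panel.n_snps, np.nan)
    for j in range(panel.n_snps):
        if n_obs[j] == 0:
            continue
        counts = [n_hom_a[j], n_het[j], n_hom_b[j]]
        observed = [c for c in counts if c > 0]
        geno_freq[j] = min(observed) / n_obs[j]
        hwe_p[j] = hwe_exact_test(n_hom_a[j], n_het[j], n_hom_b[j], midp=hwe_midp)

    fails = {
        "call_rate": call_rate < t.min_call_rate,
        "mendel": np.nan_to_num(mendel, nan=0.0) > t.max_mendel_mismatch,
        "maf": np.nan_to_num(maf, nan=0.0) < t.min_maf,
        "genotype_freq": np.nan_to_num(geno_freq, nan=1.0) < t.min_genotype_freq,
        "hwe": np.nan_to_num(hwe_p, nan=1.0) < t.min_hwe_p,
    }
    verdict = np.full(panel.n_snps, "kept", dtype=object)
    for name in reversed(_CRITERIA):
        verdict[fails[name]] = f"dropped:{name}"

    report = pd.DataFrame(
        {
            "snp_id": panel.snps["snp_id"],
            "call_rate": call_rate,
            "maf": maf,
            "min_genotype_freq": geno_freq,
            "mendel_mismatch_rate": mendel,
            "hwe_p": hwe_p,
            "verdict": verdict,
        }
    )
    kept = verdict == "kept"
    if not kept.any():
        raise GenotypeError("QC removed every SNP")
    return panel.subset_snps(kept), report
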