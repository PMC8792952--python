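"""Synthetic herd generators with known ground truth.

Three generators cover the pipeline's needs: an overlapping-generation
pedigree simulator with era-specific generation intervals for the four
selection pathways, a gene-dropping engine that transmits labelled founder
haplotypes with Poisson recombination (so every animal's true autozygous
intervals are known), and a discrete-generation Wright-Fisher simulator of
known effective size for LD-based Ne recovery.  All are byte-deterministic
for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genotype_qc import GenotypePanel, write_plink
from .pedigree import PATHWAYS, Pedigree, PedigreeRecord

__all__ = [
    "Genome",
    "HerdScenario",
    "SimulationError",
    "simulate_pedigree",
    "gene_drop",
    "simulate_wright_fisher",
    "make_fixture",
    "FIXTURE_NAMES",
]

MORGAN_BP = 100_000_000  # 1 Morgan per 100 Mb (1 cM/Mb)


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Genome:
    """Chromosome lengths in bp (chromosomes numbered from 1) and SNP density."""

    chrom_lengths_bp: tuple[int, ...] = (100_000_000, 100_000_000)
    snps_per_mb: float = 10.0

    def snp_positions(self, chrom: int) -> np.ndarray:
        """Evenly spaced 1-based positions on ``chrom`` (1-based index)."""
        length = self.chrom_lengths_bp[chrom - 1]
        step = int(1e6 / self.snps_per_mb)
        return np.arange(step // 2, length, step, dtype=np.int64) + 1

    @property
    def n_chroms(self) -> int:
        return len(self.chrom_lengths_bp)

    def total_length(self) -> int:
        return int(sum(self.chrom_lengths_bp))


_DEFAULT_GI = {
    "sire_of_bulls": 6.0,
    "dam_of_bulls": 4.0,
    "sire_of_cows": 6.0,
    "dam_of_cows": 4.0,
}


@dataclass(frozen=True)
class HerdScenario:
    n_founders: int = 40
    start_year: int = 2000
    end_year: int = 2015
    offspring_per_year: int = 30
    prop_male: float = 0.5
    gi_pre: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_GI))
    gi_post: Optional[Mapping[str, float]] = None
    gi_sd: float = 0.0
    switch_year: Optional[int] = None
    mating: str = "random"  # or "sire_dominant"
    top_k_sires_pre: int = 5
    top_k_sires_post: int = 5
    genome: Genome = Genome()
    seed: int = 0

    def __post_init__(self):
        if self.n_founders < 2 or self.offspring_per_year < 1:
            raise ValueError("counts must be positive")
        if self.switch_year is not None and not (
            self.start_year <= self.switch_year <= self.end_year
        ):
            raise ValueError("switch year outside year range")
        if self.mating not in ("random", "sire_dominant"):
            raise ValueError(f"unknown mating scheme {self.mating!r}")


def _gi_for(scenario: HerdScenario, pathway: str, year: int) -> float:
    post = (
        scenario.switch_year is not None
        and year >= scenario.switch_year
        and scenario.gi_post is not None
    )
    table = scenario.gi_post if post else scenario.gi_pre
    return float(table[pathway])


def simulate_pedigree(scenario: HerdScenario) -> tuple[Pedigree, pd.DataFrame]:
    """Overlapping-generation pedigree with pathway-specific parent ages.

    Founder birth years are spread over the decade before ``start_year`` so
    target parent ages are attainable from year one.  Returns the pedigree
    and the ground-truth GI table (pathway, era, target mean).  Raises
    :class:`SimulationError` naming the year if no eligible parent exists.
    """
    rng = np.random.default_rng(scenario.seed)
    records: list[PedigreeRecord] = []
    by_year_sex: dict[tuple[int, str], list[str]] = {}

    def add(rec: PedigreeRecord):
        records.append(rec)
        by_year_sex.setdefault((rec.birth_year, rec.sex), []).append(rec.animal_id)

    max_age = 10
    for k in range(scenario.n_founders):
        sex = "M" if k % 2 == 0 else "F"
        year = scenario.start_year - 1 - ((k // 2) % max_age)
        add(PedigreeRecord(f"FND{k:04d}", sex=sex, birth_year=year))

    n_male = int(round(scenario.offspring_per_year * scenario.prop_male))

    def pick_parent(year: int, sex: str, pathway: str,
                    pool: Optional[set] = None) -> str:
        target = _gi_for(scenario, pathway, year)
        if scenario.gi_sd > 0:
            target = max(1.0, rng.normal(target, scenario.gi_sd))
        age = max(1, int(round(target)))
        for delta in sorted(range(-max_age, max_age + 1), key=lambda d: (abs(d), d)):
            cands = by_year_sex.get((year - (age + delta), sex), [])
            if pool is not None:
                cands = [c for c in cands if c in pool]
            if cands:
                return cands[rng.integers(len(cands))]
        if pool:
            # dominant-sire pool may hold no male of the target age; the
            # pool wins over the GI target (mirrors heavy reuse of old sires)
            members = sorted(pool)
            return members[rng.integers(len(members))]
        raise SimulationError(
            f"no eligible {sex} parent for year {year} (pathway {pathway})"
        )

    for year in range(scenario.start_year, scenario.end_year + 1):
        sire_pool: Optional[set] = None
        if scenario.mating == "sire_dominant":
            k = (
                scenario.top_k_sires_post
                if scenario.switch_year is not None and year >= scenario.switch_year
                else scenario.top_k_sires_pre
            )
            males = [
                sid
                for (y, sx), ids in sorted(by_year_sex.items())
                if sx == "M" and y < year
                for sid in ids
            ]
            if not males:
                raise SimulationError(f"no eligible M parent for year {year}")
            idx = rng.choice(len(males), size=min(k, len(males)), replace=False)
            sire_pool = {males[i] for i in idx}
        for i in range(scenario.offspring_per_year):
            sex = "M" if i < n_male else "F"
            s_path = "sire_of_bulls" if sex == "M" else "sire_of_cows"
            d_path = "dam_of_bulls" if sex == "M" else "dam_of_cows"
            sire = pick_parent(year, "M", s_path, sire_pool)
            dam = pick_parent(year, "F", d_path)
            add(
                PedigreeRecord(
                    f"A{year}{i:03d}", sire_id=sire, dam_id=dam,
                    sex=sex, birth_year=year,
                )
            )

    truth_rows = []
    for pathway in PATHWAYS:
        truth_rows.append({"pathway": pathway, "era": "pre",
                           "target_gi": scenario.gi_pre[pathway]})
        if scenario.gi_post is not None:
            truth_rows.append({"pathway": pathway, "era": "post",
                               "target_gi": scenario.gi_post[pathway]})
    return Pedigree(records), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# haplotype tracks: (starts, labels) with starts[0] == 1, intervals
# [starts[k], starts[k+1]) and the last interval running to chromosome end


def _recombine(track0, track1, chrom_len: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """One meiosis over a chromosome: Poisson crossovers, random start hap."""
    n_xo = rng.poisson(chrom_len / MORGAN_BP)
    tracks = (track0, track1)
    h = int(rng.integers(2))
    if n_xo == 0:
        s, l = tracks[h]
        return s.copy(), l.copy()
    xs = np.sort(rng.integers(2, chrom_len, size=n_xo))
    bounds = np.concatenate(([1], xs, [chrom_len + 1]))
    out_starts: list[int] = []
    out_labels: list[int] = []
    for k in range(len(bounds) - 1):
        lo, hi = int(bounds[k]), int(bounds[k + 1])
        if lo >= hi:
            h ^= 1
            continue
        starts, labels = tracks[h]
        i0 = np.searchsorted(starts, lo, side="right") - 1
        i1 = np.searchsorted(starts, hi, side="left")
        for i in range(i0, i1):
            seg_start = max(int(starts[i]), lo)
            lab = int(labels[i])
            if out_labels and out_labels[-1] == lab and out_starts[-1] <= seg_start:
                continue  # merge with previous identical-label segment
            out_starts.append(seg_start)
            out_labels.append(lab)
        h ^= 1
    return np.asarray(out_starts, dtype=np.int64), np.asarray(out_labels, dtype=np.int64)


def _labels_at(track, positions: np.ndarray) -> np.ndarray:
    starts, labels = track
    return labels[np.searchsorted(starts, positions, side="right") - 1]


def _autozygous_intervals(track0, track1, chrom_len: int) -> list[tuple[int, int]]:
    """Intervals [start, end) where the two haplotype labels coincide."""
    s0, l0 = track0
    s1, l1 = track1
    cuts = np.unique(np.concatenate((s0, s1, [chrom_len + 1])))
    out: list[tuple[int, int]] = []
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        a = l0[np.searchsorted(s0, lo, side="right") - 1]
        b = l1[np.searchsorted(s1, lo, side="right") - 1]
        if a == b:
            if out and out[-1][1] == lo:
                out[-1] = (out[-1][0], int(hi))
            else:
                out.append((int(lo), int(hi)))
    return out


def gene_drop(
    pedigree: Pedigree,
    genome: Genome,
    seed: int,
    founder_freq_range: tuple[float, float] = (0.1, 0.9),
    samples: Optional[Sequence[str]] = None,
    genotypes: bool = True,
) -> tuple[Optional[GenotypePanel], dict]:
    """Drop labelled founder haplotypes through the pedigree.

    Founders receive two uniquely labelled haplotypes per chromosome; each
    meiosis recombines with Poisson crossovers at 1 Morgan / 100 Mb
    (Haldane, no interference).  Biallelic SNP alleles are assigned to
    founder haplotypes at frequencies drawn uniformly from
    ``founder_freq_range``.  Returns the genotype panel (or ``None`` when
    ``genotypes=False``) and a ground-truth dict with per-animal autozygous
    intervals and fractions.
    """
    rng = np.random.default_rng(seed)
    order = pedigree.animal_ids
    founder_count = sum(pedigree.is_founder(a) for a in order)
    founder_idx: dict[str, int] = {}

    total_len = genome.total_length()
    tracks: dict[str, list] = {}  # animal -> per-chrom [(track0, track1), ...]
    auto_intervals: dict[str, list[tuple[int, int, int]]] = {}
    auto_frac: dict[str, float] = {}

    for animal in order:
        per_chrom = []
        if pedigree.is_founder(animal):
            fi = founder_idx.setdefault(animal, len(founder_idx))
            for c in range(1, genome.n_chroms + 1):
                t0 = (np.array([1], dtype=np.int64), np.array([2 * fi], dtype=np.int64))
                t1 = (np.array([1], dtype=np.int64), np.array([2 * fi + 1], dtype=np.int64))
                per_chrom.append((t0, t1))
        else:
            sire, dam = pedigree.parents(animal)
            for c in range(1, genome.n_chroms + 1):
                length = genome.chrom_lengths_bp[c - 1]
                gametes = []
                for parent in (sire, dam):
                    if parent is None:
                        # unknown parent: fresh unique founder haplotype
                        fi = len(founder_idx)
                        founder_idx[f"__unk_{animal}_{c}_{len(gametes)}"] = fi
                        gametes.append(
                            (np.array([1], dtype=np.int64),
                             np.array([2 * fi], dtype=np.int64))
                        )
                    else:
                        t0, t1 = tracks[parent][c - 1]
                        gametes.append(_recombine(t0, t1, length, rng))
                per_chrom.append(tuple(gametes))
        tracks[animal] = per_chrom

        ivs = []
        auto_bp = 0
        for c in range(1, genome.n_chroms + 1):
            t0, t1 = tracks[animal][c - 1]
            for lo, hi in _autozygous_intervals(t0, t1, genome.chrom_lengths_bp[c - 1]):
                ivs.append((c, lo, hi))
                auto_bp += hi - lo
        auto_intervals[animal] = ivs
        auto_frac[animal] = auto_bp / total_len

    truth = {
        "autozygous_intervals": auto_intervals,
        "autozygous_fraction": pd.Series(auto_frac, name="true_autozygosity"),
    }

    if not genotypes:
        return None, truth

    sample_ids = list(samples) if samples is not None else list(order)
    n_hap = 2 * len(founder_idx)
    snp_frames = []
    call_blocks = []
    for c in range(1, genome.n_chroms + 1):
        pos = genome.snp_positions(c)
        freqs = rng.uniform(*founder_freq_range, size=len(pos))
        hap_alleles = (rng.random((n_hap, len(pos))) < freqs).astype(np.int8)
        block = np.empty((len(sample_ids), len(pos)), dtype=np.int8)
        for si, animal in enumerate(sample_ids):
            t0, t1 = tracks[animal][c - 1]
            lab0 = _labels_at(t0, pos)
            lab1 = _labels_at(t1, pos)
            block[si] = hap_alleles[lab0, np.arange(len(pos))] + hap_alleles[
                lab1, np.arange(len(pos))
            ]
        call_blocks.append(block)
        snp_frames.append(
            pd.DataFrame(
                {
                    "snp_id": [f"snp{c}_{k}" for k in range(len(pos))],
                    "chrom": c,
                    "bp": pos,
                    "a1": "A",
                    "a2": "B",
                }
            )
        )
    panel = GenotypePanel(
        sample_ids=sample_ids,
        snps=pd.concat(snp_frames, ignore_index=True),
        calls=np.concatenate(call_blocks, axis=1),
    )
    return panel, truth


def simulate_wright_fisher(
    ne: int,
    n_generations: int,
    genome: Genome,
    n_sampled: int,
    seed: int,
    maf_floor: float = 0.05,
    init_freq_range: tuple[float, float] = (0.1, 0.9),
    track_heterozygosity: bool = False,
):
    """Discrete-generation Wright-Fisher diploids with recombination.

    Starts from linkage equilibrium at uniform random site frequencies,
    mates randomly (two parents drawn with replacement each offspring) for
    ``n_generations``, samples ``n_sampled`` diploids and ascertains sites
    at final-generation MAF >= ``maf_floor``.  With
    ``track_heterozygosity=True`` returns ``(panel, het_series)`` where
    ``het_series[t]`` is the population mean observed heterozygosity after
    generation t.
    """
    if ne < 2 or n_generations < 1:
        raise ValueError("need ne >= 2 and n_generations >= 1")
    if n_sampled > ne:
        raise ValueError(f"cannot sample {n_sampled} from population of {ne}")
    rng = np.random.default_rng(seed)

    positions = [genome.snp_positions(c) for c in range(1, genome.n_chroms + 1)]
    lengths = genome.chrom_lengths_bp
    # haps[c]: (2*ne, n_sites) int8; rows 2i, 2i+1 belong to individual i
    haps = []
    for pos in positions:
        freqs = rng.uniform(*init_freq_range, size=len(pos))
        haps.append((rng.random((2 * ne, len(pos))) < freqs).astype(np.int8))

    het_series = []
    for _ in range(n_generations):
        new_haps = [np.empty_like(h) for h in haps]
        parents = rng.integers(ne, size=(ne, 2))
        for i in range(ne):
            for which, parent in enumerate(parents[i]):
                for c, pos in enumerate(positions):
                    h0 = haps[c][2 * parent]
                    h1 = haps[c][2 * parent + 1]
                    n_xo = rng.poisson(lengths[c] / MORGAN_BP)
                    cur = int(rng.integers(2))
                    if n_xo == 0:
                        gamete = h0 if cur == 0 else h1
                    else:
                        xs = np.sort(rng.integers(2, lengths[c], size=n_xo))
                        seg = np.searchsorted(xs, pos, side="right")
                        use1 = (seg + cur) % 2 == 1
                        gamete = np.where(use1, h1, h0)
                    new_haps[c][2 * i + which] = gamete
        haps = new_haps
        if track_heterozygosity:
            het_series.append(
                float(
                    np.mean(
                        [np.mean(h[0::2] != h[1::2]) for h in haps]
                    )
                )
            )

    idx = rng.choice(ne, size=n_sampled, replace=False)
    sample_ids = [f"WF{i:04d}" for i in range(n_sampled)]
    snp_frames = []
    call_blocks = []
    for c, pos in enumerate(positions):
        dosage = haps[c][2 * idx] + haps[c][2 * idx + 1]
        freq = dosage.mean(axis=0) / 2.0
        keep = np.minimum(freq, 1 - freq) >= maf_floor
        if keep.any():
            call_blocks.append(dosage[:, keep].astype(np.int8))
            snp_frames.append(
                pd.DataFrame(
                    {
                        "snp_id": [f"wf{c + 1}_{k}" for k in np.flatnonzero(keep)],
                        "chrom": c + 1,
                        "bp": pos[keep],
                        "a1": "A",
                        "a2": "B",
                    }
                )
            )
    if not snp_frames:
        raise SimulationError(
            "all sites fixed; increase initial variation or shorten the run"
        )
    panel = GenotypePanel(
        sample_ids=sample_ids,
        snps=pd.concat(snp_frames, ignore_index=True),
        calls=np.concatenate(call_blocks, axis=1),
    )
    if track_heterozygosity:
        return panel, np.asarray(het_series)
    return panel


# ---------------------------------------------------------------------------
# registered on-disk fixtures


def _write_pedigree_csv(ped: Pedigree, path: Path) -> None:
    ped.to_frame().to_csv(path, index=False)


def _fixture_small_herd(out: Path) -> None:
    scenario = HerdScenario(
        n_founders=24, start_year=2000, end_year=2012, offspring_per_year=24,
        genome=Genome((60_000_000, 60_000_000), snps_per_mb=15.0), seed=11,
    )
    ped, gi_truth = simulate_pedigree(scenario)
    panel, truth = gene_drop(ped, scenario.genome, seed=12)
    _write_pedigree_csv(ped, out / "pedigree.csv")
    write_plink(panel, out / "genotypes.ped", out / "genotypes.map")
    truth["autozygous_fraction"].rename_axis("id").reset_index().to_csv(
        out / "true_autozygosity.tsv", sep="\t", index=False
    )
    gi_truth.to_csv(out / "true_gi.tsv", sep="\t", index=False)


def _fixture_gs_transition_herd(out: Path) -> None:
    scenario = HerdScenario(
        n_founders=30, start_year=2000, end_year=2019, offspring_per_year=40,
        switch_year=2011, mating="sire_dominant",
        top_k_sires_pre=10, top_k_sires_post=2,
        gi_pre=dict(_DEFAULT_GI),
        gi_post={"sire_of_bulls": 3.0, "dam_of_bulls": 3.0,
                 "sire_of_cows": 3.0, "dam_of_cows": 3.0},
        genome=Genome((60_000_000,), snps_per_mb=10.0), seed=21,
    )
    ped, gi_truth = simulate_pedigree(scenario)
    _write_pedigree_csv(ped, out / "pedigree.csv")
    panel, truth = gene_drop(ped, scenario.genome, seed=22)
    write_plink(panel, out / "genotypes.ped", out / "genotypes.map")
    truth["autozygous_fraction"].rename_axis("id").reset_index().to_csv(
        out / "true_autozygosity.tsv", sep="\t", index=False
    )
    gi_truth.to_csv(out / "true_gi.tsv", sep="\t", index=False)


def _fixture_wf_ne100(out: Path) -> None:
    panel = simulate_wright_fisher(
        ne=100, n_generations=60,
        genome=Genome((50_000_000, 50_000_000), snps_per_mb=8.0),
        n_sampled=80, seed=31,
    )
    write_plink(panel, out / "genotypes.ped", out / "genotypes.map")
    (out / "true_ne.tsv").write_text("true_ne\n100\n")


def _fixture_toy_worked_examples(out: Path) -> None:
    # the worked pedigrees from the module docs: full-sib and half-sib matings
    rows = [
        "id,sire,dam,sex,birth_year",
        "S1,0,0,M,2000",
        "D1,0,0,F,2000",
        "D2,0,0,F,2000",
        "B1,S1,D1,M,2003",
        "C1,S1,D1,F,2003",
        "C2,S1,D2,F,2003",
        "X_FULLSIB,B1,C1,F,2008",
        "X_HALFSIB,B1,C2,F,2008",
    ]
    (out / "pedigree.csv").write_text("\n".join(rows) + "\n")
    # 2-sample 3-SNP genotypes with one missing call
    (out / "genotypes.map").write_text(
        "1\ts1\t0\t1000000\n1\ts2\t0\t2000000\n2\ts3\t0\t1500000\n"
    )
    (out / "genotypes.ped").write_text(
        "X_FULLSIB X_FULLSIB 0 0 2 -9 A A A G G G\n"
        "X_HALFSIB X_HALFSIB 0 0 2 -9 A A 0 0 G G\n"
    )


_FIXTURES = {
    "small_herd": _fixture_small_herd,
    "gs_transition_herd": _fixture_gs_transition_herd,
    "wf_ne100": _fixture_wf_ne100,
    "toy_worked_examples": _fixture_toy_worked_examples,
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def make_fixture(name: str, out_dir) -> Path:
    """Write a registered fixture's files under ``out_dir/name``; byte-stable."""
    if name not in _FIXTURES:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    out = Path(out_dir) / name
    out.mkdir(parents=True, exist_ok=True)
    _FIXTURES[name](out)
    return out
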