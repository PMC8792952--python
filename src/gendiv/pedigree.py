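"""Pedigree data model and genealogy-based statistics.

Provides the :class:`Pedigree` container (validated, topologically ordered
parent map) and the statistics computed from it: pedigree inbreeding
coefficients (F_ped, tabular/recursive-kinship method), complete generation
equivalents (CGE), generation intervals split by the four selection pathways,
and a pedigree-based effective population size series derived from the rate
of inbreeding per generation cohort.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UNKNOWN",
    "PedigreeRecord",
    "Pedigree",
    "PedigreeError",
    "CycleError",
    "load_pedigree",
    "compute_fped",
    "compute_cge",
    "generation_intervals",
    "pedigree_ne",
    "PATHWAYS",
]

#: Sentinel for an unknown parent.
UNKNOWN = None

PATHWAYS = ("sire_of_bulls", "dam_of_bulls", "sire_of_cows", "dam_of_cows")


class PedigreeError(ValueError):
    """Invalid pedigree input (duplicate ids, malformed rows, ...)."""


class CycleError(PedigreeError):
    """An animal is its own ancestor."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One pedigree row.

    ``sire_id``/``dam_id`` are ``None`` when unknown; ``sex`` is one of
    ``"M"``, ``"F"``, ``"U"``; ``birth_year`` is ``None`` when missing.
    """

    animal_id: str
    sire_id: Optional[str] = None
    dam_id: Optional[str] = None
    sex: str = "U"
    birth_year: Optional[int] = None


class Pedigree:
    """Validated, acyclic pedigree with parents ordered before offspring."""

    def __init__(self, records: Iterable[PedigreeRecord]):
        recs: dict[str, PedigreeRecord] = {}
        for r in records:
            if r.animal_id in recs:
                raise PedigreeError(f"duplicate animal id: {r.animal_id!r}")
            recs[r.animal_id] = r
        # auto-add referenced-but-unlisted parents as founders
        for r in list(recs.values()):
            for pid, psex in ((r.sire_id, "M"), (r.dam_id, "F")):
                if pid is not None and pid not in recs:
                    recs[pid] = PedigreeRecord(pid, sex=psex)
        self._records = recs
        self._order = self._topological_order()
        self._index = {a: i for i, a in enumerate(self._order)}

    def _topological_order(self) -> list[str]:
        # Kahn's algorithm; deterministic (insertion order of ready queue).
        children: dict[str, list[str]] = {a: [] for a in self._records}
        indeg = {a: 0 for a in self._records}
        for r in self._records.values():
            for pid in (r.sire_id, r.dam_id):
                if pid is not None:
                    children[pid].append(r.animal_id)
                    indeg[r.animal_id] += 1
        ready = [a for a in self._records if indeg[a] == 0]
        order: list[str] = []
        while ready:
            a = ready.pop(0)
            order.append(a)
            for c in children[a]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
        if len(order) != len(self._records):
            on_cycle = next(a for a in self._records if indeg[a] > 0)
            raise CycleError(f"pedigree contains a cycle involving {on_cycle!r}")
        return order

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self._records

    def __getitem__(self, animal_id: str) -> PedigreeRecord:
        return self._records[animal_id]

    @property
    def animal_ids(self) -> list[str]:
        """Animal ids in topological order (parents first)."""
        return list(self._order)

    @property
    def records(self) -> list[PedigreeRecord]:
        return [self._records[a] for a in self._order]

    def parents(self, animal_id: str) -> tuple[Optional[str], Optional[str]]:
        r = self._records[animal_id]
        return r.sire_id, r.dam_id

    def topo_index(self, animal_id: str) -> int:
        return self._index[animal_id]

    def is_founder(self, animal_id: str) -> bool:
        r = self._records[animal_id]
        return r.sire_id is None and r.dam_id is None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (r.animal_id, r.sire_id or "0", r.dam_id or "0", r.sex,
             r.birth_year if r.birth_year is not None else "")
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "birth_year"])


_SEX_CODES = {
    "m": "M", "male": "M", "1": "M",
    "f": "F", "female": "F", "2": "F",
    "u": "U", "unknown": "U", "0": "U", "": "U",
}


def load_pedigree(
    path,
    *,
    sep: Optional[str] = None,
    id_col: str = "id",
    sire_col: str = "sire",
    dam_col: str = "dam",
    sex_col: str = "sex",
    year_col: str = "birth_year",
    unknown_codes: Sequence[str] = ("0", ""),
) -> Pedigree:
    """Read a delimited pedigree file into a validated :class:`Pedigree`.

    The file must have a header with at least the id/sire/dam columns; sex
    and birth-year columns are optional.  Parent ids matching
    ``unknown_codes`` (or empty cells) are normalized to unknown; parents
    referenced but not listed are added as founders with missing birth year.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                     dtype=str, keep_default_na=False)
    for col in (id_col, sire_col, dam_col):
        if col not in df.columns:
            raise PedigreeError(f"missing required column {col!r} in {path}")
    unknown = set(unknown_codes)

    def norm_parent(v: str) -> Optional[str]:
        v = v.strip()
        return None if v in unknown else v

    records = []
    for _, row in df.iterrows():
        sex = "U"
        if sex_col in df.columns:
            sex = _SEX_CODES.get(str(row[sex_col]).strip().lower(), "U")
        year = None
        if year_col in df.columns:
            raw = str(row[year_col]).strip()
            if raw not in ("", "NA", "nan"):
                year = int(float(raw))
        records.append(
            PedigreeRecord(
                animal_id=str(row[id_col]).strip(),
                sire_id=norm_parent(str(row[sire_col])),
                dam_id=norm_parent(str(row[dam_col])),
                sex=sex,
                birth_year=year,
            )
        )
    return Pedigree(records)


def compute_fped(pedigree: Pedigree) -> pd.Series:
    """Inbreeding coefficient of every animal by recursive kinship.

    F of an animal is the kinship of its parents; kinship is evaluated by the
    classic recursion (``phi(i,i) = (1+F_i)/2``; otherwise recurse on the
    younger animal's parents) with memoisation, processing animals in
    topological order so ancestor F values are always available.  Founders
    and animals with at most one known parent get 0.
    """
    order = pedigree.animal_ids
    idx = pedigree.topo_index
    F: dict[str, float] = {}
    memo: dict[tuple[str, str], float] = {}

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10000))
    try:
        def kin(a: Optional[str], b: Optional[str]) -> float:
            if a is None or b is None:
                return 0.0
            if a == b:
                return 0.5 * (1.0 + F[a])
            if idx(a) > idx(b):
                a, b = b, a
            key = (a, b)
            v = memo.get(key)
            if v is None:
                s, d = pedigree.parents(b)
                v = 0.5 * (kin(a, s) + kin(a, d))
                memo[key] = v
            return v

        for animal in order:
            s, d = pedigree.parents(animal)
            F[animal] = kin(s, d)
    finally:
        sys.setrecursionlimit(old_limit)
    return pd.Series(F, name="F_ped").loc[order]


def compute_cge(pedigree: Pedigree) -> pd.Series:
    """Complete generation equivalent: sum over known-ancestor paths of (1/2)^g.

    Computed by the recursion ``CGE(i) = sum over known parents p of
    (1 + CGE(p)) / 2`` in topological order; founders get 0.
    """
    cge: dict[str, float] = {}
    for animal in pedigree.animal_ids:
        total = 0.0
        for p in pedigree.parents(animal):
            if p is not None:
                total += 0.5 * (1.0 + cge[p])
        cge[animal] = total
    return pd.Series(cge, name="CGE").loc[pedigree.animal_ids]


def inbreeding_table(pedigree: Pedigree) -> pd.DataFrame:
    """Per-animal table of F_ped and CGE (plus sex and birth year)."""
    fped = compute_fped(pedigree)
    cge = compute_cge(pedigree)
    recs = pedigree.records
    return pd.DataFrame(
        {
            "id": [r.animal_id for r in recs],
            "F_ped": fped.values,
            "CGE": cge.values,
            "sex": [r.sex for r in recs],
            "birth_year": [r.birth_year for r in recs],
        }
    ).set_index("id")


def generation_intervals(
    pedigree: Pedigree,
    year_range: Optional[tuple[int, int]] = None,
) -> tuple[pd.DataFrame, dict]:
    """Mean parent age at offspring birth, per pathway and offspring birth year.

    Offspring sex routes each parent-offspring pair to a pathway: male
    offspring feed the sire/dam *of bulls* pathways, female offspring the
    *of cows* pathways.  Pairs missing either birth year are skipped and
    tallied; non-positive intervals are excluded with a warning.  Returns
    the per-(pathway, year) table and a skip log.
    """
    sums: dict[tuple[str, int], float] = {}
    counts: dict[tuple[str, int], int] = {}
    skip_log = {"missing_year": 0, "nonpositive_interval": 0, "unknown_sex": 0}

    for r in pedigree.records:
        if r.sex == "M":
            pathways = {"sire": "sire_of_bulls", "dam": "dam_of_bulls"}
        elif r.sex == "F":
            pathways = {"sire": "sire_of_cows", "dam": "dam_of_cows"}
        else:
            if r.sire_id is not None or r.dam_id is not None:
                skip_log["unknown_sex"] += 1
            continue
        if year_range is not None and (
            r.birth_year is None
            or not (year_range[0] <= r.birth_year <= year_range[1])
        ):
            continue
        for role, pid in (("sire", r.sire_id), ("dam", r.dam_id)):
            if pid is None:
                continue
            parent = pedigree[pid]
            if r.birth_year is None or parent.birth_year is None:
                skip_log["missing_year"] += 1
                continue
            interval = r.birth_year - parent.birth_year
            if interval <= 0:
                skip_log["nonpositive_interval"] += 1
                continue
            key = (pathways[role], r.birth_year)
            sums[key] = sums.get(key, 0.0) + interval
            counts[key] = counts.get(key, 0) + 1

    if skip_log["nonpositive_interval"]:
        warnings.warn(
            f"excluded {skip_log['nonpositive_interval']} parent-offspring "
            "pair(s) with non-positive birth-year interval",
            stacklevel=2,
        )
    rows = [
        {
            "pathway": pathway,
            "year": year,
            "mean_interval": sums[(pathway, year)] / counts[(pathway, year)],
            "n_offspring": counts[(pathway, year)],
        }
        for (pathway, year) in sorted(sums)
    ]
    return pd.DataFrame(rows, columns=["pathway", "year", "mean_interval",
                                       "n_offspring"]), skip_log


def pedigree_ne(
    inbreeding: pd.DataFrame,
    pedigree: Pedigree,
    window_years: int = 5,
    gi_years: float = 5.0,
    min_n: int = 10,
) -> pd.DataFrame:
    """Effective population size per generation cohort from pedigree F.

    Annual mean F_ped values are pooled into consecutive birth-year cohorts
    of ``window_years`` length.  At each cohort boundary the per-generation
    inbreeding rate is the two-point slope of ln(1 - F-bar), i.e.
    ``dF = 1 - (1 - F_next) / (1 - F_prev)``, and Ne = 1 / (2 dF).
    Non-positive rates are flagged (``infinite_ne``) rather than reported
    as numbers.

    ``inbreeding`` must carry ``F_ped`` and ``birth_year`` columns (as from
    :func:`inbreeding_table`).  Cohorts with fewer than ``min_n`` animals are
    dropped; fewer than two usable cohorts is an error.
    """
    df = inbreeding.dropna(subset=["birth_year"]).copy()
    df = df[df["birth_year"].notna()]
    if df.empty:
        raise PedigreeError("no animals with birth years for pedigree Ne")
    years = df["birth_year"].astype(int)
    y0 = int(years.min())
    cohort_idx = (years - y0) // int(window_years)
    grouped = df.groupby(cohort_idx)["F_ped"].agg(["mean", "size"])
    grouped = grouped[grouped["size"] >= min_n]
    if len(grouped) < 2:
        raise PedigreeError(
            "need at least 2 cohorts with >= min_n animals for pedigree Ne"
        )
    rows = []
    idxs = grouped.index.to_list()
    for prev, nxt in zip(idxs[:-1], idxs[1:]):
        fbar_prev = grouped.loc[prev, "mean"]
        fbar_next = grouped.loc[nxt, "mean"]
        n_gen = (nxt - prev) * window_years / gi_years
        log_rate = (np.log1p(-fbar_next) - np.log1p(-fbar_prev)) / n_gen
        dfgen = 1.0 - np.exp(log_rate)
        start = y0 + nxt * window_years
        label = f"{start}-{start + window_years - 1}"
        if dfgen <= 0:
            rows.append({"cohort": label, "t": nxt, "delta_f_gen": dfgen,
                         "ne": np.nan, "flag": "infinite_ne"})
        else:
            rows.append({"cohort": label, "t": nxt, "delta_f_gen": dfgen,
                         "ne": 1.0 / (2.0 * dfgen), "flag": ""})
    return pd.DataFrame(rows, columns=["cohort", "t", "delta_f_gen", "ne", "flag"])
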