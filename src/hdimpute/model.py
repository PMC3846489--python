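"""Shared data containers for two-panel SNP genotype data.

Genotypes are stored as alternate-allele dosages in ``{0, 1, 2}`` with
``MISSING = -1``. Haplotypes are binary alleles in ``{0, 1}``, two rows per
animal (adjacent). Marker coordinates are 1-based base pairs on numbered
autosomes; the marker map carries panel membership (``HD_ONLY`` markers are
present only on the high-density chip, ``BOTH`` markers are shared with the
medium-density chip).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

PANEL_HD_ONLY = "HD_ONLY"
PANEL_BOTH = "BOTH"

UNKNOWN_PARENT = "0"


def _as_str_array(values) -> np.ndarray:
    return np.asarray(values, dtype=object)


@dataclass
class MarkerMap:
    """Ordered marker metadata with panel membership.

    ``table`` columns: ``marker_id`` (unique), ``chromosome`` (int),
    ``position_bp`` (int, 1-based), ``panel`` (``HD_ONLY`` | ``BOTH``),
    sorted by (chromosome, position_bp).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["marker_id", "chromosome", "position_bp", "panel"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"marker map missing columns: {missing}")
        t = self.table.reset_index(drop=True)
        if t["marker_id"].duplicated().any():
            dup = t.loc[t["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ValueError(f"duplicate marker id: {dup}")
        bad = set(t["panel"]) - {PANEL_HD_ONLY, PANEL_BOTH}
        if bad:
            raise ValueError(f"invalid panel labels: {sorted(bad)}")
        order = np.lexsort((t["position_bp"].to_numpy(), t["chromosome"].to_numpy()))
        if not np.array_equal(order, np.arange(len(t))):
            t = t.iloc[order].reset_index(drop=True)
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> np.ndarray:
        return _as_str_array(self.table["marker_id"].to_numpy())

    @property
    def chromosomes(self) -> np.ndarray:
        return self.table["chromosome"].to_numpy(dtype=np.int64)

    @property
    def positions_bp(self) -> np.ndarray:
        return self.table["position_bp"].to_numpy(dtype=np.int64)

    @property
    def panels(self) -> np.ndarray:
        return self.table["panel"].to_numpy()

    def shared_ids(self) -> np.ndarray:
        """Marker ids present on both chips (the mimicked 50K panel)."""
        return self.marker_ids[self.panels == PANEL_BOTH]

    def hd_only_ids(self) -> np.ndarray:
        return self.marker_ids[self.panels == PANEL_HD_ONLY]

    def subset(self, marker_ids) -> "MarkerMap":
        keep = set(marker_ids)
        unknown = keep - set(self.marker_ids)
        if unknown:
            raise KeyError(f"markers not in map: {sorted(unknown)[:5]}")
        mask = np.fromiter((m in keep for m in self.marker_ids), bool, len(self))
        return MarkerMap(self.table.loc[mask].reset_index(drop=True))

    def index_of(self, marker_ids) -> np.ndarray:
        lookup = {m: i for i, m in enumerate(self.marker_ids)}
        try:
            return np.array([lookup[m] for m in marker_ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"marker not in map: {exc.args[0]}") from None


def _index_ids(ids: np.ndarray, requested, kind: str) -> np.ndarray:
    lookup = {v: i for i, v in enumerate(ids)}
    unknown = [r for r in requested if r not in lookup]
    if unknown:
        raise KeyError(f"unknown {kind} id(s): {unknown[:5]}")
    return np.array([lookup[r] for r in requested], dtype=np.int64)


@dataclass
class GenotypeMatrix:
    """Animals x markers alternate-allele dosage matrix with MISSING = -1."""

    animal_ids: np.ndarray
    marker_ids: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.animal_ids = _as_str_array(self.animal_ids)
        self.marker_ids = _as_str_array(self.marker_ids)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.animal_ids), len(self.marker_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.marker_ids)} markers"
            )
        valid = np.isin(self.calls, (MISSING, 0, 1, 2))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValueError(f"invalid genotype codes: {bad.tolist()}")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.animal_ids.copy(), self.marker_ids.copy(), self.calls.copy())

    def subset(self, animals=None, markers=None) -> "GenotypeMatrix":
        """Restrict to the requested ids, preserving the requested order."""
        if markers is not None and len(list(markers)) == 0:
            raise ValueError("empty marker subset requested")
        if animals is not None and len(list(animals)) == 0:
            raise ValueError("empty animal subset requested")
        rows = (
            np.arange(self.n_animals)
            if animals is None
            else _index_ids(self.animal_ids, list(animals), "animal")
        )
        cols = (
            np.arange(self.n_markers)
            if markers is None
            else _index_ids(self.marker_ids, list(markers), "marker")
        )
        return GenotypeMatrix(self.animal_ids[rows], self.marker_ids[cols], self.calls[np.ix_(rows, cols)])

    def call_rate_per_animal(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    def missing_fraction_per_marker(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def alt_allele_frequency(self) -> np.ndarray:
        """Alternate-allele frequency per marker over non-missing calls (NaN if none)."""
        obs = self.calls != MISSING
        n = obs.sum(axis=0)
        alt = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)

    def minor_allele_frequency(self) -> np.ndarray:
        p = self.alt_allele_frequency()
        return np.minimum(p, 1.0 - p)


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes; rows 2i and 2i+1 belong to ``animal_ids[i]``."""

    animal_ids: np.ndarray
    marker_ids: np.ndarray
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.animal_ids = _as_str_array(self.animal_ids)
        self.marker_ids = _as_str_array(self.marker_ids)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (2 * len(self.animal_ids), len(self.marker_ids)):
            raise ValueError(
                f"alleles shape {self.alleles.shape} does not match "
                f"2x{len(self.animal_ids)} haplotypes x {len(self.marker_ids)} markers"
            )
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def haplotype_ids(self) -> np.ndarray:
        return _as_str_array(
            [f"{a}_h{j}" for a in self.animal_ids for j in (1, 2)]
        )

    def to_genotypes(self) -> GenotypeMatrix:
        calls = self.alleles[0::2] + self.alleles[1::2]
        return GenotypeMatrix(self.animal_ids.copy(), self.marker_ids.copy(), calls)

    def subset(self, animals=None, markers=None) -> "HaplotypePanel":
        rows_a = (
            np.arange(len(self.animal_ids))
            if animals is None
            else _index_ids(self.animal_ids, list(animals), "animal")
        )
        cols = (
            np.arange(len(self.marker_ids))
            if markers is None
            else _index_ids(self.marker_ids, list(markers), "marker")
        )
        hap_rows = np.empty(2 * len(rows_a), dtype=np.int64)
        hap_rows[0::2] = 2 * rows_a
        hap_rows[1::2] = 2 * rows_a + 1
        return HaplotypePanel(self.animal_ids[rows_a], self.marker_ids[cols], self.alleles[np.ix_(hap_rows, cols)])


@dataclass
class Pedigree:
    """Pedigree records: animal_id, sire_id, dam_id, sex, birth_year, breed.

    Unknown parents are coded ``"0"``. Referenced parents must be present
    in the table; the pedigree must be acyclic (checked on construction).
    """

    table: pd.DataFrame
    _order: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        required = ["animal_id", "sire_id", "dam_id", "sex", "birth_year", "breed"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"pedigree missing columns: {missing}")
        t = self.table.reset_index(drop=True)
        ids = set(t["animal_id"])
        if len(ids) != len(t):
            raise ValueError("duplicate animal ids in pedigree")
        for col in ("sire_id", "dam_id"):
            refs = set(t[col]) - {UNKNOWN_PARENT}
            orphan = refs - ids
            if orphan:
                raise ValueError(f"{col} references absent animals: {sorted(orphan)[:5]}")
        self.table = t
        self._order = self._toposort()

    def _toposort(self) -> np.ndarray:
        """Kahn's algorithm parents-before-offspring; raises on cycles."""
        idx = {a: i for i, a in enumerate(self.table["animal_id"])}
        n = len(idx)
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=np.int64)
        for i, (s, d) in enumerate(zip(self.table["sire_id"], self.table["dam_id"])):
            for p in (s, d):
                if p != UNKNOWN_PARENT:
                    children[idx[p]].append(i)
                    indeg[i] += 1
        queue = [i for i in range(n) if indeg[i] == 0]
        out = []
        while queue:
            i = queue.pop()
            out.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(out) != n:
            raise ValueError("pedigree contains a cycle")
        return np.array(out, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def animal_ids(self) -> np.ndarray:
        return _as_str_array(self.table["animal_id"].to_numpy())

    def topological_order(self) -> np.ndarray:
        """Row indices sorted parents-before-offspring."""
        return self._order.copy()

    def founders(self) -> np.ndarray:
        t = self.table
        mask = (t["sire_id"] == UNKNOWN_PARENT) & (t["dam_id"] == UNKNOWN_PARENT)
        return _as_str_array(t.loc[mask, "animal_id"].to_numpy())

    def parents_of(self, animal_id: str) -> tuple[str, str]:
        row = self.table.loc[self.table["animal_id"] == animal_id]
        if row.empty:
            raise KeyError(f"animal not in pedigree: {animal_id}")
        return str(row["sire_id"].iloc[0]), str(row["dam_id"].iloc[0])

    def birth_years(self) -> dict[str, int]:
        return dict(zip(self.table["animal_id"], self.table["birth_year"].astype(int)))
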