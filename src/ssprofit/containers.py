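"""In-memory containers for pedigree and genotype data.

Phenotypes travel as plain :class:`pandas.DataFrame` objects with one row per
animal: an ``animal`` id column, the contemporary-group factor columns
(``farm``, ``year``, ``season``, ``sex``, ``mg`` and optionally ``test_id``),
and one column per trait (NaN = no record).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, StructuralError

UNKNOWN_PARENT = 0


@dataclass
class PedigreeTable:
    """Animal/sire/dam records, the basis of A and inbreeding.

    ``df`` columns: ``id, sire, dam`` (ints, 0 = unknown parent) and
    optionally ``birth_date, sex, farm``. Rows are kept ancestor-sorted:
    every parent appears before its offspring.
    """

    df: pd.DataFrame

    def __post_init__(self):
        req = {"id", "sire", "dam"}
        missing = req - set(self.df.columns)
        if missing:
            raise DataError(f"pedigree missing columns {sorted(missing)}")
        self.df = self.df.reset_index(drop=True)
        ids = self.df["id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise DataError("duplicate animal ids in pedigree")
        if np.any(ids == UNKNOWN_PARENT):
            raise DataError("animal id 0 is reserved for unknown parents")
        for col in ("sire", "dam"):
            bad = self.df["id"].to_numpy() == self.df[col].to_numpy()
            if bad.any():
                raise DataError(
                    f"animal listed as its own {col}: ids {self.df['id'].to_numpy()[bad][:5]}"
                )
        self._sort_ancestors_first()

    def _sort_ancestors_first(self):
        """Topological sort; raises StructuralError on a cycle."""
        ids = self.df["id"].to_numpy()
        pos = {a: i for i, a in enumerate(ids)}
        n = len(ids)
        sire = self.df["sire"].to_numpy()
        dam = self.df["dam"].to_numpy()
        # Kahn's algorithm over parent -> offspring edges
        indeg = np.zeros(n, dtype=int)
        children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            for p in (sire[i], dam[i]):
                if p != UNKNOWN_PARENT:
                    if p not in pos:
                        raise DataError(f"parent id {p} has no pedigree record")
                    children[pos[p]].append(i)
                    indeg[i] += 1
        order = [i for i in range(n) if indeg[i] == 0]
        head = 0
        while head < len(order):
            i = order[head]
            head += 1
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    order.append(c)
        if len(order) != n:
            raise StructuralError("pedigree contains a cycle")
        self.df = self.df.iloc[order].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> np.ndarray:
        return self.df["id"].to_numpy()

    def index_of(self, ids) -> np.ndarray:
        """Row indices (ancestor-sorted order) of the given animal ids."""
        pos = {a: i for i, a in enumerate(self.ids)}
        try:
            return np.array([pos[a] for a in np.atleast_1d(ids)], dtype=int)
        except KeyError as e:
            raise DataError(f"animal id {e.args[0]} not in pedigree") from None

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Row indices of sire and dam per animal; -1 where unknown."""
        pos = {a: i for i, a in enumerate(self.ids)}
        pos[UNKNOWN_PARENT] = -1
        s = np.array([pos[a] for a in self.df["sire"]], dtype=int)
        d = np.array([pos[a] for a in self.df["dam"]], dtype=int)
        return s, d


@dataclass
class GenotypeMatrix:
    """Allele counts (0/1/2, NaN = missing) for the genotyped animals.

    ``snp_map`` has one row per SNP: ``snp`` (name), ``chrom``, ``pos``.
    """

    ids: np.ndarray
    matrix: np.ndarray  # animals x SNPs, float with NaN for missing
    snp_map: pd.DataFrame = field(default=None)

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.ids):
            raise DataError("genotype matrix shape does not match id list")
        obs = self.matrix[~np.isnan(self.matrix)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise DataError("genotype codes must be 0, 1 or 2 (NaN = missing)")
        if self.snp_map is None:
            self.snp_map = pd.DataFrame({
                "snp": [f"snp{j+1}" for j in range(self.n_snps)],
                "chrom": np.ones(self.n_snps, dtype=int),
                "pos": np.arange(1, self.n_snps + 1),
            })
        if len(self.snp_map) != self.n_snps:
            raise DataError("snp_map length does not match genotype columns")

    @property
    def n_animals(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_snps(self) -> int:
        return self.matrix.shape[1]

    def allele_freqs(self) -> np.ndarray:
        """Observed frequency of the counted (second) allele per SNP."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.matrix, axis=0) / 2.0
        return np.where(np.isnan(p), 0.0, p)

    def imputed(self) -> np.ndarray:
        """Matrix with missing entries replaced by the column mean (2p)."""
        m = self.matrix.copy()
        fill = 2.0 * self.allele_freqs()
        idx = np.where(np.isnan(m))
        m[idx] = fill[idx[1]]
        return m

    def subset(self, animal_mask=None, snp_mask=None) -> "GenotypeMatrix":
        a = np.arange(self.n_animals) if animal_mask is None else np.flatnonzero(animal_mask)
        s = np.arange(self.n_snps) if snp_mask is None else np.flatnonzero(snp_mask)
        return GenotypeMatrix(
            ids=self.ids[a],
            matrix=self.matrix[np.ix_(a, s)],
            snp_map=self.snp_map.iloc[s].reset_index(drop=True),
        )
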