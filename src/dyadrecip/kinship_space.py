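"""Pedigree relatedness, household distances, and kin-class labels.

Relatedness between two families is the mean coefficient of relatedness
(``r = 2·φ`` for non-inbred pairs, with φ the kinship coefficient — the
probability that two alleles drawn at random, one from each individual, are
identical by descent) over all cross-family member pairs.  Distances between
household point locations are great-circle distances by the spherical law of
cosines.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .io_model import PedigreeEntry, Village

EARTH_RADIUS_KM = 6371.0

KIN_THRESHOLD = 0.25  # close kin: mean r >= 0.25


class Pedigree:
    """Parent lookup with memoized recursive kinship coefficients."""

    def __init__(self, entries: list[PedigreeEntry]):
        self._parents: dict[str, tuple[str | None, str | None]] = {
            e.individual_id: (e.father_id, e.mother_id) for e in entries
        }
        self._depth: dict[str, int] = {}
        self._phi_cache: dict[frozenset, float] = {}

    def parents(self, a: str) -> tuple[str | None, str | None]:
        if a not in self._parents:
            raise KeyError(f"unknown individual {a!r}")
        return self._parents[a]

    def depth(self, a: str) -> int:
        """Generation depth: founders 0, child = 1 + max(parent depths)."""
        if a in self._depth:
            return self._depth[a]
        f, m = self.parents(a)
        d = 1 + max(
            (self.depth(p) for p in (f, m) if p is not None), default=-1
        )
        self._depth[a] = d
        return d

    def phi(self, a: str, b: str) -> float:
        """Kinship coefficient φ(a, b); founders are mutually unrelated."""
        key = frozenset((a, b))
        if key in self._phi_cache:
            return self._phi_cache[key]
        if a == b:
            f, m = self.parents(a)
            val = 0.5 * (1.0 + (self.phi(f, m) if f and m else 0.0))
        else:
            # recurse on the deeper individual: it cannot be an ancestor of
            # the shallower one, so the standard recursion is valid
            if self.depth(a) < self.depth(b):
                a, b = b, a
            f, m = self.parents(a)
            if f is None and m is None:
                val = 0.0
            else:
                val = 0.5 * (
                    (self.phi(f, b) if f else 0.0) + (self.phi(m, b) if m else 0.0)
                )
        self._phi_cache[key] = val
        return val


def kinship_coefficient(pedigree: Pedigree | list[PedigreeEntry],
                        a: str, b: str) -> float:
    """Probability of identity by descent φ(a, b)."""
    if not isinstance(pedigree, Pedigree):
        pedigree = Pedigree(pedigree)
    return pedigree.phi(a, b)


def relatedness(pedigree: Pedigree | list[PedigreeEntry], a: str, b: str) -> float:
    """Coefficient of relatedness r = 2φ (non-inbred convention); r(a,a)=1 scale."""
    if not isinstance(pedigree, Pedigree):
        pedigree = Pedigree(pedigree)
    return 2.0 * pedigree.phi(a, b)


@dataclass
class RelatednessMatrix:
    """Mean pairwise relatedness between families (symmetric, diagonal unused)."""

    family_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        F = len(self.family_ids)
        if self.r.shape != (F, F):
            raise ValueError("relatedness matrix shape mismatch")
        if not np.allclose(self.r, self.r.T):
            raise ValueError("relatedness matrix must be symmetric")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.r, index=self.family_ids, columns=self.family_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RelatednessMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(family_ids=list(df.index.astype(str)), r=df.to_numpy())


@dataclass
class DistanceMatrix:
    """Great-circle distances between household locations, kilometers."""

    family_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        F = len(self.family_ids)
        if self.d.shape != (F, F):
            raise ValueError("distance matrix shape mismatch")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.d, index=self.family_ids, columns=self.family_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(family_ids=list(df.index.astype(str)), d=df.to_numpy())


def family_relatedness(pedigree: Pedigree | list[PedigreeEntry],
                       village: Village) -> RelatednessMatrix:
    """Mean relatedness of each member of family i with each member of family j."""
    if not isinstance(pedigree, Pedigree):
        pedigree = Pedigree(pedigree)
    fams = village.families
    for f in fams:
        if f.size == 0:
            raise ValueError(f"family {f.family_id} is empty")
    F = len(fams)
    r = np.zeros((F, F))
    for i in range(F):
        for j in range(i + 1, F):
            vals = [
                2.0 * pedigree.phi(a, b)
                for a in fams[i].member_ids
                for b in fams[j].member_ids
            ]
            r[i, j] = r[j, i] = float(np.mean(vals))
    return RelatednessMatrix(family_ids=village.family_ids, r=r)


def spherical_distance(loc1: tuple[float, float], loc2: tuple[float, float]) -> float:
    """Great-circle distance (km) by the spherical law of cosines."""
    lat1, lon1 = np.radians(loc1)
    lat2, lon2 = np.radians(loc2)
    c = np.sin(lat1) * np.sin(lat2) + np.cos(lat1) * np.cos(lat2) * np.cos(lon2 - lon1)
    return float(EARTH_RADIUS_KM * np.arccos(np.clip(c, -1.0, 1.0)))


def family_distances(village: Village) -> DistanceMatrix:
    F = village.n_families
    d = np.zeros((F, F))
    for i in range(F):
        for j in range(i + 1, F):
            d[i, j] = d[j, i] = spherical_distance(
                village.families[i].location, village.families[j].location
            )
    return DistanceMatrix(family_ids=village.family_ids, d=d)


def kin_class(r: float, threshold: float = KIN_THRESHOLD) -> str:
    """Kin class of a dyad: close_kin (r >= 0.25), distant_kin (0 < r < 0.25),
    non_kin (r = 0)."""
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"relatedness {r} outside [0, 1]")
    if r >= threshold:
        return "close_kin"
    if r > 0.0:
        return "distant_kin"
    return "non_kin"


def is_close_kin(r: np.ndarray | float, threshold: float = KIN_THRESHOLD):
    """Binary split used by the dynamical analysis: close (r >= 0.25) vs not."""
    return np.asarray(r) >= threshold


def kin_class_counts(relmat: RelatednessMatrix,
                     threshold: float = KIN_THRESHOLD) -> dict[str, int]:
    """Counts of unordered family dyads by kin class."""
    F = len(relmat.family_ids)
    iu = np.triu_indices(F, k=1)
    vals = relmat.r[iu]
    return {
        "close_kin": int((vals >= threshold).sum()),
        "distant_kin": int(((vals > 0) & (vals < threshold)).sum()),
        "non_kin": int((vals == 0).sum()),
        "total": len(vals),
    }
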