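"""Pedigree handling and additive relationship algebra.

A pedigree is a list of (animal, sire, dam) triples, optionally birth-dated.
From it this module computes inbreeding coefficients F, the dense numerator
relationship matrix A (tabular method) and the sparse inverse of A by
Henderson's rules with the inbreeding-adjusted Mendelian-sampling variances.

Unknown parents are treated as unrelated base-population founders (no genetic
groups are fitted).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN = -1  # internal index sentinel for an unknown parent

__all__ = ["Pedigree", "PedigreeError", "UNKNOWN"]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (duplicates, cycles)."""


@dataclass
class Pedigree:
    """A validated, topologically sorted pedigree.

    Parameters
    ----------
    ids : array of str
        Animal identifiers, parents preceding offspring.
    sire, dam : int arrays
        Positional parent indices into ``ids``; ``UNKNOWN`` (-1) if unknown.
    birth : float array
        Birth date as proleptic-Gregorian ordinal day; NaN if unknown.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    birth: np.ndarray
    warnings: list = field(default_factory=list, repr=False)

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        """Build and validate a pedigree from an animal/sire/dam frame.

        ``df`` needs columns ``animal``, ``sire``, ``dam`` and optionally
        ``birth_date``.  Unknown parents are NaN/None/"0"/"" . Parents that
        never appear as animal rows are appended as founders with unknown
        birth date.  Rows are topologically sorted; a cycle (an animal that
        is its own ancestor) raises :class:`PedigreeError` naming a member.
        """
        animals = df["animal"].astype(str).to_numpy()
        dup = pd.Series(animals).duplicated()
        if dup.any():
            raise PedigreeError(
                f"duplicate animal ids in pedigree: {sorted(set(animals[dup.to_numpy()]))}"
            )

        def _clean(col):
            s = df[col].astype(object)
            out = []
            for v in s:
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    out.append(None)
                else:
                    v = str(v).strip()
                    out.append(None if v in ("", "0", "nan", "NA", ".") else v)
            return out

        sires = _clean("sire")
        dams = _clean("dam")
        if "birth_date" in df.columns:
            births = pd.to_datetime(df["birth_date"], errors="coerce")
            birth_ord = np.array(
                [t.toordinal() if pd.notna(t) else np.nan for t in births], dtype=float
            )
        else:
            birth_ord = np.full(len(animals), np.nan)

        known = set(animals)
        implied = []
        for p in sires + dams:
            if p is not None and p not in known:
                known.add(p)
                implied.append(p)
        all_ids = list(animals) + implied
        pos = {a: i for i, a in enumerate(all_ids)}
        n = len(all_ids)
        sire_idx = np.full(n, UNKNOWN, dtype=np.int64)
        dam_idx = np.full(n, UNKNOWN, dtype=np.int64)
        birth = np.concatenate([birth_ord, np.full(len(implied), np.nan)])
        for i, (s, d) in enumerate(zip(sires, dams)):
            sire_idx[i] = pos[s] if s is not None else UNKNOWN
            dam_idx[i] = pos[d] if d is not None else UNKNOWN

        order = _toposort(np.array(all_ids), sire_idx, dam_idx)
        inv = np.empty(n, dtype=np.int64)
        inv[order] = np.arange(n)
        remap = np.where(sire_idx[order] >= 0, inv[np.maximum(sire_idx[order], 0)], UNKNOWN)
        remap_d = np.where(dam_idx[order] >= 0, inv[np.maximum(dam_idx[order], 0)], UNKNOWN)
        ped = cls(
            ids=np.array(all_ids, dtype=object)[order],
            sire=remap,
            dam=remap_d,
            birth=birth[order],
        )
        ped._check_birth_order()
        return ped

    def _check_birth_order(self):
        for i in range(self.n):
            for p in (self.sire[i], self.dam[i]):
                if p != UNKNOWN and np.isfinite(self.birth[p]) and np.isfinite(self.birth[i]):
                    if self.birth[p] >= self.birth[i]:
                        self.warnings.append(
                            f"parent {self.ids[p]} not birth-dated before offspring {self.ids[i]}"
                        )

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def index(self) -> dict:
        if not hasattr(self, "_index"):
            self._index = {a: i for i, a in enumerate(self.ids)}
        return self._index

    def to_frame(self) -> pd.DataFrame:
        def _id(p):
            return self.ids[p] if p != UNKNOWN else "0"

        return pd.DataFrame(
            {
                "animal": self.ids,
                "sire": [_id(p) for p in self.sire],
                "dam": [_id(p) for p in self.dam],
                "birth_date": [
                    pd.Timestamp.fromordinal(int(b)).date().isoformat()
                    if np.isfinite(b)
                    else ""
                    for b in self.birth
                ],
            }
        )

    # ------------------------------------------------------------------
    # pruning
    # ------------------------------------------------------------------
    def prune(self, phenotyped, drop_unknown_birth: bool = True) -> "Pedigree":
        """Restrict to phenotyped animals plus their ancestor closure.

        Animals with unknown birth dates are dropped unless they are required
        ancestors of a phenotyped animal, in which case they are retained as
        founders.  Phenotyped ids absent from the pedigree are collected in
        ``.warnings`` of the returned pedigree.
        """
        missing = sorted(set(map(str, phenotyped)) - set(self.ids))
        keep = np.zeros(self.n, dtype=bool)
        for a in phenotyped:
            i = self.index.get(str(a))
            if i is not None:
                keep[i] = True
        # ancestor closure: sorted order means a backward sweep suffices
        for i in range(self.n - 1, -1, -1):
            if keep[i]:
                for p in (self.sire[i], self.dam[i]):
                    if p != UNKNOWN:
                        keep[p] = True
        if drop_unknown_birth:
            # non-required undated animals go; required ones stay (as is)
            required = keep.copy()
            keep &= np.isfinite(self.birth) | required
        idx = np.flatnonzero(keep)
        inv = np.full(self.n, UNKNOWN, dtype=np.int64)
        inv[idx] = np.arange(len(idx))

        def _remap(parr):
            out = np.full(len(idx), UNKNOWN, dtype=np.int64)
            for j, i in enumerate(idx):
                p = parr[i]
                out[j] = inv[p] if p != UNKNOWN else UNKNOWN
            return out

        sub = Pedigree(
            ids=self.ids[idx].copy(),
            sire=_remap(self.sire),
            dam=_remap(self.dam),
            birth=self.birth[idx].copy(),
        )
        if missing:
            sub.warnings.append(f"phenotyped ids absent from pedigree: {missing}")
        return sub

    # ------------------------------------------------------------------
    # relationship algebra
    # ------------------------------------------------------------------
    def mendelian_variance(self, assume_noninbred: bool = False) -> np.ndarray:
        """Per-animal Mendelian-sampling variance d_i (as a fraction of sigma2_a).

        d_i = 0.5 - 0.25 (F_s + F_d) with both parents known,
              0.75 - 0.25 F_p with one parent known, and 1 for founders.
        """
        F = np.zeros(self.n) if assume_noninbred else self.inbreeding()
        d = np.ones(self.n)
        for i in range(self.n):
            s, dm = self.sire[i], self.dam[i]
            if s != UNKNOWN and dm != UNKNOWN:
                d[i] = 0.5 - 0.25 * (F[s] + F[dm])
            elif s != UNKNOWN:
                d[i] = 0.75 - 0.25 * F[s]
            elif dm != UNKNOWN:
                d[i] = 0.75 - 0.25 * F[dm]
        return d

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients F by the Meuwissen-Luo recursion.

        F_i = sum_j L_ij^2 d_j - 1 over the ancestors j of i (including i),
        where L is the Cholesky-factor path matrix of A and d_j the
        Mendelian-sampling variance. Founders have F = 0.
        """
        if hasattr(self, "_F"):
            return self._F
        n = self.n
        F = np.zeros(n)
        d = np.empty(n)
        L = np.zeros(n)
        for i in range(n):
            s, dm = self.sire[i], self.dam[i]
            if s != UNKNOWN and dm != UNKNOWN:
                d[i] = 0.5 - 0.25 * (F[s] + F[dm])
            elif s != UNKNOWN or dm != UNKNOWN:
                d[i] = 0.75 - 0.25 * F[max(s, dm)]
            else:
                d[i] = 1.0
                continue  # founder: F stays 0
            if s == UNKNOWN or dm == UNKNOWN:
                continue  # one unknown parent: F = 0
            # trace ancestors of i, highest index first
            heap = [-i]
            L[i] = 1.0
            aii = 0.0
            touched = [i]
            while heap:
                j = -heapq.heappop(heap)
                lj = L[j]
                if lj == 0.0:
                    continue
                aii += lj * lj * d[j]
                L[j] = 0.0
                for p in (self.sire[j], self.dam[j]):
                    if p != UNKNOWN:
                        if L[p] == 0.0:
                            heapq.heappush(heap, -p)
                            touched.append(p)
                        L[p] += 0.5 * lj
            F[i] = aii - 1.0
            for j in touched:
                L[j] = 0.0
        self._F = F
        return F

    def relationship_matrix(self, max_dense: int = 6000) -> np.ndarray:
        """Dense numerator relationship matrix A by the tabular method.

        a(i,i) = 1 + 0.5 a(s_i, d_i); a(i,j) = 0.5 (a(j, s_i) + a(j, d_i)).
        Intended for modest pedigrees; above ``max_dense`` animals use
        :meth:`a_inverse` instead.
        """
        if self.n > max_dense:
            raise ValueError(
                f"pedigree has {self.n} animals; dense A is limited to "
                f"{max_dense} - use a_inverse() for the mixed-model path"
            )
        n = self.n
        A = np.zeros((n, n))
        for i in range(n):
            s, dm = self.sire[i], self.dam[i]
            row = np.zeros(i)
            if s != UNKNOWN:
                row += 0.5 * A[s, :i]
            if dm != UNKNOWN:
                row += 0.5 * A[dm, :i]
            A[i, :i] = row
            A[:i, i] = row
            A[i, i] = 1.0 + (0.5 * A[s, dm] if (s != UNKNOWN and dm != UNKNOWN) else 0.0)
        return A

    def a_inverse(self, assume_noninbred: bool = False) -> sp.csr_matrix:
        """Sparse inverse of A by Henderson's rules with inbreeding.

        Each animal i contributes alpha_i = 1/d_i to (i,i), -alpha_i/2 to
        (i, parent) and alpha_i/4 to (parent, parent) pairs, for its known
        parents.  ``assume_noninbred`` forces d from F = 0 (oracle toggle).
        """
        d = self.mendelian_variance(assume_noninbred=assume_noninbred)
        rows, cols, vals = [], [], []
        for i in range(self.n):
            alpha = 1.0 / d[i]
            parents = [p for p in (self.sire[i], self.dam[i]) if p != UNKNOWN]
            rows.append(i)
            cols.append(i)
            vals.append(alpha)
            for p in parents:
                rows += [i, p]
                cols += [p, i]
                vals += [-0.5 * alpha, -0.5 * alpha]
            for p in parents:
                for q in parents:
                    rows.append(p)
                    cols.append(q)
                    vals.append(0.25 * alpha)
        Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(self.n, self.n))
        return Ainv.tocsr()


def _toposort(ids: np.ndarray, sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Kahn topological order (parents first); raises on cycles."""
    n = len(ids)
    children = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p == i:
                raise PedigreeError(f"animal {ids[i]} listed as its own parent")
            if p != UNKNOWN:
                children[p].append(i)
                indeg[i] += 1
    queue = sorted(np.flatnonzero(indeg == 0), key=lambda i: i)
    order = []
    head = 0
    queue = list(queue)
    while head < len(queue):
        i = queue[head]
        head += 1
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != n:
        members = [str(ids[i]) for i in np.flatnonzero(indeg > 0)]
        raise PedigreeError(f"pedigree contains a cycle involving: {members}")
    return np.array(order, dtype=np.int64)
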