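"""Partial numerator relationship matrices by breed origin.

The additive covariance of a two-breed composite population decomposes as

    G = sigma2_A * A_A + sigma2_B * A_B + sigma2_S * A_S,

where A_A and A_B are partial relationship matrices for genes of breed A
and B origin and A_S accounts for the segregation variance created when
crossbred parents transmit gametes of mixed breed origin.  All three
follow the tabular parent-average recursion; they differ only in the
within-family (Mendelian-sampling) term:

    off-diagonal: a_X(i, j) = (a_X(sire_i, j) + a_X(dam_i, j)) / 2
    diagonal:     a_X(i, i) = base_X(i) + a_X(sire_i, dam_i) / 2

with base_X(i) = f_X(i) for breed sources and base_S(i) = s_i =
2(f_A(s)f_B(s) + f_A(d)f_B(d)) for segregation; unknown-parent terms are
zero.  Animals with a zero diagonal contribute nothing (null rows and
columns); production code never stores them: matrices are collapsed to
the contributor set and only the sparse collapsed inverse is assembled,
via the Henderson rules weighted by the per-source Mendelian-sampling
variances d_X(i) = base_X(i) - (a_X(s,s) + a_X(d,d)) / 4, computed
row-wise in Meuwissen-Luo fashion without storing the full matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .pedigree import UNKNOWN, BreedComposition, Pedigree

#: Sources of additive variability: breed A, breed B, segregation.
SOURCES = ("A", "B", "S")

#: Null-contribution detection threshold; breed fractions are dyadic
#: rationals in practice so true zeros are exact.
EPS = 1e-12


class SingularContributorError(ValueError):
    """A contributor has a non-positive Mendelian-sampling variance."""


@dataclass
class ContributorMap:
    """Ordered contributor set for one source and its index maps.

    ``members`` are global codes (pedigree order); ``collapsed`` maps
    global code -> collapsed index (-1 for non-contributors).  This is the
    information content of the scatter matrix that re-inserts null rows.
    """

    source: str
    members: np.ndarray          # global codes, ascending
    collapsed: np.ndarray        # (q+1,) int, -1 where non-contributing

    @property
    def q_x(self) -> int:
        return len(self.members)

    def is_member(self, code: int) -> bool:
        return self.collapsed[code] >= 0


@dataclass
class PartialNRM:
    """Collapsed partial relationship matrix over the contributor set."""

    source: str
    matrix: np.ndarray
    cmap: ContributorMap


@dataclass
class MendelianVariances:
    """Per-source within-family variance coefficients d_X(i).

    ``d`` and ``diag`` have length q+1; entries are zero for
    non-contributors.  ``diag`` holds the tabular diagonal a_X(i, i).
    """

    source: str
    d: np.ndarray
    diag: np.ndarray


def segregation_ms_coefficient(f_sire: float, f_dam: float) -> float:
    """Coefficient s_i of sigma2_S in the Mendelian-sampling variance.

    Arguments are the breed-A fractions of the two parents.  Purebred
    parents give 0 (an F1 carries no segregation variance); two F1
    parents give 1 (fully expressed in the F2).
    """
    return 2.0 * (f_sire * (1.0 - f_sire) + f_dam * (1.0 - f_dam))


def _base_values(ped: Pedigree, bc: BreedComposition, source: str) -> np.ndarray:
    if source == "A":
        v = bc.f[:, 0].copy()
    elif source == "B":
        v = bc.f[:, 1].copy()
    elif source == "S":
        v = bc.seg_coeff.copy()
    else:
        raise ValueError(f"unknown source {source!r}")
    v[0] = 0.0
    return v


def contributors(ped: Pedigree, bc: BreedComposition, source: str) -> ContributorMap:
    """Identify animals with non-null contributions to a source.

    Breed-source membership is f_X(i) > eps; segregation membership is
    s_i > eps or a contributing parent (equivalently, a nonzero diagonal
    in the tabular A_S).
    """
    base = _base_values(ped, bc, source)
    q = ped.q
    member = np.zeros(q + 1, dtype=bool)
    for i in ped.animals():
        if base[i] > EPS:
            member[i] = True
        elif source == "S":
            s, d = ped.sire[i], ped.dam[i]
            if (s != UNKNOWN and member[s]) or (d != UNKNOWN and member[d]):
                member[i] = True
    members = np.flatnonzero(member)
    collapsed = np.full(q + 1, -1, dtype=np.int64)
    collapsed[members] = np.arange(len(members))
    return ContributorMap(source=source, members=members, collapsed=collapsed)


def partial_nrm_tabular(ped: Pedigree, bc: BreedComposition, source: str) -> np.ndarray:
    """Full q x q partial relationship matrix by the tabular method.

    Oracle/testing path (dense, O(q^2) memory); rows and columns of
    non-contributors are exactly zero.
    """
    base = _base_values(ped, bc, source)
    q = ped.q
    a = np.zeros((q + 1, q + 1))
    for i in ped.animals():
        s, d = ped.sire[i], ped.dam[i]
        row = np.zeros(q + 1)
        if s != UNKNOWN:
            row += 0.5 * a[s]
        if d != UNKNOWN:
            row += 0.5 * a[d]
        a[i, :i] = row[:i]
        a[:i, i] = row[:i]
        cross = a[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0
        a[i, i] = base[i] + 0.5 * cross
    return a[1:, 1:]


def mendelian_variances(
    ped: Pedigree, bc: BreedComposition, source: str, cmap: ContributorMap | None = None
) -> MendelianVariances:
    """Row-wise Meuwissen-Luo computation of d_X(i) and the diagonals.

    Uses the generalized Cholesky factorization A_X = L D_X L' (L the
    pedigree gene-flow matrix): d_X(i) = base_X(i) - (a_ss + a_dd)/4 from
    the parents' diagonals, then a_X(i,i) = sum_j L_ij^2 d_X(j) by tracing
    the ancestry of i, one row at a time, without storing A_X.
    Raises :class:`SingularContributorError` if a contributor's d is not
    positive (completely inbred contributing parents).
    """
    if cmap is None:
        cmap = contributors(ped, bc, source)
    base = _base_values(ped, bc, source)
    q = ped.q
    d = np.zeros(q + 1)
    diag = np.zeros(q + 1)
    L = np.zeros(q + 1)
    sire, dam = ped.sire, ped.dam
    for i in ped.animals():
        if not cmap.is_member(i):
            continue
        s, dd_ = sire[i], dam[i]
        di = base[i]
        if s != UNKNOWN:
            di -= 0.25 * diag[s]
        if dd_ != UNKNOWN:
            di -= 0.25 * diag[dd_]
        if di <= EPS:
            raise SingularContributorError(
                f"animal {ped.ids[i]!r}: Mendelian-sampling variance for source "
                f"{source} is {di:.3e} (completely inbred contributing parents)"
            )
        d[i] = di
        # Trace ancestors: a_ii = sum of L_ij^2 d_j over ancestors j <= i.
        L[i] = 1.0
        acc = 0.0
        touched = [i]
        for j in range(i, 0, -1):
            w = L[j]
            if w == 0.0:
                continue
            acc += w * w * d[j]
            if sire[j] != UNKNOWN:
                if L[sire[j]] == 0.0:
                    touched.append(sire[j])
                L[sire[j]] += 0.5 * w
            if dam[j] != UNKNOWN:
                if L[dam[j]] == 0.0:
                    touched.append(dam[j])
                L[dam[j]] += 0.5 * w
        for j in touched:
            L[j] = 0.0
        diag[i] = acc
    return MendelianVariances(source=source, d=d, diag=diag)


def collapsed_matrix(ped: Pedigree, bc: BreedComposition, source: str) -> PartialNRM:
    """Collapsed (contributors-only) partial NRM, via the tabular path."""
    cmap = contributors(ped, bc, source)
    full = partial_nrm_tabular(ped, bc, source)
    m = cmap.members - 1  # tabular matrix is 0-based over codes 1..q
    return PartialNRM(source=source, matrix=full[np.ix_(m, m)], cmap=cmap)


def collapsed_inverse(
    ped: Pedigree,
    bc: BreedComposition,
    source: str,
    cmap: ContributorMap | None = None,
    mv: MendelianVariances | None = None,
) -> sparse.csc_matrix:
    """Sparse inverse of the collapsed partial NRM by Henderson's rules.

    For each contributor i with w = 1/d_X(i): add w at (i,i), -w/2 between
    i and each contributing parent, and w/4 between every pair of
    contributing parents (including a parent with itself).  Exact because
    non-contributing parents have identically zero rows in A_X.
    """
    if cmap is None:
        cmap = contributors(ped, bc, source)
    if mv is None:
        mv = mendelian_variances(ped, bc, source, cmap)
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in cmap.members:
        ci = cmap.collapsed[i]
        w = 1.0 / mv.d[i]
        parents = [
            cmap.collapsed[p]
            for p in (ped.sire[i], ped.dam[i])
            if p != UNKNOWN and cmap.is_member(p)
        ]
        add(ci, ci, w)
        for p in parents:
            add(ci, p, -0.5 * w)
            add(p, ci, -0.5 * w)
        for p in parents:
            for p2 in parents:
                add(p, p2, 0.25 * w)
    n = cmap.q_x
    return sparse.csc_matrix((vals, (rows, cols)), shape=(n, n))


def expand_collapsed(values: np.ndarray, cmap: ContributorMap, q: int) -> np.ndarray:
    """Scatter contributor-indexed values into a full (q+1,) vector.

    Non-contributors (and the sentinel slot 0) get exact zeros; this is
    the action of the scatter matrix that restores the null-row pattern.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != cmap.q_x:
        raise ValueError(
            f"expected {cmap.q_x} contributor values for source {cmap.source}, "
            f"got {values.shape[0]}"
        )
    out = np.zeros(q + 1)
    out[cmap.members] = values
    return out


def assemble_total_G(
    partials: dict[str, np.ndarray], variances: dict[str, float]
) -> np.ndarray:
    """Dense total additive covariance sum_X sigma2_X A_X (oracle path)."""
    total = None
    for src, a in partials.items():
        v = variances[src]
        if v < 0:
            raise ValueError(f"negative variance for source {src}")
        total = v * a if total is None else total + v * a
    return total
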