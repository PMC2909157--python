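"""Maternal multibreed linear model: design, mixed-model equations, BLUP.

The observation model is a Willham-type maternal model with breeding
values split by breed origin,

    y = X b + sum_X (Z_oX a_oX + Z_mX a_mX) + Z_p e_p + e,

where for each source X in {A, B, S} the direct/maternal pair
(a_oX, a_mX) lives on the collapsed contributor set of that source with
covariance G0X (x) A*_X, e_p is a permanent-environment effect of dams
with recorded progeny, and e is the residual.  Fixed effects carry a
vague but proper normal prior N(0, K), K = k I with large k, so the
coefficient matrix is always positive definite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

from .components import GeneticCovSet
from .partial_nrm import (
    SOURCES,
    ContributorMap,
    collapsed_inverse,
    contributors,
    expand_collapsed,
)
from .pedigree import UNKNOWN, BreedComposition, CrossCovariates, Pedigree


class ModelBuildError(ValueError):
    pass


@dataclass
class ModelSpec:
    """Which effects enter the model.

    Factors are dummy-coded to full rank (first level absorbed into the
    intercept); covariates are optionally centered.  When
    ``cross_covariates`` is set, direct/maternal breed fraction and
    heterosis regressors are appended to the fixed part.
    """

    response: str = "weight"
    factors: tuple = ("sex", "age_of_dam")
    covariates: tuple = ("day_of_birth",)
    cross_covariates: bool = True
    center_covariates: bool = True
    sources: tuple = SOURCES


@dataclass
class DesignMatrices:
    X: np.ndarray
    fixed_names: list
    Z: dict                      # (source, 'o'|'m') -> csr incidence
    Zp: sparse.csr_matrix
    y: np.ndarray
    cmaps: dict                  # source -> ContributorMap
    a_inv: dict                  # source -> csc collapsed inverse
    pe_dams: np.ndarray          # dam codes owning a permanent-env. level
    animal_codes: np.ndarray
    dam_codes: np.ndarray
    q: int
    sources: tuple = SOURCES

    @property
    def n_records(self) -> int:
        return self.X.shape[0]


@dataclass
class MixedModelSystem:
    """Sparse symmetric MME: C theta = r, with the block layout recorded."""

    C: sparse.csc_matrix
    r: np.ndarray
    W: sparse.csr_matrix
    y: np.ndarray
    layout: dict                 # name -> slice into theta
    dm: DesignMatrices
    vc: GeneticCovSet
    k: float

    @property
    def n_unknowns(self) -> int:
        return self.C.shape[0]


@dataclass
class LocationState:
    """Solutions/draws for all location parameters of the model."""

    theta: np.ndarray
    layout: dict
    dm: DesignMatrices

    @property
    def b(self) -> np.ndarray:
        return self.theta[self.layout["fixed"]]

    def a(self, source: str, effect: str) -> np.ndarray:
        return self.theta[self.layout[(source, effect)]]

    @property
    def e_p(self) -> np.ndarray:
        return self.theta[self.layout["pe"]]


def _indicator(rows_codes: np.ndarray, cmap: ContributorMap, n: int) -> sparse.csr_matrix:
    """n x q_X incidence; all-zero row when the code is a non-contributor."""
    cols = cmap.collapsed[rows_codes]
    keep = cols >= 0
    data = np.ones(keep.sum())
    return sparse.csr_matrix(
        (data, (np.flatnonzero(keep), cols[keep])), shape=(n, cmap.q_x)
    )


def build_design(
    records: pd.DataFrame,
    ped: Pedigree,
    bc: BreedComposition,
    cross: CrossCovariates,
    spec: ModelSpec | None = None,
) -> DesignMatrices:
    """Assemble fixed and random design matrices from a record table.

    ``records`` needs columns ``animal`` plus the factors/covariates and
    the response named in the spec.  The dam is taken from the pedigree;
    records on animals with an unknown dam are rejected (maternal terms
    would be undefined).
    """
    spec = spec or ModelSpec()
    n = len(records)
    try:
        animal_codes = np.array([ped.code[str(a)] for a in records["animal"]])
    except KeyError as err:
        raise ModelBuildError(f"record references unknown animal {err}") from None
    dam_codes = ped.dam[animal_codes]
    if np.any(dam_codes == UNKNOWN):
        bad = records["animal"].iloc[int(np.argmax(dam_codes == UNKNOWN))]
        raise ModelBuildError(f"record animal {bad!r} has an unknown dam")

    cols = [np.ones(n)]
    names = ["intercept"]
    for fac in spec.factors:
        dummies = pd.get_dummies(records[fac].astype(str), prefix=fac, drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
            names.append(c)
    for cov in spec.covariates:
        v = records[cov].to_numpy(dtype=float)
        if spec.center_covariates:
            v = v - v.mean()
        cols.append(v)
        names.append(cov)
    if spec.cross_covariates:
        cols += [
            cross.direct_breed[animal_codes],
            cross.maternal_breed[animal_codes],
            cross.direct_heterosis[animal_codes],
            cross.maternal_heterosis[animal_codes],
        ]
        names += ["breed_direct", "breed_maternal", "het_direct", "het_maternal"]
    X = np.column_stack(cols)
    zero = np.flatnonzero(np.all(X == 0.0, axis=0))
    if zero.size:
        raise ModelBuildError(f"all-zero fixed-effect column(s): {[names[z] for z in zero]}")

    cmaps, a_inv, Z = {}, {}, {}
    active = []
    for src in spec.sources:
        cmap = contributors(ped, bc, src)
        if cmap.q_x == 0:
            continue
        active.append(src)
        cmaps[src] = cmap
        a_inv[src] = collapsed_inverse(ped, bc, src, cmap)
        Z[(src, "o")] = _indicator(animal_codes, cmap, n)
        Z[(src, "m")] = _indicator(dam_codes, cmap, n)

    pe_dams = np.unique(dam_codes)
    dam_idx = {d: j for j, d in enumerate(pe_dams)}
    Zp = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), [dam_idx[d] for d in dam_codes])),
        shape=(n, len(pe_dams)),
    )
    y = records[spec.response].to_numpy(dtype=float)
    return DesignMatrices(
        X=X,
        fixed_names=names,
        Z=Z,
        Zp=Zp,
        y=y,
        cmaps=cmaps,
        a_inv=a_inv,
        pe_dams=pe_dams,
        animal_codes=animal_codes,
        dam_codes=dam_codes,
        q=ped.q,
        sources=tuple(active),
    )


def build_mme(dm: DesignMatrices, vc: GeneticCovSet, k: float = 1e7) -> MixedModelSystem:
    """Henderson's mixed-model equations on the collapsed system.

    C = W'W / sigma2_e + blockdiag(K^-1, {G0X^-1 (x) A*_X^-1}_X, I/sigma2_pe)
    and r = W'y / sigma2_e, with W = [X | Z_oA Z_mA | ... | Z_p] and each
    source block ordered (all direct | all maternal) so the Kronecker
    structure holds with the 2 x 2 G0X.
    """
    vc.validate(sources=dm.sources)
    blocks = [sparse.csr_matrix(dm.X)]
    layout = {"fixed": slice(0, dm.X.shape[1])}
    pos = dm.X.shape[1]
    prior = [sparse.identity(dm.X.shape[1], format="csc") / k]
    for src in dm.sources:
        qx = dm.cmaps[src].q_x
        layout[(src, "o")] = slice(pos, pos + qx)
        layout[(src, "m")] = slice(pos + qx, pos + 2 * qx)
        pos += 2 * qx
        blocks += [dm.Z[(src, "o")], dm.Z[(src, "m")]]
        g0_inv = np.linalg.inv(vc.g0[src])
        prior.append(sparse.kron(g0_inv, dm.a_inv[src], format="csc"))
    d = len(dm.pe_dams)
    layout["pe"] = slice(pos, pos + d)
    blocks.append(dm.Zp)
    prior.append(sparse.identity(d, format="csc") / vc.sigma2_pe)
    W = sparse.hstack(blocks, format="csr")
    C = (W.T @ W) / vc.sigma2_e + sparse.block_diag(prior, format="csc")
    r = W.T @ dm.y / vc.sigma2_e
    return MixedModelSystem(
        C=sparse.csc_matrix(C), r=r, W=W, y=dm.y, layout=layout, dm=dm, vc=vc, k=k
    )


def solve_blup(system: MixedModelSystem) -> LocationState:
    """Exact sparse solve of the MME (LU), with a residual-norm check."""
    lu = splu(system.C)
    theta = lu.solve(system.r)
    res = system.C @ theta - system.r
    denom = max(np.linalg.norm(system.r), 1.0)
    if np.linalg.norm(res) / denom > 1e-8:
        raise np.linalg.LinAlgError("mixed-model system solve did not converge")
    return LocationState(theta=theta, layout=system.layout, dm=system.dm)


def total_breeding_values(state: LocationState) -> pd.DataFrame:
    """Per-animal total direct and maternal breeding values.

    Each source's collapsed solutions are scattered back to the full
    animal list (zeros for non-contributors) and summed across sources.
    """
    dm = state.dm
    q = dm.q
    total = {"o": np.zeros(q + 1), "m": np.zeros(q + 1)}
    per_source = {}
    for src in dm.sources:
        for eff in ("o", "m"):
            v = expand_collapsed(state.a(src, eff), dm.cmaps[src], q)
            per_source[(src, eff)] = v
            total[eff] += v
    out = {"direct_total": total["o"][1:], "maternal_total": total["m"][1:]}
    for (src, eff), v in per_source.items():
        out[f"{'direct' if eff == 'o' else 'maternal'}_{src}"] = v[1:]
    return pd.DataFrame(out, index=np.arange(1, q + 1))
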