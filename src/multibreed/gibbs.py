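"""Single-site, systematic-scan Gibbs sampler for the multibreed model.

The hierarchy is: normal likelihood for the records; normal priors for
fixed effects (vague but proper, variance k), breeding values by breed
origin (G0X (x) A*_X) and permanent-environment effects; conjugate
scaled inverse-chi-squared priors for the scalar variances and inverse
Wishart priors for the 2 x 2 G0X matrices.  All full conditionals are
then recognizable:

* each scalar location theta_i | rest ~ N((r_i - sum_{j!=i} C_ij theta_j)
  / C_ii, 1 / C_ii) with (C, r) the current mixed-model system;
* sigma2 | rest ~ ScaledInvChi2(nu + n, (SS + nu s2_0) / (nu + n));
* G0X | rest ~ InvWishart(nu_X + q_X, nu_X G0X_0 + S_X), with S_X the
  2 x 2 matrix of quadratic forms u' A*_X^-1 u of the current direct and
  maternal vectors.

The prior convention is the animal-breeding one in which the scale
parameter is nu times the prior "location" S0 (so S0 is a statement about
where the distribution is centred, up to the usual (nu - p - 1) shift of
the inverse-Wishart mean).

The scan order is fixed: fixed effects, then sources A, B, S (direct
block then maternal block within each), then the permanent-environment
effects; then the three G0X draws and the two scalar draws.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import invwishart

from .components import COMPONENT_NAMES, GeneticCovSet
from .model import DesignMatrices, LocationState, MixedModelSystem, build_mme

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


class DivergentChainError(RuntimeError):
    """The sampler produced a non-finite state."""


@dataclass
class PriorSpec:
    """Scale matrices/values and degrees of belief for all components.

    ``g0_scale[src]`` is the 2 x 2 prior location for G0X and
    ``g0_df[src]`` its degrees of belief; ``pe``/``e`` are (scale, df)
    pairs for the scalar variances.  ``k`` is the fixed-effect prior
    variance (vague but proper).
    """

    g0_scale: dict
    g0_df: dict
    pe_scale: float
    pe_df: float
    e_scale: float
    e_df: float
    k: float = 1e7

    def __post_init__(self):
        if self.k < 1e7:
            raise ValueError("fixed-effect prior variance k must be >= 1e7")
        for src, g in self.g0_scale.items():
            g = np.asarray(g, dtype=float)
            self.g0_scale[src] = g
            if np.linalg.eigvalsh(g).min() <= 0:
                raise ValueError(f"prior scale G0{src} must be positive definite")
            if self.g0_df[src] <= 0:
                raise ValueError("degrees of belief must be positive")
        if min(self.pe_scale, self.e_scale) <= 0 or min(self.pe_df, self.e_df) <= 0:
            raise ValueError("scalar prior scales and dfs must be positive")

    def mean_covset(self) -> GeneticCovSet:
        """Prior locations packaged as a component set (starting values)."""
        return GeneticCovSet(
            g0={s: np.array(g, dtype=float) for s, g in self.g0_scale.items()},
            sigma2_pe=self.pe_scale,
            sigma2_e=self.e_scale,
        )


@dataclass
class ChainConfig:
    n_iter: int = 20_000
    burn_in: int = 2_000
    thin: int = 10
    seed: int = 0
    save_locations: bool = False

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must be in [0, n_iter)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


def _scan_python(indptr, indices, data, r, theta, z):
    for i in range(theta.shape[0]):
        s = 0.0
        cii = 0.0
        for p in range(indptr[i], indptr[i + 1]):
            j = indices[p]
            if j == i:
                cii = data[p]
            else:
                s += data[p] * theta[j]
        theta[i] = (r[i] - s) / cii + z[i] / np.sqrt(cii)


if _HAVE_NUMBA:
    _scan = njit(cache=False)(_scan_python)
else:  # pragma: no cover
    _scan = _scan_python


def sample_locations_single_site(
    theta: np.ndarray, system: MixedModelSystem, rng: np.random.Generator
) -> np.ndarray:
    """One full systematic scan of all location parameters, in place.

    Each scalar unknown is drawn from its normal full conditional given
    every other unknown and the current (co)variance components embedded
    in the system.  The column pattern of the symmetric C supplies the
    row sums.
    """
    C = system.C
    z = rng.standard_normal(theta.shape[0])
    _scan(C.indptr, C.indices, C.data, system.r, theta, z)
    if not np.all(np.isfinite(theta)):
        raise DivergentChainError("non-finite location draw")
    return theta


def sample_scalar_variance(
    sum_sq: float, n_terms: int, scale: float, df: float, rng: np.random.Generator
) -> float:
    """Scaled inverse-chi-squared draw for a scalar variance component.

    Posterior df is df + n_terms and posterior scale
    (sum_sq + df * scale) / (df + n_terms); with n_terms = 0 this is a
    draw from the prior.
    """
    if sum_sq < 0:
        raise ValueError("sum of squares must be non-negative")
    post_df = df + n_terms
    post_scale = (sum_sq + df * scale) / post_df
    return post_df * post_scale / rng.chisquare(post_df)


def sample_g0(
    S: np.ndarray, q_x: int, scale0: np.ndarray, df0: float, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-Wishart draw for a 2 x 2 source covariance matrix.

    ``S`` is the matrix of quadratic forms of the current breeding-value
    vectors against the collapsed inverse; with q_x = 0 the draw comes
    from the prior.
    """
    df = df0 + q_x
    psi = df0 * np.asarray(scale0, dtype=float) + S
    if np.linalg.eigvalsh(psi).min() <= 0:
        raise DivergentChainError("non-positive-definite inverse-Wishart scale")
    draw = invwishart.rvs(df=df, scale=psi, random_state=rng)
    draw = np.atleast_2d(draw)
    return 0.5 * (draw + draw.T)


def _quadratic_forms(a_o: np.ndarray, a_m: np.ndarray, a_inv: sparse.csc_matrix):
    qo = a_inv @ a_o
    qm = a_inv @ a_m
    return np.array(
        [[a_o @ qo, a_o @ qm], [a_o @ qm, a_m @ qm]]
    )


def config_hash(priors: PriorSpec, config: ChainConfig) -> str:
    text = repr(
        (
            {s: priors.g0_scale[s].tolist() for s in sorted(priors.g0_scale)},
            {s: priors.g0_df[s] for s in sorted(priors.g0_df)},
            priors.pe_scale, priors.pe_df, priors.e_scale, priors.e_df, priors.k,
            config.n_iter, config.burn_in, config.thin, config.seed,
        )
    )
    return hashlib.sha256(text.encode()).hexdigest()[:12]


class GibbsSampler:
    """Systematic-scan Gibbs sampler over a built design.

    Only the variance-dependent blocks of the mixed-model system are
    rebuilt between iterations; the incidence structure is fixed.
    """

    def __init__(self, dm: DesignMatrices, priors: PriorSpec, config: ChainConfig):
        self.dm = dm
        self.priors = priors
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.vc = priors.mean_covset()
        self.system = build_mme(dm, self.vc, k=priors.k)
        self.theta = np.zeros(self.system.n_unknowns)
        self._WtW = (self.system.W.T @ self.system.W).tocsc()
        self._Wty = self.system.W.T @ dm.y

    # -- one iteration -------------------------------------------------
    def _refresh_system(self) -> None:
        dm, vc = self.dm, self.vc
        prior = [sparse.identity(dm.X.shape[1], format="csc") / self.priors.k]
        for src in dm.sources:
            g0_inv = np.linalg.inv(vc.g0[src])
            prior.append(sparse.kron(g0_inv, dm.a_inv[src], format="csc"))
        prior.append(
            sparse.identity(len(dm.pe_dams), format="csc") / vc.sigma2_pe
        )
        C = self._WtW / vc.sigma2_e + sparse.block_diag(prior, format="csc")
        self.system.C = sparse.csc_matrix(C)
        self.system.r = self._Wty / vc.sigma2_e
        self.system.vc = vc

    def step(self) -> GeneticCovSet:
        dm, rng = self.dm, self.rng
        self._refresh_system()
        sample_locations_single_site(self.theta, self.system, rng)
        layout = self.system.layout
        g0 = {}
        for src in ("A", "B", "S"):
            if src in dm.sources:
                a_o = self.theta[layout[(src, "o")]]
                a_m = self.theta[layout[(src, "m")]]
                S = _quadratic_forms(a_o, a_m, dm.a_inv[src])
                q_x = dm.cmaps[src].q_x
            else:
                S, q_x = np.zeros((2, 2)), 0
            g0[src] = sample_g0(S, q_x, self.priors.g0_scale.get(src, np.eye(2)),
                                self.priors.g0_df.get(src, 4.0), rng)
        e_p = self.theta[layout["pe"]]
        s2_pe = sample_scalar_variance(
            float(e_p @ e_p), len(e_p), self.priors.pe_scale, self.priors.pe_df, rng
        )
        e = dm.y - self.system.W @ self.theta
        s2_e = sample_scalar_variance(
            float(e @ e), len(e), self.priors.e_scale, self.priors.e_df, rng
        )
        self.vc = GeneticCovSet(g0=g0, sigma2_pe=s2_pe, sigma2_e=s2_e)
        if not np.all(np.isfinite(self.vc.as_vector())):
            raise DivergentChainError("non-finite variance draw")
        return self.vc

    def run(self) -> pd.DataFrame:
        cfg = self.config
        rows, idx, locs = [], [], []
        for it in range(1, cfg.n_iter + 1):
            try:
                vc = self.step()
            except DivergentChainError as err:
                raise DivergentChainError(f"iteration {it}: {err}") from None
            if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                rows.append(vc.as_vector())
                idx.append(it)
                if cfg.save_locations:
                    locs.append(self.theta.copy())
        samples = pd.DataFrame(rows, columns=list(COMPONENT_NAMES), index=idx)
        samples.attrs["seed"] = cfg.seed
        samples.attrs["config_hash"] = config_hash(self.priors, cfg)
        if cfg.save_locations:
            samples.attrs["locations"] = np.array(locs)
        return samples

    def location_state(self) -> LocationState:
        return LocationState(theta=self.theta, layout=self.system.layout, dm=self.dm)


def run_chain(dm: DesignMatrices, priors: PriorSpec, config: ChainConfig) -> pd.DataFrame:
    """Run a full chain over a built design; returns thinned samples.

    Reproducible for a given seed: the sample table (and file written by
    :func:`write_chain`) is bitwise identical across reruns.
    """
    return GibbsSampler(dm, priors, config).run()


def write_chain(samples: pd.DataFrame, path) -> None:
    """Plain-text chain file: header comments name seed and config hash."""
    with open(path, "w") as fh:
        fh.write(f"# seed={samples.attrs.get('seed')}\n")
        fh.write(f"# config_hash={samples.attrs.get('config_hash')}\n")
        samples.to_csv(fh, sep="\t", index_label="iteration")


def read_chain(path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", comment="#", index_col="iteration")
    return samples
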