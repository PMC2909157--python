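"""Posterior summaries and derived genetic parameters.

Summaries follow the usual MCMC reporting for animal-model variance
components: mean, SD, median, kernel-density mode (Gaussian kernel,
Silverman bandwidth, argmax on a 512-point grid) and the shortest 95%
highest-posterior-density interval.  Derived parameters for a reference
breed group with weights (w_A, w_B, w_S):

    V_o  = w_A s2_Ao + w_B s2_Bo + w_S s2_So        (and V_m analogously)
    C_om = w_A s_AoAm + w_B s_BoBm + w_S s_SoSm
    V_P  = V_o + V_m + C_om + s2_pe + s2_e
    h2_o = V_o / V_P,  h2_m = V_m / V_P,  r_om = C_om / sqrt(V_o V_m)

Both the plug-in evaluation at a point estimate and the per-draw
posterior of the derived quantities are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .components import COMPONENT_NAMES, GeneticCovSet, ReferenceGroup

DERIVED_NAMES = ("v_direct", "v_maternal", "cov_dm", "v_phenotypic",
                 "h2_direct", "h2_maternal", "r_dm")


@dataclass
class GeneticParameters:
    """Variance partition and genetic parameters for one breed group."""

    v_direct: float
    v_maternal: float
    cov_dm: float
    share_direct: dict          # source -> % of V_o
    share_maternal: dict
    v_phenotypic: float = np.nan
    h2_direct: float = np.nan
    h2_maternal: float = np.nan
    r_dm: float = np.nan

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in DERIVED_NAMES}


def hpd_interval(x: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the sorted samples."""
    xs = np.sort(np.asarray(x, dtype=float))
    n = len(xs)
    m = int(np.ceil(prob * n))
    if m >= n:
        return float(xs[0]), float(xs[-1])
    widths = xs[m - 1:] - xs[: n - m + 1]
    j = int(np.argmin(widths))
    return float(xs[j]), float(xs[j + m - 1])


def kde_mode(x: np.ndarray, gridsize: int = 512) -> float:
    """Mode as the argmax of a Gaussian-kernel density on a regular grid."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0.0:
        return float(x[0])
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), gridsize)
    return float(grid[np.argmax(kde(grid))])


def kde_curve(x: np.ndarray, gridsize: int = 512) -> pd.DataFrame:
    """(grid, density) table of the Gaussian-kernel density estimate."""
    x = np.asarray(x, dtype=float)
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), gridsize)
    return pd.DataFrame({"grid": grid, "density": kde(grid)})


def ess_initial_positive(x: np.ndarray) -> float:
    """Effective sample size via the initial-positive-sequence estimator.

    Sums autocovariances in adjacent pairs while the pair sums stay
    positive (Geyer's initial positive sequence), giving a consistent
    overestimate of the integrated autocorrelation time for reversible
    chains.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.ptp(x) == 0.0:
        return float(n if np.ptp(x) else 1.0)
    rho = autocorrelation(x, max_lag=n - 2)
    pair = rho[0::2][: len(rho[1::2])] + rho[1::2]
    tau = -1.0
    for k, g in enumerate(pair):
        if k > 0 and g <= 0:
            break
        tau += 2.0 * g
    tau = max(tau, 1.0 / n)
    return float(min(n / tau, n))


def autocorrelation(x: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Autocorrelation function (FFT-based), lags 0..max_lag."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if max_lag is None:
        max_lag = min(n - 1, 1000)
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[: max_lag + 1] / n
    if acov[0] == 0.0:
        return np.ones(max_lag + 1)
    return acov / acov[0]


def summarize_chain(samples: pd.DataFrame, prob: float = 0.95,
                    min_samples: int = 100) -> pd.DataFrame:
    """Posterior summary table: mean, SD, median, KDE mode, HPD, ESS."""
    if len(samples) < min_samples:
        raise ValueError(
            f"need at least {min_samples} post-burn-in samples, have {len(samples)}"
        )
    rows = {}
    for col in samples.columns:
        x = samples[col].to_numpy(dtype=float)
        lo, hi = hpd_interval(x, prob)
        rows[col] = {
            "mean": x.mean(),
            "sd": x.std(ddof=1),
            "median": float(np.median(x)),
            "mode": kde_mode(x),
            "hpd_lower": lo,
            "hpd_upper": hi,
            "ess": ess_initial_positive(x),
        }
    return pd.DataFrame(rows).T


def variance_partition(vc: GeneticCovSet, group: ReferenceGroup) -> GeneticParameters:
    """Source-weighted additive variances and their percent shares."""
    w = group.weights
    contrib_o = {s: w[s] * vc.g0[s][0, 0] for s in ("A", "B", "S")}
    contrib_m = {s: w[s] * vc.g0[s][1, 1] for s in ("A", "B", "S")}
    v_o = sum(contrib_o.values())
    v_m = sum(contrib_m.values())
    if v_o <= 0 or v_m <= 0:
        raise ValueError("non-positive total additive variance for this group")
    c_om = sum(w[s] * vc.g0[s][0, 1] for s in ("A", "B", "S"))
    return GeneticParameters(
        v_direct=v_o,
        v_maternal=v_m,
        cov_dm=c_om,
        share_direct={s: 100.0 * contrib_o[s] / v_o for s in contrib_o},
        share_maternal={s: 100.0 * contrib_m[s] / v_m for s in contrib_m},
    )


def genetic_parameters(
    vc: GeneticCovSet, group: ReferenceGroup, include_environment: bool = True
) -> GeneticParameters:
    """Heritabilities and direct-maternal correlation for a breed group.

    The phenotypic variance of the group is V_o + V_m + C_om plus, when
    ``include_environment``, the permanent-environment and residual
    variances; the heritability denominator therefore carries the
    direct-maternal covariance with coefficient one.
    """
    gp = variance_partition(vc, group)
    v_p = gp.v_direct + gp.v_maternal + gp.cov_dm
    if include_environment:
        v_p += vc.sigma2_pe + vc.sigma2_e
    if v_p <= 0:
        raise ValueError("non-positive phenotypic variance")
    gp.v_phenotypic = v_p
    gp.h2_direct = gp.v_direct / v_p
    gp.h2_maternal = gp.v_maternal / v_p
    gp.r_dm = gp.cov_dm / np.sqrt(gp.v_direct * gp.v_maternal)
    return gp


def posterior_parameters(samples: pd.DataFrame, group: ReferenceGroup) -> pd.DataFrame:
    """Per-draw derived parameters, summarized like the raw components.

    Reports the posterior of each derived quantity (mean of ratio), which
    differs from the plug-in ratio of posterior means by a Jensen gap;
    both views are useful and the plug-in one is available through
    :func:`genetic_parameters` at the summarized point estimate.
    """
    derived = []
    for _, row in samples.iterrows():
        vc = GeneticCovSet.from_vector(row[list(COMPONENT_NAMES)].to_numpy())
        gp = genetic_parameters(vc, group)
        derived.append(gp.as_dict())
    return summarize_chain(pd.DataFrame(derived, index=samples.index),
                           min_samples=min(100, len(samples)))


def chain_diagnostics(samples: pd.DataFrame, max_lag: int | None = None) -> pd.DataFrame:
    """Per-component ACF summary, ESS and a split-chain mean z-score.

    The z-score compares first-half and second-half means using
    ESS-adjusted standard errors; a degenerate (constant) chain is
    flagged with ``degenerate = True`` and NaN diagnostics.
    """
    rows = {}
    for col in samples.columns:
        x = samples[col].to_numpy(dtype=float)
        n = len(x)
        if np.ptp(x) == 0.0:
            rows[col] = {"ess": np.nan, "acf_lag1": np.nan, "split_z": np.nan,
                         "degenerate": True}
            continue
        rho = autocorrelation(x, max_lag=max_lag or min(n // 10, 500))
        half = n // 2
        a, b = x[:half], x[half:]
        ess_a = ess_initial_positive(a)
        ess_b = ess_initial_positive(b)
        se = np.sqrt(a.var(ddof=1) / ess_a + b.var(ddof=1) / ess_b)
        rows[col] = {
            "ess": ess_initial_positive(x),
            "acf_lag1": float(rho[1]) if len(rho) > 1 else np.nan,
            "split_z": float((a.mean() - b.mean()) / se) if se > 0 else np.nan,
            "degenerate": False,
        }
    return pd.DataFrame(rows).T
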