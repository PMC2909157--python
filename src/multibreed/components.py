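"""Containers for the eleven (co)variance components of the model.

Per source X in {A, B, S} a 2 x 2 direct/maternal genetic covariance
matrix G0X, plus the maternal permanent-environment and residual
variances.  The canonical scalar ordering used in chain files is::

    sigma2_Ao cov_Ao_Am sigma2_Am
    sigma2_Bo cov_Bo_Bm sigma2_Bm
    sigma2_So cov_So_Sm sigma2_Sm
    sigma2_pe sigma2_e
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

COMPONENT_NAMES = (
    "sigma2_Ao", "cov_Ao_Am", "sigma2_Am",
    "sigma2_Bo", "cov_Bo_Bm", "sigma2_Bm",
    "sigma2_So", "cov_So_Sm", "sigma2_Sm",
    "sigma2_pe", "sigma2_e",
)


@dataclass
class GeneticCovSet:
    """The eleven scalar (co)variance components.

    ``g0`` maps source -> 2x2 array [[var_direct, cov], [cov, var_maternal]].
    """

    g0: dict
    sigma2_pe: float
    sigma2_e: float

    @classmethod
    def from_scalars(
        cls,
        a: tuple[float, float, float],
        b: tuple[float, float, float],
        s: tuple[float, float, float],
        sigma2_pe: float,
        sigma2_e: float,
    ) -> "GeneticCovSet":
        """Build from (var_direct, cov, var_maternal) triples per source."""

        def m(t):
            return np.array([[t[0], t[1]], [t[1], t[2]]], dtype=float)

        return cls(g0={"A": m(a), "B": m(b), "S": m(s)}, sigma2_pe=sigma2_pe,
                   sigma2_e=sigma2_e)

    def as_vector(self) -> np.ndarray:
        vals = []
        for src in ("A", "B", "S"):
            g = self.g0[src]
            vals += [g[0, 0], g[0, 1], g[1, 1]]
        vals += [self.sigma2_pe, self.sigma2_e]
        return np.array(vals)

    @classmethod
    def from_vector(cls, v) -> "GeneticCovSet":
        v = np.asarray(v, dtype=float)
        if v.shape != (11,):
            raise ValueError("expected 11 components")
        return cls.from_scalars(tuple(v[0:3]), tuple(v[3:6]), tuple(v[6:9]), v[9], v[10])

    def as_dict(self) -> dict:
        return dict(zip(COMPONENT_NAMES, self.as_vector()))

    def validate(self, sources=("A", "B", "S")) -> None:
        for src in sources:
            g = self.g0[src]
            if not np.allclose(g, g.T):
                raise ValueError(f"G0{src} is not symmetric")
            if np.linalg.eigvalsh(g).min() <= 0:
                raise ValueError(f"G0{src} is not positive definite")
        if self.sigma2_pe <= 0 or self.sigma2_e <= 0:
            raise ValueError("scalar variances must be positive")


@dataclass
class ReferenceGroup:
    """Source weights (w_A, w_B, w_S) defining a reference breed group.

    The additive variance expressed in the group is the weighted sum of
    the per-source components; the same weights apply to direct and
    maternal variances and to the direct-maternal covariances.  For an F2
    group the weights are (0.5, 0.5, 1): half of each breed's genes and
    the segregation variance fully expressed.
    """

    w_a: float
    w_b: float
    w_s: float
    name: str = ""

    def __post_init__(self):
        if self.w_a < 0 or self.w_b < 0 or self.w_s < 0:
            raise ValueError("reference-group weights must be non-negative")
        if abs(self.w_a + self.w_b - 1.0) > 1e-9:
            raise ValueError("breed weights w_A + w_B must sum to 1")

    @property
    def weights(self) -> dict:
        return {"A": self.w_a, "B": self.w_b, "S": self.w_s}


#: The F2 (inter-se cross of F1s) reference group.
F2_GROUP = ReferenceGroup(0.5, 0.5, 1.0, name="F2")
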