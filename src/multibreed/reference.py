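"""Published reference values for the Angus x Hereford weaning-weight study.

An experimental Angus x Hereford crossbred herd (weaning weight, ~3750
records, ~4700 pedigreed animals) is the canonical application of the
multibreed maternal model.  This module packages, as plain data:

* the 25 genotype classes of the mating design -- parental lines, F1 in
  both directions, F2-F4 inter-se, backcrosses, three- and four-breed
  rotationals and advanced crosses -- with their record counts and the
  expected breed-A (Angus) fractions of individual, sire and dam;
* the published posterior means of the eleven (co)variance components of
  the fitted model, and the prior scales / degrees of belief used there.

The genotype-class table doubles as the recipe book for the synthetic
mating plans in :mod:`multibreed.simulate`: each class names the pools
its sires and dams are drawn from.
"""

from __future__ import annotations

from dataclasses import dataclass

from .components import GeneticCovSet
from .gibbs import PriorSpec


@dataclass(frozen=True)
class GenotypeClass:
    """One mating type: label, parent pools, record count, printed f_A."""

    label: str
    mating: str                  # human-readable mating description
    sire_pool: str               # label of the pool sires come from
    dam_pool: str
    n_records: int
    f_individual: float          # printed, rounded to 2 decimals
    f_sire: float
    f_dam: float


#: Pools "BASE_A"/"BASE_B" denote founder purebreds (not record classes).
GENOTYPE_CLASSES = (
    GenotypeClass("ANGUS", "A x A", "BASE_A", "BASE_A", 711, 1.00, 1.00, 1.00),
    GenotypeClass("HEREFORD", "H x H", "BASE_B", "BASE_B", 431, 0.00, 0.00, 0.00),
    GenotypeClass("F1_HxA", "F1(H x A)", "HEREFORD", "ANGUS", 393, 0.50, 0.00, 1.00),
    GenotypeClass("F1_AxH", "F1(A x H)", "ANGUS", "HEREFORD", 301, 0.50, 1.00, 0.00),
    GenotypeClass("F2_HAxHA", "F2(HA x HA)", "F1_HxA", "F1_HxA", 235, 0.50, 0.50, 0.50),
    GenotypeClass("F2_AHxAH", "F2(AH x AH)", "F1_AxH", "F1_AxH", 183, 0.50, 0.50, 0.50),
    GenotypeClass("F3", "F3(F2 x F2)", "F2_HAxHA", "F2_AHxAH", 254, 0.50, 0.50, 0.50),
    GenotypeClass("F4", "F4(F3 x F3)", "F3", "F3", 104, 0.50, 0.50, 0.50),
    GenotypeClass("B1_AxHA", "B1(A x HA)", "ANGUS", "F1_HxA", 78, 0.75, 1.00, 0.50),
    GenotypeClass("B1_AxAH", "B1(A x AH)", "ANGUS", "F1_AxH", 72, 0.75, 1.00, 0.50),
    GenotypeClass("B1_HxHA", "B1(H x HA)", "HEREFORD", "F1_HxA", 77, 0.25, 0.00, 0.50),
    GenotypeClass("B1_HxAH", "B1(H x AH)", "HEREFORD", "F1_AxH", 67, 0.25, 0.00, 0.50),
    GenotypeClass("B1_AHxA", "B1(AH x A)", "F1_AxH", "ANGUS", 180, 0.75, 0.50, 1.00),
    GenotypeClass("B1_HAxH", "B1(HA x H)", "F1_HxA", "HEREFORD", 132, 0.25, 0.50, 0.00),
    GenotypeClass("R3_AxB1HHA", "R3[A x B1(H x HA)]", "ANGUS", "B1_HxHA",
                  77, 0.63, 1.00, 0.25),
    GenotypeClass("R3_AxB1HAH", "R3[A x B1(H x AH)]", "ANGUS", "B1_HxAH",
                  51, 0.63, 1.00, 0.25),
    GenotypeClass("R3_HxB1AHA", "R3[H x B1(A x HA)]", "HEREFORD", "B1_AxHA",
                  96, 0.38, 0.00, 0.75),
    GenotypeClass("R3_HxB1AHxA", "R3[H x B1(AH x A)]", "HEREFORD", "B1_AHxA",
                  51, 0.38, 0.00, 0.75),
    GenotypeClass("R4_AxR3", "R4(A x R3)", "ANGUS", "R3_HxB1AHA", 67, 0.69, 1.00, 0.38),
    GenotypeClass("R4_HxR3", "R4(H x R3)", "HEREFORD", "R3_AxB1HHA", 68, 0.31, 0.00, 0.63),
    GenotypeClass("ADV_F3xF1HA", "F3 x F1(HA)", "F3", "F1_HxA", 19, 0.50, 0.50, 0.50),
    GenotypeClass("ADV_F3xF1AH", "F3 x F1(AH)", "F3", "F1_AxH", 27, 0.50, 0.50, 0.50),
    GenotypeClass("ADV_F3xF4", "F3 x F4", "F3", "F4", 30, 0.50, 0.50, 0.50),
    GenotypeClass("ADV_AxR4", "A x R4", "ANGUS", "R4_HxR3", 21, 0.66, 1.00, 0.31),
    GenotypeClass("ADV_HxR4", "H x R4", "HEREFORD", "R4_AxR3", 24, 0.34, 0.00, 0.69),
)

#: Published posterior means of the eleven components (kg^2; covariances kg^2).
#: Triples are (direct variance, direct-maternal covariance, maternal variance)
#: per source; A = Angus, B = Hereford, S = segregation.
REFERENCE_POSTERIOR_MEANS = GeneticCovSet.from_scalars(
    a=(120.74, -27.00, 37.63),
    b=(100.24, -56.31, 95.18),
    s=(9.62, 9.55, 13.37),
    sigma2_pe=95.53,
    sigma2_e=187.34,
)

#: Prior scales and degrees of belief used in the published analysis.
REFERENCE_PRIORS = PriorSpec(
    g0_scale={
        "A": [[85.0, -25.0], [-25.0, 35.0]],
        "B": [[76.0, -50.0], [-50.0, 70.0]],
        "S": [[10.0, 8.0], [8.0, 9.0]],
    },
    g0_df={"A": 20.0, "B": 20.0, "S": 5.0},
    pe_scale=80.0,
    pe_df=100.0,
    e_scale=170.0,
    e_df=100.0,
)
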