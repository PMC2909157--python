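"""Synthetic crossbred pedigrees, phenotypes, and a gene-dropping oracle.

The generator emulates the Angus x Hereford mating design: founder
purebreds of both breeds, then cohorts of parental, F1 (both directions),
F2-F4 inter-se, backcross, rotational and advanced matings, each drawing
sires and dams from previously generated pools so the pedigree is deep
and the breed groups are connected.  Breeding values are generated
sequentially by source (parent average plus a Mendelian deviation with
per-source variance d_X(i) G0X) and phenotypes follow the maternal model
with dam permanent-environment effects shared across a dam's progeny.

The gene-dropping oracle is an independent construction of the additive
covariance: explicit unlinked loci with breed-specific allele-effect
distributions, dropped through the pedigree by fair Mendelian
transmission, from which the empirical covariance of genotypic values is
estimated across replicates.  With per-locus within-breed variances v_X
and breed mean differences delta_t, the implied components are
sigma2_X = 2 sum_t v_Xt and sigma2_S = 1/2 sum_t delta_t^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .components import GeneticCovSet
from .partial_nrm import contributors, mendelian_variances
from .pedigree import (
    UNKNOWN,
    BreedComposition,
    Pedigree,
    PedigreeRecord,
    compute_breed_fractions,
    compute_cross_covariates,
    from_records,
)
from .reference import GENOTYPE_CLASSES


@dataclass
class Cohort:
    """One mating type: n offspring from sire_pool males x dam_pool females."""

    label: str
    sire_pool: str
    dam_pool: str
    n: int


@dataclass
class MatingPlan:
    """Counts of founder purebreds and the cohort list, in mating order.

    ``family_size`` controls how many progeny share a dam within one
    cohort; dams reused across cohorts give the repeated-dam structure
    that identifies the permanent-environment variance.
    """

    n_base_a: int = 60
    n_base_b: int = 40
    cohorts: tuple = ()
    family_size: int = 3

    def __post_init__(self):
        if self.n_base_a < 2 or self.n_base_b < 2:
            raise ValueError("need at least a male and a female founder per breed")
        for c in self.cohorts:
            if c.n < 1:
                raise ValueError(f"cohort {c.label} has no offspring")


def reference_plan(scale: float = 1.0, min_n: int = 2) -> MatingPlan:
    """The full 25-class mating design, with record counts scaled down.

    ``scale = 1`` reproduces the published cohort sizes (~3750 records);
    smaller scales keep every mating type represented (at least ``min_n``
    offspring each).
    """
    cohorts = tuple(
        Cohort(g.label, g.sire_pool, g.dam_pool, max(min_n, round(g.n_records * scale)))
        for g in GENOTYPE_CLASSES
    )
    n_a = max(10, round(180 * scale))
    n_b = max(10, round(120 * scale))
    return MatingPlan(n_base_a=n_a, n_base_b=n_b, cohorts=cohorts)


@dataclass
class FixedEffects:
    """True fixed-effect values for phenotype simulation (kg scale)."""

    mu: float = 150.0
    sex: dict = field(default_factory=lambda: {"M": 8.0, "F": 0.0})
    age_of_dam: dict = field(default_factory=lambda: {"2": 0.0, "3": 5.0, "4": 8.0})
    day_of_birth_slope: float = 0.3
    breed_direct: float = 5.0
    breed_maternal: float = 3.0
    het_direct: float = 10.0
    het_maternal: float = 5.0


@dataclass
class TrueParameters:
    """Generating values: the 11 components plus the fixed effects."""

    vc: GeneticCovSet
    fixed: FixedEffects = field(default_factory=FixedEffects)


def simulate_pedigree(plan: MatingPlan, rng: np.random.Generator) -> Pedigree:
    """Generate a pedigree following the mating plan.

    Every animal carries its genotype-class label; sexes alternate within
    a cohort so later cohorts always find sires and dams.  Within a
    cohort, dams are drawn without replacement (recycling if the pool is
    small) and each dam's family shares one sire.
    """
    records: list[PedigreeRecord] = []
    pools: dict[str, dict[str, list[str]]] = {}

    def add_pool(label):
        pools.setdefault(label, {"M": [], "F": []})

    for breed, nb, fa in (("BASE_A", plan.n_base_a, 1.0), ("BASE_B", plan.n_base_b, 0.0)):
        add_pool(breed)
        for k in range(nb):
            sex = "M" if k % 4 == 0 else "F"  # cow-heavy founder herds
            aid = f"{breed}_{k + 1}"
            records.append(PedigreeRecord(animal=aid, f_a=fa, sex=sex, label=breed))
            pools[breed][sex].append(aid)

    for cohort in plan.cohorts:
        for pool in (cohort.sire_pool, cohort.dam_pool):
            if pool not in pools:
                raise ValueError(
                    f"cohort {cohort.label} references pool {pool!r} before it exists"
                )
        sires_avail = pools[cohort.sire_pool]["M"]
        dams_avail = pools[cohort.dam_pool]["F"]
        if not sires_avail or not dams_avail:
            raise ValueError(f"cohort {cohort.label}: empty sire or dam pool")
        n_fam = max(1, math.ceil(cohort.n / plan.family_size))
        fam_dams = [
            dams_avail[j]
            for j in rng.permutation(len(dams_avail))[: min(n_fam, len(dams_avail))]
        ]
        fam_sires = [sires_avail[j] for j in rng.integers(0, len(sires_avail), len(fam_dams))]
        add_pool(cohort.label)
        for k in range(cohort.n):
            fam = k % len(fam_dams)
            sex = "M" if k % 2 == 0 else "F"
            aid = f"{cohort.label}_{k + 1}"
            records.append(
                PedigreeRecord(
                    animal=aid, sire=fam_sires[fam], dam=fam_dams[fam], sex=sex,
                    label=cohort.label,
                )
            )
            pools[cohort.label][sex].append(aid)
    return from_records(records)


def simulate_breeding_values(
    ped: Pedigree,
    bc: BreedComposition,
    vc: GeneticCovSet,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Direct/maternal breeding values per source, sequentially in order.

    For each source X and contributor i, (a_o, a_m)_i is the mean of the
    contributing parents' pairs plus a Mendelian deviation drawn from
    N2(0, d_X(i) G0X); non-contributors keep exact zeros.
    """
    out = {}
    for src in ("A", "B", "S"):
        cmap = contributors(ped, bc, src)
        vals = np.zeros((ped.q + 1, 2))
        if cmap.q_x:
            mv = mendelian_variances(ped, bc, src, cmap)
            chol = np.linalg.cholesky(vc.g0[src])
            for i in cmap.members:
                mean = 0.5 * (vals[ped.sire[i]] + vals[ped.dam[i]])
                vals[i] = mean + math.sqrt(mv.d[i]) * (chol @ rng.standard_normal(2))
        out[src] = vals
    return out


def simulate_phenotypes(
    ped: Pedigree,
    bvalues: dict[str, np.ndarray],
    params: TrueParameters,
    rng: np.random.Generator,
    bc: BreedComposition | None = None,
) -> pd.DataFrame:
    """Records for every animal with a known dam, under the maternal model.

    y = fixed part + sum_X a_oX(animal) + sum_X a_mX(dam) + e_p(dam) + e,
    with one permanent-environment effect per dam shared by all her
    progeny records.  Sex comes from the pedigree; age-of-dam class and
    day of birth are drawn per record.
    """
    bc = bc or compute_breed_fractions(ped)
    cross = compute_cross_covariates(ped, bc)
    fx = params.fixed
    vc = params.vc
    e_p = {
        d: rng.normal(0.0, math.sqrt(vc.sigma2_pe))
        for d in np.unique(ped.dam[1:])
        if d != UNKNOWN
    }
    rows = []
    for i in ped.animals():
        d = ped.dam[i]
        if d == UNKNOWN:
            continue
        sex = ped.sex[i] or ("M" if i % 2 == 0 else "F")
        aod = str(rng.choice(list(fx.age_of_dam)))
        dob = float(np.round(rng.uniform(0.0, 60.0), 1))
        y = (
            fx.mu
            + fx.sex[sex]
            + fx.age_of_dam[aod]
            + fx.day_of_birth_slope * dob
            + fx.breed_direct * cross.direct_breed[i]
            + fx.breed_maternal * cross.maternal_breed[i]
            + fx.het_direct * cross.direct_heterosis[i]
            + fx.het_maternal * cross.maternal_heterosis[i]
        )
        for src in ("A", "B", "S"):
            y += bvalues[src][i, 0] + bvalues[src][d, 1]
        y += e_p[d] + rng.normal(0.0, math.sqrt(vc.sigma2_e))
        rows.append(
            {
                "animal": ped.ids[i],
                "dam": ped.ids[d],
                "sex": sex,
                "age_of_dam": aod,
                "day_of_birth": dob,
                "weight": y,
            }
        )
    return pd.DataFrame(rows)


def simulate_dataset(
    plan: MatingPlan, params: TrueParameters, seed: int
) -> tuple[Pedigree, pd.DataFrame]:
    """Pedigree plus phenotype records for a plan, reproducible per seed."""
    rng = np.random.default_rng(seed)
    ped = simulate_pedigree(plan, rng)
    bc = compute_breed_fractions(ped)
    bvs = simulate_breeding_values(ped, bc, params.vc, rng)
    records = simulate_phenotypes(ped, bvs, params, rng, bc)
    return ped, records


def gene_drop_oracle(
    ped: Pedigree,
    sigma2: dict[str, float],
    rng: np.random.Generator,
    n_loci: int = 100,
    n_replicates: int = 50_000,
    batch: int = 2_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical additive covariance matrix by explicit gene dropping.

    Base animals must be purebred.  Per replicate, each founder receives
    2 x n_loci allele effects from its breed's distribution (normal with
    per-locus variance sigma2_X / (2 n_loci); breed means differ by
    sqrt(2 sigma2_S / n_loci) per locus); descendants inherit one allele
    per parent per locus, chosen by a fair coin.  Returns the covariance
    of genotypic values over replicates and the per-entry Monte Carlo
    standard error sqrt((C_ii C_jj + C_ij^2) / R).
    """
    q = ped.q
    for i in ped.animals():
        if ped.is_base[i] and ped.declared_f[i] not in (0.0, 1.0):
            raise ValueError("gene-dropping oracle requires purebred base animals")
        if not ped.is_base[i] and (ped.sire[i] == UNKNOWN or ped.dam[i] == UNKNOWN):
            raise ValueError("gene-dropping oracle requires both parents or none")
    v = {"A": sigma2["A"] / (2 * n_loci), "B": sigma2["B"] / (2 * n_loci)}
    delta = math.sqrt(2.0 * sigma2["S"] / n_loci)
    mu = {"A": +0.5 * delta, "B": -0.5 * delta}
    s1 = np.zeros(q)
    s2 = np.zeros((q, q))
    done = 0
    while done < n_replicates:
        nb = min(batch, n_replicates - done)
        alleles = np.empty((nb, q + 1, n_loci, 2))
        for i in ped.animals():
            if ped.is_base[i]:
                br = "A" if ped.declared_f[i] == 1.0 else "B"
                alleles[:, i] = rng.normal(mu[br], math.sqrt(v[br]), (nb, n_loci, 2))
            else:
                for k, parent in ((0, ped.sire[i]), (1, ped.dam[i])):
                    pick = rng.integers(0, 2, (nb, n_loci, 1))
                    alleles[:, i, :, k] = np.take_along_axis(
                        alleles[:, parent], pick, axis=2
                    )[:, :, 0]
        g = alleles[:, 1:].sum(axis=(2, 3))
        s1 += g.sum(axis=0)
        s2 += g.T @ g
        done += nb
    r = n_replicates
    cov = (s2 - np.outer(s1, s1) / r) / (r - 1)
    se = np.sqrt((np.outer(np.diag(cov), np.diag(cov)) + cov**2) / r)
    return cov, se
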