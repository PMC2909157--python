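"""Design matrices, mixed-model equations, BLUP and its dense equivalence."""

import numpy as np
import pandas as pd
import pytest

import multibreed as mb
from multibreed.model import ModelBuildError
from multibreed.partial_nrm import SOURCES

from conftest import classical_nrm, f2_records


def make_records(ped, animals, rng, weight=None):
    n = len(animals)
    return pd.DataFrame(
        {
            "animal": animals,
            "sex": [("M" if k % 2 else "F") for k in range(n)],
            "age_of_dam": [str(2 + k % 3) for k in range(n)],
            "day_of_birth": rng.uniform(0, 60, n).round(1),
            "weight": rng.normal(150, 10, n) if weight is None else weight,
        }
    )


@pytest.fixture
def f2_data(f2_pedigree, rng):
    ped = f2_pedigree
    bc = mb.compute_breed_fractions(ped)
    cross = mb.compute_cross_covariates(ped, bc)
    records = make_records(ped, ["f2", "bc"], rng)
    return ped, bc, cross, records


SMALL_VC = mb.GeneticCovSet.from_scalars(
    a=(100.0, -20.0, 40.0), b=(80.0, -30.0, 60.0), s=(10.0, 5.0, 8.0),
    sigma2_pe=50.0, sigma2_e=150.0,
)


class TestBuildDesign:
    def test_shapes_and_null_rows(self, f2_data):
        ped, bc, cross, records = f2_data
        dm = mb.build_design(records, ped, bc, cross)
        assert dm.X.shape[0] == 2
        # each Z row has at most a single unit entry
        for z in dm.Z.values():
            assert set(np.unique(z.toarray())) <= {0.0, 1.0}
            assert np.all(z.sum(axis=1) <= 1)
        # F2 record: direct breed covariate 0.5, heterosis 0.5
        j = dm.fixed_names.index("breed_direct")
        assert dm.X[0, j] == 0.5
        assert dm.X[0, dm.fixed_names.index("het_direct")] == 0.5

    def test_purebred_record_has_zero_rows_for_other_sources(self, rng):
        recs = [
            mb.PedigreeRecord("p1", f_a=1.0), mb.PedigreeRecord("p2", f_a=1.0),
            mb.PedigreeRecord("b0", f_a=0.0), mb.PedigreeRecord("b1", f_a=0.0),
            mb.PedigreeRecord("c", sire="p1", dam="p2"),
            mb.PedigreeRecord("x", sire="b0", dam="b1"),
        ]
        ped = mb.from_records(recs)
        bc = mb.compute_breed_fractions(ped)
        cross = mb.compute_cross_covariates(ped, bc)
        records = make_records(ped, ["c", "x"], rng)
        dm = mb.build_design(
            records, ped, bc, cross, mb.ModelSpec(cross_covariates=False)
        )
        assert "S" not in dm.sources  # no crossbred parents anywhere
        assert dm.Z[("B", "o")][0].nnz == 0  # purebred-A record: no B equation

    def test_unknown_animal_rejected(self, f2_data):
        ped, bc, cross, records = f2_data
        records.loc[0, "animal"] = "ghost"
        with pytest.raises(ModelBuildError, match="unknown animal"):
            mb.build_design(records, ped, bc, cross)

    def test_record_with_unknown_dam_rejected(self, f2_data, rng):
        ped, bc, cross, _ = f2_data
        records = make_records(ped, ["a1"], rng)
        with pytest.raises(ModelBuildError, match="unknown dam"):
            mb.build_design(records, ped, bc, cross)


class TestBuildMME:
    def test_symmetric_positive_definite(self, f2_data):
        ped, bc, cross, records = f2_data
        dm = mb.build_design(records, ped, bc, cross,
                             mb.ModelSpec(cross_covariates=False))
        system = mb.build_mme(dm, SMALL_VC)
        C = system.C.toarray()
        assert np.allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() > 0

    def test_fixed_block_is_xtx_plus_ridge(self, f2_data):
        ped, bc, cross, records = f2_data
        dm = mb.build_design(records, ped, bc, cross,
                             mb.ModelSpec(cross_covariates=False))
        k = 1e7
        system = mb.build_mme(dm, SMALL_VC, k=k)
        nf = dm.X.shape[1]
        expected = dm.X.T @ dm.X / SMALL_VC.sigma2_e + np.eye(nf) / k
        assert np.allclose(system.C.toarray()[:nf, :nf], expected)

    def test_non_positive_definite_g0_rejected(self, f2_data):
        ped, bc, cross, records = f2_data
        dm = mb.build_design(records, ped, bc, cross,
                             mb.ModelSpec(cross_covariates=False))
        bad = mb.GeneticCovSet.from_scalars(
            a=(1.0, 2.0, 1.0), b=(80.0, -30.0, 60.0), s=(10.0, 5.0, 8.0),
            sigma2_pe=50.0, sigma2_e=150.0,
        )
        with pytest.raises(ValueError, match="positive definite"):
            mb.build_mme(dm, bad)


def dense_multisource_blup(records, ped, bc, cross, vc, spec, k=1e7):
    """Oracle: one genetic effect pair per animal with the full tabular
    covariance sum_X G0X (x) A_X, solved densely."""
    dm = mb.build_design(records, ped, bc, cross, spec)
    q, n = ped.q, len(records)
    partials = {s: mb.partial_nrm_tabular(ped, bc, s) for s in SOURCES}
    sigma = sum(np.kron(vc.g0[s], partials[s]) for s in SOURCES)
    Zo = np.zeros((n, q))
    Zm = np.zeros((n, q))
    Zo[np.arange(n), dm.animal_codes - 1] = 1.0
    Zm[np.arange(n), dm.dam_codes - 1] = 1.0
    Zp = dm.Zp.toarray()
    W = np.hstack([dm.X, Zo, Zm, Zp])
    prior = np.zeros((W.shape[1], W.shape[1]))
    nf = dm.X.shape[1]
    prior[:nf, :nf] = np.eye(nf) / k
    prior[nf:nf + 2 * q, nf:nf + 2 * q] = np.linalg.inv(sigma)
    prior[nf + 2 * q:, nf + 2 * q:] = np.eye(Zp.shape[1]) / vc.sigma2_pe
    C = W.T @ W / vc.sigma2_e + prior
    theta = np.linalg.solve(C, W.T @ records["weight"].to_numpy() / vc.sigma2_e)
    return theta[nf:nf + q], theta[nf + q:nf + 2 * q]


class TestSolveBlup:
    def test_no_records_limit_gives_zero_solutions(self, f2_data):
        ped, bc, cross, records = f2_data
        records = records.copy()
        spec = mb.ModelSpec(cross_covariates=False)
        dm = mb.build_design(records, ped, bc, cross, spec)
        # With the response orthogonal to everything (y = 0) all random
        # effects shrink to zero.
        dm.y = np.zeros_like(dm.y)
        state = mb.solve_blup(mb.build_mme(dm, SMALL_VC))
        tbv = mb.total_breeding_values(state)
        assert np.allclose(tbv["direct_total"], 0.0)

    def test_shrinkage_to_zero_with_vanishing_genetic_variance(self, f2_data):
        ped, bc, cross, records = f2_data
        spec = mb.ModelSpec(cross_covariates=False)
        dm = mb.build_design(records, ped, bc, cross, spec)
        tiny = mb.GeneticCovSet.from_scalars(
            a=(1e-8, 0.0, 1e-8), b=(1e-8, 0.0, 1e-8), s=(1e-8, 0.0, 1e-8),
            sigma2_pe=1e-8, sigma2_e=150.0,
        )
        state = mb.solve_blup(mb.build_mme(dm, tiny))
        tbv = mb.total_breeding_values(state)
        assert np.abs(tbv["direct_total"]).max() < 1e-6

    def test_collapsed_equals_dense_single_covariance_model(self, rng):
        """Collapsed multi-source BLUP reproduces the dense total-G BLUP."""
        recs = f2_records() + [
            mb.PedigreeRecord("f3", sire="f2", dam="f1b"),
            mb.PedigreeRecord("bc2", sire="f1a", dam="f1b"),
        ]
        ped = mb.from_records(recs)
        bc = mb.compute_breed_fractions(ped)
        cross = mb.compute_cross_covariates(ped, bc)
        records = make_records(ped, ["f2", "bc", "f3", "bc2"], rng)
        spec = mb.ModelSpec(cross_covariates=False)
        dm = mb.build_design(records, ped, bc, cross, spec)
        state = mb.solve_blup(mb.build_mme(dm, SMALL_VC))
        tbv = mb.total_breeding_values(state)
        a_o, a_m = dense_multisource_blup(records, ped, bc, cross, SMALL_VC, spec)
        assert np.abs(tbv["direct_total"].to_numpy() - a_o).max() < 1e-6
        assert np.abs(tbv["maternal_total"].to_numpy() - a_m).max() < 1e-6

    def test_equal_breed_variances_reduce_to_single_nrm_model(self, rng):
        """With G0A = G0B and no segregation contributors the multibreed
        solutions equal a classical single-NRM maternal animal model."""
        recs = [
            mb.PedigreeRecord("a1", f_a=1.0), mb.PedigreeRecord("a2", f_a=1.0),
            mb.PedigreeRecord("b1", f_a=0.0), mb.PedigreeRecord("b2", f_a=0.0),
            mb.PedigreeRecord("f1a", sire="a1", dam="b1"),
            mb.PedigreeRecord("f1b", sire="a2", dam="b2"),
            mb.PedigreeRecord("c1", sire="a1", dam="b2"),
        ]
        ped = mb.from_records(recs)
        bc = mb.compute_breed_fractions(ped)
        cross = mb.compute_cross_covariates(ped, bc)
        records = make_records(ped, ["f1a", "f1b", "c1"], rng)
        spec = mb.ModelSpec(cross_covariates=False)
        g0 = np.array([[90.0, -25.0], [-25.0, 50.0]])
        vc = mb.GeneticCovSet(
            g0={"A": g0, "B": g0, "S": np.eye(2)}, sigma2_pe=50.0, sigma2_e=150.0
        )
        dm = mb.build_design(records, ped, bc, cross, spec)
        assert "S" not in dm.sources
        state = mb.solve_blup(mb.build_mme(dm, vc))
        tbv = mb.total_breeding_values(state)

        # independent oracle: classical NRM animal model, dense solve
        q, n = ped.q, len(records)
        nrm = classical_nrm(ped)
        sig = np.kron(g0, nrm)
        Zo = np.zeros((n, q))
        Zm = np.zeros((n, q))
        Zo[np.arange(n), dm.animal_codes - 1] = 1.0
        Zm[np.arange(n), dm.dam_codes - 1] = 1.0
        W = np.hstack([dm.X, Zo, Zm, dm.Zp.toarray()])
        nf = dm.X.shape[1]
        prior = np.zeros((W.shape[1],) * 2)
        prior[:nf, :nf] = np.eye(nf) / 1e7
        prior[nf:nf + 2 * q, nf:nf + 2 * q] = np.linalg.inv(sig)
        prior[nf + 2 * q:, nf + 2 * q:] = np.eye(dm.Zp.shape[1]) / vc.sigma2_pe
        C = W.T @ W / vc.sigma2_e + prior
        theta = np.linalg.solve(C, W.T @ dm.y / vc.sigma2_e)
        assert np.abs(tbv["direct_total"].to_numpy() - theta[nf:nf + q]).max() < 1e-6

    def test_solution_invariant_to_source_block_order(self, rng):
        recs = f2_records()
        ped = mb.from_records(recs)
        bc = mb.compute_breed_fractions(ped)
        cross = mb.compute_cross_covariates(ped, bc)
        records = make_records(ped, ["f2", "bc"], rng)
        out = {}
        for order in (("A", "B", "S"), ("S", "B", "A")):
            spec = mb.ModelSpec(cross_covariates=False, sources=order)
            dm = mb.build_design(records, ped, bc, cross, spec)
            state = mb.solve_blup(mb.build_mme(dm, SMALL_VC))
            out[order] = mb.total_breeding_values(state)["direct_total"].to_numpy()
        assert np.allclose(*out.values(), atol=1e-9)
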