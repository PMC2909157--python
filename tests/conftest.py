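import numpy as np
import pytest

import multibreed as mb


def classical_nrm(ped):
    """Independent tabular Wright numerator relationship matrix (oracle)."""
    q = ped.q
    a = np.zeros((q + 1, q + 1))
    for i in range(1, q + 1):
        s, d = ped.sire[i], ped.dam[i]
        for j in range(1, i):
            v = 0.0
            if s:
                v += 0.5 * a[s, j]
            if d:
                v += 0.5 * a[d, j]
            a[i, j] = a[j, i] = v
        a[i, i] = 1.0 + (0.5 * a[s, d] if s and d else 0.0)
    return a[1:, 1:]


def trio_records():
    """Purebred A sire, purebred B dam, F1 child."""
    return [
        mb.PedigreeRecord("s", f_a=1.0),
        mb.PedigreeRecord("d", f_a=0.0),
        mb.PedigreeRecord("c", sire="s", dam="d"),
    ]


def f2_records():
    """Two founder pairs, two F1s, an F2 and a backcross."""
    return [
        mb.PedigreeRecord("a1", f_a=1.0),
        mb.PedigreeRecord("a2", f_a=1.0),
        mb.PedigreeRecord("b1", f_a=0.0),
        mb.PedigreeRecord("b2", f_a=0.0),
        mb.PedigreeRecord("f1a", sire="a1", dam="b1"),
        mb.PedigreeRecord("f1b", sire="a2", dam="b2"),
        mb.PedigreeRecord("f2", sire="f1a", dam="f1b"),
        mb.PedigreeRecord("bc", sire="a1", dam="f1b"),
    ]


@pytest.fixture
def trio_pedigree():
    return mb.from_records(trio_records())


@pytest.fixture
def f2_pedigree():
    return mb.from_records(f2_records())


@pytest.fixture
def rng():
    return np.random.default_rng(20251002)


def random_crossbred_pedigree(rng, n_base_a=4, n_base_b=4, n_offspring=16):
    """Small random two-breed pedigree with crossbred parents (for oracles)."""
    recs = []
    ids = []
    for k in range(n_base_a):
        recs.append(mb.PedigreeRecord(f"A{k}", f_a=1.0))
        ids.append(f"A{k}")
    for k in range(n_base_b):
        recs.append(mb.PedigreeRecord(f"B{k}", f_a=0.0))
        ids.append(f"B{k}")
    for k in range(n_offspring):
        s, d = rng.choice(len(ids), size=2, replace=False)
        recs.append(mb.PedigreeRecord(f"X{k}", sire=ids[s], dam=ids[d]))
        ids.append(f"X{k}")
    return mb.from_records(recs)


def round_half_up(x, decimals=2):
    x = np.asarray(x, dtype=float)
    scale = 10.0**decimals
    return np.floor(x * scale + 0.5) / scale
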