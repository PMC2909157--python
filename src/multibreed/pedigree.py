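"""Pedigree handling for multibreed populations.

Reads and validates pedigrees, orders them so every parent precedes its
offspring, and computes expected breed compositions together with the
crossbreeding regressors (breed fraction and expected heterozygosity) used
as fixed-effect covariates in the multibreed animal model.

Identifiers are opaque strings mapped to dense integer codes 1..q in
topological order; code 0 is the sentinel for an unknown parent.  Breed
fractions follow the parent-average recursion f_i = (f_sire + f_dam)/2,
seeded by the declared fractions of base animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = 0
#: Breed order of the fraction vectors: index 0 = breed A, index 1 = breed B.
BREEDS = ("A", "B")


class PedigreeError(ValueError):
    """Structural problem in a pedigree (duplicates, cycles, bad fractions)."""


class MissingBreedFractionError(PedigreeError):
    """A base (or phantom) animal lacks a declared breed fraction."""


@dataclass
class PedigreeRecord:
    """One pedigree row prior to integer coding.

    ``f_a`` is the declared breed-A fraction.  It is mandatory for base
    animals (both parents unknown) and for animals with exactly one known
    parent, where it is interpreted as the breed-A fraction of the phantom
    base parent filling the unknown slot.  ``sire_f_a`` / ``dam_f_a``
    declare parental fractions of a *crossbred* base animal (needed by the
    segregation coefficient); purebred base animals default to purebred
    parents.
    """

    animal: str
    sire: str = ""
    dam: str = ""
    f_a: float | None = None
    sire_f_a: float | None = None
    dam_f_a: float | None = None
    sex: str = ""
    label: str = ""


@dataclass
class Pedigree:
    """Topologically ordered pedigree with dense integer coding.

    Arrays have length q+1; slot 0 is the unknown-parent sentinel.
    """

    ids: np.ndarray            # object array, ids[0] == ""
    sire: np.ndarray           # int codes
    dam: np.ndarray
    is_base: np.ndarray        # both parents unknown
    declared_f: np.ndarray     # declared f_A (NaN where absent)
    declared_sire_f: np.ndarray
    declared_dam_f: np.ndarray
    sex: np.ndarray = None
    label: np.ndarray = None
    code: dict = field(default_factory=dict)

    @property
    def q(self) -> int:
        return len(self.ids) - 1

    def __len__(self) -> int:
        return self.q

    def animals(self):
        """Codes 1..q in pedigree (topological) order."""
        return range(1, self.q + 1)

    def to_frame(self) -> pd.DataFrame:
        idx = np.arange(1, self.q + 1)
        return pd.DataFrame(
            {
                "animal": self.ids[1:],
                "sire": [self.ids[s] if s else "0" for s in self.sire[1:]],
                "dam": [self.ids[d] if d else "0" for d in self.dam[1:]],
                "breed_a": self.declared_f[1:],
                "sire_a": self.declared_sire_f[1:],
                "dam_a": self.declared_dam_f[1:],
                "sex": self.sex[1:],
                "label": self.label[1:],
            },
            index=idx,
        )


@dataclass
class BreedComposition:
    """Expected breed-gene proportions per animal.

    ``f`` has shape (q+1, 2) with columns (f_A, f_B) summing to one.
    ``parent_f_a`` holds the breed-A fraction of each animal's sire and dam
    (declared values for base/phantom parents); ``seg_coeff`` is the
    coefficient s_i of the segregation variance in the Mendelian-sampling
    variance of animal i, s_i = 2(f_A(s)f_B(s) + f_A(d)f_B(d)).
    """

    f: np.ndarray
    parent_f_a: np.ndarray   # shape (q+1, 2): [sire_f_a, dam_f_a]
    seg_coeff: np.ndarray    # shape (q+1,)

    @property
    def f_a(self) -> np.ndarray:
        return self.f[:, 0]

    @property
    def f_b(self) -> np.ndarray:
        return self.f[:, 1]


@dataclass
class CrossCovariates:
    """Hill-style crossbreeding regressors, one row per animal (q+1,).

    direct_breed is the animal's own f_A, direct_heterosis the probability
    that a random locus carries one A and one B allele; the maternal
    columns are the same quantities for the dam (declared values when the
    dam is a phantom base animal).
    """

    direct_breed: np.ndarray
    direct_heterosis: np.ndarray
    maternal_breed: np.ndarray
    maternal_heterosis: np.ndarray


def _as_records(frame: pd.DataFrame) -> list[PedigreeRecord]:
    cols = {c.lower(): c for c in frame.columns}
    for need in ("animal", "sire", "dam"):
        if need not in cols:
            raise PedigreeError(f"pedigree file lacks required column '{need}'")

    def get(row, name, default=None):
        if name not in cols:
            return default
        v = row[cols[name]]
        if pd.isna(v):
            return default
        return v

    recs = []
    for _, row in frame.iterrows():
        recs.append(
            PedigreeRecord(
                animal=str(row[cols["animal"]]),
                sire=str(get(row, "sire", "")),
                dam=str(get(row, "dam", "")),
                f_a=get(row, "breed_a"),
                sire_f_a=get(row, "sire_a"),
                dam_f_a=get(row, "dam_a"),
                sex=str(get(row, "sex", "")),
                label=str(get(row, "label", "")),
            )
        )
    return recs


def read_pedigree(path, sep=",") -> Pedigree:
    """Read a delimited pedigree file (columns animal,sire,dam[,breed_a,...]).

    "0", "" and NA all denote an unknown parent.  Rows may appear in any
    order; the result is topologically sorted.
    """
    frame = pd.read_csv(path, sep=sep, dtype=str)
    num_cols = [c for c in frame.columns if c.lower() in ("breed_a", "sire_a", "dam_a")]
    for c in num_cols:
        frame[c] = pd.to_numeric(frame[c], errors="coerce")
    return from_records(_as_records(frame))


def from_records(records: list[PedigreeRecord]) -> Pedigree:
    """Build a topologically ordered :class:`Pedigree` from raw records."""
    seen = set()
    for r in records:
        if r.animal in ("", "0"):
            raise PedigreeError("animal id may not be empty or '0'")
        if r.animal in seen:
            raise PedigreeError(f"duplicate animal id {r.animal!r}")
        seen.add(r.animal)

    by_id = {r.animal: r for r in records}

    def norm(parent):
        return "" if parent in ("", "0", "nan", "None") else parent

    # Parents referenced but never listed are refused: their fractions
    # would have to be invented silently.
    for r in records:
        for p in (norm(r.sire), norm(r.dam)):
            if p and p not in by_id:
                raise PedigreeError(
                    f"parent {p!r} of {r.animal!r} has no pedigree row; add it "
                    "(with breed_a if it is a base animal) or mark it unknown"
                )

    # Kahn topological sort, stable in input order.
    order, ready, n_parents, children = [], [], {}, {}
    for r in records:
        s, d = norm(r.sire), norm(r.dam)
        n_parents[r.animal] = (s != "") + (d != "")
        for p in (s, d):
            if p:
                children.setdefault(p, []).append(r.animal)
        if n_parents[r.animal] == 0:
            ready.append(r.animal)
    while ready:
        a = ready.pop(0)
        order.append(a)
        for c in children.get(a, []):
            n_parents[c] -= 1
            if n_parents[c] == 0:
                ready.append(c)
    if len(order) != len(records):
        cyc = sorted(set(by_id) - set(order))
        raise PedigreeError(f"pedigree contains a cycle involving {cyc[:5]}")

    q = len(order)
    code = {a: i for i, a in enumerate(order, start=1)}
    ids = np.empty(q + 1, dtype=object)
    ids[0] = ""
    sire = np.zeros(q + 1, dtype=np.int64)
    dam = np.zeros(q + 1, dtype=np.int64)
    is_base = np.zeros(q + 1, dtype=bool)
    decl_f = np.full(q + 1, np.nan)
    decl_sf = np.full(q + 1, np.nan)
    decl_df = np.full(q + 1, np.nan)
    sex = np.empty(q + 1, dtype=object)
    label = np.empty(q + 1, dtype=object)
    sex[0] = label[0] = ""
    for a in order:
        r = by_id[a]
        i = code[a]
        ids[i] = a
        s, d = norm(r.sire), norm(r.dam)
        sire[i] = code[s] if s else UNKNOWN
        dam[i] = code[d] if d else UNKNOWN
        is_base[i] = sire[i] == UNKNOWN and dam[i] == UNKNOWN
        if r.f_a is not None:
            if not (0.0 <= r.f_a <= 1.0):
                raise PedigreeError(f"breed_a of {a!r} outside [0, 1]")
            decl_f[i] = r.f_a
        decl_sf[i] = np.nan if r.sire_f_a is None else r.sire_f_a
        decl_df[i] = np.nan if r.dam_f_a is None else r.dam_f_a
        sex[i] = r.sex
        label[i] = r.label
    return Pedigree(ids, sire, dam, is_base, decl_f, decl_sf, decl_df, sex, label, code)


def compute_breed_fractions(ped: Pedigree) -> BreedComposition:
    """Expected breed proportions by the parent-average recursion.

    Base animals keep their declared fractions (purebred base animals may
    omit them only if declared via breed_a = 0 or 1; a missing declaration
    raises).  An animal with exactly one known parent uses its own
    ``breed_a`` declaration as the fraction of the phantom base parent.
    """
    q = ped.q
    f_a = np.full(q + 1, np.nan)
    pf = np.full((q + 1, 2), np.nan)
    for i in ped.animals():
        s, d = ped.sire[i], ped.dam[i]
        if ped.is_base[i]:
            if np.isnan(ped.declared_f[i]):
                raise MissingBreedFractionError(
                    f"base animal {ped.ids[i]!r} has no declared breed_a fraction"
                )
            f_a[i] = ped.declared_f[i]
            # Parental fractions of a base animal: declared, else purebred
            # parents when the animal itself is purebred.
            for k, decl in ((0, ped.declared_sire_f[i]), (1, ped.declared_dam_f[i])):
                if not np.isnan(decl):
                    pf[i, k] = decl
                elif f_a[i] in (0.0, 1.0):
                    pf[i, k] = f_a[i]
                else:
                    raise MissingBreedFractionError(
                        f"crossbred base animal {ped.ids[i]!r} needs declared "
                        "sire_a/dam_a parental fractions"
                    )
        elif s != UNKNOWN and d != UNKNOWN:
            pf[i] = (f_a[s], f_a[d])
            f_a[i] = 0.5 * (f_a[s] + f_a[d])
        else:
            # Exactly one known parent: phantom base parent with declared f.
            if np.isnan(ped.declared_f[i]):
                raise MissingBreedFractionError(
                    f"animal {ped.ids[i]!r} has one unknown parent; declare the "
                    "phantom parent's fraction in its breed_a column"
                )
            phantom = ped.declared_f[i]
            known = f_a[s] if s != UNKNOWN else f_a[d]
            pf[i] = (f_a[s], phantom) if s != UNKNOWN else (phantom, f_a[d])
            f_a[i] = 0.5 * (known + phantom)
    f = np.column_stack([f_a, 1.0 - f_a])
    f[0] = np.nan
    seg = 2.0 * (pf[:, 0] * (1.0 - pf[:, 0]) + pf[:, 1] * (1.0 - pf[:, 1]))
    seg[0] = 0.0
    return BreedComposition(f=f, parent_f_a=pf, seg_coeff=seg)


def _own_heterosis(pf_row: np.ndarray) -> float:
    """P(one A and one B allele) given parental breed-A fractions."""
    fs, fd = pf_row
    return fs * (1.0 - fd) + (1.0 - fs) * fd


def compute_cross_covariates(ped: Pedigree, bc: BreedComposition) -> CrossCovariates:
    """Breed and heterosis regressors for direct and maternal mean effects.

    Maternal covariates are the dam's direct covariates.  For a phantom dam
    (unknown in the pedigree) the breed covariate is the declared phantom
    fraction and the heterosis covariate assumes random union of gametes
    within the phantom's breed group, 2 f_A f_B (zero for purebreds).
    """
    q = ped.q
    direct_b = bc.f_a.copy()
    direct_h = np.zeros(q + 1)
    maternal_b = np.zeros(q + 1)
    maternal_h = np.zeros(q + 1)
    for i in ped.animals():
        direct_h[i] = _own_heterosis(bc.parent_f_a[i])
        d = ped.dam[i]
        if d != UNKNOWN:
            maternal_b[i] = bc.f_a[d]
            maternal_h[i] = _own_heterosis(bc.parent_f_a[d])
        else:
            fd = bc.parent_f_a[i, 1]
            maternal_b[i] = fd
            maternal_h[i] = 2.0 * fd * (1.0 - fd)
    direct_b[0] = 0.0
    return CrossCovariates(direct_b, direct_h, maternal_b, maternal_h)
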