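"""Theoretical lipid mass database.

Enumerates lipid species at sum-composition level (class + total acyl
carbons : total double bonds), derives elemental formulas from per-class
backbone rules, computes monoisotopic masses and adduct m/z values, and
supports exact-mass queries within a ppm window.

Species are named in the field's shorthand, e.g. ``PC 34:1``,
``SM d34:1``, ``TG 52:2``.  Chain-annotated names such as
``PC 16:0_20:3`` or ``SM d18:1/22:0`` are parsed by summing the chains
into a total composition; individual chains are never resolved.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ElementComposition",
    "Adduct",
    "LipidClass",
    "LipidSpecies",
    "TheoreticalIon",
    "LipidDatabase",
    "ADDUCTS",
    "LIPID_CLASSES",
    "monoisotopic_mass",
    "composition_for",
    "build_database",
    "ppm_error",
    "parse_name",
]

# IUPAC 2021 monoisotopic atomic masses (Da)
ELEMENT_MASSES = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
}
ELECTRON_MASS = 0.00054857990
PROTON_MASS = 1.00727646688


class UnknownClassError(ValueError):
    """Lipid class code not in the configured registry."""


class CompositionRangeError(ValueError):
    """(C, D) outside the configured range for the class."""


class DatabaseConfigError(ValueError):
    """Database build parameters produce an empty or invalid enumeration."""


@dataclass(frozen=True)
class ElementComposition:
    """Elemental composition over C, H, N, O, P with non-negative counts."""

    c: int = 0
    h: int = 0
    n: int = 0
    o: int = 0
    p: int = 0

    def __post_init__(self) -> None:
        for el in ("c", "h", "n", "o", "p"):
            v = getattr(self, el)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"element count {el}={v!r} must be a non-negative integer")

    def __add__(self, other: "ElementComposition") -> "ElementComposition":
        return ElementComposition(
            self.c + other.c, self.h + other.h, self.n + other.n,
            self.o + other.o, self.p + other.p,
        )

    def __sub__(self, other: "ElementComposition") -> "ElementComposition":
        return ElementComposition(
            self.c - other.c, self.h - other.h, self.n - other.n,
            self.o - other.o, self.p - other.p,
        )

    @property
    def formula(self) -> str:
        """Hill-order formula string, e.g. ``C42H82NO8P``."""
        parts = []
        for sym, cnt in (("C", self.c), ("H", self.h), ("N", self.n),
                         ("O", self.o), ("P", self.p)):
            if cnt == 0:
                continue
            parts.append(sym if cnt == 1 else f"{sym}{cnt}")
        return "".join(parts)


def monoisotopic_mass(comp: ElementComposition) -> float:
    """Monoisotopic mass in Da of a neutral composition (empty -> 0.0)."""
    return (
        comp.c * ELEMENT_MASSES["C"]
        + comp.h * ELEMENT_MASSES["H"]
        + comp.n * ELEMENT_MASSES["N"]
        + comp.o * ELEMENT_MASSES["O"]
        + comp.p * ELEMENT_MASSES["P"]
    )


@dataclass(frozen=True)
class Adduct:
    """An ESI ion form: name, polarity, mass delta (Da) and charge."""

    name: str
    polarity: str  # 'pos' | 'neg'
    delta: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.polarity not in ("pos", "neg"):
            raise ValueError(f"polarity must be 'pos' or 'neg', got {self.polarity!r}")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if abs(self.delta) >= 100:
            raise ValueError("adduct mass delta out of plausible range")


# Singly charged ESI adducts consistent with an ammonium-formate mobile phase.
ADDUCTS: dict[str, Adduct] = {
    a.name: a
    for a in (
        Adduct("[M+H]+", "pos", PROTON_MASS),
        Adduct("[M+NH4]+", "pos", 18.03382555318),
        Adduct("[M+Na]+", "pos", 22.989220701),
        Adduct("[M-H]-", "neg", -PROTON_MASS),
        Adduct("[M+HCOO]-", "neg", 44.99820285117),
    )
}


@dataclass(frozen=True)
class LipidClass:
    """A lipid class with its sum-composition backbone rule.

    The elemental composition of a species with total acyl carbons C and
    total double bonds D is ``C(C+c0) H(2C-2D+h0) N(n0) O(o0) P(p0)``;
    the class-specific offsets encode the head group and backbone.
    """

    code: str
    n_chains: int
    c0: int
    h0: int
    n0: int
    o0: int
    p0: int
    c_range: tuple[int, int]
    d_range: tuple[int, int]
    adducts_pos: tuple[str, ...]
    adducts_neg: tuple[str, ...]
    d_prefix: bool = False  # sphingoid classes rendered in d-notation

    def adducts(self, polarity: str) -> tuple[str, ...]:
        return self.adducts_pos if polarity == "pos" else self.adducts_neg


def _cls(code, n_chains, c0, h0, n0, o0, p0, c_range, d_range,
         pos, neg, d_prefix=False) -> LipidClass:
    return LipidClass(code, n_chains, c0, h0, n0, o0, p0, c_range, d_range,
                      tuple(pos), tuple(neg), d_prefix)


# Class registry.  C ranges cover the species reported in plasma and
# tissue lipidomes of this kind; even total carbon counts only.
LIPID_CLASSES: dict[str, LipidClass] = {
    c.code: c
    for c in (
        _cls("PC", 2, 8, 16, 1, 8, 1, (24, 48), (0, 12), ["[M+H]+", "[M+Na]+"], ["[M+HCOO]-"]),
        _cls("LPC", 1, 8, 18, 1, 7, 1, (12, 26), (0, 6), ["[M+H]+", "[M+Na]+"], ["[M+HCOO]-"]),
        _cls("PE", 2, 5, 10, 1, 8, 1, (24, 48), (0, 12), ["[M+H]+", "[M+Na]+"], ["[M-H]-"]),
        _cls("PS", 2, 6, 10, 1, 10, 1, (24, 48), (0, 12), ["[M+H]+", "[M+Na]+"], ["[M-H]-"]),
        _cls("PA", 2, 3, 5, 0, 8, 1, (24, 48), (0, 12), ["[M+H]+", "[M+Na]+"], ["[M-H]-"]),
        _cls("PC-O", 2, 8, 18, 1, 7, 1, (24, 48), (0, 12), ["[M+H]+", "[M+Na]+"], ["[M+HCOO]-"]),
        _cls("PE-O", 2, 5, 12, 1, 7, 1, (24, 48), (0, 12), ["[M+H]+", "[M+Na]+"], ["[M-H]-"]),
        _cls("SM", 2, 5, 13, 2, 6, 1, (24, 48), (0, 6), ["[M+H]+", "[M+Na]+"], ["[M+HCOO]-"], True),
        _cls("Cer", 2, 0, 1, 1, 3, 0, (24, 48), (0, 6), ["[M+H]+", "[M+Na]+"], ["[M-H]-"], True),
        _cls("TG", 3, 3, 2, 0, 6, 0, (30, 70), (0, 15), ["[M+NH4]+", "[M+Na]+"], []),
        _cls("CE", 1, 27, 44, 0, 2, 0, (12, 24), (0, 6), ["[M+NH4]+", "[M+Na]+"], []),
        _cls("FA", 1, 0, 0, 0, 2, 0, (12, 26), (0, 6), [], ["[M-H]-"]),
    )
}


def composition_for(class_code: str, c: int, d: int) -> ElementComposition:
    """Elemental composition of a species from its class backbone rule.

    Parameters are the class code (e.g. ``"PC"``), total acyl carbons and
    total double bonds.  Raises :class:`UnknownClassError` for an
    unregistered class and :class:`CompositionRangeError` when (C, D) is
    outside the class's configured range or violates D <= C/2.
    """
    if class_code not in LIPID_CLASSES:
        raise UnknownClassError(f"unknown lipid class {class_code!r}")
    lc = LIPID_CLASSES[class_code]
    if not (lc.c_range[0] <= c <= lc.c_range[1]):
        raise CompositionRangeError(
            f"{class_code}: total carbons {c} outside {lc.c_range}")
    if not (lc.d_range[0] <= d <= lc.d_range[1]) or d > c // 2:
        raise CompositionRangeError(
            f"{class_code}: double bonds {d} outside range for C={c}")
    return ElementComposition(
        c=c + lc.c0, h=2 * c - 2 * d + lc.h0, n=lc.n0, o=lc.o0, p=lc.p0)


_NAME_RE = re.compile(
    r"^\s*(?P<cls>[A-Za-z]+(?:-O)?)\s+(?P<chains>[dO]?-?\d+:\d+(?:[_/]d?\d+:\d+)*)\s*$"
)


def parse_name(name: str) -> tuple[str, int, int]:
    """Parse a lipid shorthand name into (class code, total C, total D).

    Accepts total-composition names (``PC 34:1``, ``SM d34:1``) and
    chain-annotated names (``PC 16:0_20:3``, ``TG 18:0_18:1_18:1``,
    ``SM d18:1/22:0``), summing chains into totals.
    """
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"cannot parse lipid name {name!r}")
    cls = m.group("cls")
    if cls not in LIPID_CLASSES:
        raise UnknownClassError(f"unknown lipid class in name {name!r}")
    chains = re.split(r"[_/]", m.group("chains"))
    c_tot = d_tot = 0
    for ch in chains:
        ch = ch.lstrip("dO-")
        cc, dd = ch.split(":")
        c_tot += int(cc)
        d_tot += int(dd)
    return cls, c_tot, d_tot


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid at sum-composition level with formula and monoisotopic mass."""

    class_code: str
    c: int
    d: int
    composition: ElementComposition = field(compare=False)
    mass: float = field(compare=False)

    @classmethod
    def create(cls, class_code: str, c: int, d: int) -> "LipidSpecies":
        comp = composition_for(class_code, c, d)
        return cls(class_code, c, d, comp, monoisotopic_mass(comp))

    @classmethod
    def from_name(cls, name: str) -> "LipidSpecies":
        return cls.create(*parse_name(name))

    @property
    def name(self) -> str:
        lc = LIPID_CLASSES[self.class_code]
        body = f"d{self.c}:{self.d}" if lc.d_prefix else f"{self.c}:{self.d}"
        return f"{self.class_code} {body}"


@dataclass(frozen=True)
class TheoreticalIon:
    """A (species, adduct) pair with its theoretical m/z."""

    species: LipidSpecies
    adduct: Adduct
    mz: float

    @classmethod
    def create(cls, species: LipidSpecies, adduct: Adduct) -> "TheoreticalIon":
        return cls(species, adduct, (species.mass + adduct.delta) / adduct.charge)

    @property
    def ion_name(self) -> str:
        return f"{self.species.name} {self.adduct.name}"


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


class LipidDatabase:
    """Theoretical ions sorted ascending by m/z, queryable by exact mass."""

    def __init__(self, ions: Sequence[TheoreticalIon], params: dict | None = None):
        seen: set[tuple] = set()
        unique = []
        for ion in ions:
            key = (ion.species.class_code, ion.species.c, ion.species.d, ion.adduct.name)
            if key in seen:
                continue
            seen.add(key)
            unique.append(ion)
        # sort by m/z; name as deterministic tie-break
        self.ions: list[TheoreticalIon] = sorted(unique, key=lambda i: (i.mz, i.ion_name))
        self._mz = np.array([i.mz for i in self.ions])
        self.params = dict(params or {})

    def __len__(self) -> int:
        return len(self.ions)

    def query(self, mz: float, tol_ppm: float = 10.0) -> list[tuple[TheoreticalIon, float]]:
        """All ions within ``tol_ppm`` of ``mz`` (inclusive), by |ppm| then name."""
        if len(self.ions) == 0:
            raise DatabaseConfigError("query on empty database")
        if tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")
        half = mz * tol_ppm * 1e-6
        lo = np.searchsorted(self._mz, mz - half, side="left")
        hi = np.searchsorted(self._mz, mz + half, side="right")
        out = []
        for ion in self.ions[lo:hi]:
            err = ppm_error(mz, ion.mz)
            if abs(err) <= tol_ppm:
                out.append((ion, err))
        out.sort(key=lambda t: (abs(t[1]), t[0].ion_name))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "name": i.species.name,
                "class": i.species.class_code,
                "C": i.species.c,
                "D": i.species.d,
                "formula": i.species.composition.formula,
                "adduct": i.adduct.name,
                "mz": i.mz,
            }
            for i in self.ions
        ]
        return pd.DataFrame(rows, columns=["name", "class", "C", "D", "formula", "adduct", "mz"])

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6f")

    def write_json(self, path) -> None:
        records = self.to_dataframe().to_dict(orient="records")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"params": self.params, "ions": records}, fh, indent=1, sort_keys=True)

    @classmethod
    def read_tsv(cls, path) -> "LipidDatabase":
        df = pd.read_csv(path, sep="\t")
        ions = [
            TheoreticalIon.create(
                LipidSpecies.create(r["class"], int(r["C"]), int(r["D"])),
                ADDUCTS[r["adduct"]],
            )
            for _, r in df.iterrows()
        ]
        return cls(ions)


def build_database(
    classes: Iterable[str] | None = None,
    polarity: str = "pos",
    c_range: tuple[int, int] | None = None,
    d_range: tuple[int, int] | None = None,
    adducts: Iterable[str] | None = None,
    mz_range: tuple[float, float] | None = None,
) -> LipidDatabase:
    """Enumerate the theoretical ion database.

    Per class, all even total carbon counts and all double-bond counts
    allowed by the class rule (intersected with ``c_range``/``d_range``
    when given) are combined with the class's adducts for ``polarity``
    (or an explicit ``adducts`` override).  ``mz_range`` restricts the
    retained ions to an instrument acquisition window.
    """
    if polarity not in ("pos", "neg"):
        raise DatabaseConfigError(f"polarity must be 'pos' or 'neg', got {polarity!r}")
    codes = list(classes) if classes is not None else sorted(LIPID_CLASSES)
    if not codes:
        raise DatabaseConfigError("empty class list")
    for code in codes:
        if code not in LIPID_CLASSES:
            raise UnknownClassError(f"unknown lipid class {code!r}")
    ions: list[TheoreticalIon] = []
    for code in sorted(set(codes)):
        lc = LIPID_CLASSES[code]
        c_lo, c_hi = lc.c_range
        if c_range is not None:
            c_lo, c_hi = max(c_lo, c_range[0]), min(c_hi, c_range[1])
        adduct_names = tuple(adducts) if adducts is not None else lc.adducts(polarity)
        adduct_objs = []
        for a in adduct_names:
            if a not in ADDUCTS:
                raise DatabaseConfigError(f"unknown adduct {a!r}")
            if ADDUCTS[a].polarity == polarity:
                adduct_objs.append(ADDUCTS[a])
        for c in range(c_lo + (c_lo % 2), c_hi + 1, 2):
            d_lo, d_hi = lc.d_range
            if d_range is not None:
                d_lo, d_hi = max(d_lo, d_range[0]), min(d_hi, d_range[1])
            for d in range(d_lo, min(d_hi, c // 2) + 1):
                sp = LipidSpecies.create(code, c, d)
                for ad in adduct_objs:
                    ion = TheoreticalIon.create(sp, ad)
                    if mz_range is None or (mz_range[0] <= ion.mz <= mz_range[1]):
                        ions.append(ion)
    if not ions:
        raise DatabaseConfigError("enumeration produced no ions; check ranges and polarity")
    params = {
        "classes": sorted(set(codes)),
        "polarity": polarity,
        "c_range": list(c_range) if c_range else None,
        "d_range": list(d_range) if d_range else None,
        "adducts": sorted(adducts) if adducts is not None else None,
        "mz_range": list(mz_range) if mz_range else None,
    }
    return LipidDatabase(ions, params)
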