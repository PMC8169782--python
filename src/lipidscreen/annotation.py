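"""Exact-mass peak annotation with class-diagnostic MS/MS confirmation.

MS1 peaks are matched against the theoretical database within a ppm
window; candidate identities can then be confirmed by the presence of
class-diagnostic fragment ions or neutral losses in an MS/MS spectrum
acquired on the same precursor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from pyteomics import mgf as _mgf

from .lipids import LipidDatabase, TheoreticalIon

__all__ = [
    "Peak",
    "Spectrum",
    "FragmentRule",
    "Annotation",
    "DEFAULT_FRAGMENT_RULES",
    "annotate_peaks",
    "confirm_with_msms",
    "resolve_ambiguity",
    "read_mgf",
    "write_mgf",
]

# Fragment/neutral-loss reference masses (Da), from elemental composition
PHOSPHOCHOLINE_FRAGMENT = 184.07332101  # C5H15NO4P+
PE_HEAD_NEUTRAL_LOSS = 141.01909437     # C2H8NO4P
CHOLESTADIENYL_FRAGMENT = 369.35157786  # C27H45+
SERINE_NEUTRAL_LOSS = 87.03202840       # C3H5NO2
WATER = 18.01056468
AMMONIA = 17.02654910


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass
class Spectrum:
    """A peak list with polarity and MS level (precursor m/z at MS2)."""

    peaks: list[Peak]
    polarity: str = "pos"
    ms_level: int = 1
    precursor_mz: float | None = None

    def __post_init__(self) -> None:
        if self.ms_level == 2 and self.precursor_mz is None:
            raise ValueError("MS2 spectrum requires a precursor m/z")
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    def has_peak(self, mz: float, tol_da: float) -> bool:
        return any(abs(p.mz - mz) <= tol_da for p in self.peaks)


@dataclass(frozen=True)
class FragmentRule:
    """A diagnostic fragment (absolute m/z) or neutral loss for a class."""

    class_code: str
    polarity: str
    fragment_mz: float | None = None
    neutral_loss: float | None = None
    tolerance: float = 0.01

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("fragment tolerance must be positive")
        if (self.fragment_mz is None) == (self.neutral_loss is None):
            raise ValueError("rule must set exactly one of fragment_mz / neutral_loss")


# Standard class-diagnostic ions under low-energy CID.
DEFAULT_FRAGMENT_RULES: tuple[FragmentRule, ...] = (
    FragmentRule("PC", "pos", fragment_mz=PHOSPHOCHOLINE_FRAGMENT),
    FragmentRule("LPC", "pos", fragment_mz=PHOSPHOCHOLINE_FRAGMENT),
    FragmentRule("SM", "pos", fragment_mz=PHOSPHOCHOLINE_FRAGMENT),
    FragmentRule("PC-O", "pos", fragment_mz=PHOSPHOCHOLINE_FRAGMENT),
    FragmentRule("PE", "pos", neutral_loss=PE_HEAD_NEUTRAL_LOSS),
    FragmentRule("PE-O", "pos", neutral_loss=PE_HEAD_NEUTRAL_LOSS),
    FragmentRule("CE", "pos", fragment_mz=CHOLESTADIENYL_FRAGMENT),
    FragmentRule("Cer", "pos", neutral_loss=WATER),
    # TG/CE ammonium adducts readily lose NH3; acyl-chain losses are not
    # usable as sum-composition-level diagnostics.
    FragmentRule("TG", "pos", neutral_loss=AMMONIA),
    FragmentRule("PS", "neg", neutral_loss=SERINE_NEUTRAL_LOSS),
)


@dataclass(frozen=True)
class Annotation:
    """A candidate identity for an observed peak."""

    peak_mz: float
    ion: TheoreticalIon
    ppm: float
    msms_confirmed: bool = False
    no_rule: bool = False

    @property
    def name(self) -> str:
        return self.ion.species.name


def annotate_peaks(
    spectrum: Spectrum, db: LipidDatabase, tol_ppm: float = 10.0
) -> list[Annotation]:
    """Annotate every MS1 peak with all database matches within ``tol_ppm``.

    Returns one :class:`Annotation` per (peak, candidate) pair; per peak,
    candidates are ordered by |ppm error|.
    """
    if spectrum.ms_level != 1:
        raise ValueError("annotate_peaks expects an MS1 spectrum")
    db_pol = db.params.get("polarity")
    if db_pol is not None and db_pol != spectrum.polarity:
        raise ValueError(
            f"polarity mismatch: spectrum {spectrum.polarity!r} vs database {db_pol!r}")
    out: list[Annotation] = []
    for peak in spectrum.peaks:
        for ion, err in db.query(peak.mz, tol_ppm):
            out.append(Annotation(peak.mz, ion, err))
    return out


def confirm_with_msms(
    ann: Annotation,
    msms: Spectrum,
    rules: tuple[FragmentRule, ...] = DEFAULT_FRAGMENT_RULES,
    frag_tol_da: float = 0.01,
) -> Annotation:
    """Set ``msms_confirmed`` from the class-diagnostic fragments.

    The MS/MS precursor must lie within the 3 Da isolation window of the
    annotated peak.  A class without any rule for the spectrum polarity
    is flagged ``no_rule`` and left unconfirmed.
    """
    if msms.ms_level != 2:
        raise ValueError("confirmation requires an MS2 spectrum")
    if abs(msms.precursor_mz - ann.peak_mz) > 3.0:
        raise ValueError(
            f"precursor {msms.precursor_mz:.4f} outside the 3 Da isolation "
            f"window of peak {ann.peak_mz:.4f}")
    class_rules = [
        r for r in rules
        if r.class_code == ann.ion.species.class_code and r.polarity == msms.polarity
    ]
    if not class_rules:
        return replace(ann, msms_confirmed=False, no_rule=True)
    ok = True
    for rule in class_rules:
        tol = max(rule.tolerance, frag_tol_da)
        if rule.fragment_mz is not None:
            ok &= msms.has_peak(rule.fragment_mz, tol)
        else:
            ok &= msms.has_peak(ann.peak_mz - rule.neutral_loss, tol)
    return replace(ann, msms_confirmed=ok, no_rule=False)


def resolve_ambiguity(candidates: list[Annotation]) -> Annotation:
    """Pick one identity for a peak: confirmed beats unconfirmed, then
    smaller |ppm|, then canonical name order (deterministic)."""
    if not candidates:
        raise ValueError("no candidates to resolve")
    return min(
        candidates,
        key=lambda a: (not a.msms_confirmed, abs(a.ppm), a.ion.ion_name),
    )


def read_mgf(path) -> list[Spectrum]:
    """Read MS/MS spectra from an MGF file."""
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            charge = entry["params"].get("charge")
            pol = "neg" if charge and str(charge[0]).endswith("-") else "pos"
            peaks = [
                Peak(float(mz), float(it))
                for mz, it in zip(entry["m/z array"], entry["intensity array"])
            ]
            spectra.append(
                Spectrum(
                    peaks,
                    polarity=pol,
                    ms_level=2,
                    precursor_mz=float(entry["params"]["pepmass"][0]),
                )
            )
    return spectra


def write_mgf(spectra: list[Spectrum], path) -> None:
    """Write MS2 spectra to MGF (MS1 spectra are skipped)."""
    entries = []
    for s in spectra:
        if s.ms_level != 2:
            continue
        entries.append(
            {
                "m/z array": [p.mz for p in s.peaks],
                "intensity array": [p.intensity for p in s.peaks],
                "params": {
                    "pepmass": s.precursor_mz,
                    "charge": "1+" if s.polarity == "pos" else "1-",
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")
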