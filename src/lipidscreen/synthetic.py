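"""Synthetic three-group lipidomics cohorts with planted ground truth.

Generates feature tables with the statistical structure the downstream
analysis assumes: log-normal intensities, a small set of marker features
with planted group fold-changes, pooled-QC injections with purely
analytical noise, and feature m/z values drawn from the theoretical
database with ppm-scale noise.  The planted truth is returned alongside
the table and serves as the oracle for every downstream stage.

The default design emulates a three-group case/control study of uterine
fibroids: 15 controls, 35 first-time cases (UF), 31 recurrent cases
(RUF); 267 plasma lipid features acquired in positive mode over
m/z 400-1000; 8 control-vs-UF markers and 17 UF-vs-RUF markers with
moderate effect sizes (|log2 FC| in [0.6, 1.5]) and a within-group
coefficient of variation of 0.3.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .annotation import DEFAULT_FRAGMENT_RULES, Peak, Spectrum
from .feature_table import FeatureTable, SampleInfo
from .lipids import LipidDatabase, LipidSpecies, build_database, parse_name

__all__ = [
    "PlantedMarker",
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_spectra",
    "preset_paper_design",
]

# Marker identities planted by the preset, chosen so reports read like a
# plasma lipidomics study: disease markers (present in both case groups
# vs control) and recurrence markers (recurrent cases only).
DISEASE_MARKER_NAMES = (
    "LPC 18:2", "PC 16:0_20:3", "PC 18:0_18:1", "PC 18:0_20:3",
    "SM d18:1/22:0", "SM d18:1/22:1", "SM d18:1/24:0", "TG 18:0_18:1_18:1",
)
RECURRENCE_MARKER_NAMES = (
    "CE 18:2", "CE 20:4", "PC 16:0_22:6", "PC 18:0_18:2", "SM d12:0/14:1",
    "SM d18:1/22:0", "SM d18:1/22:1", "SM d18:1/24:0", "SM d18:1/24:1",
    "SM d18:2/16:0", "SM d18:2/24:1", "TG 14:1_18:1_18:2",
    "TG 16:0_16:1_18:2", "TG 16:0_18:1_18:2", "TG 16:1_18:0_18:1",
    "TG 16:1_18:0_18:3", "TG 18:1_18:2_18:3",
)


class PlantedMarker(BaseModel):
    feature_index: int = Field(ge=0)
    groups: tuple[str, ...]          # groups carrying the fold change
    log2_fc: float
    name: str | None = None          # preferred lipid identity


class SimulationConfig(BaseModel):
    """Generator parameters; the seed is mandatory."""

    group_sizes: dict[str, int] = {"control": 15, "UF": 35, "RUF": 31}
    n_features: int = Field(default=267, ge=1)
    markers: list[PlantedMarker] = []
    base_log10_mean: float = 5.0     # typical raw intensity ~1e5
    base_log10_sd: float = 0.5       # feature-to-feature spread
    cv: float = Field(default=0.3, gt=0)      # within-group CV, natural scale
    qc_cv: float = Field(default=0.1, gt=0)   # analytical CV of pooled QC
    ppm_sigma: float = Field(default=2.0, ge=0)
    polarity: str = "pos"
    mz_range: tuple[float, float] = (400.0, 1000.0)
    matrix: str = "plasma"
    n_qc: int = Field(default=5, ge=0)
    seed: int

    @field_validator("group_sizes")
    @classmethod
    def _sizes(cls, v):
        bad = [g for g, n in v.items() if n < 2]
        if bad:
            raise ValueError(f"groups with fewer than 2 samples: {bad}")
        return v

    @model_validator(mode="after")
    def _markers_in_range(self):
        bad = [m.feature_index for m in self.markers
               if m.feature_index >= self.n_features]
        if bad:
            raise ValueError(f"marker feature indices out of range: {bad}")
        groups = set(self.group_sizes)
        for m in self.markers:
            missing = set(m.groups) - groups
            if missing:
                raise ValueError(f"marker groups not in design: {sorted(missing)}")
        return self

    @property
    def log10_noise_sd(self) -> float:
        """Within-group SD on the log10 scale implied by the natural-scale CV."""
        return math.sqrt(math.log(1 + self.cv**2)) / math.log(10)

    @property
    def qc_log10_noise_sd(self) -> float:
        return math.sqrt(math.log(1 + self.qc_cv**2)) / math.log(10)


@dataclass
class GroundTruth:
    """The planted truth: marker effects and true lipid identity per feature."""

    markers: dict[str, dict] = field(default_factory=dict)
    identities: dict[str, dict] = field(default_factory=dict)
    config: SimulationConfig | None = None

    def marker_ids(self, group_pair: tuple[str, str] | None = None) -> list[str]:
        """Feature ids whose planted effect separates the given pair
        (effect present in exactly one of the two groups)."""
        if group_pair is None:
            return sorted(self.markers)
        a, b = group_pair
        out = []
        for fid, info in self.markers.items():
            g = set(info["groups"])
            if (a in g) != (b in g):
                out.append(fid)
        return sorted(out)

    def to_json(self, path) -> None:
        payload = {
            "markers": self.markers,
            "identities": self.identities,
            "config": None if self.config is None else self.config.model_dump(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        cfg = None if d.get("config") is None else SimulationConfig(**d["config"])
        return cls(markers=d["markers"], identities=d["identities"], config=cfg)


def preset_paper_design(seed: int = 7) -> SimulationConfig:
    """The documented default three-group plasma design.

    15/35/31 samples, 267 features, 8 disease markers (fold change in
    both case groups) and 17 recurrence markers (fold change in the
    recurrent group only), |log2 FC| in [0.6, 1.5] with alternating
    signs, CV 0.3, positive mode m/z 400-1000.
    """
    markers: list[PlantedMarker] = []
    fcs = np.linspace(1.5, 0.6, len(DISEASE_MARKER_NAMES))
    for i, (name, fc) in enumerate(zip(DISEASE_MARKER_NAMES, fcs)):
        markers.append(PlantedMarker(
            feature_index=i, groups=("UF", "RUF"),
            log2_fc=float(fc if i % 2 == 0 else -fc), name=name))
    fcs = np.linspace(1.5, 0.6, len(RECURRENCE_MARKER_NAMES))
    for i, (name, fc) in enumerate(zip(RECURRENCE_MARKER_NAMES, fcs)):
        markers.append(PlantedMarker(
            feature_index=len(DISEASE_MARKER_NAMES) + i, groups=("RUF",),
            log2_fc=float(fc if i % 2 == 0 else -fc), name=name))
    return SimulationConfig(markers=markers, seed=seed)


def _feature_identities(
    config: SimulationConfig, db: LipidDatabase, rng: np.random.Generator
) -> list[dict]:
    """Assign a true lipid ion to every feature.

    Marker features get their preferred named species (first allowed
    adduct); the remaining features draw distinct ions from the
    database at random.
    """
    by_index = {m.feature_index: m for m in config.markers}
    ions_by_species: dict[tuple, list] = {}
    for ion in db.ions:
        key = (ion.species.class_code, ion.species.c, ion.species.d)
        ions_by_species.setdefault(key, []).append(ion)

    identities: list[dict | None] = [None] * config.n_features
    used = set()
    for idx, marker in by_index.items():
        name = marker.name
        if name is None:
            continue
        key = parse_name(name)
        candidates = ions_by_species.get(key)
        if not candidates:
            sp = LipidSpecies.create(*key)
            identities[idx] = {"name": name, "sum_name": sp.name, "adduct": None,
                               "class": key[0], "theoretical_mz": None,
                               "mass": sp.mass}
            continue
        ion = candidates[0]
        used.add(id(ion))
        identities[idx] = {
            "name": name, "sum_name": ion.species.name,
            "adduct": ion.adduct.name, "class": ion.species.class_code,
            "theoretical_mz": ion.mz, "mass": ion.species.mass,
        }
    pool = [i for i in db.ions if id(i) not in used]
    n_need = sum(1 for x in identities if x is None)
    if n_need > len(pool):
        raise ValueError(
            f"database too small: {len(pool)} ions for {n_need} features")
    chosen = rng.choice(len(pool), size=n_need, replace=False)
    it = iter(chosen)
    for i in range(config.n_features):
        if identities[i] is None:
            ion = pool[int(next(it))]
            identities[i] = {
                "name": ion.species.name, "sum_name": ion.species.name,
                "adduct": ion.adduct.name, "class": ion.species.class_code,
                "theoretical_mz": ion.mz, "mass": ion.species.mass,
            }
    return identities


def simulate_cohort(
    config: SimulationConfig, db: LipidDatabase | None = None
) -> tuple[FeatureTable, GroundTruth]:
    """Draw one cohort: intensity(f, s) = 10^N(mu_f, sigma) * 2^FC(f, g).

    mu_f is drawn once per feature; sigma is the log10 SD implied by the
    configured CV; the fold change applies in the marker's affected
    groups.  QC samples are repeated injections of the pooled sample:
    their expectation is the pooled mean log-intensity and their noise
    the (smaller) analytical CV.  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed)
    if db is None:
        db = build_database(polarity=config.polarity, mz_range=config.mz_range)

    identities = _feature_identities(config, db, rng)
    nf = config.n_features
    mu = rng.normal(config.base_log10_mean, config.base_log10_sd, size=nf)
    sigma = config.log10_noise_sd

    # per-feature, per-group log2 fold change
    groups = list(config.group_sizes)
    fc = {g: np.zeros(nf) for g in groups}
    truth_markers: dict[str, dict] = {}
    feature_ids = [f"F{i + 1:04d}" for i in range(nf)]
    for m in config.markers:
        for g in m.groups:
            fc[g][m.feature_index] += m.log2_fc
        truth_markers[feature_ids[m.feature_index]] = {
            "log2_fc": m.log2_fc,
            "groups": list(m.groups),
            "name": m.name or identities[m.feature_index]["name"],
        }

    cols, infos = [], []
    data = []
    log2_to_log10 = math.log10(2.0)
    for g in groups:
        n_g = config.group_sizes[g]
        shift = fc[g] * log2_to_log10
        block = rng.normal(mu[:, None] + shift[:, None], sigma, size=(nf, n_g))
        data.append(block)
        prefix = {"control": "C", "UF": "UF", "RUF": "RUF"}.get(g, g)
        for j in range(n_g):
            sid = f"{prefix}{j + 1:02d}"
            cols.append(sid)
            infos.append(SampleInfo(sid, g, config.matrix, False))
    # pooled-QC expectation: weighted mean of group means per feature
    n_total = sum(config.group_sizes.values())
    pooled = mu + sum(
        config.group_sizes[g] * fc[g] for g in groups) * log2_to_log10 / n_total
    if config.n_qc:
        block = rng.normal(pooled[:, None], config.qc_log10_noise_sd,
                           size=(nf, config.n_qc))
        data.append(block)
        for j in range(config.n_qc):
            sid = f"QC{j + 1:02d}"
            cols.append(sid)
            infos.append(SampleInfo(sid, groups[0], config.matrix, True))

    intensities = pd.DataFrame(
        np.power(10.0, np.concatenate(data, axis=1)),
        index=pd.Index(feature_ids, name="feature_id"), columns=cols)

    mz_obs = np.array([
        ident["theoretical_mz"] if ident["theoretical_mz"] is not None
        else ident["mass"]
        for ident in identities
    ])
    mz_obs = mz_obs * (1.0 + rng.normal(0.0, config.ppm_sigma * 1e-6, size=nf))
    features = pd.DataFrame(
        {"mz": mz_obs, "annotation": [ident["name"] for ident in identities]},
        index=intensities.index)

    table = FeatureTable(intensities, features, infos)
    truth = GroundTruth(
        markers=truth_markers,
        identities={fid: ident for fid, ident in zip(feature_ids, identities)},
        config=config,
    )
    return table, truth


def simulate_spectra(
    truth: GroundTruth,
    db: LipidDatabase,
    ppm_sigma: float = 2.0,
    seed: int | None = None,
) -> list[Spectrum]:
    """One MS1 spectrum over all true ions plus one MS/MS per species.

    MS1 peaks sit at the theoretical m/z perturbed by Gaussian ppm noise
    and are restricted to the database's m/z window; each MS/MS spectrum
    contains the class-diagnostic fragments so that annotation can be
    confirmed downstream.
    """
    cfg_seed = truth.config.seed if truth.config is not None else 0
    rng = np.random.default_rng(seed if seed is not None else cfg_seed)
    polarity = db.params.get("polarity", "pos")
    mz_range = db.params.get("mz_range")

    missing = [
        i["sum_name"] for i in truth.identities.values()
        if i["theoretical_mz"] is None
    ]
    if missing:
        raise ValueError(f"species outside the database: {sorted(set(missing))}")

    ms1_peaks = []
    ms2: list[Spectrum] = []
    seen = set()
    for ident in truth.identities.values():
        if ident["sum_name"] in seen:
            continue
        seen.add(ident["sum_name"])
        mz = ident["theoretical_mz"] * (1.0 + rng.normal(0.0, ppm_sigma * 1e-6))
        if mz_range and not (mz_range[0] <= mz <= mz_range[1]):
            continue
        ms1_peaks.append(Peak(mz, 1.0e5))
        frags = []
        for rule in DEFAULT_FRAGMENT_RULES:
            if rule.class_code != ident["class"] or rule.polarity != polarity:
                continue
            fmz = rule.fragment_mz if rule.fragment_mz is not None else mz - rule.neutral_loss
            if fmz > 0:
                frags.append(Peak(fmz, 1.0e4))
        if frags:
            ms2.append(Spectrum(frags, polarity=polarity, ms_level=2, precursor_mz=mz))
    return [Spectrum(ms1_peaks, polarity=polarity, ms_level=1)] + ms2
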