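"""Synthetic cohort generator: determinism, planted effects, null features."""

import numpy as np
import pytest
from pydantic import ValidationError
from scipy import stats as scipy_stats

from lipidscreen.synthetic import (
    DISEASE_MARKER_NAMES,
    RECURRENCE_MARKER_NAMES,
    PlantedMarker,
    SimulationConfig,
    preset_paper_design,
    simulate_cohort,
)


def test_same_seed_identical_tables():
    config = preset_paper_design(seed=31)
    t1, g1 = simulate_cohort(config)
    t2, g2 = simulate_cohort(config)
    assert t1.intensities.equals(t2.intensities)
    assert t1.features.equals(t2.features)
    assert g1.markers == g2.markers


def test_different_seed_differs():
    t1, _ = simulate_cohort(preset_paper_design(seed=1))
    t2, _ = simulate_cohort(preset_paper_design(seed=2))
    assert not t1.intensities.equals(t2.intensities)


def test_noise_free_fold_change_exact():
    """With vanishing CV a planted log2 FC of 1 gives a group ratio of
    exactly 2 for that feature."""
    config = SimulationConfig(
        group_sizes={"control": 4, "UF": 4, "RUF": 4},
        n_features=10,
        markers=[PlantedMarker(feature_index=0, groups=("UF",), log2_fc=1.0)],
        cv=1e-12, ppm_sigma=0.0, n_qc=0, seed=1)
    table, _ = simulate_cohort(config)
    row = table.intensities.iloc[0]
    ctrl = row[table.group_columns("control")].mean()
    uf = row[table.group_columns("UF")].mean()
    assert uf / ctrl == pytest.approx(2.0, rel=1e-6)
    # non-marker feature: identical across groups
    row5 = table.intensities.iloc[5]
    assert row5[table.group_columns("UF")].mean() == pytest.approx(
        row5[table.group_columns("control")].mean(), rel=1e-6)


def test_lognormal_mean_ratio_within_ci():
    """At CV 0.3 and n = 200/group the sample mean ratio of a log2 FC = 1
    marker falls inside the analytic log-normal 95% CI around 2."""
    config = SimulationConfig(
        group_sizes={"control": 200, "UF": 200, "RUF": 2},
        n_features=5,
        markers=[PlantedMarker(feature_index=0, groups=("UF",), log2_fc=1.0)],
        cv=0.3, n_qc=0, seed=77)
    table, _ = simulate_cohort(config)
    row = table.intensities.iloc[0]
    a = row[table.group_columns("control")].to_numpy()
    b = row[table.group_columns("UF")].to_numpy()
    ratio = b.mean() / a.mean()
    # SE of a log-normal mean: mean * cv / sqrt(n); propagate to the ratio
    se = np.sqrt(2) * 0.3 / np.sqrt(200) * 2.0
    assert abs(ratio - 2.0) < 1.96 * se * 1.5


def test_null_features_identical_distribution():
    """Pooled draws of a non-marker feature from different groups pass a
    two-sample KS test at alpha = 0.001."""
    config = SimulationConfig(
        group_sizes={"control": 400, "UF": 400, "RUF": 2},
        n_features=25, markers=[], n_qc=0, seed=5)
    table, _ = simulate_cohort(config)
    a = np.log10(table.intensities[table.group_columns("control")].to_numpy()).ravel()
    b = np.log10(table.intensities[table.group_columns("UF")].to_numpy()).ravel()
    # compare within matching features to avoid mixing feature means
    stat, p = scipy_stats.ks_2samp(
        a - np.log10(table.intensities[table.group_columns("control")]).mean(axis=1).to_numpy().repeat(400),
        b - np.log10(table.intensities[table.group_columns("UF")]).mean(axis=1).to_numpy().repeat(400),
    )
    assert p > 0.001


def test_qc_samples_have_low_variability():
    table, _ = simulate_cohort(preset_paper_design(seed=3))
    qc_cols = [s.sample_id for s in table.samples if s.is_qc]
    assert len(qc_cols) == 5
    qc = table.intensities[qc_cols]
    rsd = (qc.std(axis=1, ddof=1) / qc.mean(axis=1))
    assert rsd.median() < 0.15  # analytical CV 0.1 << biological CV 0.3


def test_preset_counts_and_validity():
    config = preset_paper_design(seed=1)
    assert config.group_sizes == {"control": 15, "UF": 35, "RUF": 31}
    assert config.n_features == 267
    disease = [m for m in config.markers if set(m.groups) == {"UF", "RUF"}]
    recurrence = [m for m in config.markers if set(m.groups) == {"RUF"}]
    assert len(disease) == len(DISEASE_MARKER_NAMES) == 8
    assert len(recurrence) == len(RECURRENCE_MARKER_NAMES) == 17
    assert all(0.6 <= abs(m.log2_fc) <= 1.5 for m in config.markers)


def test_truth_marker_pairs():
    _, truth = simulate_cohort(preset_paper_design(seed=2))
    assert len(truth.marker_ids(("control", "UF"))) == 8
    assert len(truth.marker_ids(("UF", "RUF"))) == 17
    assert len(truth.marker_ids(("control", "RUF"))) == 25


def test_feature_mz_near_theoretical():
    table, truth = simulate_cohort(preset_paper_design(seed=4))
    for fid in list(truth.identities)[:40]:
        ident = truth.identities[fid]
        if ident["theoretical_mz"] is None:
            continue
        obs = float(table.features.loc[fid, "mz"])
        ppm = 1e6 * (obs - ident["theoretical_mz"]) / ident["theoretical_mz"]
        assert abs(ppm) < 12  # ~6 sigma at the default 2 ppm noise


def test_truth_round_trip(tmp_path):
    _, truth = simulate_cohort(preset_paper_design(seed=6))
    truth.to_json(tmp_path / "truth.json")
    from lipidscreen.synthetic import GroundTruth

    back = GroundTruth.from_json(tmp_path / "truth.json")
    assert back.markers == truth.markers
    assert back.config == truth.config


def test_config_validation_errors():
    with pytest.raises(ValidationError):
        SimulationConfig(seed=1, group_sizes={"control": 1, "UF": 5, "RUF": 5})
    with pytest.raises(ValidationError):
        SimulationConfig(
            seed=1, n_features=5,
            markers=[PlantedMarker(feature_index=9, groups=("UF",), log2_fc=1.0)])
    with pytest.raises(ValidationError):
        SimulationConfig(
            seed=1,
            markers=[PlantedMarker(feature_index=0, groups=("XX",), log2_fc=1.0)])
    with pytest.raises(ValidationError):
        SimulationConfig()  # seed is mandatory
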