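"""Simulate the three-group plasma cohort with planted markers.

Draws the default study design — 15 controls, 35 first-time cases (UF),
31 recurrent cases (RUF), 267 lipid features, 8 disease markers and 17
recurrence markers with |log2 FC| in [0.6, 1.5] — and writes the feature
table, sample sheet, planted ground truth and simulated spectra under
results/cohort/.
"""

import argparse
from pathlib import Path

from lipidscreen.annotation import write_mgf
from lipidscreen.feature_table import write_table
from lipidscreen.lipids import build_database
from lipidscreen.synthetic import preset_paper_design, simulate_cohort, simulate_spectra

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()

    OUT.mkdir(parents=True, exist_ok=True)
    config = preset_paper_design(seed=args.seed)
    table, truth = simulate_cohort(config)
    write_table(table, OUT / "table.csv", OUT / "samples.csv")
    truth.to_json(OUT / "truth.json")
    db = build_database(polarity=config.polarity, mz_range=config.mz_range)
    spectra = simulate_spectra(truth, db, ppm_sigma=config.ppm_sigma)
    write_mgf(spectra, OUT / "spectra.mgf")

    groups = {}
    for s in table.samples:
        key = "QC" if s.is_qc else s.group
        groups[key] = groups.get(key, 0) + 1
    print(f"cohort: {table.n_features} features x {table.n_samples} samples "
          f"({', '.join(f'{k}={v}' for k, v in groups.items())}), seed {args.seed}")
    print(f"planted markers: {len(truth.markers)} "
          f"({len(truth.marker_ids(('control', 'UF')))} disease, "
          f"{len(truth.marker_ids(('UF', 'RUF')))} recurrence) -> {OUT}")


if __name__ == "__main__":
    main()
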