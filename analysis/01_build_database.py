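"""Build the theoretical lipid ion databases used throughout the analysis.

Enumerates every lipid class at sum-composition level with its ESI
adducts, for the plasma acquisition window (positive mode, m/z 400-1000)
and for both polarities over the tissue window (m/z 100-1800), and
writes them as TSV under results/.
"""

import argparse
from pathlib import Path

from lipidscreen.lipids import build_database

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    OUT.mkdir(exist_ok=True)
    plasma = build_database(polarity="pos", mz_range=(400.0, 1000.0))
    plasma.write_tsv(OUT / "db_plasma_pos.tsv")
    print(f"plasma positive-mode database: {len(plasma)} ions "
          f"({len({i.species.name for i in plasma.ions})} species) "
          f"-> {OUT / 'db_plasma_pos.tsv'}")
    for pol in ("pos", "neg"):
        tissue = build_database(polarity=pol, mz_range=(100.0, 1800.0))
        tissue.write_tsv(OUT / f"db_tissue_{pol}.tsv")
        print(f"tissue {pol} database: {len(tissue)} ions "
              f"-> {OUT / f'db_tissue_{pol}.tsv'}")


if __name__ == "__main__":
    main()
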