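"""Compute monthly SPI and SPEI (3-month scale) from the site climate.

Checks that the drought-year analogues stand out as dry anomalies in the
July-September seasonal window, as the growth analysis assumes.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _config import STUDY

from pinedrought.pipeline import run_pipeline

run_pipeline(STUDY, ("climate",))

idx = pd.read_csv(Path(STUDY.outdir) / "drought_indices.csv")
jas = idx[idx["month"].isin([7, 8, 9])].groupby("year")[["spi", "spei"]].mean()
print("July-September mean drought indices:")
for year in STUDY.drought_years:
    print(f"  {year}: SPI {jas.loc[year, 'spi']:+.2f}  SPEI {jas.loc[year, 'spei']:+.2f}")
normal = jas.drop(list(STUDY.drought_years))
print(f"  other years: SPI {normal['spi'].mean():+.2f}  SPEI {normal['spei'].mean():+.2f}")
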