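"""Replicated 10-fold cross-validation of GBLUP and ABLUP.

Reports predictive ability (PA), predictive accuracy (PAC = PA/sqrt(h2),
GBLUP heritability for both models) and mean theoretical accuracy (TAC)
per trait and model.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _config import STUDY

from pinedrought.pipeline import run_pipeline

run_pipeline(STUDY, ("cv",))

cv = pd.read_csv(Path(STUDY.outdir) / "cv_report.csv")
print(cv[["trait", "model", "pa", "pa_se", "pac", "tac"]].round(3).to_string(index=False))
best = cv.loc[cv.groupby("trait")["pa"].idxmax()]
n_gblup = (best["model"] == "GBLUP").sum()
print(f"\nGBLUP gives the higher predictive ability for {n_gblup}/{len(best)} traits")
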