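"""REML variance components: heritability per trait under GBLUP and ABLUP,
and the genetic/phenotypic correlation between drought resistance and
growth with likelihood-ratio tests.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _config import STUDY

from pinedrought import io, mixed_model
from pinedrought.pipeline import run_pipeline

run_pipeline(STUDY, ("fit",))

out = Path(STUDY.outdir)
fits = json.loads((out / "fit_report.json").read_text())["fits"]
print(f"{'trait':>6} {'h2 GBLUP':>12} {'h2 ABLUP':>12}")
for trait in STUDY.traits:
    g = fits[f"{trait}/GBLUP"]
    a = fits[f"{trait}/ABLUP"]
    print(f"{trait:>6} {g['h2']:.2f} ({g['h2_se']:.2f}) {a['h2']:.2f} ({a['h2_se']:.2f})")

phenos = pd.read_csv(out / "phenotypes.csv").set_index("tree")
G = io.read_relationship(out / "G_matrix.csv", kind="G-tuned")
prog = [i for i in G.ids if i in phenos.index]
Gp = G.submatrix(prog)
y1, y2 = phenos["RS"].reindex(prog), phenos["BAI"].reindex(prog)
full = mixed_model.reml_bivariate(y1, y2, Gp)
no_ra = mixed_model.reml_bivariate(y1, y2, Gp, fix_ra=0.0)
no_r = mixed_model.reml_bivariate(y1, y2, Gp, fix_ra=0.0, fix_re=0.0)
p_ra = mixed_model.lrt_correlation(full, no_ra, 1)
p_rp = mixed_model.lrt_correlation(full, no_r, 2)
print(f"\nRS-BAI: r_a = {full.r_a:.2f} (se {full.r_a_se:.2f}, LRT p = {p_ra:.3g}); "
      f"r_p = {full.r_p:.2f} (LRT p = {p_rp:.3g})")
pd.DataFrame(
    [{"pair": "RS-BAI", "r_a": full.r_a, "r_a_se": full.r_a_se,
      "p_ra": p_ra, "r_e": full.r_e, "r_p": full.r_p, "p_rp": p_rp}]
).to_csv(out / "correlations.csv", index=False)
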