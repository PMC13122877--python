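"""Genotype QC and construction of the A and (tuned) G matrices.

Applies the missingness (<= 40%) and MAF (> 5%) filters, mean-imputes the
survivors, builds the pedigree A by the tabular method and the VanRaden G,
and blends G with the identity (w = 0.01) for invertibility.
"""

import itertools
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from _config import STUDY

from pinedrought import io
from pinedrought.pipeline import run_pipeline

run_pipeline(STUDY, ("kinship",))

out = Path(STUDY.outdir)
A = io.read_relationship(out / "A_matrix.csv")
G = io.read_relationship(out / "G_matrix.csv", kind="G-tuned")
ped = io.read_pedigree(out / "pedigree.csv")
pos = {i: k for k, i in enumerate(G.ids)}
sib_g, sib_a = [], []
for _, members in ped.families().items():
    for a, b in itertools.combinations(members, 2):
        sib_g.append(G.values[pos[a], pos[b]])
        sib_a.append(A.values[pos[a], pos[b]])
print(f"A: {A.n} individuals, mean diagonal {np.diag(A.values).mean():.3f}")
print(f"G: mean diagonal {np.diag(G.values).mean():.3f}, "
      f"condition number {G.condition_number:.1f}" if G.condition_number
      else f"G: mean diagonal {np.diag(G.values).mean():.3f}")
print(f"full-sib pairs: mean A {np.mean(sib_a):.3f}, mean G {np.mean(sib_g):.3f} "
      "(G varies around the pedigree expectation through Mendelian sampling)")
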