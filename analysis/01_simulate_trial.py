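"""Generate the synthetic progeny trial.

Partial diallel of 33 parents -> 158 full-sib families, gene-dropped SNP
genotypes, true multi-trait breeding values, 1971-2011 monthly climate with
the 2002-2003 and 2006 drought analogues, and per-tree annual ring series.
Writes pedigree/genotype/climate/ring/truth files under results/study.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _config import STUDY

from pinedrought import io
from pinedrought.pipeline import run_pipeline

run_pipeline(STUDY, ("simulate",))

ped = io.read_pedigree(Path(STUDY.outdir) / "pedigree.csv")
fams = ped.families()
sizes = [len(m) for m in fams.values()]
print(f"simulated {len(ped.founders)} founders, {len(fams)} full-sib families, "
      f"{len(ped.progeny)} progeny (family sizes {min(sizes)}-{max(sizes)})")
print(f"artifacts in {STUDY.outdir}")
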