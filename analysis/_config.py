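"""Shared configuration for the numbered analysis drivers.

One synthetic study at the trial's scale (33 parents, 158 families,
~600 progeny) lives under results/study; every driver reads and extends it.
"""

from pinedrought.pipeline import PipelineConfig

STUDY = PipelineConfig(
    outdir="results/study",
    seed=1,
    n_snps=3000,
    n_causal=500,
    cv_folds=10,
    cv_replicates=3,
    traits=("RS", "RC", "RL", "BAI", "HGT", "DBH"),
)
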