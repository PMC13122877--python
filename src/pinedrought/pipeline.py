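"""End-to-end pipeline orchestration.

Stages (in dependency order): ``simulate`` -> ``climate`` -> ``dendro`` ->
``kinship`` -> ``fit`` -> ``cv`` -> ``scenarios``. Each stage writes its
artifacts under the configured output directory together with a provenance
sidecar (stage name, config hash, master seed) so a report can verify that
all artifacts come from one configuration. Deterministic stages reproduce
byte-identical outputs on re-run with the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dendro, evaluation, io, kinship, mixed_model
from .climate_indices import drought_index_table
from .containers import GeneticArchitecture
from .simulate import (
    GrowthParams,
    default_study_architecture,
    simulate_breeding_values,
    simulate_climate,
    simulate_genotypes,
    simulate_pedigree,
    simulate_ring_series,
    substream,
)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "climate", "dendro", "kinship", "fit", "cv", "scenarios")

_DEPENDS = {
    "simulate": (),
    "climate": ("simulate",),
    "dendro": ("simulate", "climate"),
    "kinship": ("simulate",),
    "fit": ("kinship", "dendro"),
    "cv": ("kinship", "dendro"),
    "scenarios": ("cv", "fit"),
}


@dataclass
class PipelineConfig:
    """All pipeline settings; every output records its hash and the seed."""

    outdir: str = "results/pipeline"
    seed: int = 1
    # mating design / genotypes
    n_parents: int = 33
    n_families: int = 158
    family_size_range: tuple[int, int] = (1, 7)
    crosses_per_parent: tuple[int, int] = (8, 9)
    n_snps: int = 4000
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.1
    n_causal: int = 500
    # climate / trial years
    planting_year: int = 1971
    last_year: int = 2011
    latitude: float = 63.55
    drought_years: tuple[int, ...] = (2002, 2003, 2006)
    # dendro settings
    dr_drought_years: tuple[int, ...] = (2002, 2003)
    lloret_pre_window: int = 3
    lloret_post_window: int = 3
    spline_stiffness: float | None = None
    chronology_start_year: int = 1990
    index_scale: int = 3
    # QC / G tuning
    qc_max_missing: float = 0.4
    qc_min_maf: float = 0.05
    g_blend_weight: float = 0.01
    g_blend_target: str = "identity"
    # evaluation
    cv_folds: int = 10
    cv_replicates: int = 10
    traits: tuple[str, ...] = ("RS", "RC", "RL", "BAI", "HGT", "DBH")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        for tup_field in (
            "family_size_range", "crosses_per_parent", "founder_maf_range",
            "drought_years", "dr_drought_years", "traits",
        ):
            setattr(cfg, tup_field, tuple(getattr(cfg, tup_field)))
        return cfg


def _sidecar(cfg: PipelineConfig, stage: str, path: Path, extra: dict | None = None):
    meta = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        **(extra or {}),
    }
    path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def _require(outdir: Path, artifact: str, stage: str, needed_by: str) -> Path:
    p = outdir / artifact
    if not p.exists():
        raise FileNotFoundError(
            f"stage '{needed_by}' requires artifact {artifact!r}; "
            f"run stage '{stage}' first"
        )
    return p


def run_pipeline(
    config: PipelineConfig, stages: tuple[str, ...] | list[str] = STAGES
) -> dict:
    """Execute the requested pipeline stages; returns a summary dict."""
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; valid: {STAGES}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": config.config_hash(), "stages": list(stages)}
    for stage in STAGES:  # canonical order regardless of request order
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        _STAGE_FN[stage](config, outdir, summary)
        log.info("stage %-9s done in %.1fs", stage, time.perf_counter() - t0)
    return summary


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, outdir: Path, summary: dict) -> None:
    ped = simulate_pedigree(
        cfg.n_parents, cfg.n_families, cfg.family_size_range,
        cfg.crosses_per_parent, seed=substream(cfg.seed, "pedigree"),
    )
    geno = simulate_genotypes(
        ped, cfg.n_snps, cfg.founder_maf_range, cfg.missing_rate,
        seed=substream(cfg.seed, "genotypes"),
    )
    arch = default_study_architecture(n_causal=cfg.n_causal)
    truth = simulate_breeding_values(geno, arch, seed=substream(cfg.seed, "bv"))
    climate = simulate_climate(
        cfg.planting_year, cfg.last_year, seed=substream(cfg.seed, "climate"),
        latitude=cfg.latitude, drought_years=cfg.drought_years,
    )
    params = GrowthParams(
        planting_year=cfg.planting_year, last_year=cfg.last_year,
        drought_years=cfg.drought_years,
    )
    rings, statics = simulate_ring_series(
        truth, climate, params, seed=substream(cfg.seed, "rings"),
        tree_ids=ped.progeny,
    )
    io.write_pedigree(ped, outdir / "pedigree.csv")
    io.write_genotypes_tsv(geno, outdir / "genotypes.tsv")
    climate.to_csv(outdir / "climate.csv", index=False)
    rings.to_csv(outdir / "rings.csv", index=False)
    statics.to_csv(outdir / "statics.csv", index=False)
    truth.bv_frame().to_csv(outdir / "true_breeding_values.csv")
    rw = {
        t: pd.Series(sub["RW"].to_numpy(), index=sub["year"].to_numpy())
        for t, sub in rings.groupby("tree")
    }
    io.write_rwl(rw, outdir / "rings.rwl")
    _sidecar(cfg, "simulate", outdir / "simulate.provenance.json",
             {"n_individuals": len(ped), "n_progeny": len(ped.progeny)})
    summary["n_progeny"] = len(ped.progeny)


def _stage_climate(cfg: PipelineConfig, outdir: Path, summary: dict) -> None:
    clim_path = _require(outdir, "climate.csv", "simulate", "climate")
    climate = pd.read_csv(clim_path)
    idx = drought_index_table(
        climate, scale=cfg.index_scale, latitude=cfg.latitude
    )
    idx.to_csv(outdir / "drought_indices.csv", index=False)
    _sidecar(cfg, "climate", outdir / "climate.provenance.json")


def _stage_dendro(cfg: PipelineConfig, outdir: Path, summary: dict) -> None:
    rings = pd.read_csv(_require(outdir, "rings.csv", "simulate", "dendro"))
    statics = pd.read_csv(outdir / "statics.csv")
    idx = pd.read_csv(
        _require(outdir, "drought_indices.csv", "climate", "dendro")
    )
    ped = io.read_pedigree(outdir / "pedigree.csv")
    fam_of = {
        iid: f"{s}x{d}"
        for iid, s, d, g in zip(ped.ids, ped.sire, ped.dam, ped.generation)
        if g > 0
    }

    bai_rows, resid_rows, pheno_rows = [], [], []
    for tree, sub in rings.groupby("tree"):
        sub = sub.sort_values("year")
        rw = pd.Series(sub["RW"].to_numpy(), index=sub["year"].to_numpy())
        bai = dendro.rw_to_bai(rw)
        bai_rows.append(pd.DataFrame({"tree": tree, "year": bai.index, "bai": bai.to_numpy()}))
        det = dendro.detrend_spline(bai, cfg.spline_stiffness)
        res = dendro.prewhiten_ar1(det)
        resid_rows.append(pd.DataFrame({"tree": tree, "year": res.index, "value": res.to_numpy()}))
        ll = dendro.lloret_indices(
            bai, cfg.dr_drought_years, cfg.lloret_pre_window, cfg.lloret_post_window
        )
        cwr, cwrr = dendro.conduit_reinforcement(
            sub["CWT"].to_numpy(), sub["LDR"].to_numpy(), sub["LDT"].to_numpy()
        )
        pheno_rows.append(
            {
                "tree": tree,
                "RS": ll["RS"], "RC": ll["RC"], "RL": ll["RL"],
                "BAI": float(bai.mean()),
                "LDR": float(sub["LDR"].mean()),
                "LDT": float(sub["LDT"].mean()),
                "WD": float(sub["WD"].mean()),
                "CWT": float(sub["CWT"].mean()),
                "CWR": float(np.mean(cwr)), "CWRr": float(np.mean(cwrr)),
            }
        )
    bai_long = pd.concat(bai_rows, ignore_index=True)
    residuals = pd.concat(resid_rows, ignore_index=True)
    chron = dendro.build_chronology(
        residuals, groups=None, start_year=cfg.chronology_start_year
    )
    fam_chron = dendro.build_chronology(
        residuals, groups=fam_of, start_year=cfg.chronology_start_year
    )
    phenos = pd.DataFrame(pheno_rows).merge(statics, on="tree")

    site = chron.set_index("year")["index"]
    corr = dendro.climate_growth_correlation(
        site, idx, "spei", seed=substream(cfg.seed, "boot"),
    )
    bai_long.to_csv(outdir / "bai.csv", index=False)
    chron.to_csv(outdir / "chronology_site.csv", index=False)
    fam_chron.to_csv(outdir / "chronology_family.csv", index=False)
    phenos.to_csv(outdir / "phenotypes.csv", index=False)
    corr.to_csv(outdir / "climate_growth_correlation.csv", index=False)
    _sidecar(cfg, "dendro", outdir / "dendro.provenance.json",
             {"n_trees": int(phenos.shape[0])})


def _stage_kinship(cfg: PipelineConfig, outdir: Path, summary: dict) -> None:
    ped = io.read_pedigree(_require(outdir, "pedigree.csv", "simulate", "kinship"))
    geno = io.read_genotypes_tsv(
        _require(outdir, "genotypes.tsv", "simulate", "kinship")
    )
    A = kinship.a_matrix(ped)
    geno_qc = kinship.qc_genotypes(geno, cfg.qc_max_missing, cfg.qc_min_maf)
    geno_full = kinship.impute_simple(geno_qc, "mean")
    G = kinship.g_matrix(geno_full)
    target = A if cfg.g_blend_target == "A" else "identity"
    Gt = kinship.tune_g(G, cfg.g_blend_weight, target)
    io.write_relationship(A, outdir / "A_matrix.csv")
    io.write_relationship(Gt, outdir / "G_matrix.csv")
    _sidecar(cfg, "kinship", outdir / "kinship.provenance.json",
             {"n_snps_after_qc": geno_full.n_snps,
              "g_condition_number": Gt.condition_number})


def _load_phenotypes(outdir: Path, needed_by: str) -> pd.DataFrame:
    p = _require(outdir, "phenotypes.csv", "dendro", needed_by)
    return pd.read_csv(p).set_index("tree")


def _stage_fit(cfg: PipelineConfig, outdir: Path, summary: dict) -> None:
    phenos = _load_phenotypes(outdir, "fit")
    A = io.read_relationship(_require(outdir, "A_matrix.csv", "kinship", "fit"))
    G = io.read_relationship(outdir / "G_matrix.csv", kind="G-tuned")
    report = {}
    for trait in cfg.traits:
        y = phenos[trait].reindex(G.ids)
        for label, K in (("GBLUP", G), ("ABLUP", A)):
            fit = mixed_model.reml_univariate(y, K)
            report[f"{trait}/{label}"] = {
                "sigma2_a": fit.sigma2_a, "sigma2_e": fit.sigma2_e,
                "h2": fit.h2, "h2_se": fit.h2_se, "loglik": fit.loglik,
                "n_obs": fit.n_obs,
            }
            ebv = pd.DataFrame({"ebv": fit.ebv, "se_ebv": fit.se_ebv})
            ebv.to_csv(outdir / f"ebv_{trait}_{label}.csv")
    (outdir / "fit_report.json").write_text(
        json.dumps({"config_hash": cfg.config_hash(), "seed": cfg.seed,
                    "fits": report}, indent=2, sort_keys=True) + "\n"
    )
    _sidecar(cfg, "fit", outdir / "fit.provenance.json")


def _stage_cv(cfg: PipelineConfig, outdir: Path, summary: dict) -> None:
    phenos = _load_phenotypes(outdir, "cv")
    A = io.read_relationship(_require(outdir, "A_matrix.csv", "kinship", "cv"))
    G = io.read_relationship(outdir / "G_matrix.csv", kind="G-tuned")
    prog = [i for i in G.ids if i in phenos.index]
    Gp, Ap = G.submatrix(prog), A.submatrix(prog)
    rows = []
    for trait in cfg.traits:
        y = phenos[trait].reindex(prog)
        h2_g = mixed_model.reml_univariate(y, Gp).h2
        for label, K in (("GBLUP", Gp), ("ABLUP", Ap)):
            rep = evaluation.crossvalidate(
                y, K, cfg.cv_folds, cfg.cv_replicates,
                seed=substream(cfg.seed, f"cv-{trait}"),
                trait=trait, h2_reference=h2_g,
            )
            rows.append(
                {
                    "trait": trait, "model": label,
                    "pa": rep.pa_mean, "pa_se": rep.pa_se, "pac": rep.pac,
                    "tac": rep.tac_mean,
                    "tac_se_replicates": rep.tac_se_over_replicates,
                    "tac_se_individuals": rep.tac_se_over_individuals,
                    "h2_gblup_ref": h2_g,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "cv_report.csv", index=False)
    _sidecar(cfg, "cv", outdir / "cv.provenance.json")


def _stage_scenarios(cfg: PipelineConfig, outdir: Path, summary: dict) -> None:
    cv = pd.read_csv(_require(outdir, "cv_report.csv", "cv", "scenarios"))
    phenos = _load_phenotypes(outdir, "scenarios")
    A = io.read_relationship(
        _require(outdir, "A_matrix.csv", "kinship", "scenarios")
    )
    prog = [i for i in A.ids if i in phenos.index]
    Ap = A.submatrix(prog)
    acc: dict[str, tuple[float, float]] = {}
    for trait in cfg.traits:
        r_gs = float(
            cv.loc[(cv["trait"] == trait) & (cv["model"] == "GBLUP"), "tac"].iloc[0]
        )
        fit = mixed_model.reml_univariate(phenos[trait].reindex(prog), Ap)
        tac_ps = evaluation.ablup_benchmark_tac(fit, Ap)
        acc[trait] = (r_gs, float(tac_ps.mean()))
    table = evaluation.scenario_table(acc)
    table.to_csv(outdir / "selection_response.csv", index=False)
    _sidecar(cfg, "scenarios", outdir / "scenarios.provenance.json")
    summary["selection_response"] = table.to_dict("records")


_STAGE_FN = {
    "simulate": _stage_simulate,
    "climate": _stage_climate,
    "dendro": _stage_dendro,
    "kinship": _stage_kinship,
    "fit": _stage_fit,
    "cv": _stage_cv,
    "scenarios": _stage_scenarios,
}
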