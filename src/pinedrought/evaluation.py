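"""Prediction evaluation: cross-validation, PA/PAC/TAC and selection response.

Predictive ability (PA) is the Pearson correlation between predicted
breeding values of masked validation individuals and their adjusted
phenotypes; predictive accuracy PAC = PA / sqrt(h2), using the GBLUP
heritability for both models. Theoretical accuracy is
TAC_i = sqrt(1 - SE_i^2 / ((1 + F_i) s2a)), the expected correlation between
true and predicted breeding values; GBLUP reports it over cross-validation
folds while the pedigree benchmark (ABLUP) reports it from the full-data
fit without CV. The relative selection response compares genomic to
pedigree selection per unit time: RSR = (r_GS / r_PS) * (CL_PS / CL_GS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import RelationshipMatrix
from .mixed_model import ModelFit, reml_univariate

__all__ = [
    "CVReport",
    "ScenarioResult",
    "crossvalidate",
    "predictive_accuracy",
    "theoretical_accuracy",
    "selection_response",
    "scenario_table",
    "DEFAULT_SCENARIOS",
]

# (strategy, CL_PS, CL_GS): conventional pedigree cycles of 36 y (backward)
# and 21 y (forward) against genomic cycles of 18 y (natural flowering) and
# 11 y (greenhouse flower stimulation)
DEFAULT_SCENARIOS: tuple[tuple[str, float, float], ...] = (
    ("backward", 36.0, 18.0),
    ("backward", 36.0, 11.0),
    ("forward", 21.0, 18.0),
    ("forward", 21.0, 11.0),
)


@dataclass
class CVReport:
    """Aggregated cross-validation metrics for one trait x model."""

    trait: str
    model: str
    folds: int
    replicates: int
    seed: int
    pa_mean: float
    pa_se: float
    pac: float
    tac_mean: float
    tac_se_over_replicates: float
    tac_se_over_individuals: float
    h2_mean: float
    per_fold: pd.DataFrame = field(repr=False)


@dataclass
class ScenarioResult:
    strategy: str
    cl_ps: float
    cl_gs: float
    r_gs: float
    r_ps: float
    rsr: float
    efficiency_percent: float


def crossvalidate(
    y: pd.Series,
    K: RelationshipMatrix,
    folds: int = 10,
    replicates: int = 10,
    seed: int = 0,
    trait: str = "trait",
    h2_reference: float | None = None,
) -> CVReport:
    """Replicated k-fold cross-validation of (G/A)BLUP prediction.

    Per replicate the phenotyped individuals are randomly partitioned into
    ``folds`` unstratified folds; per fold the model is refitted with the
    validation phenotypes masked and PA computed on the masked individuals.
    Metrics are averaged fold -> replicate, then mean +/- empirical SE over
    replicates. ``h2_reference`` (GBLUP h2) feeds PAC; if omitted, the mean
    refit h2 is used.
    """
    y = y.reindex(K.ids)
    ids = np.array(K.ids)
    phen = np.isfinite(y.to_numpy(float))
    if not phen.all():
        raise ValueError("crossvalidate expects every individual phenotyped")
    n = len(ids)
    if n // folds < 5:
        raise ValueError(
            f"{n} individuals over {folds} folds leaves validation folds "
            "below 5 members"
        )
    rng = np.random.default_rng(seed)
    diag = np.diag(K.values)
    records = []
    for rep in range(replicates):
        perm = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        fold_of[perm] = np.arange(n) % folds
        for f in range(folds):
            val = fold_of == f
            y_train = y.copy()
            y_train[ids[val]] = np.nan
            fit = reml_univariate(y_train, K)
            pred = fit.ebv.loc[ids[val]].to_numpy()
            truth = y.loc[ids[val]].to_numpy()
            pa = float(np.corrcoef(pred, truth)[0, 1])
            tac_i = theoretical_accuracy(
                fit.se_ebv.loc[ids[val]].to_numpy(),
                diag[val] - 1.0,
                fit.sigma2_a,
            )
            records.append(
                {
                    "replicate": rep,
                    "fold": f,
                    "pa": pa,
                    "tac": float(np.mean(tac_i)),
                    "tac_var_individuals": float(np.var(tac_i, ddof=1))
                    if len(tac_i) > 1
                    else 0.0,
                    "n_val": int(val.sum()),
                    "h2": fit.h2,
                }
            )
    per_fold = pd.DataFrame(records)
    by_rep = per_fold.groupby("replicate")[["pa", "tac", "h2"]].mean()
    pa_mean = float(by_rep["pa"].mean())
    pa_se = float(by_rep["pa"].std(ddof=1) / np.sqrt(replicates)) if replicates > 1 else float("nan")
    tac_mean = float(by_rep["tac"].mean())
    tac_se_rep = (
        float(by_rep["tac"].std(ddof=1) / np.sqrt(replicates))
        if replicates > 1
        else float("nan")
    )
    n_val_total = per_fold["n_val"].sum()
    tac_se_ind = float(
        np.sqrt(per_fold["tac_var_individuals"].mean() / max(n_val_total, 1))
    )
    h2_mean = float(by_rep["h2"].mean())
    h2_for_pac = h2_reference if h2_reference is not None else h2_mean
    pac = predictive_accuracy(pa_mean, h2_for_pac)
    model = "GBLUP" if K.kind.startswith("G") else "ABLUP"
    return CVReport(
        trait=trait,
        model=model,
        folds=folds,
        replicates=replicates,
        seed=seed,
        pa_mean=pa_mean,
        pa_se=pa_se,
        pac=pac,
        tac_mean=tac_mean,
        tac_se_over_replicates=tac_se_rep,
        tac_se_over_individuals=tac_se_ind,
        h2_mean=h2_mean,
        per_fold=per_fold,
    )


def predictive_accuracy(pa: float, h2_gblup: float) -> float:
    """PAC = PA / sqrt(h2). May exceed 1 (reported with a warning)."""
    if not (0.0 < h2_gblup <= 1.0):
        raise ValueError("h2 must lie in (0, 1]")
    pac = pa / np.sqrt(h2_gblup)
    if abs(pac) > 1.0:
        warnings.warn(f"PAC = {pac:.3f} exceeds 1 in magnitude", stacklevel=2)
    return float(pac)


def theoretical_accuracy(
    se_ebv: np.ndarray,
    F: np.ndarray | float,
    sigma2_a: float,
    tol: float = 1e-8,
) -> np.ndarray:
    """Per-individual TAC_i = sqrt(1 - SE_i^2 / ((1 + F_i) s2a)).

    A radicand slightly below zero (within ``tol``) is clamped to 0 with a
    warning; beyond tolerance the inputs are inconsistent and raise.
    """
    if sigma2_a <= 0:
        raise ValueError("sigma2_a must be positive")
    se2 = np.asarray(se_ebv, dtype=float) ** 2
    denom = (1.0 + np.asarray(F, dtype=float)) * sigma2_a
    rad = 1.0 - se2 / denom
    if np.any(rad < -tol):
        raise ValueError(
            f"SE^2 exceeds (1 + F) sigma2_a by more than tolerance "
            f"(min radicand {rad.min():.3g})"
        )
    if np.any(rad < 0):
        warnings.warn("TAC radicand clamped to 0 within tolerance", stacklevel=2)
    return np.sqrt(np.clip(rad, 0.0, None))


def ablup_benchmark_tac(fit: ModelFit, K: RelationshipMatrix) -> pd.Series:
    """Full-data (no CV) per-individual TAC from an ABLUP fit."""
    F = K.inbreeding()
    tac = theoretical_accuracy(fit.se_ebv.to_numpy(), F, fit.sigma2_a)
    return pd.Series(tac, index=K.ids, name="tac")


def selection_response(
    r_gs: float, r_ps: float, cl_ps: float, cl_gs: float, strategy: str = ""
) -> ScenarioResult:
    """Relative selection response of genomic over pedigree selection.

    RSR = (r_GS / r_PS) * (CL_PS / CL_GS); efficiency = (RSR - 1) * 100%.
    """
    for name, v in (("r_gs", r_gs), ("r_ps", r_ps), ("cl_ps", cl_ps), ("cl_gs", cl_gs)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    rsr = (r_gs / r_ps) * (cl_ps / cl_gs)
    return ScenarioResult(
        strategy=strategy,
        cl_ps=cl_ps,
        cl_gs=cl_gs,
        r_gs=r_gs,
        r_ps=r_ps,
        rsr=float(rsr),
        efficiency_percent=float((rsr - 1.0) * 100.0),
    )


def scenario_table(
    accuracies: dict[str, tuple[float, float]],
    scenarios: tuple[tuple[str, float, float], ...] = DEFAULT_SCENARIOS,
) -> pd.DataFrame:
    """Selection-efficiency table over traits and breeding-cycle scenarios.

    ``accuracies`` maps trait -> (r_GS, r_PS). Efficiency percentages are
    rounded to one decimal in the table; intermediates are unrounded.
    """
    rows = []
    for strategy, cl_ps, cl_gs in scenarios:
        for trait, (r_gs, r_ps) in accuracies.items():
            res = selection_response(r_gs, r_ps, cl_ps, cl_gs, strategy=strategy)
            rows.append(
                {
                    "strategy": strategy,
                    "cycle": f"{cl_ps:.0f}->{cl_gs:.0f}",
                    "trait": trait,
                    "rsr": res.rsr,
                    "efficiency_percent": round(res.efficiency_percent, 1),
                }
            )
    return pd.DataFrame(rows)
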