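"""Synthetic trial generator with known genetic and climatic ground truth.

Emulates the structure of a northern-Sweden full-sib progeny trial: a partial
diallel mating design, genotyping-by-sequencing-like SNP dosages produced by
Mendelian gene dropping from Hardy-Weinberg founders, marker-determined true
breeding values with a target multi-trait covariance, and annual ring series
driven by an age trend, AR(1) persistence, growing-season water balance and
discrete drought years whose growth penalty depends on each tree's resistance
breeding value.

All generators take an explicit seed; :func:`substream` derives independent
named substreams from a single master seed so components are individually
reproducible.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from .containers import (
    UNKNOWN,
    GeneticArchitecture,
    GenotypeMatrix,
    Pedigree,
    TrueValues,
)

__all__ = [
    "InfeasibleDesignError",
    "substream",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_breeding_values",
    "simulate_climate",
    "GrowthParams",
    "simulate_ring_series",
    "default_study_architecture",
]


class InfeasibleDesignError(ValueError):
    """Mating-design constraints cannot be satisfied; message names the binding one."""


def substream(master_seed: int, name: str) -> int:
    """Derive a named, reproducible child seed (< 2**31) from a master seed."""
    return (zlib.crc32(name.encode()) ^ (int(master_seed) * 2654435761)) % (2**31 - 1)


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(
    n_parents: int,
    n_families: int,
    family_size_range: tuple[int, int],
    crosses_per_parent: tuple[int, int],
    seed: int,
    max_retries: int = 1000,
) -> Pedigree:
    """Simulate a partial diallel: founders, full-sib families, progeny.

    Each family is a distinct unordered pair of founders. Per-parent usage is
    kept within ``crosses_per_parent`` whenever the aggregate constraint
    ``n_parents*min <= 2*n_families <= n_parents*max`` permits it; otherwise
    the balanced band floor/ceil(2*n_families/n_parents) is used with a
    warning. Family sizes are drawn uniformly from ``family_size_range``.
    """
    lo_f, hi_f = family_size_range
    lo_u, hi_u = crosses_per_parent
    if lo_f < 1 or hi_f < lo_f or lo_u < 0 or hi_u < max(lo_u, 1):
        raise InfeasibleDesignError("family size / usage ranges must be positive")
    max_pairs = comb(n_parents, 2)
    if n_families > max_pairs:
        raise InfeasibleDesignError(
            f"n_families={n_families} exceeds the number of distinct parent "
            f"pairs C({n_parents},2)={max_pairs}"
        )
    slots = 2 * n_families
    if not (n_parents * lo_u <= slots <= n_parents * hi_u):
        lo_u = slots // n_parents
        hi_u = -(-slots // n_parents)
        warnings.warn(
            f"crosses_per_parent={crosses_per_parent} incompatible with "
            f"{n_families} families over {n_parents} parents "
            f"(2*families={slots} parent slots); using balanced band "
            f"({lo_u}, {hi_u})",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_parents)))
    parents = [f"P{k + 1:0{width}d}" for k in range(n_parents)]

    chosen = _select_crosses(n_parents, n_families, lo_u, hi_u, rng, max_retries)

    ids = list(parents)
    sire: list[str] = [UNKNOWN] * n_parents
    dam: list[str] = [UNKNOWN] * n_parents
    gen = [0] * n_parents
    sizes = rng.integers(lo_f, hi_f + 1, size=n_families)
    for fam_no, ((a, b), size) in enumerate(zip(chosen, sizes), start=1):
        for k in range(1, int(size) + 1):
            ids.append(f"F{fam_no:03d}_{k}")
            sire.append(parents[a])
            dam.append(parents[b])
            gen.append(1)
    return Pedigree(ids=ids, sire=sire, dam=dam, generation=gen)


def _select_crosses(
    n_parents: int,
    n_families: int,
    lo_u: int,
    hi_u: int,
    rng: np.random.Generator,
    max_retries: int,
) -> list[tuple[int, int]]:
    """Randomized round-robin pair selection under per-parent usage bounds."""
    for _ in range(max_retries):
        usage = np.zeros(n_parents, dtype=int)
        taken: set[tuple[int, int]] = set()
        ok = True
        for _ in range(n_families):
            # favour the least-used parents so the usage band can close
            order = np.lexsort((rng.random(n_parents), usage))
            pair = None
            for a in order:
                if usage[a] >= hi_u:
                    continue
                for b in order:
                    if b == a or usage[b] >= hi_u:
                        continue
                    key = (min(a, b), max(a, b))
                    if key not in taken:
                        pair = key
                        break
                if pair is not None:
                    break
            if pair is None:
                ok = False
                break
            taken.add(pair)
            usage[list(pair)] += 1
        if ok and np.all(usage >= lo_u):
            return sorted(taken, key=lambda p: (p[0], p[1]))
    raise InfeasibleDesignError(
        f"could not place {n_families} families with per-parent usage in "
        f"({lo_u}, {hi_u}) after {max_retries} attempts; the usage upper "
        "bound is the binding constraint"
    )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    ped: Pedigree,
    n_snps: int,
    founder_maf_range: tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Gene-drop biallelic SNP genotypes through a pedigree.

    Founders are drawn in Hardy-Weinberg proportions at a per-SNP alternate
    allele frequency sampled uniformly from ``founder_maf_range``; each
    non-founder receives one allele from each parent, independently across
    SNPs (no linkage). Missing entries are masked uniformly at random.
    """
    lo, hi = founder_maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("founder_maf_range must lie within (0, 0.5]")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    parent_idx = ped.parent_indices()
    gens = np.asarray(ped.generation)
    if np.any((gens > 0) & (parent_idx == -1).any(axis=1)):
        raise ValueError("non-founders with unknown parents cannot be gene-dropped")

    rng = np.random.default_rng(seed)
    n = len(ped)
    p = rng.uniform(lo, hi, size=n_snps)
    alleles = np.empty((n, n_snps, 2), dtype=np.int8)
    for i in range(n):
        s, d = parent_idx[i]
        if s == -1:  # founder: HWE draw
            alleles[i] = rng.random((n_snps, 2)) < p[:, None]
        else:
            pick = rng.integers(0, 2, size=(2, n_snps))
            alleles[i, :, 0] = alleles[s, np.arange(n_snps), pick[0]]
            alleles[i, :, 1] = alleles[d, np.arange(n_snps), pick[1]]
    dosages = alleles.sum(axis=2).astype(float)
    if missing_rate > 0:
        mask = rng.random(dosages.shape) < missing_rate
        dosages[mask] = np.nan
    snp_ids = [f"SNP{j + 1:06d}" for j in range(n_snps)]
    return GenotypeMatrix(ids=list(ped.ids), snp_ids=snp_ids, dosages=dosages)


# ---------------------------------------------------------------------------
# breeding values
# ---------------------------------------------------------------------------

def _sym_sqrt(m: np.ndarray, inverse: bool = False) -> np.ndarray:
    w, v = np.linalg.eigh(m)
    w = np.clip(w, 0.0, None)
    if inverse:
        with np.errstate(divide="ignore"):
            s = np.where(w > 1e-12 * max(w.max(), 1.0), 1.0 / np.sqrt(w), 0.0)
    else:
        s = np.sqrt(w)
    return (v * s) @ v.T


def simulate_breeding_values(
    geno: GenotypeMatrix,
    arch: GeneticArchitecture,
    seed: int = 0,
) -> TrueValues:
    """Draw causal SNP effects and compute marker-determined breeding values.

    Effects are multivariate normal across traits, then linearly rescaled so
    the realized sample covariance of the breeding values equals ``Sigma_a``
    exactly. Missing dosages contribute their per-SNP mean to the truth.
    """
    if arch.n_causal > geno.n_snps:
        raise ValueError("n_causal exceeds the number of SNPs")
    rng = np.random.default_rng(seed)
    t = arch.n_traits
    causal = np.sort(rng.choice(geno.n_snps, size=arch.n_causal, replace=False))

    Z = geno.dosages[:, causal].copy()
    col_mean = np.nanmean(Z, axis=0)
    nan = np.isnan(Z)
    if nan.any():
        Z[nan] = np.take(col_mean, np.nonzero(nan)[1])

    effects_full = np.zeros((geno.n_snps, t))
    if np.allclose(arch.Sigma_a, 0.0):
        bv = np.zeros((geno.n_individuals, t))
        return TrueValues(list(geno.ids), list(arch.trait_names), bv,
                          effects_full, causal)

    raw = rng.standard_normal((arch.n_causal, t))
    bv_raw = Z @ raw
    C = np.cov(bv_raw, rowvar=False).reshape(t, t)
    # T' C T = Sigma_a  with  T = C^{-1/2} Sigma_a^{1/2}
    T = _sym_sqrt(C, inverse=True) @ _sym_sqrt(arch.Sigma_a)
    eff = raw @ T
    bv = Z @ eff
    effects_full[causal] = eff
    return TrueValues(list(geno.ids), list(arch.trait_names), bv,
                      effects_full, causal)


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------

def simulate_climate(
    start_year: int = 1971,
    end_year: int = 2011,
    seed: int = 0,
    latitude: float = 63.55,
    mean_annual_temp: float = 2.5,
    seasonal_amplitude: float = 12.5,
    drought_years: tuple[int, ...] = (2002, 2003, 2006),
    drought_precip_factor: float = 0.35,
    drought_temp_anomaly: float = 2.0,
) -> pd.DataFrame:
    """Monthly boreal-site climate (temp deg C, precip mm) with drought years.

    Temperature follows a sinusoidal seasonal cycle around the site mean;
    precipitation is gamma-distributed around a summer-peaked monthly
    climatology. In drought years the May-September precipitation is scaled
    down and temperature raised, emulating the 2002-2003 and 2006 episodes.
    """
    rng = np.random.default_rng(seed)
    years = np.arange(start_year, end_year + 1)
    months = np.arange(1, 13)
    # summer-peaked monthly normals (mm), annual total ~600 mm
    precip_norm = 35.0 + 30.0 * np.exp(-0.5 * ((months - 7.5) / 2.2) ** 2)
    rows = []
    for y in years:
        t_anom = rng.normal(0.0, 1.0)
        for m in months:
            temp = (
                mean_annual_temp
                - seasonal_amplitude * np.cos(2.0 * np.pi * (m - 1) / 12.0)
                + t_anom
                + rng.normal(0.0, 1.2)
            )
            shape = 4.0
            precip = rng.gamma(shape, precip_norm[m - 1] / shape)
            if y in drought_years and 5 <= m <= 9:
                precip *= drought_precip_factor
                temp += drought_temp_anomaly
            rows.append((int(y), int(m), float(temp), float(precip)))
    df = pd.DataFrame(rows, columns=["year", "month", "temp", "precip"])
    df.attrs["latitude"] = latitude
    return df


# ---------------------------------------------------------------------------
# ring series and static traits
# ---------------------------------------------------------------------------

@dataclass
class GrowthParams:
    """Growth-model settings for the annual ring simulator.

    The age trend is Hugershoff-like, ``A * age^b * exp(-c*age) + d`` (mm),
    peaking at age b/c (~18 years by default so the juvenile phase covers
    roughly the first 15 years). ``phi`` is the AR(1) coefficient of the
    log-growth noise, ``climate_sens`` the log-scale coefficient on the
    standardized growing-season water balance, ``tree_env_sd`` a permanent
    per-tree micro-site effect on log growth, and ``drought_mult`` the mean
    growth multiplier applied in drought years, modulated individual-by-
    individual by the (standardized) resistance breeding value through
    ``resistance_slope`` (positive slope: higher breeding value, milder
    drought penalty). Recovery breeding values analogously modulate the
    first ``recovery_window`` post-drought years.

    The default noise and slope magnitudes are set so the emergent per-tree
    phenotypes show low-to-moderate narrow-sense heritability (drought
    ratios around 0.2, mean basal area increment around 0.3), the genetic-
    control regime reported for such traits in conifer progeny trials.
    """

    planting_year: int = 1971
    last_year: int = 2011
    trend_scale: float = 0.35
    trend_power: float = 1.1
    trend_decay: float = 0.06
    trend_floor: float = 0.30
    phi: float = 0.5
    climate_sens: float = 0.25
    noise_sd: float = 0.25
    tree_env_sd: float = 0.35  # permanent micro-site effect on log growth
    drought_years: tuple[int, ...] = (2002, 2003, 2006)
    drought_mult: float = 0.6
    resistance_slope: float = 0.12
    resistance_trait: str = "resistance"
    recovery_slope: float = 0.10
    recovery_trait: str = "recovery"
    recovery_window: int = 2
    growth_sens: float = 0.25
    growth_trait: str = "growth"
    anatomy_traits: dict = field(
        default_factory=lambda: {
            "CWT": ("wall_thickness", 2.8, 0.25),
            "LDR": ("lumen_radial", 28.0, 2.0),
            "LDT": ("lumen_tangential", 26.0, 2.0),
            "WD": ("density", 420.0, 25.0),
        }
    )
    anatomy_year_noise: float = 0.5  # fraction of the trait's residual SD
    static_traits: dict = field(
        default_factory=lambda: {"HGT": (9.0, 1.2), "DBH": (12.0, 2.0)}
    )
    static_h2: float = 0.4  # target narrow-sense h2 of the static growth traits

    def age_trend(self, age: np.ndarray) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        return (
            self.trend_scale * age**self.trend_power * np.exp(-self.trend_decay * age)
            + self.trend_floor
        )


def _growing_season_signal(climate: pd.DataFrame, latitude: float) -> pd.Series:
    """Standardized June-August water balance (precip - Thornthwaite PET)."""
    from .climate_indices import thornthwaite_pet

    pet = thornthwaite_pet(climate, latitude=latitude)
    bal = climate["precip"].to_numpy() - pet.to_numpy()
    df = climate.assign(balance=bal)
    summer = df[df["month"].between(6, 8)].groupby("year")["balance"].sum()
    sd = summer.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return summer * 0.0
    return (summer - summer.mean()) / sd


def simulate_ring_series(
    truth: TrueValues,
    climate: pd.DataFrame,
    params: GrowthParams | None = None,
    seed: int = 0,
    tree_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-tree annual ring series and static growth traits.

    Returns ``(rings, statics)``: a long table with one row per tree-year and
    columns RW/CWT/LDR/LDT/WD, and a per-tree table with HGT and DBH.

    Ring width for tree i in year y is
    ``trend(age) * exp(g_i + s*c_y + e_{i,y}) * m_{i,y}`` where ``c_y`` is
    the standardized growing-season water balance, ``e`` an AR(1) lognormal
    noise term and ``m`` the drought/recovery multiplier (1 outside drought
    and recovery years). Multipliers are mean-corrected so the population
    mean drought multiplier equals ``drought_mult`` exactly.
    """
    params = params or GrowthParams()
    rng = np.random.default_rng(seed)
    years = np.arange(params.planting_year + 1, params.last_year + 1)
    clim_years = set(climate["year"].unique())
    missing = [int(y) for y in years if y not in clim_years]
    if missing:
        raise ValueError(f"climate does not cover simulated ring years {missing}")
    for dy in params.drought_years:
        if dy not in clim_years:
            raise ValueError(f"drought year {dy} outside climate span")

    latitude = climate.attrs.get("latitude", 63.55)
    c = _growing_season_signal(climate, latitude).reindex(years).to_numpy()
    ages = years - params.planting_year
    trend = params.age_trend(ages)

    ids = tree_ids if tree_ids is not None else list(truth.ids)
    bvf = truth.bv_frame()

    def _std_bv(trait: str) -> np.ndarray:
        if trait in bvf.columns:
            v = bvf.loc[ids, trait].to_numpy()
            sd = v.std(ddof=1)
            return (v - v.mean()) / sd if sd > 0 else np.zeros(len(ids))
        return np.zeros(len(ids))

    z_res = _std_bv(params.resistance_trait)
    z_rec = _std_bv(params.recovery_trait)
    z_gro = _std_bv(params.growth_trait)

    n, ny = len(ids), len(years)
    # AR(1) log-noise, stationary start
    e = np.zeros((n, ny))
    innov_sd = params.noise_sd
    if params.noise_sd > 0:
        stat_sd = innov_sd / np.sqrt(max(1.0 - params.phi**2, 1e-12))
        e[:, 0] = rng.normal(0.0, stat_sd, size=n)
        for t in range(1, ny):
            e[:, t] = params.phi * e[:, t - 1] + rng.normal(0.0, innov_sd, size=n)

    env = (
        rng.normal(0.0, params.tree_env_sd, size=n)
        if params.tree_env_sd > 0
        else np.zeros(n)
    )
    log_rw = (
        np.log(trend)[None, :]
        + params.climate_sens * c[None, :]
        + params.growth_sens * z_gro[:, None]
        + env[:, None]
        + e
    )
    rw = np.exp(log_rw)

    # drought multiplier, mean-corrected so E[m] = drought_mult
    s = params.resistance_slope
    m_drought = params.drought_mult * np.exp(s * z_res - 0.5 * s**2)
    sr = params.recovery_slope
    m_recov = np.exp(sr * z_rec - 0.5 * sr**2)
    drought_set = set(params.drought_years)
    last_drought = max(drought_set) if drought_set else None
    for t, y in enumerate(years):
        if y in drought_set:
            rw[:, t] *= m_drought
        elif last_drought is not None and 0 < y - last_drought <= params.recovery_window:
            rw[:, t] *= np.clip(m_recov, 0.05, None)

    rows: dict[str, np.ndarray] = {
        "tree": np.repeat(ids, ny),
        "year": np.tile(years, n),
        "RW": rw.ravel(),
    }
    for col, (trait, mu, res_sd) in params.anatomy_traits.items():
        base = np.full(n, mu) + (
            bvf.loc[ids, trait].to_numpy() if trait in bvf.columns else 0.0
        )
        tree_env = rng.normal(0.0, res_sd, size=n)
        yr_noise = rng.normal(
            0.0, params.anatomy_year_noise * res_sd, size=(n, ny)
        )
        vals = base[:, None] + tree_env[:, None] + yr_noise
        rows[col] = vals.ravel()
    rings = pd.DataFrame(rows)

    # static growth traits: genetic part from the (standardized) growth
    # breeding value, scaled so var(genetic)/(var(genetic)+res_sd^2) hits the
    # configured target heritability
    statics = {"tree": ids}
    h2s = params.static_h2 if np.any(z_gro != 0) else 0.0
    for col, (mu, res_sd) in params.static_traits.items():
        if h2s > 0:
            gen_sd = res_sd * np.sqrt(h2s / (1.0 - h2s))
            bv_part = z_gro * gen_sd
        else:
            bv_part = np.zeros(n)
        statics[col] = mu + bv_part + rng.normal(0.0, res_sd, size=n)
    statics = pd.DataFrame(statics)
    return rings, statics


def default_study_architecture(n_causal: int = 500) -> GeneticArchitecture:
    """Trait architecture mirroring the study's estimated genetic control.

    Heritabilities: resistance 0.22, recovery 0.15, growth 0.3 (BAI-like),
    lumen/wall/density 0.74/0.53/0.57; resistance-growth genetic correlation
    positive (0.55-like), density negatively correlated with growth.
    """
    traits = [
        "growth",
        "resistance",
        "recovery",
        "lumen_radial",
        "lumen_tangential",
        "wall_thickness",
        "density",
    ]
    h2 = [0.30, 0.22, 0.15, 0.74, 0.48, 0.53, 0.57]
    t = len(traits)
    Ra = np.eye(t)

    def set_r(a: str, b: str, r: float) -> None:
        i, j = traits.index(a), traits.index(b)
        Ra[i, j] = Ra[j, i] = r

    set_r("growth", "resistance", 0.55)
    set_r("growth", "recovery", 0.6)
    set_r("resistance", "recovery", 0.4)
    set_r("growth", "lumen_radial", 0.5)
    set_r("growth", "density", -0.5)
    set_r("lumen_radial", "lumen_tangential", 0.49)
    set_r("wall_thickness", "density", 0.7)
    set_r("lumen_radial", "density", -0.45)
    # nudge to the nearest PSD correlation matrix if needed
    w, v = np.linalg.eigh(Ra)
    if w.min() < 1e-8:
        w = np.clip(w, 1e-8, None)
        Ra = (v * w) @ v.T
        d = np.sqrt(np.diag(Ra))
        Ra = Ra / np.outer(d, d)
    # phenotypic variances on the measurement scales used by the ring simulator
    vp = [1.0, 1.0, 1.0, 2.0**2 / 0.48, 2.0**2 / 0.52, 0.25**2 / 0.47, 25.0**2 / 0.43]
    return GeneticArchitecture.from_targets(
        traits, h2, genetic_corr=Ra, residual_corr=0.1,
        phenotypic_var=vp, n_causal=n_causal,
    )
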