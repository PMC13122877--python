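"""Core data containers shared across the pipeline.

The analysis moves data through a small set of typed containers: a
:class:`Pedigree` encoding the mating design, a :class:`GenotypeMatrix` of
SNP dosages, a :class:`RelationshipMatrix` (pedigree-derived A or
marker-derived G), and the simulation ground-truth objects
(:class:`GeneticArchitecture`, :class:`TrueValues`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "GenotypeMatrix",
    "RelationshipMatrix",
    "GeneticArchitecture",
    "TrueValues",
    "PedigreeError",
]

UNKNOWN = "0"  # sentinel for an unknown parent in files and tables


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


@dataclass
class Pedigree:
    """A topologically ordered pedigree.

    Parameters
    ----------
    ids
        Individual labels, parents before offspring.
    sire, dam
        Parent labels aligned with ``ids``; ``"0"`` marks an unknown parent.
    generation
        0 for founders, >= 1 for progeny.
    """

    ids: list[str]
    sire: list[str]
    dam: list[str]
    generation: list[int]

    def __post_init__(self) -> None:
        n = len(self.ids)
        if not (len(self.sire) == len(self.dam) == len(self.generation) == n):
            raise PedigreeError("pedigree columns have unequal lengths")
        if len(set(self.ids)) != n:
            raise PedigreeError("duplicate individual ids in pedigree")
        pos = {iid: k for k, iid in enumerate(self.ids)}
        for k, (iid, s, d, g) in enumerate(
            zip(self.ids, self.sire, self.dam, self.generation)
        ):
            for p in (s, d):
                if p != UNKNOWN:
                    if p not in pos:
                        raise PedigreeError(f"parent {p!r} of {iid!r} not in pedigree")
                    if pos[p] >= k:
                        raise PedigreeError(
                            f"parent {p!r} listed after offspring {iid!r}"
                        )
            if g == 0 and (s != UNKNOWN or d != UNKNOWN):
                raise PedigreeError(f"founder {iid!r} has a recorded parent")
            if g > 0 and (s == UNKNOWN) != (d == UNKNOWN) is True:
                # allow single unknown parent only for user-supplied pedigrees;
                # the simulator always records both
                pass

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def founders(self) -> list[str]:
        return [i for i, g in zip(self.ids, self.generation) if g == 0]

    @property
    def progeny(self) -> list[str]:
        return [i for i, g in zip(self.ids, self.generation) if g > 0]

    def parent_indices(self) -> np.ndarray:
        """(n, 2) integer array of parent positions, -1 for unknown."""
        pos = {iid: k for k, iid in enumerate(self.ids)}
        out = np.full((len(self), 2), -1, dtype=np.int64)
        for k, (s, d) in enumerate(zip(self.sire, self.dam)):
            if s != UNKNOWN:
                out[k, 0] = pos[s]
            if d != UNKNOWN:
                out[k, 1] = pos[d]
        return out

    def families(self) -> dict[tuple[str, str], list[str]]:
        """Map unordered parent pair -> list of full-sib progeny ids."""
        fams: dict[tuple[str, str], list[str]] = {}
        for iid, s, d, g in zip(self.ids, self.sire, self.dam, self.generation):
            if g > 0 and s != UNKNOWN and d != UNKNOWN:
                key = tuple(sorted((s, d)))
                fams.setdefault(key, []).append(iid)
        return fams

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": self.sire,
                "dam": self.dam,
                "generation": self.generation,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        gen = (
            df["generation"].astype(int).tolist()
            if "generation" in df.columns
            else [
                0 if (s == UNKNOWN and d == UNKNOWN) else 1
                for s, d in zip(df["sire"].astype(str), df["dam"].astype(str))
            ]
        )
        return cls(
            ids=df["id"].astype(str).tolist(),
            sire=df["sire"].astype(str).tolist(),
            dam=df["dam"].astype(str).tolist(),
            generation=gen,
        )


@dataclass
class GenotypeMatrix:
    """SNP dosage matrix (individuals x SNPs), dosages in {0, 1, 2}, NaN missing."""

    ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray  # float array, NaN = missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.snp_ids)} SNPs"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per SNP from non-missing entries."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        snps = [s for s, k in zip(self.snp_ids, keep) if k]
        return GenotypeMatrix(self.ids, snps, self.dosages[:, keep])

    def subset_individuals(self, ids: list[str]) -> "GenotypeMatrix":
        pos = {iid: k for k, iid in enumerate(self.ids)}
        idx = [pos[i] for i in ids]
        return GenotypeMatrix(list(ids), self.snp_ids, self.dosages[idx, :])


@dataclass
class RelationshipMatrix:
    """Additive relationship matrix with labelled rows/columns.

    ``kind`` is ``"A"`` (pedigree), ``"G"`` (VanRaden genomic) or
    ``"G-tuned"`` (blended for invertibility). The diagonal entries are
    1 + F_i, with F_i the inbreeding coefficient of individual i.
    """

    kind: str
    ids: list[str]
    values: np.ndarray
    condition_number: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("relationship matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def inbreeding(self) -> np.ndarray:
        """F_i = diagonal - 1."""
        return np.diag(self.values) - 1.0

    def submatrix(self, ids: list[str]) -> "RelationshipMatrix":
        pos = {iid: k for k, iid in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids])
        return RelationshipMatrix(
            self.kind, list(ids), self.values[np.ix_(idx, idx)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class GeneticArchitecture:
    """Multi-trait additive architecture used as simulation ground truth.

    ``Sigma_a`` and ``Sigma_e`` are the additive-genetic and residual
    covariance matrices across traits; per-trait narrow-sense heritability is
    h2_t = Sigma_a[t, t] / (Sigma_a[t, t] + Sigma_e[t, t]).
    """

    trait_names: list[str]
    Sigma_a: np.ndarray
    Sigma_e: np.ndarray
    n_causal: int

    def __post_init__(self) -> None:
        t = len(self.trait_names)
        self.Sigma_a = np.atleast_2d(np.asarray(self.Sigma_a, dtype=float))
        self.Sigma_e = np.atleast_2d(np.asarray(self.Sigma_e, dtype=float))
        for name, m in (("Sigma_a", self.Sigma_a), ("Sigma_e", self.Sigma_e)):
            if m.shape != (t, t):
                raise ValueError(f"{name} must be {t}x{t}")
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
        if np.min(np.linalg.eigvalsh(self.Sigma_a)) < -1e-10:
            raise ValueError("Sigma_a is not positive semidefinite")

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def heritabilities(self) -> np.ndarray:
        va = np.diag(self.Sigma_a)
        ve = np.diag(self.Sigma_e)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(va + ve > 0, va / (va + ve), 0.0)

    @classmethod
    def from_targets(
        cls,
        trait_names: list[str],
        h2: list[float],
        genetic_corr: np.ndarray | float = 0.0,
        residual_corr: np.ndarray | float = 0.0,
        phenotypic_var: list[float] | None = None,
        n_causal: int = 500,
    ) -> "GeneticArchitecture":
        """Build covariances from target heritabilities and correlations."""
        t = len(trait_names)
        h2 = np.asarray(h2, dtype=float)
        if np.any((h2 < 0) | (h2 >= 1)):
            raise ValueError("target h2 must be in [0, 1)")
        vp = np.ones(t) if phenotypic_var is None else np.asarray(phenotypic_var)
        va = h2 * vp
        ve = (1.0 - h2) * vp
        Ra = cls._corr_matrix(genetic_corr, t)
        Re = cls._corr_matrix(residual_corr, t)
        sa = np.sqrt(va)
        se = np.sqrt(ve)
        return cls(
            trait_names=list(trait_names),
            Sigma_a=Ra * np.outer(sa, sa),
            Sigma_e=Re * np.outer(se, se),
            n_causal=n_causal,
        )

    @staticmethod
    def _corr_matrix(corr: np.ndarray | float, t: int) -> np.ndarray:
        if np.isscalar(corr):
            m = np.full((t, t), float(corr))
            np.fill_diagonal(m, 1.0)
            return m
        m = np.atleast_2d(np.asarray(corr, dtype=float))
        if m.shape != (t, t):
            raise ValueError("correlation matrix shape mismatch")
        if np.any(np.abs(m) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        return m


@dataclass
class TrueValues:
    """Simulation ground truth: true breeding values and causal SNP effects."""

    ids: list[str]
    trait_names: list[str]
    breeding_values: np.ndarray  # individuals x traits
    causal_effects: np.ndarray  # SNPs x traits (zeros for non-causal)
    causal_indices: np.ndarray = field(default_factory=lambda: np.array([], int))

    def bv_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.breeding_values, index=self.ids, columns=self.trait_names
        )

    def bv(self, trait: str) -> pd.Series:
        j = self.trait_names.index(trait)
        return pd.Series(self.breeding_values[:, j], index=self.ids, name=trait)
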