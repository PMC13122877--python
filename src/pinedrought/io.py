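"""File readers and writers for the pipeline's interchange formats.

Plain-text formats throughout: pedigree/phenotype/climate CSV, genotype TSV
(individuals x SNPs, 0/1/2/NA), a minimal GT-only VCF, Tucson-format .rwl
ring-width files (decadal layout, 0.01 mm units, 999 end marker; the
-9999/0.001 mm dialect is accepted on read), and labelled square CSV for
relationship matrices.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import UNKNOWN, GenotypeMatrix, Pedigree, RelationshipMatrix

__all__ = [
    "write_pedigree", "read_pedigree",
    "write_genotypes_tsv", "read_genotypes_tsv",
    "write_vcf", "read_vcf",
    "write_rwl", "read_rwl",
    "write_relationship", "read_relationship",
]


# -- pedigree ---------------------------------------------------------------

def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    ped.to_frame().to_csv(path, index=False)


def read_pedigree(path: str | Path) -> Pedigree:
    df = pd.read_csv(path, dtype=str)
    if "generation" in df.columns:
        df["generation"] = df["generation"].astype(int)
    df["sire"] = df["sire"].fillna(UNKNOWN)
    df["dam"] = df["dam"].fillna(UNKNOWN)
    return Pedigree.from_frame(df)


# -- genotypes --------------------------------------------------------------

def write_genotypes_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(geno.dosages, index=geno.ids, columns=geno.snp_ids)
    df.index.name = "id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return GenotypeMatrix(
        ids=[str(i) for i in df.index],
        snp_ids=[str(c) for c in df.columns],
        dosages=df.to_numpy(dtype=float),
    )


def write_vcf(geno: GenotypeMatrix, path: str | Path, chrom: str = "SIM") -> None:
    """Minimal diploid GT-only VCF; dosage 0/1/2 -> 0/0, 0/1, 1/1, NaN -> ./."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.ids)
            + "\n"
        )
        for j, snp in enumerate(geno.snp_ids):
            col = geno.dosages[:, j]
            gts = [
                gt_map.get(float(v), "./.") if np.isfinite(v) else "./."
                for v in col
            ]
            fh.write(
                f"{chrom}\t{j + 1}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a (possibly minimal) VCF into dosages via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = var.gt_types.astype(float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        rows.append(dos)
    return GenotypeMatrix(
        ids=ids, snp_ids=snp_ids, dosages=np.array(rows).T
    )


# -- Tucson .rwl ------------------------------------------------------------

def write_rwl(series: dict[str, pd.Series], path: str | Path) -> None:
    """Write ring-width series (mm, indexed by year) in decadal Tucson format.

    Values are stored in 0.01 mm; each series ends with the 999 marker.
    """
    with open(path, "w") as fh:
        for sid, s in series.items():
            s = s.sort_index()
            years = s.index.to_numpy(dtype=int)
            if np.any(np.diff(years) != 1):
                raise ValueError(f"series {sid!r} has non-contiguous years")
            vals = np.round(s.to_numpy(dtype=float) * 100.0).astype(int)
            tokens = list(zip(years, vals)) + [(years[-1] + 1, 999)]
            k = 0
            while k < len(tokens):
                year = tokens[k][0]
                decade_end = (year // 10) * 10 + 10
                row = []
                while k < len(tokens) and tokens[k][0] < decade_end:
                    row.append(tokens[k][1])
                    k += 1
                fh.write(
                    f"{sid:<8s}{year:4d}" + "".join(f"{v:6d}" for v in row) + "\n"
                )


def read_rwl(path: str | Path) -> dict[str, pd.Series]:
    """Read a decadal Tucson .rwl file into per-series mm ring widths.

    Both stop-marker dialects are handled: 999 (values in 0.01 mm) and
    -9999 (values in 0.001 mm). Duplicate series ids raise.
    """
    raw: dict[str, list[tuple[int, int]]] = {}
    closed: set[str] = set()
    marker: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            sid = line[:8].strip()
            try:
                year = int(line[8:12])
            except ValueError:
                continue  # header line
            if sid in closed:
                raise ValueError(f"duplicate/overlapping series id {sid!r}")
            vals = raw.setdefault(sid, [])
            body = line[12:].rstrip("\n")
            on_line = 0  # values consumed on this line: year = line year + offset
            for pos in range(0, len(body), 6):
                tok = body[pos : pos + 6].strip()
                if not tok:
                    continue
                v = int(tok)
                if v in (999, -9999):
                    closed.add(sid)
                    marker[sid] = v
                    break
                vals.append((year + on_line, v))
                on_line += 1
    out: dict[str, pd.Series] = {}
    for sid, vals in raw.items():
        if not vals:
            continue
        years = [y for y, _ in vals]
        scale = 1000.0 if marker.get(sid) == -9999 else 100.0
        out[sid] = pd.Series(
            [v / scale for _, v in vals], index=years, name=sid
        )
    if not out:
        warnings.warn(f"no ring series found in {path}", stacklevel=2)
    return out


# -- relationship matrices --------------------------------------------------

def write_relationship(rel: RelationshipMatrix, path: str | Path) -> None:
    df = rel.to_frame()
    df.index.name = f"kind={rel.kind}"
    df.to_csv(path, float_format="%.8g")


def read_relationship(path: str | Path, kind: str | None = None) -> RelationshipMatrix:
    df = pd.read_csv(path, index_col=0)
    k = kind or (df.index.name or "kind=A").split("=", 1)[-1]
    return RelationshipMatrix(
        kind=k, ids=[str(c) for c in df.columns], values=df.to_numpy(dtype=float)
    )
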