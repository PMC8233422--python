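"""Readers and writers for the pipeline's exchange formats.

Dialects: pedigree CSV (animal,sire,dam; 0 = unknown), PLINK RAW dosage
matrix + PLINK MAP, phenotype CSV, gene models as GFF3 (1-based closed) or
BED (0-based half-open) — both normalised to the internal 1-based closed
convention — gene sets as GMT, and a 1-based lower-triangle coordinate text
format for symmetric sparse matrices (the dialect common BLUP tooling
expects). Every reader raises line-numbered errors on malformed input, and
(write then read) is the identity for every structure the package emits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .qc import GenotypeMatrix, snp_map_frame
from .relationships import Pedigree

__all__ = [
    "write_pedigree",
    "read_pedigree",
    "write_plink_raw",
    "read_plink_raw",
    "write_plink_map",
    "read_plink_map",
    "write_phenotypes",
    "read_phenotypes",
    "write_bed",
    "read_bed",
    "write_gff3",
    "read_gff3",
    "write_gmt",
    "read_gmt",
    "write_coord_matrix",
    "read_coord_matrix",
]

_FLOAT_FMT = "%.10g"


# --------------------------------------------------------------------------
# pedigree


def write_pedigree(ped: Pedigree, path) -> None:
    df = pd.DataFrame(
        {
            "animal": np.arange(1, ped.n_animals + 1),
            "sire": ped.sire,
            "dam": ped.dam,
        }
    )
    if ped.generation is not None:
        df["generation"] = ped.generation
    if ped.sex is not None:
        df["sex"] = ped.sex
    df.to_csv(path, index=False)


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path)
    for col in ("animal", "sire", "dam"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing pedigree column {col!r}")
    if not np.array_equal(df["animal"].to_numpy(), np.arange(1, len(df) + 1)):
        raise ValueError(f"{path}: animals must be numbered consecutively from 1")
    return Pedigree(
        sire=df["sire"].to_numpy(),
        dam=df["dam"].to_numpy(),
        generation=df["generation"].to_numpy() if "generation" in df else None,
        sex=df["sex"].to_numpy() if "sex" in df else None,
    )


# --------------------------------------------------------------------------
# PLINK RAW / MAP


def write_plink_raw(genotypes: GenotypeMatrix, path) -> None:
    """PLINK --recode A dialect: FID IID PAT MAT SEX PHENOTYPE then SNP_A."""
    header = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"] + [
        f"{s}_A" for s in genotypes.snp_ids
    ]
    with open(path, "w") as fh:
        fh.write(" ".join(header) + "\n")
        for i, aid in enumerate(genotypes.animal_ids):
            row = genotypes.dosages[i]
            calls = " ".join("NA" if np.isnan(v) else str(int(v)) for v in row)
            fh.write(f"0 {aid} 0 0 0 -9 {calls}\n")


def read_plink_raw(path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        if header[:6] != ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]:
            raise ValueError(f"{path}:1: not a PLINK RAW header")
        snp_ids = [c[:-2] if c.endswith("_A") else c for c in header[6:]]
        animals: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + len(snp_ids):
                raise ValueError(
                    f"{path}:{lineno}: expected {6 + len(snp_ids)} fields, got {len(parts)}"
                )
            animals.append(parts[1])
            try:
                rows.append(
                    np.array(
                        [np.nan if v == "NA" else float(v) for v in parts[6:]],
                        dtype=np.float64,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad dosage value ({exc})") from None
    ids: np.ndarray = np.array(animals)
    try:  # animal ids are integers when written by the simulator
        ids = ids.astype(np.int64)
    except ValueError:
        pass
    return GenotypeMatrix(ids, np.array(snp_ids), np.vstack(rows))


def write_plink_map(snp_map: pd.DataFrame, path) -> None:
    """PLINK MAP: chromosome, SNP id, genetic distance (0), bp position."""
    out = pd.DataFrame(
        {
            "chromosome": snp_map["chromosome"],
            "snp_id": snp_map["snp_id"],
            "cm": 0,
            "position_bp": snp_map["position_bp"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_plink_map(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chromosome", "snp_id", "cm", "position_bp"],
        dtype={"chromosome": str, "snp_id": str},
    )
    if df.isna().any().any():
        raise ValueError(f"{path}: malformed MAP file")
    return snp_map_frame(df["snp_id"], df["chromosome"], df["position_bp"])


# --------------------------------------------------------------------------
# phenotypes


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("animal_id", "service_sire", "y"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing phenotype column {col!r}")
    for col in ("dim_class", "uterine_disease", "year_season", "breed_type"):
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    return df


# --------------------------------------------------------------------------
# gene models (internal convention: 1-based closed start_bp/end_bp)


def write_bed(genes: pd.DataFrame, path) -> None:
    """BED is 0-based half-open: start-1, end."""
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            score = 0
            fh.write(
                f"{row.chromosome}\t{int(row.start_bp) - 1}\t{int(row.end_bp)}\t"
                f"{row.gene_id}\t{score}\t{row.strand}\n"
            )


def read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: BED needs >= 4 columns")
            try:
                start0, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from None
            if start0 < 0 or end <= start0:
                raise ValueError(f"{path}:{lineno}: invalid BED interval")
            strand = parts[5] if len(parts) > 5 else "+"
            rows.append((parts[3], parts[0], start0 + 1, end, strand))
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start_bp", "end_bp", "strand"])


def write_gff3(genes: pd.DataFrame, path, source: str = "liabscan") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            attrs = f"ID={row.gene_id};Name={row.gene_id}"
            fh.write(
                f"{row.chromosome}\t{source}\tgene\t{int(row.start_bp)}\t{int(row.end_bp)}"
                f"\t.\t{row.strand}\t.\t{attrs}\n"
            )


def read_gff3(path, feature_type: str = "gene") -> pd.DataFrame:
    """Gene models from GFF3 via gffutils (1-based closed, as GFF3 itself)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        gid = feat.attributes.get("ID", [feat.id])[0]
        rows.append((gid, feat.seqid, feat.start, feat.end, feat.strand or "+"))
    if not rows:
        raise ValueError(f"{path}: no {feature_type!r} features found")
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start_bp", "end_bp", "strand"])


# --------------------------------------------------------------------------
# gene sets (GMT)


def write_gmt(collection: dict[str, tuple[str, frozenset]], path) -> None:
    with open(path, "w") as fh:
        for term_id in sorted(collection):
            name, members = collection[term_id]
            fh.write("\t".join([term_id, name] + sorted(members)) + "\n")


def read_gmt(path) -> dict[str, tuple[str, frozenset]]:
    collection: dict[str, tuple[str, frozenset]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs term, description and >= 1 gene"
                )
            term_id, name = parts[0], parts[1]
            if term_id in collection:
                raise ValueError(f"{path}:{lineno}: duplicate term {term_id!r}")
            collection[term_id] = (name, frozenset(g for g in parts[2:] if g))
    return collection


# --------------------------------------------------------------------------
# symmetric sparse matrices as coordinate text


def write_coord_matrix(matrix: sp.spmatrix, path) -> None:
    """1-based (i, j, value) rows, lower triangle only, i >= j."""
    coo = sp.coo_matrix(sp.triu(matrix).T)  # lower triangle via transpose of upper
    order = np.lexsort((coo.col, coo.row))
    with open(path, "w") as fh:
        fh.write(f"% symmetric {matrix.shape[0]} {matrix.shape[1]}\n")
        for i, j, v in zip(coo.row[order] + 1, coo.col[order] + 1, coo.data[order]):
            fh.write(f"{i} {j} {_FLOAT_FMT % v}\n")


def read_coord_matrix(path) -> sp.csr_matrix:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 4 or header[0] != "%" or header[1] != "symmetric":
            raise ValueError(f"{path}:1: expected '% symmetric n m' header")
        n, m = int(header[2]), int(header[3])
        rows, cols, vals = [], [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'i j value'")
            try:
                i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed coordinate entry") from None
            if i < j:
                raise ValueError(f"{path}:{lineno}: upper-triangle entry in lower-triangle file")
            rows.append(i - 1)
            cols.append(j - 1)
            vals.append(v)
            if i != j:
                rows.append(j - 1)
                cols.append(i - 1)
                vals.append(v)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, m)).tocsr()
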