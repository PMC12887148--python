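"""File readers and writers.

Formats: pedigree/phenotype/report CSV, genotypes as whitespace text in the
BLUPF90 dialect (id then an unseparated 0/1/2 string, 5 = missing) or the
PLINK RAW dialect (header row, space-separated 0/1/2 with NA missing), and
relationship matrices as MatrixMarket text with a plain-text id sidecar.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import GenotypeMatrix, PedigreeTable, UNKNOWN_PARENT
from .errors import DataError

PED_COLUMNS = ["id", "sire", "dam", "birth_date", "sex", "farm"]


def read_pedigree(path) -> PedigreeTable:
    """Pedigree CSV with header id,sire,dam[,birth_date,sex,farm]; 0 = unknown.

    Parents that appear only in the sire/dam columns are appended as
    founder records. Self-parenting and unparseable dates raise DataError
    with the offending line number.
    """
    df = pd.read_csv(path)
    missing = {"id", "sire", "dam"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing column(s) {sorted(missing)}")
    for col in ("id", "sire", "dam"):
        try:
            df[col] = df[col].astype(np.int64)
        except (ValueError, TypeError) as e:
            raise DataError(f"{path}: non-integer value in {col!r}: {e}") from None
    for i, rec in df.iterrows():
        if rec["id"] in (rec["sire"], rec["dam"]):
            raise DataError(f"{path} line {i + 2}: animal {rec['id']} is its own parent")
    if "birth_date" in df.columns:
        try:
            df["birth_date"] = pd.to_datetime(df["birth_date"], format="mixed")
        except (ValueError, TypeError):
            bad = pd.to_datetime(df["birth_date"], errors="coerce", format="mixed").isna()
            line = int(np.flatnonzero(bad)[0]) + 2
            raise DataError(f"{path} line {line}: unparseable birth_date") from None

    known = set(df["id"])
    extra = sorted(
        (set(df["sire"]) | set(df["dam"])) - known - {UNKNOWN_PARENT}
    )
    if extra:
        pad = pd.DataFrame({"id": extra, "sire": UNKNOWN_PARENT, "dam": UNKNOWN_PARENT})
        if "birth_date" in df.columns:
            pad["birth_date"] = df["birth_date"].min() - pd.Timedelta(days=365)
        for col in df.columns:
            if col not in pad.columns:
                pad[col] = pd.NA
        df = pd.concat([pad[df.columns], df], ignore_index=True)
    return PedigreeTable(df)


def write_pedigree(ped: PedigreeTable, path) -> None:
    df = ped.df.copy()
    if "birth_date" in df.columns:
        df["birth_date"] = pd.to_datetime(df["birth_date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def read_genotypes(path, dialect: str = "blupf90", snp_map: pd.DataFrame | None = None,
                   pedigree: PedigreeTable | None = None,
                   on_unknown_id: str = "warn") -> GenotypeMatrix:
    """Read a genotype matrix; codes 0/1/2, missing 5 (blupf90) or NA (plink_raw).

    With a pedigree given, ids absent from it are excluded with a warning
    (``on_unknown_id='error'`` raises instead).
    """
    ids, rows = [], []
    if dialect == "blupf90":
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                parts = line.split()
                if not parts:
                    continue
                if len(parts) != 2:
                    raise DataError(f"{path} line {ln}: expected 'id genotypes'")
                ids.append(parts[0])
                row = np.array([int(c) for c in parts[1]], dtype=float)
                if not np.isin(row, (0, 1, 2, 5)).all():
                    raise DataError(f"{path} line {ln}: illegal genotype code")
                row[row == 5] = np.nan
                rows.append(row)
    elif dialect == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+")
        lead = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")
                if c in df.columns]
        if "IID" not in df.columns:
            raise DataError(f"{path}: PLINK RAW file needs an IID column")
        snp_cols = [c for c in df.columns if c not in lead]
        ids = df["IID"].tolist()
        rows = [pd.to_numeric(df[c], errors="coerce").to_numpy() for c in snp_cols]
        rows = list(np.array(rows).T)
        if snp_map is None:
            snp_map = pd.DataFrame({
                "snp": [c.rsplit("_", 1)[0] for c in snp_cols],
                "chrom": 1, "pos": np.arange(1, len(snp_cols) + 1),
            })
    else:
        raise DataError(f"unknown genotype dialect {dialect!r}")

    lens = {len(r) for r in rows}
    if len(lens) > 1:
        raise DataError(f"{path}: ragged genotype rows (lengths {sorted(lens)})")
    mat = np.vstack(rows) if rows else np.zeros((0, 0))
    try:
        ids_arr = np.array([int(i) for i in ids])
    except ValueError:
        ids_arr = np.array(ids)
    g = GenotypeMatrix(ids=ids_arr, matrix=mat, snp_map=snp_map)
    if pedigree is not None:
        known = np.isin(g.ids, pedigree.ids)
        if not known.all():
            msg = f"{(~known).sum()} genotyped id(s) absent from pedigree"
            if on_unknown_id == "error":
                raise DataError(msg)
            import warnings
            warnings.warn(msg + "; excluded")
            g = g.subset(animal_mask=known)
    return g


def write_genotypes(geno: GenotypeMatrix, path, dialect: str = "blupf90") -> None:
    if dialect == "blupf90":
        with open(path, "w") as fh:
            for i, a in enumerate(geno.ids):
                row = geno.matrix[i]
                s = "".join("5" if np.isnan(v) else str(int(v)) for v in row)
                fh.write(f"{a} {s}\n")
    elif dialect == "plink_raw":
        cols = [f"{s}_A" for s in geno.snp_map["snp"]]
        df = pd.DataFrame(geno.matrix, columns=cols)
        df.insert(0, "PHENOTYPE", -9)
        df.insert(0, "SEX", 0)
        df.insert(0, "MAT", 0)
        df.insert(0, "PAT", 0)
        df.insert(0, "IID", geno.ids)
        df.insert(0, "FID", geno.ids)
        df.to_csv(path, sep=" ", index=False, na_rep="NA",
                  float_format="%.0f")
    else:
        raise DataError(f"unknown genotype dialect {dialect!r}")


def write_snp_map(geno: GenotypeMatrix, path) -> None:
    geno.snp_map.to_csv(path, index=False)


def read_snp_map(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "animal" not in df.columns:
        raise DataError(f"{path}: phenotype CSV needs an 'animal' column")
    return df


def write_phenotypes(phen: pd.DataFrame, path) -> None:
    phen.to_csv(path, index=False)


def save_matrix(mat, ids, path) -> None:
    """Persist a relationship matrix as MatrixMarket text plus an id sidecar
    (``<path>.ids``, one animal id per line, row order)."""
    m = sp.coo_matrix(mat) if sp.issparse(mat) else np.asarray(mat)
    scipy.io.mmwrite(os.fspath(path), m)
    with open(f"{os.fspath(path)}.ids", "w") as fh:
        fh.writelines(f"{a}\n" for a in ids)


def load_matrix(path):
    """Inverse of :func:`save_matrix`; returns (matrix, ids). Sparse inputs
    come back sparse CSR, dense arrays dense."""
    m = scipy.io.mmread(os.fspath(path))
    with open(f"{os.fspath(path)}.ids") as fh:
        ids = np.array([int(line.strip()) for line in fh if line.strip()])
    if sp.issparse(m):
        m = m.tocsr()
    else:
        m = np.asarray(m)
    return m, ids
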