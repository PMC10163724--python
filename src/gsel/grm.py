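"""Relationship matrices: the four genomic constructions and pedigree A.

Four GRM normalizations are supported, crossing two choices:

* divisor pooled over markers ("S...") versus per-marker ("I...");
* marker variance assumed from Hardy-Weinberg proportions 2p(1-p)
  ("...P") versus the empirical ("true") genotype variance
  Var* = p1 + 4 p2 - (p1 + 2 p2)^2 ("...V").

SP is VanRaden's classical matrix Z Z' / sum(2p(1-p)) with Z = M - 2p;
IP is the GCTA-style matrix Z D Z' with D_ii = 1/(m 2p_i(1-p_i));
SV and IV replace both the column mean (p1 + 2 p2) and the variance by
their empirical counterparts, which removes the bias the HWE assumption
introduces in populations under selection, inbreeding or drift.  For IV,
trace(G)/n = 1 holds exactly because each standardized column has unit
population variance.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import (
    GenotypeMatrix,
    MarkerFrequencies,
    center_matrix,
    genotype_frequencies,
    mean_impute,
)

GRM_METHODS = ("SP", "IP", "SV", "IV")


@dataclasses.dataclass
class RelationshipMatrix:
    """Symmetric animal x animal kinship with its construction tag."""

    values: np.ndarray
    ids: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.ids = np.asarray(self.ids, dtype=object)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape inconsistent with ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, animal_ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.ids)}
        try:
            return np.array([lookup[a] for a in animal_ids], dtype=np.intp)
        except KeyError as err:
            raise KeyError(f"animal {err.args[0]!r} absent from relationship matrix")


def marker_variance(freqs: MarkerFrequencies, convention: str = "TRUE") -> np.ndarray:
    """Per-marker genotype variance under the HWE or the empirical convention.

    HWE returns 2p(1-p); TRUE returns p1 + 4 p2 - (p1 + 2 p2)^2, the
    population (divide-by-n) variance of the dosage column.  The two are
    equal whenever genotype frequencies sit at HWE proportions.
    """
    if convention.upper() == "HWE":
        return 2.0 * freqs.p * (1.0 - freqs.p)
    if convention.upper() == "TRUE":
        mean = freqs.p1 + 2.0 * freqs.p2
        return freqs.p1 + 4.0 * freqs.p2 - mean**2
    raise ValueError("convention must be 'HWE' or 'TRUE'")


def build_grm(
    geno: GenotypeMatrix | np.ndarray,
    method: str = "IV",
    freqs: MarkerFrequencies | None = None,
    ids=None,
) -> RelationshipMatrix:
    """Build one of the four genomic relationship matrices.

    Accepts either a :class:`GenotypeMatrix` (frequencies computed and
    missing cells mean-imputed internally) or an already-imputed dosage
    array plus explicit `freqs`/`ids`.
    """
    method = method.upper()
    if method not in GRM_METHODS:
        raise ValueError(f"method must be one of {GRM_METHODS}, got {method!r}")
    if isinstance(geno, GenotypeMatrix):
        freqs = freqs or genotype_frequencies(geno)
        matrix = mean_impute(geno, freqs)
        ids = geno.animal_ids
    else:
        if freqs is None or ids is None:
            raise ValueError("raw-matrix input requires freqs and ids")
        matrix = np.asarray(geno, dtype=np.float64)

    convention = "HWE" if method.endswith("P") else "TRUE"
    var = marker_variance(freqs, convention)
    if np.any(var <= 0) or np.any(~np.isfinite(var)):
        n_bad = int(np.sum(~(var > 0)))
        raise ValueError(
            f"{n_bad} markers have zero variance under the {convention} "
            "convention; run qc_filter before building a GRM"
        )
    centering = "hwe" if convention == "HWE" else "observed"
    z = center_matrix(matrix, freqs, centering)
    m = z.shape[1]
    if method.startswith("S"):
        g = (z @ z.T) / var.sum()
    else:
        g = (z / np.sqrt(m * var)) @ (z / np.sqrt(m * var)).T
    g = 0.5 * (g + g.T)
    return RelationshipMatrix(g, ids, method)


def regularize(rel: RelationshipMatrix, epsilon: float = 0.01) -> RelationshipMatrix:
    """Shrink toward the identity: (1 - eps) G + eps I, guaranteeing an
    invertible matrix for the mixed-model equations."""
    if not 0.0 < epsilon < 1.0:
        raise ValueError(f"epsilon must lie in (0, 1), got {epsilon}")
    n = rel.n
    values = (1.0 - epsilon) * rel.values + epsilon * np.eye(n)
    return RelationshipMatrix(values, rel.ids, rel.method)


# ---------------------------------------------------------------------------
# Pedigree numerator relationship matrix


class Pedigree:
    """Three-column pedigree (id, sire, dam); unknown parents are None/0.

    Construction topologically sorts the records and rejects cycles and
    self-parenting.
    """

    def __init__(self, records: pd.DataFrame):
        df = records.copy()
        df.columns = ["id", "sire", "dam"]
        for col in df.columns:
            df[col] = df[col].astype(object)
        unknown = {None, "0", 0, "", np.nan}
        df["sire"] = df["sire"].map(lambda x: None if x in unknown or pd.isna(x) else x)
        df["dam"] = df["dam"].map(lambda x: None if x in unknown or pd.isna(x) else x)
        if df["id"].duplicated().any():
            raise ValueError("duplicate animal ids in pedigree")
        for _, row in df.iterrows():
            if row["id"] in (row["sire"], row["dam"]):
                raise ValueError(f"animal {row['id']!r} is its own parent")
        # implicit founders: parents that never appear as an id
        ids = set(df["id"])
        parents = {p for p in pd.concat([df["sire"], df["dam"]]) if p is not None}
        for p in sorted(parents - ids, key=str):
            df = pd.concat(
                [pd.DataFrame([{"id": p, "sire": None, "dam": None}]), df],
                ignore_index=True,
            )
        self.records = self._toposort(df)

    @staticmethod
    def _toposort(df: pd.DataFrame) -> pd.DataFrame:
        order: list[int] = []
        placed: set = set()
        pending = list(df.index)
        while pending:
            progressed = False
            remaining = []
            for idx in pending:
                sire, dam = df.at[idx, "sire"], df.at[idx, "dam"]
                if (sire is None or sire in placed) and (dam is None or dam in placed):
                    order.append(idx)
                    placed.add(df.at[idx, "id"])
                    progressed = True
                else:
                    remaining.append(idx)
            if not progressed:
                raise ValueError("pedigree contains a cycle")
            pending = remaining
        return df.loc[order].reset_index(drop=True)

    @property
    def ids(self) -> np.ndarray:
        return self.records["id"].to_numpy(dtype=object)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Pedigree":
        df = pd.read_csv(path, sep="\t", dtype=object, comment="#")
        return cls(df.iloc[:, :3])

    def to_tsv(self, path: str | Path) -> None:
        out = self.records.fillna("0")
        out.to_csv(path, sep="\t", index=False)


def build_numerator_A(ped: Pedigree) -> RelationshipMatrix:
    """Additive (numerator) relationship matrix by the tabular method.

    Founders get diagonal 1; unknown parents are treated as unrelated
    founders.  O(n^2), adequate for pedigrees of a few thousand animals.
    """
    ids = ped.ids
    pos = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    sire_ix = np.full(n, -1, dtype=np.intp)
    dam_ix = np.full(n, -1, dtype=np.intp)
    for i, (_, row) in enumerate(ped.records.iterrows()):
        if row["sire"] is not None:
            sire_ix[i] = pos[row["sire"]]
        if row["dam"] is not None:
            dam_ix[i] = pos[row["dam"]]
    a = np.zeros((n, n))
    for i in range(n):
        s, d = sire_ix[i], dam_ix[i]
        f_i = 0.5 * a[s, d] if (s >= 0 and d >= 0) else 0.0
        a[i, i] = 1.0 + f_i
        for j in range(i):
            val = 0.0
            if s >= 0:
                val += 0.5 * a[j, s]
            if d >= 0:
                val += 0.5 * a[j, d]
            a[i, j] = a[j, i] = val
    return RelationshipMatrix(a, ids, "PEDIGREE_A")


# ---------------------------------------------------------------------------
# GCTA binary GRM format and plain TSV


def write_gcta_grm(rel: RelationshipMatrix, prefix: str | Path, n_markers: int = 0) -> None:
    """Write .grm.bin/.grm.N.bin/.grm.id (float32 lower triangle, row-major)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = rel.n
    tri = rel.values[np.tril_indices(n)].astype(np.float32)
    tri.tofile(str(prefix) + ".grm.bin")
    np.full(tri.shape, float(n_markers), dtype=np.float32).tofile(
        str(prefix) + ".grm.N.bin"
    )
    pd.DataFrame({"fid": rel.ids, "iid": rel.ids}).to_csv(
        str(prefix) + ".grm.id", sep="\t", header=False, index=False
    )


def read_gcta_grm(prefix: str | Path, method: str = "SP") -> RelationshipMatrix:
    prefix = str(prefix)
    ids = pd.read_csv(prefix + ".grm.id", sep=r"\s+", header=None)[1].to_numpy(
        dtype=object
    )
    n = len(ids)
    tri = np.fromfile(prefix + ".grm.bin", dtype=np.float32).astype(np.float64)
    if len(tri) != n * (n + 1) // 2:
        raise ValueError("GRM binary size inconsistent with id file")
    values = np.zeros((n, n))
    values[np.tril_indices(n)] = tri
    values = values + np.tril(values, -1).T
    return RelationshipMatrix(values, ids, method)


def write_grm_tsv(rel: RelationshipMatrix, path: str | Path) -> None:
    pd.DataFrame(rel.values, index=rel.ids, columns=rel.ids).to_csv(path, sep="\t")


def read_grm_tsv(path: str | Path, method: str = "SP") -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RelationshipMatrix(df.to_numpy(), df.index.to_numpy(dtype=object), method)
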