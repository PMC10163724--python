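"""Genotype container, quality control, allele/genotype frequencies, imputation, centering.

Dosages count copies of the A1 allele of the ``.bim`` allele pair, coded
0/1/2 with ``-1`` for missing.  All genomic relationship matrices and the
Bayesian regressions are built on top of this module.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

_NON_AUTOSOMES = {"X", "Y", "XY", "MT", "M", "Z", "W", "0"}


@dataclasses.dataclass
class GenotypeMatrix:
    """Animals x markers dosage matrix with a marker map.

    Parameters
    ----------
    dosages : ndarray of int8, shape (n_animals, n_markers)
        Allele dosages in {0, 1, 2}; ``-1`` marks a missing call.
    animal_ids : ndarray of str
        Unique animal identifiers, one per row.
    markers : DataFrame
        One row per column of `dosages` with columns
        ``marker_id, chrom, pos, a1, a2``; sorted by (chrom, pos).
    """

    dosages: np.ndarray
    animal_ids: np.ndarray
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (animals x markers)")
        n, m = self.dosages.shape
        if len(self.animal_ids) != n:
            raise ValueError(f"{len(self.animal_ids)} animal ids for {n} rows")
        if len(self.markers) != m:
            raise ValueError(f"{len(self.markers)} marker records for {m} columns")
        if len(set(self.animal_ids)) != n:
            raise ValueError("animal ids are not unique")
        if self.markers["marker_id"].duplicated().any():
            raise ValueError("marker ids are not unique")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages contain codes outside {0,1,2,missing}")
        if (self.markers["pos"].to_numpy() < 0).any():
            raise ValueError("marker positions must be non-negative")
        self.markers = self.markers.reset_index(drop=True)

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def sorted_by_position(self) -> "GenotypeMatrix":
        """Return a copy with markers sorted by (chromosome, position)."""
        order = self.markers.sort_values(
            ["chrom", "pos"], kind="mergesort"
        ).index.to_numpy()
        return GenotypeMatrix(
            self.dosages[:, order],
            self.animal_ids.copy(),
            self.markers.iloc[order].reset_index(drop=True),
        )

    def subset(self, animals=None, markers=None) -> "GenotypeMatrix":
        """Subset by integer row/column indices (either may be None)."""
        a = np.arange(self.n_animals) if animals is None else np.asarray(animals)
        m = np.arange(self.n_markers) if markers is None else np.asarray(markers)
        return GenotypeMatrix(
            self.dosages[np.ix_(a, m)],
            self.animal_ids[a],
            self.markers.iloc[m].reset_index(drop=True),
        )


@dataclasses.dataclass
class MarkerFrequencies:
    """Per-marker allele and genotype frequencies over non-missing calls.

    ``p`` is the A1-allele frequency, ``p1``/``p2`` the frequencies of the
    heterozygote and the A1 homozygote; the identity p = 0.5*p1 + p2 holds
    by construction.  Markers with zero calls have NaN frequencies and are
    flagged in ``undefined``.
    """

    p: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    call_rate: np.ndarray
    undefined: np.ndarray

    @property
    def maf(self) -> np.ndarray:
        return np.minimum(self.p, 1.0 - self.p)


@dataclasses.dataclass
class QCThresholds:
    maf_min: float = 0.05
    marker_call_rate_min: float = 0.9
    animal_missing_max: float = 0.10
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        for name in ("maf_min", "marker_call_rate_min", "animal_missing_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def genotype_frequencies(geno: GenotypeMatrix) -> MarkerFrequencies:
    """Compute p, p1, p2 and call rate per marker over non-missing calls."""
    d = geno.dosages
    observed = d != MISSING
    n_obs = observed.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(n_obs > 0, (d == 1).sum(axis=0) / n_obs, np.nan)
        p2 = np.where(n_obs > 0, (d == 2).sum(axis=0) / n_obs, np.nan)
    p = 0.5 * p1 + p2
    call_rate = n_obs / d.shape[0]
    return MarkerFrequencies(
        p=p, p1=p1, p2=p2, call_rate=call_rate, undefined=n_obs == 0
    )


def qc_filter(
    geno: GenotypeMatrix, thr: QCThresholds | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply marker/animal quality control.

    Animals with too many missing calls are removed first; marker
    frequencies are then recomputed on the survivors before the MAF and
    call-rate filters (PLINK's conventional order).  Returns the filtered
    matrix and a report with one row per rule.
    """
    thr = thr or QCThresholds()
    d = geno.dosages
    miss_frac = (d == MISSING).mean(axis=1)
    keep_animals = np.flatnonzero(miss_frac <= thr.animal_missing_max)
    n_animals_removed = geno.n_animals - len(keep_animals)
    geno = geno.subset(animals=keep_animals)

    chrom = geno.markers["chrom"].astype(str).str.upper().to_numpy()
    autosomal = ~np.isin(chrom, sorted(_NON_AUTOSOMES))
    n_nonauto = 0
    if thr.autosomes_only:
        n_nonauto = int((~autosomal).sum())
        geno = geno.subset(markers=np.flatnonzero(autosomal))

    freqs = genotype_frequencies(geno)
    with np.errstate(invalid="ignore"):
        low_maf = freqs.undefined | (freqs.maf < thr.maf_min)
        low_cr = freqs.call_rate < thr.marker_call_rate_min
    n_maf = int(low_maf.sum())
    n_cr = int((low_cr & ~low_maf).sum())
    keep_markers = np.flatnonzero(~(low_maf | low_cr))
    if len(keep_markers) == 0:
        raise ValueError("quality control removed every marker")
    geno = geno.subset(markers=keep_markers)

    report = pd.DataFrame(
        {
            "rule": [
                "animal_missingness",
                "non_autosomal",
                "low_maf",
                "low_call_rate",
            ],
            "count_removed": [n_animals_removed, n_nonauto, n_maf, n_cr],
        }
    )
    return geno, report


def mean_impute(
    geno: GenotypeMatrix, freqs: MarkerFrequencies | None = None
) -> np.ndarray:
    """Replace missing dosages by the marker mean 2p; returns float64 matrix."""
    freqs = freqs if freqs is not None else genotype_frequencies(geno)
    if freqs.undefined.any():
        bad = geno.markers["marker_id"][freqs.undefined].tolist()
        raise ValueError(f"cannot impute markers with zero calls: {bad[:5]}")
    out = geno.dosages.astype(np.float64)
    miss = geno.dosages == MISSING
    if miss.any():
        fill = np.broadcast_to(2.0 * freqs.p, out.shape)
        out[miss] = fill[miss]
    return out


def center_matrix(
    matrix: np.ndarray,
    freqs: MarkerFrequencies,
    convention: str = "hwe",
) -> np.ndarray:
    """Column-center an imputed dosage matrix.

    ``"hwe"`` subtracts the Hardy-Weinberg mean 2p (the classical Z);
    ``"observed"`` subtracts the empirical mean p1 + 2*p2 (used by the
    true-variance relationship matrices).  The two coincide exactly at HWE
    genotype proportions.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.shape[1] != len(freqs.p):
        raise ValueError(
            f"matrix has {matrix.shape[1]} columns but {len(freqs.p)} marker frequencies"
        )
    if convention == "hwe":
        mu = 2.0 * freqs.p
    elif convention == "observed":
        mu = freqs.p1 + 2.0 * freqs.p2
    else:
        raise ValueError("convention must be 'hwe' or 'observed'")
    return matrix - mu


# ---------------------------------------------------------------------------
# PLINK binary and TSV dosage IO


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK .bed/.bim/.fam fileset (SNP-major .bed only)."""
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype=str,
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "marker_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "marker_id": str, "a1": str, "a2": str},
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:2].tobytes() != b"\x6c\x1b":
        raise ValueError(f"{prefix}.bed: bad magic bytes")
    if raw[2] != 0x01:
        raise ValueError(f"{prefix}.bed: not SNP-major")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:].reshape(m, bytes_per_snp)
    # 2-bit codes per individual: 00 hom A1, 10 het, 11 hom A2, 01 missing
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (body[:, :, None] >> shifts) & 0b11          # (m, bytes, 4)
    codes = codes.reshape(m, -1)[:, :n]
    lut = np.array([2, MISSING, 1, 0], dtype=np.int8)    # A1 dosage
    dosages = lut[codes].T
    markers = bim[["marker_id", "chrom", "pos", "a1", "a2"]].copy()
    markers["pos"] = markers["pos"].astype(np.int64)
    geno = GenotypeMatrix(dosages, fam["iid"].to_numpy(dtype=object), markers)
    return geno.sorted_by_position()


def write_plink(geno: GenotypeMatrix, prefix: str | Path) -> None:
    """Write .bed (SNP-major) plus .bim/.fam companions."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = geno.n_animals, geno.n_markers
    fam = pd.DataFrame(
        {
            "fid": geno.animal_ids,
            "iid": geno.animal_ids,
            "father": "0",
            "mother": "0",
            "sex": "0",
            "pheno": "-9",
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    bim = geno.markers.copy()
    bim["cm"] = 0
    bim[["chrom", "marker_id", "cm", "pos", "a1", "a2"]].to_csv(
        prefix.with_suffix(".bim"), sep="\t", header=False, index=False
    )
    inv = np.array([3, 2, 0], dtype=np.uint8)            # dosage -> 2-bit code
    codes = np.where(geno.dosages == MISSING, 1, inv[np.maximum(geno.dosages, 0)])
    pad = (-n) % 4
    if pad:
        codes = np.vstack([codes, np.zeros((pad, m), dtype=np.uint8)])
    codes = codes.T.reshape(m, -1, 4).astype(np.uint8)
    packed = (
        codes[:, :, 0]
        | (codes[:, :, 1] << 2)
        | (codes[:, :, 2] << 4)
        | (codes[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(b"\x6c\x1b\x01")
        packed.tofile(fh)


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    """Read the plain TSV dosage format: header row of marker ids, first
    column animal id, cells in {0,1,2,NA}.  Marker map defaults to one
    chromosome with positions in column order (useful for fixtures)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    dosages = df.to_numpy(dtype=float)
    dosages = np.where(np.isnan(dosages), MISSING, dosages).astype(np.int8)
    markers = pd.DataFrame(
        {
            "marker_id": df.columns.astype(str),
            "chrom": "1",
            "pos": np.arange(len(df.columns), dtype=np.int64),
            "a1": "A",
            "a2": "B",
        }
    )
    return GenotypeMatrix(dosages, df.index.to_numpy(dtype=object), markers)


def write_dosage_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        np.where(geno.dosages == MISSING, np.nan, geno.dosages),
        index=pd.Index(geno.animal_ids, name="animal_id"),
        columns=geno.markers["marker_id"],
    )
    df.to_csv(path, sep="\t", na_rep="NA")
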