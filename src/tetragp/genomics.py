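"""Allele-dosage matrices and the additive genomic relationship matrix (GRM)
for autotetraploids.

In a tetraploid, a biallelic SNP genotype is summarised by its allele
*dosage*: the integer count of the alternative allele, 0-4. Entering dosages
linearly into a relationship matrix corresponds to a purely additive model of
marker effects. The GRM here is the VanRaden-style matrix generalised to
ploidy ``k``:

    Z = M - k * p          (column-centred dosages)
    G = Z Z' / (k * sum_m p_m (1 - p_m))

where ``p_m`` is the allele frequency of marker ``m``. At ploidy 2 this is
exactly VanRaden method 1; the denominator is the summed binomial dosage
variance, so diag(G) averages ~1 for unrelated individuals in
Hardy-Weinberg-like equilibrium.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DosageMatrix",
    "GenomicRelationship",
    "DosageError",
    "read_dosages",
    "write_dosages",
    "allele_frequencies",
    "compute_grm",
    "write_grm",
    "read_grm",
]


class DosageError(ValueError):
    """Raised for malformed or out-of-range dosage inputs."""


@dataclass
class DosageMatrix:
    """Genotype × marker table of integer allele dosages.

    Missing entries are encoded as NaN in ``dosages`` (kept float for that
    reason) and flagged in ``missing_mask``.
    """

    genotype_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray  # (n_genotypes, n_markers), float with NaN = missing
    ploidy: int = 4

    missing_mask: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise DosageError("dosage matrix must be 2-dimensional")
        n, m = self.dosages.shape
        if n == 0 or m == 0:
            raise DosageError("dosage matrix has an empty dimension")
        if len(self.genotype_ids) != n or len(self.marker_ids) != m:
            raise DosageError("ID lists do not match matrix shape")
        if len(set(self.genotype_ids)) != n:
            raise DosageError("duplicate genotype IDs")
        if self.ploidy < 1:
            raise DosageError(f"invalid ploidy {self.ploidy}")
        self.missing_mask = np.isnan(self.dosages)
        obs = self.dosages[~self.missing_mask]
        if obs.size:
            bad = (obs < 0) | (obs > self.ploidy)
            if bad.any():
                rows, cols = np.where(
                    ~self.missing_mask
                    & ((self.dosages < 0) | (self.dosages > self.ploidy))
                )
                i, j = int(rows[0]), int(cols[0])
                raise DosageError(
                    f"dosage {self.dosages[i, j]:g} out of range [0, {self.ploidy}] "
                    f"at genotype {self.genotype_ids[i]!r}, marker {self.marker_ids[j]!r}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosages.shape

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    @property
    def n_non_integer(self) -> int:
        obs = self.dosages[~self.missing_mask]
        return int(np.sum(obs != np.round(obs)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=self.genotype_ids, columns=self.marker_ids
        )


@dataclass
class GenomicRelationship:
    """Symmetric additive genomic relationship matrix with its normalisation."""

    genotype_ids: list[str]
    G: np.ndarray
    normalization_constant: float

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        asym = np.max(np.abs(self.G - self.G.T))
        if asym > 1e-10:
            raise ValueError(f"G is not symmetric (max asymmetry {asym:g})")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.G, index=self.genotype_ids, columns=self.genotype_ids)

    def subset(self, ids: list[str]) -> np.ndarray:
        """Return the sub-matrix of G for ``ids`` (order preserved)."""
        pos = {g: i for i, g in enumerate(self.genotype_ids)}
        idx = np.array([pos[g] for g in ids])
        return self.G[np.ix_(idx, idx)]


def read_dosages(path: str | Path, ploidy: int = 4) -> DosageMatrix:
    """Read a dosage CSV/TSV: genotype rows, marker columns, header required.

    The delimiter (comma or tab) is sniffed from the header line. Empty cells
    and the token ``NA`` are treated as missing.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", "na", ""])
    if df.shape[1] == 0:
        raise DosageError(f"{path}: no marker columns found")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise DosageError(f"{path}: non-numeric dosage entry ({exc})") from exc
    return DosageMatrix(
        genotype_ids=[str(g) for g in df.index],
        marker_ids=[str(m) for m in df.columns],
        dosages=values,
        ploidy=ploidy,
    )


def write_dosages(dm: DosageMatrix, path: str | Path) -> None:
    frame = dm.to_frame()
    # preserve integer look where nothing is missing
    if dm.n_missing == 0:
        frame = frame.astype(int)
    frame.to_csv(path, index_label="genotype_id")


def allele_frequencies(dm: DosageMatrix) -> np.ndarray:
    """Per-marker alternative-allele frequency p_m = mean(dosage) / ploidy.

    Computed over non-missing entries; a marker with no observed entries is
    an error (its frequency is undefined).
    """
    all_missing = dm.missing_mask.all(axis=0)
    if all_missing.any():
        bad = [dm.marker_ids[j] for j in np.where(all_missing)[0][:10]]
        raise DosageError(f"markers with all dosages missing: {bad}")
    return np.nanmean(dm.dosages, axis=0) / dm.ploidy


def compute_grm(
    dm: DosageMatrix,
    min_maf: float = 0.0,
    impute_policy: str = "mean",
    ridge: float = 0.0,
) -> GenomicRelationship:
    """Additive GRM from allele dosages.

    Parameters
    ----------
    min_maf
        Markers with minor-allele frequency below this are dropped before
        centring. Default 0 (no filtering; upstream pipelines usually filter).
    impute_policy
        ``"mean"`` replaces missing dosages with ``ploidy * p_m`` (the
        population mean) before centring; ``"zero_center"`` sets the centred
        value to zero, which is the same thing. Anything else raises.
    ridge
        Optional multiple of the mean diagonal added to diag(G) to guarantee
        strict positive definiteness for downstream factorisations.
    """
    if impute_policy not in ("mean", "zero_center"):
        raise ValueError(f"unknown impute_policy {impute_policy!r}")
    p = allele_frequencies(dm)
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= min_maf
    if not keep.any():
        raise DosageError("no markers left after MAF filtering")
    M = dm.dosages[:, keep]
    pk = p[keep]
    Z = M - dm.ploidy * pk[None, :]
    Z[np.isnan(Z)] = 0.0  # mean imputation == zero after centring
    denom = dm.ploidy * float(np.sum(pk * (1.0 - pk)))
    if denom <= 0.0:
        raise DosageError(
            "zero normalisation constant: all retained markers are monomorphic"
        )
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)
    if ridge > 0.0:
        G = G + ridge * float(np.mean(np.diag(G))) * np.eye(G.shape[0])
    return GenomicRelationship(
        genotype_ids=list(dm.genotype_ids), G=G, normalization_constant=denom
    )


def write_grm(gr: GenomicRelationship, path: str | Path) -> None:
    gr.to_frame().to_csv(path, index_label="genotype_id")


def read_grm(path: str | Path) -> GenomicRelationship:
    df = pd.read_csv(path, index_col=0)
    return GenomicRelationship(
        genotype_ids=[str(g) for g in df.index],
        G=df.to_numpy(dtype=float),
        normalization_constant=float("nan"),
    )


def content_hash(*paths: str | Path) -> str:
    """Short content hash of input files, for cache keys in the pipeline."""
    h = hashlib.sha256()
    for p in paths:
        h.update(Path(p).read_bytes())
    return h.hexdigest()[:16]
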