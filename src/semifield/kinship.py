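"""Marker data handling and the genomic additive relationship matrix.

Markers are allele dosages (counts of the alternate allele, 0/1/2) for a
set of lines. The relationship matrix follows VanRaden's first method:
with ``p_j`` the observed alternate-allele frequency of marker ``j`` and
``Z = M - 2P`` the column-centred dosage matrix,

    G = Z Z' / (2 * sum_j p_j * (1 - p_j)).

Allele frequencies are computed from the study lines themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerDataError",
    "DegeneratePanelError",
    "MarkerMatrix",
    "GenomicRelationship",
    "load_markers",
    "write_markers",
    "impute_and_filter",
    "vanraden_g",
    "write_g",
    "load_g",
]


class MarkerDataError(ValueError):
    """Malformed or inconsistent marker input."""


class DegeneratePanelError(ValueError):
    """Marker panel carries no usable polymorphism."""


@dataclass
class MarkerMatrix:
    """Lines x markers allele-dosage matrix.

    Attributes
    ----------
    line_ids : list of str
        Unique line identifiers, one per row of ``dosages``.
    dosages : ndarray of float, shape (n_lines, n_markers)
        Dosage of the alternate allele; entries in {0, 1, 2} or NaN for
        missing.
    marker_ids : list of str
        Marker identifiers, one per column.
    """

    line_ids: list
    dosages: np.ndarray
    marker_ids: list
    #: strict matrices hold raw calls in {0,1,2}; imputed ones any value in [0,2]
    strict: bool = True

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.line_ids = list(self.line_ids)
        self.marker_ids = list(self.marker_ids)
        if self.dosages.ndim != 2:
            raise MarkerDataError("dosages must be a 2-D matrix")
        n, m = self.dosages.shape
        if len(self.line_ids) != n:
            raise MarkerDataError(f"{len(self.line_ids)} line ids for {n} dosage rows")
        if len(self.marker_ids) != m:
            raise MarkerDataError(f"{len(self.marker_ids)} marker ids for {m} dosage columns")
        if m < 1:
            raise MarkerDataError("need at least one marker")
        if len(set(self.line_ids)) != n:
            dups = sorted({x for x in self.line_ids if self.line_ids.count(x) > 1})
            raise MarkerDataError(f"duplicate line ids: {dups}")
        if self.strict:
            bad = ~(np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0)))
        else:
            bad = ~(np.isnan(self.dosages)
                    | ((self.dosages >= 0.0) & (self.dosages <= 2.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MarkerDataError(
                f"dosage {self.dosages[i, j]!r} at line {self.line_ids[i]!r}, "
                f"marker {self.marker_ids[j]!r} is not "
                + ("0/1/2/missing" if self.strict else "within [0, 2]")
            )

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())

    def allele_frequencies(self) -> np.ndarray:
        """Observed alternate-allele frequency per marker (missing skipped)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=pd.Index(self.line_ids, name="line"),
                            columns=self.marker_ids)


@dataclass
class GenomicRelationship:
    """Genomic additive relationship matrix over a fixed line order."""

    G: np.ndarray
    line_ids: list
    mean_diagonal: float = field(init=False)

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=float)
        self.line_ids = list(self.line_ids)
        if self.G.shape != (len(self.line_ids),) * 2:
            raise ValueError("G shape does not match line ids")
        if not np.allclose(self.G, self.G.T, atol=1e-10 * (1 + np.abs(self.G).max())):
            raise ValueError("G is not symmetric")
        self.mean_diagonal = float(np.mean(np.diag(self.G)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.G, index=pd.Index(self.line_ids, name="line"),
                            columns=self.line_ids)


def load_markers(path, sep=None) -> MarkerMatrix:
    """Read a marker table: first column line id, remaining columns dosages.

    ``sep=None`` sniffs comma vs. tab from the header line. Empty cells
    and the token ``NA`` are treated as missing. PLINK ``.raw`` additive
    exports are accepted by passing ``sep=" "`` and are detected by their
    FID/IID leading columns.
    """
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype={0: str}, na_values=["NA", "na", ""])
    cols = list(df.columns)
    if cols[:2] == ["FID", "IID"]:  # PLINK .raw additive coding
        ids = df["IID"].astype(str).tolist()
        drop = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in cols]
        body = df.drop(columns=drop)
    else:
        ids = df.iloc[:, 0].astype(str).tolist()
        body = df.iloc[:, 1:]
    if len(set(ids)) != len(ids):
        dups = sorted({x for x in ids if ids.count(x) > 1})
        raise MarkerDataError(f"duplicate line ids in {path}: {dups}")
    dosages = body.to_numpy(dtype=float)
    bad = ~(np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise MarkerDataError(
            f"{path}: dosage {dosages[i, j]!r} at row {ids[i]!r}, column "
            f"{body.columns[j]!r} is not 0/1/2/missing"
        )
    return MarkerMatrix(ids, dosages, list(body.columns))


def write_markers(m: MarkerMatrix, path, sep=",") -> None:
    m.to_frame().to_csv(path, sep=sep)


def impute_and_filter(m: MarkerMatrix, drop_monomorphic: bool = True) -> MarkerMatrix:
    """Mean-impute missing dosages; optionally drop zero-variance markers.

    Missing entries are replaced by the marker's mean observed dosage,
    which preserves the allele-frequency estimate. Marker order is
    preserved.
    """
    d = m.dosages.copy()
    col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
    # markers with no observed calls cannot be imputed meaningfully -> treat as monomorphic at 0
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    miss = np.isnan(d)
    d[miss] = np.broadcast_to(col_mean, d.shape)[miss]
    keep = np.ones(d.shape[1], dtype=bool)
    if drop_monomorphic:
        keep = d.std(axis=0) > 0
        if not keep.any():
            raise DegeneratePanelError("all markers are monomorphic after imputation")
    ids = [mid for mid, k in zip(m.marker_ids, keep) if k]
    return MarkerMatrix(m.line_ids, d[:, keep], ids, strict=False)


def vanraden_g(m: MarkerMatrix, ridge: float = 0.0) -> GenomicRelationship:
    """Build G = ZZ'/(2*sum p(1-p)) from a complete dosage matrix.

    Parameters
    ----------
    m : MarkerMatrix
        Must contain no missing entries (run :func:`impute_and_filter`).
    ridge : float
        Optional epsilon added to the diagonal for downstream solver
        stability (default 0: no blending).
    """
    if m.has_missing:
        raise MarkerDataError("missing dosages present; impute before building G")
    p = m.allele_frequencies()
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise DegeneratePanelError("all markers monomorphic: VanRaden denominator is zero")
    Z = m.dosages - 2.0 * p[None, :]
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)
    if ridge:
        G = G + ridge * np.eye(G.shape[0])
    return GenomicRelationship(G, m.line_ids)


def write_g(g: GenomicRelationship, path) -> None:
    g.to_frame().to_csv(path)


def load_g(path) -> GenomicRelationship:
    df = pd.read_csv(path, index_col=0)
    return GenomicRelationship(df.to_numpy(dtype=float), [str(x) for x in df.index])
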