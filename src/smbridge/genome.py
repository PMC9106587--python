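"""Genomic containers: interval sets (BED convention) and binned contact matrices.

Coordinates are 0-based, half-open throughout; a bin is labelled by its start
coordinate.  Contact matrices are per-chromosome, symmetric, nonnegative, and
optionally carry per-bin balancing weights from iterative correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class IntervalSet:
    """Records of (chrom, start, end), 0-based half-open, sorted within chrom."""

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    names: np.ndarray | None = None

    def __post_init__(self):
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValueError("chroms/starts/ends must have equal length")
        if np.any(self.starts >= self.ends):
            raise ValueError("intervals must satisfy start < end")
        # sort by (chrom, start)
        order = np.lexsort((self.starts, self.chroms.astype(str)))
        self.chroms = self.chroms[order]
        self.starts = self.starts[order]
        self.ends = self.ends[order]
        if self.names is not None:
            self.names = np.asarray(self.names, dtype=object)[order]

    def __len__(self) -> int:
        return len(self.starts)

    @classmethod
    def from_records(cls, records) -> "IntervalSet":
        records = list(records)
        if not records:
            return cls(np.array([], dtype=object), np.array([], dtype=np.int64),
                       np.array([], dtype=np.int64))
        chroms, starts, ends = zip(*[(r[0], r[1], r[2]) for r in records])
        return cls(np.array(chroms, dtype=object), np.array(starts), np.array(ends))

    def records(self):
        return list(zip(self.chroms.tolist(), self.starts.tolist(), self.ends.tolist()))

    def subset(self, mask: np.ndarray) -> "IntervalSet":
        names = self.names[mask] if self.names is not None else None
        return IntervalSet(self.chroms[mask], self.starts[mask], self.ends[mask], names)


def write_bed(intervals: IntervalSet, path) -> None:
    df = pd.DataFrame({"chrom": intervals.chroms, "start": intervals.starts,
                       "end": intervals.ends})
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> IntervalSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return IntervalSet(df["chrom"].to_numpy(dtype=object),
                       df["start"].to_numpy(), df["end"].to_numpy())


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts for one chromosome.

    ``matrix`` is dense float64; masked (zero-coverage) bins have all-zero
    rows and, once balanced, NaN bias entries.
    """

    chrom: str
    resolution: int
    matrix: np.ndarray
    balanced: bool = False
    bias: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, rtol=0, atol=1e-9):
            raise ValueError("contact matrix must be symmetric")
        if np.any(self.matrix < 0):
            raise ValueError("contact matrix must be nonnegative")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def coverage_mask(self) -> np.ndarray:
        """True for bins with any contact (usable bins)."""
        return self.matrix.sum(axis=0) > 0


def write_contacts_tsv(m: ContactMatrix, path) -> None:
    """Upper-triangle triplets `chrom bin_i bin_j count` with a #resolution header."""
    iu, ju = np.nonzero(np.triu(m.matrix))
    df = pd.DataFrame({"chrom": m.chrom, "bin_i": iu, "bin_j": ju,
                       "count": m.matrix[iu, ju]})
    with open(path, "w") as fh:
        fh.write(f"#resolution={m.resolution}\n")
        df.to_csv(fh, sep="\t", index=False, header=False, float_format="%.10g")


def read_contacts_tsv(path) -> ContactMatrix:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#resolution="):
            raise ValueError("missing #resolution sidecar header")
        resolution = int(header.split("=", 1)[1])
        df = pd.read_csv(fh, sep="\t", header=None,
                         names=["chrom", "bin_i", "bin_j", "count"])
    if df.empty:
        raise ValueError("empty contact file")
    chrom = str(df["chrom"].iloc[0])
    n = int(max(df["bin_i"].max(), df["bin_j"].max())) + 1
    mat = np.zeros((n, n))
    mat[df["bin_i"], df["bin_j"]] = df["count"]
    mat = np.triu(mat) + np.triu(mat, 1).T
    return ContactMatrix(chrom=chrom, resolution=resolution, matrix=mat)
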