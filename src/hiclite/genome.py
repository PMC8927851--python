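"""Genome binning: fixed-size bins over a set of chromosomes.

Bins are 0-based half-open intervals ``[k*B, (k+1)*B)``; the last bin of a
chromosome may be short.  A :class:`GenomeBins` object provides per-chromosome
bin counts, global bin offsets (so a whole genome can live in one matrix), and
coordinate <-> bin conversions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeBins", "read_chromsizes", "write_chromsizes"]


def read_chromsizes(path) -> dict[str, int]:
    """Read a UCSC two-column chrom.sizes file (chrom<TAB>length)."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1],
                     names=["chrom", "length"], comment="#")
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def write_chromsizes(chromsizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, length in chromsizes.items():
            fh.write(f"{name}\t{int(length)}\n")


@dataclass(frozen=True)
class GenomeBins:
    """Partition of a genome into fixed-size bins.

    Parameters
    ----------
    chromsizes
        Ordered mapping of chromosome name to length in bp.
    bin_size
        Bin width B in bp.
    """

    chromsizes: dict[str, int]
    bin_size: int
    _n_bins: dict[str, int] = field(init=False, repr=False)
    _offsets: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        n_bins, offsets, off = {}, {}, 0
        for name, length in self.chromsizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            n = int(np.ceil(length / self.bin_size))
            n_bins[name] = n
            offsets[name] = off
            off += n
        object.__setattr__(self, "_n_bins", n_bins)
        object.__setattr__(self, "_offsets", offsets)

    # -- sizes -------------------------------------------------------------
    @property
    def chrom_names(self) -> list[str]:
        return list(self.chromsizes)

    @property
    def n_bins_total(self) -> int:
        return sum(self._n_bins.values())

    def n_bins(self, chrom: str) -> int:
        return self._n_bins[chrom]

    def offset(self, chrom: str) -> int:
        """Global index of the chromosome's first bin."""
        return self._offsets[chrom]

    def chrom_slice(self, chrom: str) -> slice:
        off = self._offsets[chrom]
        return slice(off, off + self._n_bins[chrom])

    # -- conversions -------------------------------------------------------
    def bin_of(self, chrom: str, pos_1based: int | np.ndarray) -> np.ndarray:
        """Chromosome-local bin index of a 1-based position."""
        return (np.asarray(pos_1based, dtype=np.int64) - 1) // self.bin_size

    def global_bin(self, chrom: str, pos_1based) -> np.ndarray:
        return self.bin_of(chrom, pos_1based) + self._offsets[chrom]

    def bin_table(self) -> pd.DataFrame:
        """Bins table (chrom, start, end, binID) matching the triplet export."""
        rows = []
        for name, length in self.chromsizes.items():
            off = self._offsets[name]
            for k in range(self._n_bins[name]):
                rows.append((name, k * self.bin_size,
                             min((k + 1) * self.bin_size, length), off + k))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "binID"])

    def same_bins(self, other: "GenomeBins") -> bool:
        return (self.bin_size == other.bin_size
                and self.chromsizes == other.chromsizes)

    @classmethod
    def from_file(cls, path, bin_size: int) -> "GenomeBins":
        return cls(read_chromsizes(path), bin_size)
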