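"""Valid-pairs I/O.

The on-disk dialect is the HiC-Pro-style tab-separated text: one contact per
line, at least seven columns::

    read_id  chrom1  pos1  strand1  chrom2  pos2  strand2  [extra ignored]

Positions are 1-based bp; strands are ``+``/``-``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ValidPairs", "read_valid_pairs", "write_valid_pairs"]

_COLUMNS = ["read_id", "chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]


@dataclass
class ValidPairs:
    """A set of validated Hi-C contact records.

    ``df`` has columns read_id, chrom1, pos1, strand1, chrom2, pos2, strand2
    (positions 1-based).  ``n_skipped`` counts malformed / off-genome input
    lines discarded at parse time.
    """

    df: pd.DataFrame
    source: str = ""
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.df)

    @property
    def is_cis(self) -> np.ndarray:
        return (self.df["chrom1"] == self.df["chrom2"]).to_numpy()

    def subset(self, mask: np.ndarray) -> "ValidPairs":
        return ValidPairs(self.df.loc[mask].reset_index(drop=True),
                          source=self.source)


def read_valid_pairs(path, chromsizes: dict[str, int],
                     strict: bool = False) -> ValidPairs:
    """Parse a valid-pairs file, validating records against the genome.

    Records on unknown chromosomes or with out-of-range positions are skipped
    with a warning (``strict=True`` aborts instead).  Extra columns beyond the
    seventh are ignored.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=_COLUMNS, usecols=range(7),
                         dtype={"read_id": str, "chrom1": str, "strand1": str,
                                "chrom2": str, "strand2": str},
                         on_bad_lines="skip")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty valid-pairs file")
        return ValidPairs(pd.DataFrame(columns=_COLUMNS), source=str(path))

    n_in = len(df)
    df = df.dropna(subset=_COLUMNS)
    pos1 = pd.to_numeric(df["pos1"], errors="coerce")
    pos2 = pd.to_numeric(df["pos2"], errors="coerce")
    df = df.assign(pos1=pos1, pos2=pos2).dropna(subset=["pos1", "pos2"])

    len1 = df["chrom1"].map(chromsizes)
    len2 = df["chrom2"].map(chromsizes)
    ok = (len1.notna() & len2.notna()
          & (df["pos1"] >= 1) & (df["pos1"] <= len1.fillna(0))
          & (df["pos2"] >= 1) & (df["pos2"] <= len2.fillna(0)))
    n_skipped = n_in - int(ok.sum())
    if n_skipped:
        msg = f"{path}: skipped {n_skipped} malformed/off-genome record(s)"
        if strict:
            raise ValueError(msg)
        logger.warning(msg)
    df = df.loc[ok].reset_index(drop=True)
    df["pos1"] = df["pos1"].astype(np.int64)
    df["pos2"] = df["pos2"].astype(np.int64)
    if df.empty:
        warnings.warn(f"{path}: no valid records parsed")
    return ValidPairs(df, source=str(path), n_skipped=n_skipped)


def write_valid_pairs(pairs: ValidPairs, path) -> None:
    pairs.df.to_csv(path, sep="\t", header=False, index=False)
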