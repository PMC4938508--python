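"""Binary disorder calls, IDR extraction and predictor-overlap tables.

An IDR is a maximal run of at least ``min_len`` (default 30) consecutive
residues called disordered.  A protein with at least one IDR is labeled
IDP, otherwise FOP (fully ordered protein).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._util import round_half_up
from .predict import ScoreTrack

DEFAULT_MIN_IDR_LEN = 30

IDP = "IDP"
FOP = "FOP"

IDR_COLUMNS = ("protein_id", "start", "end", "length", "predictor")


@dataclass(frozen=True)
class IDRInterval:
    """A maximal disordered stretch, 1-based inclusive."""

    protein_id: str
    start: int
    end: int
    predictor: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"bad IDR interval [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def binarize(track: ScoreTrack) -> np.ndarray:
    """Per-residue disorder calls (True = disordered).

    Higher-is-disordered tracks call disorder at ``score >= threshold``;
    lower-is-disordered tracks at ``score < threshold``.
    """
    if track.higher_is_disordered:
        return track.scores >= track.threshold
    return track.scores < track.threshold


def call_idrs(
    calls: np.ndarray | Iterable[bool],
    min_len: int = DEFAULT_MIN_IDR_LEN,
    protein_id: str = "",
    predictor: str = "",
) -> list[IDRInterval]:
    """Extract maximal True-runs of length >= min_len, in order."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    arr = np.asarray(list(calls), dtype=bool)
    out: list[IDRInterval] = []
    # run-length encode via change points
    padded = np.concatenate(([False], arr, [False]))
    diffs = np.flatnonzero(padded[1:] != padded[:-1])
    for lo, hi in zip(diffs[::2], diffs[1::2]):
        if hi - lo >= min_len:
            out.append(
                IDRInterval(
                    protein_id=protein_id,
                    start=int(lo) + 1,
                    end=int(hi),
                    predictor=predictor,
                )
            )
    return out


def idrs_from_track(
    track: ScoreTrack, min_len: int = DEFAULT_MIN_IDR_LEN
) -> list[IDRInterval]:
    return call_idrs(
        binarize(track),
        min_len=min_len,
        protein_id=track.protein_id,
        predictor=track.predictor,
    )


def classify_idp(idrs: Iterable[IDRInterval]) -> str:
    """IDP iff the protein has at least one qualifying IDR."""
    return IDP if any(True for _ in idrs) else FOP


def inclusion_table(datasets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Pairwise overlap of per-predictor IDP sets.

    For every unordered pair, percent inclusion is
    ``100 * |A ∩ B| / min(|A|, |B|)`` rounded half-up to 2 decimals.
    The ``pair`` column orients the names so the larger set comes with
    '>' (ties broken lexicographically).  Pairs whose smaller set is
    empty are flagged and carry NaN.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two predictors")
    rows = []
    for a, b in combinations(datasets, 2):
        sa, sb = datasets[a], datasets[b]
        na, nb = len(sa), len(sb)
        inter = len(sa & sb)
        if na > nb or (na == nb and a < b):
            pair = f"{a} > {b}" if na != nb else f"{a} < {b}"
        else:
            pair = f"{a} < {b}"
        smaller = min(na, nb)
        flagged = smaller == 0
        pct = float("nan") if flagged else round_half_up(100.0 * inter / smaller, 2)
        rows.append(
            {
                "pair": pair,
                "predictor_a": a,
                "predictor_b": b,
                "n_a": na,
                "n_b": nb,
                "n_intersection": inter,
                "pct_inclusion": pct,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)


def write_idrs(idrs: Iterable[IDRInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(IDR_COLUMNS) + "\n")
        for iv in idrs:
            fh.write(
                f"{iv.protein_id}\t{iv.start}\t{iv.end}\t{iv.length}\t"
                f"{iv.predictor}\n"
            )


def read_idrs(path: str | Path) -> list[IDRInterval]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    return [
        IDRInterval(
            protein_id=str(r.protein_id),
            start=int(r.start),
            end=int(r.end),
            predictor="" if pd.isna(r.predictor) else str(r.predictor),
        )
        for r in df.itertuples()
    ]
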