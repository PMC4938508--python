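"""Sequence and feature-table I/O.

Sequences travel as FASTA; topology features (membrane-spanning segments
and sided topological domains) travel as a flat TSV with UniProt-style
1-based inclusive coordinates.  All coordinates stay 1-based inclusive
throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import round_half_up

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Residues accepted in input sequences; X is kept but excluded from
#: composition statistics downstream.
ALLOWED_AA = set(STANDARD_AA) | {"X"}

TRANSMEM = "TRANSMEM"
TOPO_DOM = "TOPO_DOM"
FEATURE_KINDS = {TRANSMEM, TOPO_DOM}
TOPO_LABELS = {"Cytoplasmic", "Extracellular", "Lumenal"}

SINGLE_PASS = "single-pass"
MULTI_PASS = "multi-pass"
UNANNOTATED = "unannotated"

FEATURE_COLUMNS = ("protein_id", "kind", "start", "end", "label")


class FeatureError(ValueError):
    """Raised for malformed or inconsistent feature annotations."""


@dataclass(frozen=True)
class FeatureInterval:
    """One annotated interval, 1-based inclusive.

    ``label`` is required for TOPO_DOM (one of Cytoplasmic,
    Extracellular, Lumenal) and must be empty for TRANSMEM.
    """

    kind: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise FeatureError(f"unknown feature kind {self.kind!r}")
        if self.start < 1 or self.start > self.end:
            raise FeatureError(
                f"bad interval [{self.start}, {self.end}] (1-based inclusive)"
            )
        if self.kind == TOPO_DOM:
            if self.label not in TOPO_LABELS:
                raise FeatureError(f"bad TOPO_DOM label {self.label!r}")
        elif self.label:
            raise FeatureError("TRANSMEM features carry no label")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ProteinRecord:
    """A protein sequence plus its attached feature intervals."""

    id: str
    sequence: str
    features: list[FeatureInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - ALLOWED_AA
        if bad:
            warnings.warn(
                f"{self.id}: non-standard residues {sorted(bad)} kept but "
                "excluded from composition statistics",
                stacklevel=2,
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def transmem(self) -> list[FeatureInterval]:
        return sorted(
            (f for f in self.features if f.kind == TRANSMEM),
            key=lambda f: f.start,
        )

    def topo_dom(self) -> list[FeatureInterval]:
        return sorted(
            (f for f in self.features if f.kind == TOPO_DOM),
            key=lambda f: f.start,
        )

    def attach_features(self, intervals: Iterable[FeatureInterval]) -> None:
        """Attach intervals, enforcing bounds and TRANSMEM disjointness."""
        for iv in intervals:
            if iv.end > self.length:
                raise FeatureError(
                    f"{self.id}: feature [{iv.start}, {iv.end}] exceeds "
                    f"length {self.length}"
                )
            self.features.append(iv)
        tms = self.transmem()
        for a, b in zip(tms, tms[1:]):
            if b.start <= a.end:
                raise FeatureError(
                    f"{self.id}: overlapping TRANSMEM features "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into records (features empty, order preserved).

    The header token up to the first whitespace is the id; duplicate ids
    and empty sequences are hard errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA id {entry.id!r}")
        seen.add(entry.id)
        records.append(ProteinRecord(id=entry.id, sequence=str(entry.seq)))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def read_features(path: str | Path) -> dict[str, list[FeatureInterval]]:
    """Read the feature TSV into ``{protein_id: [FeatureInterval, ...]}``.

    Expected header: ``protein_id  kind  start  end  label``; the label
    column may be empty for TRANSMEM rows.  Errors carry line numbers.
    """
    out: dict[str, list[FeatureInterval]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[:4]) != FEATURE_COLUMNS[:4]:
            raise FeatureError(
                f"{path}: expected header {FEATURE_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise FeatureError(f"{path}:{lineno}: too few columns")
            pid, kind, start_s, end_s = parts[:4]
            label = parts[4].strip() if len(parts) > 4 else ""
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FeatureError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            try:
                iv = FeatureInterval(kind=kind, start=start, end=end, label=label)
            except FeatureError as exc:
                raise FeatureError(f"{path}:{lineno}: {exc}") from exc
            out.setdefault(pid, []).append(iv)
    return out


def write_features(
    features: dict[str, list[FeatureInterval]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(FEATURE_COLUMNS) + "\n")
        for pid in features:
            for iv in features[pid]:
                fh.write(
                    f"{pid}\t{iv.kind}\t{iv.start}\t{iv.end}\t{iv.label}\n"
                )


def attach_all(
    records: list[ProteinRecord], features: dict[str, list[FeatureInterval]]
) -> list[ProteinRecord]:
    """Attach parsed feature intervals to their records in place."""
    by_id = {r.id: r for r in records}
    for pid, ivs in features.items():
        if pid not in by_id:
            raise FeatureError(f"features reference unknown protein {pid!r}")
        by_id[pid].attach_features(ivs)
    return records


def classify_pass_type(record: ProteinRecord) -> str:
    """Single-pass (1 TM segment), multi-pass (>= 2) or unannotated (0)."""
    n = len(record.transmem())
    if n == 0:
        return UNANNOTATED
    return SINGLE_PASS if n == 1 else MULTI_PASS


def pass_type_summary(records: Iterable[ProteinRecord]):
    """Counts and percentages (1 decimal, half-up) per pass type."""
    import pandas as pd

    counts = {SINGLE_PASS: 0, MULTI_PASS: 0, UNANNOTATED: 0}
    for r in records:
        counts[classify_pass_type(r)] += 1
    total = sum(counts.values())
    rows = [
        {
            "pass_type": k,
            "n": v,
            "pct": round_half_up(100.0 * v / total, 1) if total else float("nan"),
        }
        for k, v in counts.items()
    ]
    return pd.DataFrame(rows)


def topology_coverage(records: Iterable[ProteinRecord]) -> float:
    """Percent of proteins carrying topology annotation (2 decimals).

    A protein counts as annotated if it has at least one TOPO_DOM
    feature.
    """
    records = list(records)
    if not records:
        raise ValueError("empty dataset")
    n_annot = sum(1 for r in records if r.topo_dom())
    return round_half_up(100.0 * n_annot / len(records), 2)
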