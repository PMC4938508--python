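"""Topology models, side localization and side/occupancy statistics.

A topology model partitions a sequence into Cytoplasmic, Extracellular,
TM and Unknown segments.  Loops whose side is not annotated are
inferred, where possible, from the annotated loops by alternation
across TM segments; Lumenal annotations count as Extracellular.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .idr import IDRInterval
from .io import (
    MULTI_PASS,
    FeatureError,
    ProteinRecord,
    classify_pass_type,
)

CYTOPLASMIC = "Cytoplasmic"
EXTRACELLULAR = "Extracellular"
TM = "TM"
UNKNOWN = "Unknown"
AMBIGUOUS = "Ambiguous"

_FLIP = {CYTOPLASMIC: EXTRACELLULAR, EXTRACELLULAR: CYTOPLASMIC}


@dataclass(frozen=True)
class Segment:
    start: int
    end: int
    side: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TopologyModel:
    """Ordered, disjoint segments jointly covering [1, L]."""

    protein_id: str
    segments: list[Segment]

    @property
    def length(self) -> int:
        return self.segments[-1].end

    def side_array(self) -> np.ndarray:
        """Per-residue side labels, index 0 = residue 1."""
        out = np.empty(self.length, dtype=object)
        for seg in self.segments:
            out[seg.start - 1 : seg.end] = seg.side
        return out

    def side_residues(self, side: str) -> int:
        return sum(s.length for s in self.segments if s.side == side)

    def loops(self) -> list[Segment]:
        return [s for s in self.segments if s.side != TM]


@dataclass(frozen=True)
class SideAssignment:
    """Majority-side call for an interval (IDR, MoRF or single site)."""

    protein_id: str
    start: int
    end: int
    side: str
    overlap_fraction: float


def _loop_regions(tms: list, length: int) -> list[tuple[int, int]]:
    """Maximal non-TM regions of [1, L], in order (may be empty list)."""
    loops = []
    prev_end = 0
    for tm in tms:
        if tm.start > prev_end + 1:
            loops.append((prev_end + 1, tm.start - 1))
        prev_end = tm.end
    if prev_end < length:
        loops.append((prev_end + 1, length))
    return loops


def build_topology(record: ProteinRecord) -> TopologyModel:
    """Build the per-protein topology model from attached features.

    Each annotated loop takes the side of its TOPO_DOM label(s); the
    remaining loops are inferred by strict alternation across TM
    segments when at least one loop side is known, else left Unknown.
    Conflicting annotations (same side on both flanks of one TM, or two
    different labels in one loop) are hard errors.
    """
    tms = record.transmem()
    loops = _loop_regions(tms, record.length)

    # index loops by parity; a missing N-terminal loop still occupies slot 0
    offset = 1 if tms and tms[0].start == 1 else 0
    loop_sides: dict[int, str] = {}
    for dom in record.topo_dom():
        for tm in tms:
            if dom.start <= tm.end and tm.start <= dom.end:
                raise FeatureError(
                    f"{record.id}: TOPO_DOM [{dom.start},{dom.end}] overlaps "
                    f"TRANSMEM [{tm.start},{tm.end}]"
                )
        side = EXTRACELLULAR if dom.label == "Lumenal" else dom.label
        for i, (lo, hi) in enumerate(loops):
            if lo <= dom.start and dom.end <= hi:
                slot = i + offset
                if loop_sides.get(slot, side) != side:
                    raise FeatureError(
                        f"{record.id}: conflicting TOPO_DOM labels in loop "
                        f"[{lo},{hi}]"
                    )
                loop_sides[slot] = side
                break
        else:
            raise FeatureError(
                f"{record.id}: TOPO_DOM [{dom.start},{dom.end}] does not fall "
                "within a single non-TM region"
            )

    # alternation: even/odd slots take opposite sides
    inferred: dict[int, str] = {}
    if loop_sides:
        anchor_slot = min(loop_sides)
        anchor_side = loop_sides[anchor_slot]
        for i in range(len(loops) + offset):
            same_parity = (i - anchor_slot) % 2 == 0
            side = anchor_side if same_parity else _FLIP[anchor_side]
            if i in loop_sides and loop_sides[i] != side:
                raise FeatureError(
                    f"{record.id}: TOPO_DOM labels violate alternation across "
                    "TM segments"
                )
            inferred[i] = side

    pieces: list[Segment] = []
    for i, (lo, hi) in enumerate(loops):
        pieces.append(Segment(lo, hi, inferred.get(i + offset, UNKNOWN)))
    pieces.extend(Segment(tm.start, tm.end, TM) for tm in tms)
    pieces.sort(key=lambda s: s.start)
    return TopologyModel(protein_id=record.id, segments=pieces)


def localize(
    model: TopologyModel, start: int, end: int, protein_id: str | None = None
) -> SideAssignment:
    """Assign an interval to a membrane side by strict residue majority.

    TM and Unknown residues do not vote; an exact tie or zero sided
    overlap yields Ambiguous.
    """
    if start < 1 or end > model.length or start > end:
        raise ValueError(
            f"interval [{start},{end}] outside [1,{model.length}]"
        )
    sides = model.side_array()[start - 1 : end]
    c = int(np.sum(sides == CYTOPLASMIC))
    e = int(np.sum(sides == EXTRACELLULAR))
    n = end - start + 1
    if c > e:
        side, frac = CYTOPLASMIC, c / n
    elif e > c:
        side, frac = EXTRACELLULAR, e / n
    else:
        side, frac = AMBIGUOUS, (c / n if c else 0.0)
    return SideAssignment(
        protein_id=protein_id or model.protein_id,
        start=start,
        end=end,
        side=side,
        overlap_fraction=frac,
    )


def filter_undeterminable(
    records: Sequence[ProteinRecord],
    models: dict[str, TopologyModel],
    min_len: int = 30,
) -> tuple[list[ProteinRecord], list[str]]:
    """Drop multi-pass proteins whose every loop is shorter than min_len.

    Such proteins cannot host a qualifying IDR inside any single
    topological domain.  Single-pass and unannotated proteins are always
    retained.
    """
    kept: list[ProteinRecord] = []
    excluded: list[str] = []
    for rec in records:
        if classify_pass_type(rec) == MULTI_PASS:
            loops = models[rec.id].loops()
            if loops and all(s.length < min_len for s in loops):
                excluded.append(rec.id)
                continue
        kept.append(rec)
    return kept, excluded


def side_statistics(
    assignments: Iterable[SideAssignment],
    pass_types: dict[str, str],
) -> pd.DataFrame:
    """Per pass type: side counts and the two-way percentage split.

    Percentages are computed over Cytoplasmic + Extracellular
    assignments only; Ambiguous counts are reported alongside.
    """
    rows: dict[str, dict[str, int]] = {}
    for a in assignments:
        pt = pass_types[a.protein_id]
        bucket = rows.setdefault(
            pt, {CYTOPLASMIC: 0, EXTRACELLULAR: 0, AMBIGUOUS: 0}
        )
        bucket[a.side] += 1
    out = []
    for pt in sorted(rows):
        b = rows[pt]
        sided = b[CYTOPLASMIC] + b[EXTRACELLULAR]
        out.append(
            {
                "pass_type": pt,
                "n_cytoplasmic": b[CYTOPLASMIC],
                "n_extracellular": b[EXTRACELLULAR],
                "n_ambiguous": b[AMBIGUOUS],
                "pct_cytoplasmic": (
                    100.0 * b[CYTOPLASMIC] / sided if sided else float("nan")
                ),
                "pct_extracellular": (
                    100.0 * b[EXTRACELLULAR] / sided if sided else float("nan")
                ),
            }
        )
    return pd.DataFrame(out)


def occupancy(
    model: TopologyModel, idrs: Iterable[IDRInterval]
) -> dict[str, float]:
    """Percent of each side's residues covered by IDRs, for one protein.

    All same-side residues of the protein are pooled before dividing;
    sides with no residues are skipped.
    """
    sides = model.side_array()
    covered = np.zeros(model.length, dtype=bool)
    for iv in idrs:
        covered[iv.start - 1 : iv.end] = True
    out: dict[str, float] = {}
    for side in (CYTOPLASMIC, EXTRACELLULAR):
        mask = sides == side
        total = int(mask.sum())
        if total:
            out[side] = 100.0 * int((mask & covered).sum()) / total
    return out


def occupancy_table(
    models: dict[str, TopologyModel],
    idrs_by_protein: dict[str, list[IDRInterval]],
    pass_types: dict[str, str],
) -> pd.DataFrame:
    """Per-protein, per-side occupancy rows for distribution plots."""
    rows = []
    for pid, model in models.items():
        occ = occupancy(model, idrs_by_protein.get(pid, []))
        for side, pct in occ.items():
            rows.append(
                {
                    "protein_id": pid,
                    "pass_type": pass_types[pid],
                    "side": side,
                    "occupancy_pct": pct,
                }
            )
    return pd.DataFrame(
        rows, columns=["protein_id", "pass_type", "side", "occupancy_pct"]
    )


def occupancy_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean occupancy with standard error, by pass type and side."""
    if table.empty:
        return pd.DataFrame(
            columns=["pass_type", "side", "n", "mean_pct", "sem_pct"]
        )
    g = table.groupby(["pass_type", "side"])["occupancy_pct"]
    out = g.agg(n="count", mean_pct="mean", sem_pct="sem").reset_index()
    out["sem_pct"] = out["sem_pct"].fillna(0.0)
    return out


def length_statistics(
    assignments: Iterable[SideAssignment],
    pass_types: dict[str, str],
) -> pd.DataFrame:
    """IDR length stats (n, mean, quartiles) by side and pass type."""
    rows = [
        {
            "pass_type": pass_types[a.protein_id],
            "side": a.side,
            "length": a.end - a.start + 1,
        }
        for a in assignments
    ]
    if not rows:
        return pd.DataFrame(
            columns=["pass_type", "side", "n", "mean", "median", "q1", "q3"]
        )
    df = pd.DataFrame(rows)
    g = df.groupby(["pass_type", "side"])["length"]
    out = g.agg(
        n="count",
        mean="mean",
        median="median",
        q1=lambda s: s.quantile(0.25),
        q3=lambda s: s.quantile(0.75),
    ).reset_index()
    return out


def write_topology(
    models: dict[str, TopologyModel], path
) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tstart\tend\tside\n")
        for pid, model in models.items():
            for seg in model.segments:
                fh.write(f"{pid}\t{seg.start}\t{seg.end}\t{seg.side}\n")


def pct_rounded(x: float, ndigits: int = 0) -> float:
    """Half-up rounding helper re-exported for table formatting."""
    return round_half_up(x, ndigits)
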