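"""Disorder-guided orientation of multi-pass membrane proteins.

Given fixed TM segments, exactly two alternating loop labelings exist.
Each candidate is scored by where the protein's IDRs fall (disorder
strongly prefers the cytoplasmic side) and by the positive-inside rule
(K/R residues near TM boundaries prefer the cytoplasmic side); the
higher combined score wins unless the margin is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .idr import IDRInterval
from .io import ProteinRecord
from .topology import (
    CYTOPLASMIC,
    EXTRACELLULAR,
    TM,
    Segment,
    TopologyModel,
)

DEFAULT_BOUNDARY_WINDOW = 15
DEFAULT_W_DISORDER = 0.5
DEFAULT_W_CHARGE = 0.5
DEFAULT_AMBIGUITY_MARGIN = 0.05

NEUTRAL = 0.5  # contribution of a component with no evidence


@dataclass
class OrientationCandidate:
    model: TopologyModel
    disorder_score: float = float("nan")
    charge_score: float = float("nan")
    combined: float = float("nan")


@dataclass
class OrientationVerdict:
    protein_id: str
    chosen: TopologyModel | None
    margin: float
    verdict: str  # "A", "B" or "ambiguous"
    candidate_a: OrientationCandidate
    candidate_b: OrientationCandidate


def enumerate_orientations(
    tm_segments: Sequence[tuple[int, int]], length: int
) -> tuple[TopologyModel, TopologyModel]:
    """The two alternating labelings over fixed TM segments.

    Candidate A assigns the N-terminal-most loop slot Cytoplasmic and
    alternates; candidate B is the complement.  Works when the first TM
    starts at residue 1 (the slot is empty but keeps its parity).
    """
    tms = sorted(tm_segments)
    if not tms:
        raise ValueError("no TM segments: nothing to orient")
    prev = 0
    for s, e in tms:
        if s < 1 or e > length or s > e or s <= prev:
            raise ValueError(f"bad TM segment [{s},{e}]")
        prev = e

    def build(first_side: str) -> TopologyModel:
        side = first_side
        segs: list[Segment] = []
        prev_end = 0
        for s, e in tms:
            if s > prev_end + 1:
                segs.append(Segment(prev_end + 1, s - 1, side))
            side = CYTOPLASMIC if side == EXTRACELLULAR else EXTRACELLULAR
            segs.append(Segment(s, e, TM))
            prev_end = e
        if prev_end < length:
            segs.append(Segment(prev_end + 1, length, side))
        return TopologyModel(protein_id="", segments=segs)

    return build(CYTOPLASMIC), build(EXTRACELLULAR)


def _boundary_mask(model: TopologyModel, window: int) -> np.ndarray:
    """Loop residues within ``window`` of either end of a TM segment."""
    mask = np.zeros(model.length, dtype=bool)
    sides = model.side_array()
    for seg in model.segments:
        if seg.side != TM:
            continue
        lo = max(1, seg.start - window)
        mask[lo - 1 : seg.start - 1] = True
        hi = min(model.length, seg.end + window)
        mask[seg.end : hi] = True
    return mask & (sides != TM)


def score_orientation(
    model: TopologyModel,
    sequence: str,
    idrs: Iterable[IDRInterval],
    boundary_window: int = DEFAULT_BOUNDARY_WINDOW,
    w_disorder: float = DEFAULT_W_DISORDER,
    w_charge: float = DEFAULT_W_CHARGE,
) -> OrientationCandidate:
    """Score one candidate labeling.

    disorder_score: fraction of loop IDR residues on cytoplasmic loops.
    charge_score: fraction of K/R residues near TM boundaries that land
    on cytoplasmic loops.  A component with no evidence contributes the
    neutral value 0.5 to the combination.
    """
    sides = model.side_array()
    idr_mask = np.zeros(model.length, dtype=bool)
    for iv in idrs:
        idr_mask[iv.start - 1 : iv.end] = True
    on_loop = sides != TM
    idr_loop = idr_mask & on_loop
    idr_total = int(idr_loop.sum())
    idr_cyto = int((idr_loop & (sides == CYTOPLASMIC)).sum())
    disorder = idr_cyto / idr_total if idr_total else float("nan")

    kr = np.array([a in "KR" for a in sequence.upper()])
    near_tm = _boundary_mask(model, boundary_window)
    kr_boundary = kr & near_tm
    kr_total = int(kr_boundary.sum())
    kr_cyto = int((kr_boundary & (sides == CYTOPLASMIC)).sum())
    charge = kr_cyto / kr_total if kr_total else float("nan")

    d_term = disorder if idr_total else NEUTRAL
    c_term = charge if kr_total else NEUTRAL
    combined = w_disorder * d_term + w_charge * c_term
    return OrientationCandidate(
        model=model,
        disorder_score=disorder,
        charge_score=charge,
        combined=combined,
    )


def predict_orientation(
    record: ProteinRecord,
    idrs: Iterable[IDRInterval],
    boundary_window: int = DEFAULT_BOUNDARY_WINDOW,
    w_disorder: float = DEFAULT_W_DISORDER,
    w_charge: float = DEFAULT_W_CHARGE,
    margin: float = DEFAULT_AMBIGUITY_MARGIN,
) -> OrientationVerdict:
    """Pick the better of the two orientations for one protein."""
    tms = [(f.start, f.end) for f in record.transmem()]
    model_a, model_b = enumerate_orientations(tms, record.length)
    model_a.protein_id = model_b.protein_id = record.id
    idrs = list(idrs)
    cand_a = score_orientation(
        model_a, record.sequence, idrs, boundary_window, w_disorder, w_charge
    )
    cand_b = score_orientation(
        model_b, record.sequence, idrs, boundary_window, w_disorder, w_charge
    )
    diff = cand_a.combined - cand_b.combined
    if abs(diff) < margin:
        verdict, chosen = "ambiguous", None
    elif diff > 0:
        verdict, chosen = "A", model_a
    else:
        verdict, chosen = "B", model_b
    return OrientationVerdict(
        protein_id=record.id,
        chosen=chosen,
        margin=diff,
        verdict=verdict,
        candidate_a=cand_a,
        candidate_b=cand_b,
    )
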