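"""Per-residue disorder score tracks.

Two scale-based predictors are implemented here: a charge/hydropathy
score (negative means disordered; threshold 0) and a disorder-propensity
scale average (positive means disordered; threshold 0).  Outputs of
external per-residue predictors are ingested from TSV rather than
reimplemented, and any set of tracks can be fused into a [0, 1]
consensus track.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from ._util import load_data_json

_SCALES = load_data_json("scales.json")
KYTE_DOOLITTLE: dict[str, float] = _SCALES["kyte_doolittle"]
TOP_IDP: dict[str, float] = _SCALES["top_idp"]

#: Charge/hydropathy decision line: score = A * <H> - |<R>| - B,
#: with hydropathy rescaled to [0, 1] via (H + 4.5) / 9.
CH_SLOPE = 2.785
CH_INTERCEPT = 1.151

DEFAULT_WINDOW_FOLDINDEX = 51
DEFAULT_WINDOW_TOPIDP = 21

FOLDINDEX = "foldindex"
TOPIDP = "topidp"
CONSENSUS = "consensus"


@dataclass
class ScoreTrack:
    """Per-residue disorder scores for one protein.

    ``higher_is_disordered`` states the orientation of the score axis;
    ``threshold`` is the decision boundary used by binarization.
    """

    protein_id: str
    predictor: str
    scores: np.ndarray
    threshold: float
    higher_is_disordered: bool

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or self.scores.size == 0:
            raise ValueError("scores must be a non-empty 1-D array")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def __len__(self) -> int:
        return self.scores.size


def _window_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Mean over the symmetric window centered at each position.

    At the termini the window shrinks symmetrically (half-width limited
    by the nearer terminus) so every residue gets a score.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    n = values.size
    half = window // 2
    cum = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo, hi = idx - h, idx + h
    return (cum[hi + 1] - cum[lo]) / (2 * h + 1)


def foldindex_score(
    sequence: str,
    window: int = DEFAULT_WINDOW_FOLDINDEX,
    protein_id: str = "",
) -> ScoreTrack:
    """Charge/hydropathy disorder score; score < 0 calls disorder.

    Per window: ``CH_SLOPE * <H> - |<R>| - CH_INTERCEPT`` where <H> is
    the mean Kyte-Doolittle hydropathy rescaled to [0, 1] and <R> is the
    mean net charge (fraction K/R minus fraction D/E).  Residue X (or
    any unknown letter) contributes scaled hydropathy 0.5 and charge 0.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    hyd = np.array(
        [(KYTE_DOOLITTLE.get(a, 0.0) + 4.5) / 9.0 for a in seq]
    )
    charge = np.array(
        [1.0 if a in "KR" else -1.0 if a in "DE" else 0.0 for a in seq]
    )
    mean_h = _window_mean(hyd, window)
    mean_r = _window_mean(charge, window)
    scores = CH_SLOPE * mean_h - np.abs(mean_r) - CH_INTERCEPT
    return ScoreTrack(
        protein_id=protein_id,
        predictor=FOLDINDEX,
        scores=scores,
        threshold=0.0,
        higher_is_disordered=False,
    )


def topidp_score(
    sequence: str,
    window: int = DEFAULT_WINDOW_TOPIDP,
    protein_id: str = "",
) -> ScoreTrack:
    """Windowed mean of the TOP-IDP propensity scale; > 0 is disordered.

    Residue X (or any unknown letter) takes scale value 0.
    """
    if not sequence:
        raise ValueError("empty sequence")
    vals = np.array([TOP_IDP.get(a, 0.0) for a in sequence.upper()])
    return ScoreTrack(
        protein_id=protein_id,
        predictor=TOPIDP,
        scores=_window_mean(vals, window),
        threshold=0.0,
        higher_is_disordered=True,
    )


def ingest_scores(
    path: str | Path,
    predictor: str,
    threshold: float,
    higher_is_disordered: bool,
    lengths: Mapping[str, int] | None = None,
) -> dict[str, ScoreTrack]:
    """Read external per-residue scores from TSV.

    Expected columns ``protein_id  position  score`` with 1-based
    positions, contiguous 1..L per protein; gaps or duplicates are hard
    errors.  If ``lengths`` is given, each track length is checked
    against it.
    """
    per_protein: dict[str, dict[int, float]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["protein_id", "position", "score"]:
            raise ValueError(
                f"{path}: expected header protein_id/position/score, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            pid, pos_s, score_s = line.rstrip("\n").split("\t")[:3]
            pos, score = int(pos_s), float(score_s)
            bucket = per_protein.setdefault(pid, {})
            if pos in bucket:
                raise ValueError(f"{path}:{lineno}: duplicate position {pos} for {pid}")
            bucket[pos] = score

    tracks: dict[str, ScoreTrack] = {}
    for pid, positions in per_protein.items():
        n = len(positions)
        if set(positions) != set(range(1, n + 1)):
            raise ValueError(f"{path}: positions for {pid} are not contiguous 1..L")
        if lengths is not None:
            if pid not in lengths:
                raise ValueError(f"{path}: unknown protein {pid}")
            if n != lengths[pid]:
                raise ValueError(
                    f"{path}: {pid} has {n} scored positions, sequence length "
                    f"is {lengths[pid]}"
                )
        scores = np.array([positions[i] for i in range(1, n + 1)])
        tracks[pid] = ScoreTrack(
            protein_id=pid,
            predictor=predictor,
            scores=scores,
            threshold=threshold,
            higher_is_disordered=higher_is_disordered,
        )
    return tracks


def write_scores(tracks: Iterable[ScoreTrack], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tscore\n")
        for t in tracks:
            for i, s in enumerate(t.scores, start=1):
                fh.write(f"{t.protein_id}\t{i}\t{s:.6g}\n")


def normalize_track(track: ScoreTrack, tau: float = 0.5) -> ScoreTrack:
    """Map a track onto a [0, 1] higher-is-disordered scale.

    Tracks already on that scale (threshold 0.5, values in [0, 1]) pass
    through unchanged.  Anything else goes through a logistic transform
    centered on the track's own threshold, so the decision boundary maps
    to 0.5 and the orientation becomes higher-is-disordered.
    """
    s = track.scores
    if (
        track.higher_is_disordered
        and track.threshold == 0.5
        and s.min() >= 0.0
        and s.max() <= 1.0
    ):
        return replace(track)
    centered = (s - track.threshold) / tau
    if not track.higher_is_disordered:
        centered = -centered
    norm = 1.0 / (1.0 + np.exp(-centered))
    return ScoreTrack(
        protein_id=track.protein_id,
        predictor=track.predictor,
        scores=norm,
        threshold=0.5,
        higher_is_disordered=True,
    )


def consensus_track(tracks: list[ScoreTrack], tau: float = 0.5) -> ScoreTrack:
    """Average the normalized tracks of one protein into a consensus."""
    if not tracks:
        raise ValueError("need at least one track")
    pids = {t.protein_id for t in tracks}
    if len(pids) > 1:
        raise ValueError(f"tracks belong to different proteins: {sorted(pids)}")
    lengths = {len(t) for t in tracks}
    if len(lengths) > 1:
        raise ValueError(f"track length mismatch: {sorted(lengths)}")
    stacked = np.vstack([normalize_track(t, tau=tau).scores for t in tracks])
    return ScoreTrack(
        protein_id=tracks[0].protein_id,
        predictor=CONSENSUS,
        scores=stacked.mean(axis=0),
        threshold=0.5,
        higher_is_disordered=True,
    )
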