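"""Synthetic membrane proteomes with known ground truth.

Proteins are built as alternating loop/TM/loop architectures.  Each
loop is independently flagged as disordered with a side-dependent
probability; disordered loops are drawn from a disorder-biased residue
composition, ordered loops and TM segments from their own compositions.
The planted truth (topology, IDR intervals, IDP/FOP labels, PTM sites,
interaction degrees) is returned alongside and round-trips through the
package's standard I/O formats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from ._util import load_data_json
from .idr import FOP, IDP, IDRInterval, write_idrs
from .io import (
    TOPO_DOM,
    TRANSMEM,
    FeatureInterval,
    ProteinRecord,
    write_fasta,
    write_features,
)
from .stats import PHOSPHO, InteractionEdge, PTMSite, write_edges, write_ptm_sites
from .topology import CYTOPLASMIC, EXTRACELLULAR, TM, Segment, TopologyModel

_COMPS = load_data_json("sim_compositions.json")
DISORDERED_COMPOSITION: dict[str, float] = _COMPS["disordered"]
ORDERED_COMPOSITION: dict[str, float] = _COMPS["ordered"]
TM_COMPOSITION: dict[str, float] = _COMPS["tm"]


@dataclass
class SimSpec:
    """Parameters of a synthetic proteome.  ``seed`` is mandatory."""

    seed: int
    n_proteins: int = 200
    p_single: float = 0.45
    tm_count_range: tuple[int, int] = (2, 10)
    tm_len_range: tuple[int, int] = (19, 23)
    loop_log_mean: float = math.log(40.0)
    loop_log_sigma: float = 0.8
    min_loop_len: int = 5
    disordered_loop_min_len: int = 45
    p_disordered_loop_cyto: float = 0.35
    p_disordered_loop_extra: float = 0.05
    p_nterm_cyto: float = 0.5
    disordered_composition: dict[str, float] = field(
        default_factory=lambda: dict(DISORDERED_COMPOSITION)
    )
    ordered_composition: dict[str, float] = field(
        default_factory=lambda: dict(ORDERED_COMPOSITION)
    )
    tm_composition: dict[str, float] = field(
        default_factory=lambda: dict(TM_COMPOSITION)
    )
    ptm_rate_idp: float = 8.0  # expected phospho sites per 100 residues
    ptm_rate_fop: float = 4.0
    serine_site_fraction: float = 0.6
    ppi_mean_degree_idp: float = 9.5
    ppi_mean_degree_fop: float = 6.0

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        for name in (
            "p_single",
            "p_disordered_loop_cyto",
            "p_disordered_loop_extra",
            "p_nterm_cyto",
            "serine_site_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "ptm_rate_idp",
            "ptm_rate_fop",
            "ppi_mean_degree_idp",
            "ppi_mean_degree_fop",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tm_count_range[0] < 2 or self.tm_count_range[0] > self.tm_count_range[1]:
            raise ValueError("tm_count_range must be (lo, hi) with 2 <= lo <= hi")
        if self.disordered_loop_min_len < 30 and (
            self.p_disordered_loop_cyto > 0 or self.p_disordered_loop_extra > 0
        ):
            raise ValueError(
                "disordered loops must be able to reach 30 residues while "
                "p_disordered > 0"
            )
        for name in (
            "disordered_composition",
            "ordered_composition",
            "tm_composition",
        ):
            comp = getattr(self, name)
            total = sum(comp.values())
            if abs(total - 1.0) > 1e-6 or any(w < 0 for w in comp.values()):
                raise ValueError(f"{name} must be non-negative and sum to 1")


@dataclass
class ProteinTruth:
    model: TopologyModel
    idrs: list[IDRInterval]
    label: str


@dataclass
class SyntheticTruth:
    proteins: dict[str, ProteinTruth]
    sites: list[PTMSite] = field(default_factory=list)
    degrees: dict[str, int] = field(default_factory=dict)


def _sample_segment(rng: np.random.Generator, comp: dict[str, float], n: int) -> str:
    letters = list(comp)
    probs = np.array([comp[a] for a in letters])
    probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=n, p=probs))


def _loop_length(rng: np.random.Generator, spec: SimSpec) -> int:
    raw = int(round(rng.lognormal(spec.loop_log_mean, spec.loop_log_sigma)))
    return max(raw, spec.min_loop_len)


def generate_proteome(
    spec: SimSpec,
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Generate records with attached features plus the planted truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records: list[ProteinRecord] = []
    truths: dict[str, ProteinTruth] = {}
    width = len(str(spec.n_proteins))
    for i in range(spec.n_proteins):
        pid = f"SYN{i + 1:0{width}d}"
        if rng.random() < spec.p_single:
            n_tm = 1
        else:
            n_tm = int(rng.integers(spec.tm_count_range[0], spec.tm_count_range[1] + 1))
        nterm_side = CYTOPLASMIC if rng.random() < spec.p_nterm_cyto else EXTRACELLULAR
        side = nterm_side
        parts: list[str] = []
        segments: list[Segment] = []
        features: list[FeatureInterval] = []
        idrs: list[IDRInterval] = []
        pos = 1
        for j in range(n_tm + 1):
            # loop segment
            length = _loop_length(rng, spec)
            p_dis = (
                spec.p_disordered_loop_cyto
                if side == CYTOPLASMIC
                else spec.p_disordered_loop_extra
            )
            disordered = rng.random() < p_dis
            if disordered:
                length = max(length, spec.disordered_loop_min_len)
                comp = spec.disordered_composition
            else:
                comp = spec.ordered_composition
            parts.append(_sample_segment(rng, comp, length))
            lo, hi = pos, pos + length - 1
            segments.append(Segment(lo, hi, side))
            label = CYTOPLASMIC if side == CYTOPLASMIC else EXTRACELLULAR
            features.append(FeatureInterval(TOPO_DOM, lo, hi, label))
            if disordered:
                idrs.append(
                    IDRInterval(protein_id=pid, start=lo, end=hi, predictor="planted")
                )
            pos = hi + 1
            # TM segment (skipped after the final loop)
            if j < n_tm:
                tm_len = int(
                    rng.integers(spec.tm_len_range[0], spec.tm_len_range[1] + 1)
                )
                parts.append(_sample_segment(rng, spec.tm_composition, tm_len))
                lo, hi = pos, pos + tm_len - 1
                segments.append(Segment(lo, hi, TM))
                features.append(FeatureInterval(TRANSMEM, lo, hi))
                pos = hi + 1
                side = CYTOPLASMIC if side == EXTRACELLULAR else EXTRACELLULAR
        rec = ProteinRecord(id=pid, sequence="".join(parts))
        rec.attach_features(features)
        records.append(rec)
        truths[pid] = ProteinTruth(
            model=TopologyModel(protein_id=pid, segments=segments),
            idrs=idrs,
            label=IDP if idrs else FOP,
        )
    return records, SyntheticTruth(proteins=truths)


def generate_ptm(
    records: list[ProteinRecord], truth: SyntheticTruth, spec: SimSpec
) -> list[PTMSite]:
    """Plant phospho sites at class-dependent Poisson rates.

    Positions are drawn without replacement over S/T/Y residues, with
    serine positions jointly carrying ``serine_site_fraction`` of the
    sampling weight whenever both groups exist.
    """
    rng = np.random.default_rng(spec.seed + 1)
    sites: list[PTMSite] = []
    for rec in records:
        cls = truth.proteins[rec.id].label
        rate = spec.ptm_rate_idp if cls == IDP else spec.ptm_rate_fop
        n = int(rng.poisson(rate * rec.length / 100.0))
        if n == 0:
            continue
        seq = rec.sequence
        s_pos = [i + 1 for i, a in enumerate(seq) if a == "S"]
        ty_pos = [i + 1 for i, a in enumerate(seq) if a in "TY"]
        eligible = s_pos + ty_pos
        if not eligible:
            continue
        if s_pos and ty_pos:
            sf = spec.serine_site_fraction
            w = np.array(
                [sf / len(s_pos)] * len(s_pos)
                + [(1.0 - sf) / len(ty_pos)] * len(ty_pos)
            )
            keep = w > 0
            eligible = [p for p, k in zip(eligible, keep) if k]
            w = w[keep]
            w = w / w.sum()
        else:
            w = None
        n = min(n, len(eligible))
        chosen = rng.choice(eligible, size=n, replace=False, p=w)
        for p in sorted(int(x) for x in chosen):
            sites.append(
                PTMSite(
                    protein_id=rec.id,
                    position=p,
                    residue=seq[p - 1],
                    mod_type=PHOSPHO,
                )
            )
    truth.sites = sites
    return sites


def generate_ppi(truth: SyntheticTruth, spec: SimSpec) -> list[InteractionEdge]:
    """Degree-configured random graph over the synthetic proteins.

    Each protein draws a Poisson target degree at its class mean; stubs
    are paired uniformly, then self-loops and duplicate pairs dropped
    and bait/prey direction assigned at random.
    """
    pids = list(truth.proteins)
    if len(pids) < 2:
        raise ValueError("need at least two proteins for a PPI network")
    rng = np.random.default_rng(spec.seed + 2)
    stubs: list[str] = []
    degrees: dict[str, int] = {}
    for pid in pids:
        mean = (
            spec.ppi_mean_degree_idp
            if truth.proteins[pid].label == IDP
            else spec.ppi_mean_degree_fop
        )
        d = int(rng.poisson(mean))
        degrees[pid] = d
        stubs.extend([pid] * d)
    truth.degrees = degrees
    rng.shuffle(stubs)
    seen: set[tuple[str, str]] = set()
    edges: list[InteractionEdge] = []
    for a, b in zip(stubs[::2], stubs[1::2]):
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        if key in seen:
            continue
        seen.add(key)
        bait, prey = (a, b) if rng.random() < 0.5 else (b, a)
        edges.append(InteractionEdge(bait_id=bait, prey_id=prey))
    return edges


def write_truth(truth: SyntheticTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    with open(outdir / "truth_topology.tsv", "w") as fh:
        fh.write("protein_id\tstart\tend\tside\n")
        for pid, t in truth.proteins.items():
            for seg in t.model.segments:
                fh.write(f"{pid}\t{seg.start}\t{seg.end}\t{seg.side}\n")
    write_idrs(
        (iv for t in truth.proteins.values() for iv in t.idrs),
        outdir / "truth_idrs.tsv",
    )
    with open(outdir / "truth_labels.tsv", "w") as fh:
        fh.write("protein_id\tlabel\n")
        for pid, t in truth.proteins.items():
            fh.write(f"{pid}\t{t.label}\n")
    with open(outdir / "truth_degrees.tsv", "w") as fh:
        fh.write("protein_id\tdegree\n")
        for pid, d in truth.degrees.items():
            fh.write(f"{pid}\t{d}\n")


def simulate_all(
    spec: SimSpec, outdir: str | Path
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Generate a proteome and write every artifact to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truth = generate_proteome(spec)
    sites = generate_ptm(records, truth, spec)
    edges = generate_ppi(truth, spec)
    write_fasta(records, outdir / "proteome.fasta")
    write_features(
        {r.id: list(r.features) for r in records}, outdir / "features.tsv"
    )
    write_ptm_sites(sites, outdir / "ptm_sites.tsv")
    write_edges(edges, outdir / "ppi_edges.tsv")
    write_truth(truth, outdir)
    return records, truth
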