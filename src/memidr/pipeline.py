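"""End-to-end orchestration: predict -> IDR -> topology -> statistics.

A run is driven by a single YAML config (CLI flags override config
keys).  Every stage writes a TSV into the output directory and the run
closes with a manifest listing parameters, seed and a content hash per
emitted file, so identical configs reproduce identical bytes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .idr import classify_idp, idrs_from_track, write_idrs
from .io import (
    attach_all,
    classify_pass_type,
    pass_type_summary,
    read_fasta,
    read_features,
    topology_coverage,
)
from .orient import predict_orientation
from .predict import (
    CONSENSUS,
    FOLDINDEX,
    TOPIDP,
    consensus_track,
    foldindex_score,
    topidp_score,
    write_scores,
)
from .simulate import SimSpec, simulate_all
from .stats import (
    composition,
    degree_stats,
    enrichment,
    ptm_stats,
    read_edges,
    read_ptm_sites,
)
from .topology import (
    build_topology,
    filter_undeterminable,
    length_statistics,
    localize,
    occupancy_summary,
    occupancy_table,
    side_statistics,
    write_topology,
)

log = logging.getLogger("memidr")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    outdir: str
    fasta: str | None = None
    features: str | None = None
    ptm: str | None = None
    ppi: str | None = None
    simulate: dict[str, Any] | None = None
    predictor: str = FOLDINDEX
    window: int | None = None
    min_idr_len: int = 30
    w_disorder: float = 0.5
    w_charge: float = 0.5
    boundary_window: int = 15
    margin: float = 0.05
    seed: int | None = None
    extra: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        cfg = cls(**kwargs, extra=extra)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.min_idr_len < 1:
            raise ConfigError("min_idr_len must be >= 1")
        if self.predictor not in {FOLDINDEX, TOPIDP, CONSENSUS}:
            raise ConfigError(f"unknown predictor {self.predictor!r}")
        if self.simulate is None:
            if not self.fasta:
                raise ConfigError("either 'fasta' or 'simulate' is required")
            for key in ("fasta", "features", "ptm", "ppi"):
                p = getattr(self, key)
                if p and not Path(p).exists():
                    raise ConfigError(f"{key} path does not exist: {p}")
        elif "seed" not in self.simulate and self.seed is None:
            raise ConfigError("simulate requires a seed")


def _tracks_for(sequence: str, pid: str, cfg: RunConfig):
    fi = foldindex_score(
        sequence, window=cfg.window or 51, protein_id=pid
    ) if cfg.predictor in {FOLDINDEX, CONSENSUS} else None
    ti = topidp_score(
        sequence, window=cfg.window or 21, protein_id=pid
    ) if cfg.predictor in {TOPIDP, CONSENSUS} else None
    if cfg.predictor == FOLDINDEX:
        return fi
    if cfg.predictor == TOPIDP:
        return ti
    return consensus_track([fi, ti])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(cfg: RunConfig) -> dict[str, Any]:
    """Execute all stages; returns the manifest dictionary."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    # --- inputs -----------------------------------------------------
    if cfg.simulate is not None:
        sim_kwargs = dict(cfg.simulate)
        if cfg.seed is not None:
            sim_kwargs.setdefault("seed", cfg.seed)
        spec = SimSpec(**sim_kwargs)
        records, _truth = simulate_all(spec, outdir / "simulated")
        ptm_path = outdir / "simulated" / "ptm_sites.tsv"
        ppi_path = outdir / "simulated" / "ppi_edges.tsv"
    else:
        records = read_fasta(cfg.fasta)
        if cfg.features:
            attach_all(records, read_features(cfg.features))
        ptm_path = Path(cfg.ptm) if cfg.ptm else None
        ppi_path = Path(cfg.ppi) if cfg.ppi else None
    log.info("loaded %d proteins", len(records))
    by_id = {r.id: r for r in records}
    pass_types = {r.id: classify_pass_type(r) for r in records}

    # --- disorder + IDRs --------------------------------------------
    tracks, idrs_by_protein = {}, {}
    for rec in records:
        try:
            tr = _tracks_for(rec.sequence, rec.id, cfg)
            tracks[rec.id] = tr
            idrs_by_protein[rec.id] = idrs_from_track(tr, min_len=cfg.min_idr_len)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"stage=predict protein={rec.id}: {exc}") from exc
    write_scores(tracks.values(), outdir / "scores.tsv")
    all_idrs = [iv for ivs in idrs_by_protein.values() for iv in ivs]
    write_idrs(all_idrs, outdir / "idrs.tsv")
    labels = {pid: classify_idp(ivs) for pid, ivs in idrs_by_protein.items()}
    pd.DataFrame(
        sorted(labels.items()), columns=["protein_id", "label"]
    ).to_csv(outdir / "idp_labels.tsv", sep="\t", index=False)
    log.info("predict+idr done (%.1fs)", time.time() - t0)

    # --- dataset summaries ------------------------------------------
    pass_type_summary(records).to_csv(
        outdir / "pass_types.tsv", sep="\t", index=False
    )

    # --- topology ----------------------------------------------------
    models = {}
    for rec in records:
        try:
            models[rec.id] = build_topology(rec)
        except Exception as exc:
            raise RuntimeError(f"stage=topology protein={rec.id}: {exc}") from exc
    write_topology(models, outdir / "topology.tsv")
    coverage = topology_coverage(records)
    kept, excluded = filter_undeterminable(records, models, cfg.min_idr_len)
    assignments = []
    for rec in kept:
        for iv in idrs_by_protein[rec.id]:
            assignments.append(localize(models[rec.id], iv.start, iv.end))
    side_statistics(assignments, pass_types).to_csv(
        outdir / "side_statistics.tsv", sep="\t", index=False
    )
    length_statistics(assignments, pass_types).to_csv(
        outdir / "length_statistics.tsv", sep="\t", index=False
    )
    occ = occupancy_table(
        {r.id: models[r.id] for r in kept}, idrs_by_protein, pass_types
    )
    occ.to_csv(outdir / "occupancy.tsv", sep="\t", index=False)
    occupancy_summary(occ).to_csv(
        outdir / "occupancy_summary.tsv", sep="\t", index=False
    )
    log.info("topology done (%.1fs)", time.time() - t0)

    # --- orientation (multi-pass only) ------------------------------
    orient_rows = []
    for rec in records:
        if len(rec.transmem()) < 1:
            continue
        v = predict_orientation(
            rec,
            idrs_by_protein[rec.id],
            boundary_window=cfg.boundary_window,
            w_disorder=cfg.w_disorder,
            w_charge=cfg.w_charge,
            margin=cfg.margin,
        )
        orient_rows.append(
            {
                "protein_id": rec.id,
                "combined_a": v.candidate_a.combined,
                "combined_b": v.candidate_b.combined,
                "margin": v.margin,
                "verdict": v.verdict,
            }
        )
    pd.DataFrame(orient_rows).to_csv(
        outdir / "orientation.tsv", sep="\t", index=False
    )

    # --- composition / enrichment -----------------------------------
    background = composition(r.sequence for r in records)
    idp_seqs = [r.sequence for r in records if labels[r.id] == "IDP"]
    idr_res = [
        by_id[iv.protein_id].sequence[iv.start - 1 : iv.end] for iv in all_idrs
    ]
    enr = pd.DataFrame({"background_pct": background})
    if idp_seqs:
        enr["idp_enrichment_pct"] = enrichment(composition(idp_seqs), background)
    if idr_res:
        enr["idr_enrichment_pct"] = enrichment(composition(idr_res), background)
    enr.index.name = "residue"
    enr.to_csv(outdir / "enrichment.tsv", sep="\t")

    # --- PTM / PPI ---------------------------------------------------
    if ptm_path is not None:
        sites = read_ptm_sites(ptm_path, records=by_id)
        tables = ptm_stats(sites, by_id, idrs_by_protein, labels)
        tables["summary"].to_csv(outdir / "ptm_summary.tsv", sep="\t", index=False)
        tables["per_protein"].to_csv(
            outdir / "ptm_per_protein.tsv", sep="\t", index=False
        )
        tables["idr_residue_breakdown"].to_csv(
            outdir / "ptm_idr_residues.tsv", sep="\t", index=False
        )
    if ppi_path is not None:
        degree_stats(read_edges(ppi_path), labels).to_csv(
            outdir / "ppi_summary.tsv", sep="\t", index=False
        )
    log.info("statistics done (%.1fs)", time.time() - t0)

    # --- manifest ----------------------------------------------------
    files = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "predictor": cfg.predictor,
            "window": cfg.window,
            "min_idr_len": cfg.min_idr_len,
            "w_disorder": cfg.w_disorder,
            "w_charge": cfg.w_charge,
            "boundary_window": cfg.boundary_window,
            "margin": cfg.margin,
            "simulate": cfg.simulate,
        },
        "n_proteins": len(records),
        "topology_coverage_pct": coverage,
        "n_excluded_undeterminable": len(excluded),
        "files": {
            str(p.relative_to(outdir)): {
                "sha256": _sha256(p),
                "n_rows": sum(1 for _ in open(p)) if p.suffix == ".tsv" else None,
            }
            for p in files
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("run complete (%.1fs)", time.time() - t0)
    return manifest


_REPORT_SECTIONS = [
    ("Dataset pass types", "pass_types.tsv"),
    ("Predictor score tracks", "scores.tsv"),
    ("IDR calls", "idrs.tsv"),
    ("IDP/FOP labels", "idp_labels.tsv"),
    ("Side localization", "side_statistics.tsv"),
    ("IDR length statistics", "length_statistics.tsv"),
    ("Side occupancy", "occupancy_summary.tsv"),
    ("Amino-acid enrichment", "enrichment.tsv"),
    ("Orientation verdicts", "orientation.tsv"),
    ("PTM statistics", "ptm_summary.tsv"),
    ("PPI statistics", "ppi_summary.tsv"),
]


def report(outdir: str | Path) -> str:
    """Render the emitted tables as one markdown document.

    Missing tables are marked absent; the report never fails on them.
    """
    outdir = Path(outdir)
    lines = ["# memidr run report", ""]
    for title, fname in _REPORT_SECTIONS:
        lines.append(f"## {title}")
        path = outdir / fname
        if not path.exists():
            lines.append("_absent_")
            lines.append("")
            continue
        if fname == "scores.tsv":
            n = sum(1 for _ in open(path)) - 1
            lines.append(f"{n} scored positions (table too large to inline)")
            lines.append("")
            continue
        df = pd.read_csv(path, sep="\t")
        lines.append("```")
        lines.append(df.to_string(index=False) if len(df) else "(empty)")
        lines.append("```")
        lines.append("")
    return "\n".join(lines)
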