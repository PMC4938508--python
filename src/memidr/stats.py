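"""Composition enrichment, PTM density and interaction-degree statistics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .idr import FOP, IDP, IDRInterval
from .io import STANDARD_AA, ProteinRecord

PHOSPHO = "phospho"
UBIQUITIN = "ubiquitin"
MOD_TYPES = {PHOSPHO, UBIQUITIN}
PHOSPHO_RESIDUES = set("STY")


class PTMError(ValueError):
    pass


@dataclass(frozen=True)
class PTMSite:
    protein_id: str
    position: int
    residue: str
    mod_type: str

    def __post_init__(self) -> None:
        if self.mod_type not in MOD_TYPES:
            raise PTMError(f"unknown mod_type {self.mod_type!r}")
        if self.position < 1:
            raise PTMError(f"bad position {self.position}")


@dataclass(frozen=True)
class InteractionEdge:
    bait_id: str
    prey_id: str

    def __post_init__(self) -> None:
        if not self.bait_id or not self.prey_id:
            raise ValueError("edge ids must be non-empty")


def composition(residue_pools: Iterable[str]) -> pd.Series:
    """Percent composition over the 20 standard residues.

    ``residue_pools`` is any iterable of residue strings (whole
    sequences, or extracted sub-segments); pools are concatenated.
    X and other non-standard letters are excluded from numerator and
    denominator.
    """
    counts = dict.fromkeys(STANDARD_AA, 0)
    total = 0
    for pool in residue_pools:
        for a in pool.upper():
            if a in counts:
                counts[a] += 1
                total += 1
    if total == 0:
        raise ValueError("no standard residues to count")
    return pd.Series(
        {a: 100.0 * counts[a] / total for a in STANDARD_AA}, name="pct"
    )


def enrichment(
    subset: pd.Series,
    background: pd.Series,
    convention: str = "ratio",
) -> pd.Series:
    """Per-residue enrichment of a subset composition vs a background.

    ``convention="ratio"`` (default) reports
    ``(subset / background - 1) * 100`` so over-represented residues are
    positive.  ``convention="inverted"`` reports
    ``100 - subset * 100 / background``, the sign-flipped variant.
    Residues with zero background are omitted (NaN) rather than
    silently zeroed.
    """
    if convention not in {"ratio", "inverted"}:
        raise ValueError(f"unknown convention {convention!r}")
    out = {}
    for a in subset.index:
        bg = background[a]
        if bg == 0:
            out[a] = float("nan")
            continue
        ratio = subset[a] / bg
        out[a] = (ratio - 1.0) * 100.0 if convention == "ratio" else 100.0 - ratio * 100.0
    res = pd.Series(out, name="enrichment_pct")
    omitted = [a for a in res.index if np.isnan(res[a])]
    res.attrs["omitted"] = omitted
    return res


def read_ptm_sites(
    path: str | Path,
    records: Mapping[str, ProteinRecord] | None = None,
    strict: bool = True,
) -> list[PTMSite]:
    """Read PTM TSV ``protein_id  position  residue  mod_type``.

    When records are supplied, the residue letter is checked against the
    sequence.  Phospho sites on non-S/T/Y residues are rejected in
    strict mode, kept with a warning otherwise.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "residue": str})
    sites: list[PTMSite] = []
    for i, row in enumerate(df.itertuples(), start=2):
        site = PTMSite(
            protein_id=str(row.protein_id),
            position=int(row.position),
            residue=str(row.residue).upper(),
            mod_type=str(row.mod_type),
        )
        if records is not None:
            rec = records.get(site.protein_id)
            if rec is None:
                raise PTMError(f"{path}:{i}: unknown protein {site.protein_id}")
            if site.position > rec.length:
                raise PTMError(
                    f"{path}:{i}: position {site.position} beyond length "
                    f"{rec.length}"
                )
            actual = rec.sequence[site.position - 1]
            if actual != site.residue:
                raise PTMError(
                    f"{path}:{i}: residue {site.residue} does not match "
                    f"sequence letter {actual} at {site.position}"
                )
        if site.mod_type == PHOSPHO and site.residue not in PHOSPHO_RESIDUES:
            msg = (
                f"{path}:{i}: phospho site on {site.residue} "
                "(expected S/T/Y)"
            )
            if strict:
                raise PTMError(msg)
            warnings.warn(msg, stacklevel=2)
        sites.append(site)
    return sites


def write_ptm_sites(sites: Iterable[PTMSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tresidue\tmod_type\n")
        for s in sites:
            fh.write(f"{s.protein_id}\t{s.position}\t{s.residue}\t{s.mod_type}\n")


def _in_idr(site: PTMSite, idrs: Iterable[IDRInterval]) -> bool:
    return any(iv.start <= site.position <= iv.end for iv in idrs)


def ptm_stats(
    sites: Iterable[PTMSite],
    records: Mapping[str, ProteinRecord],
    idrs_by_protein: Mapping[str, list[IDRInterval]],
    idp_labels: Mapping[str, str],
) -> dict[str, pd.DataFrame]:
    """PTM summaries per class (IDP/FOP) and modification type.

    Returns a dict of tables:

    ``summary``    per (class, mod_type): n proteins, % with >= 1 site,
                   mean sites per protein, mean % of residues modified,
                   % of sites inside IDRs.
    ``per_protein`` per-protein site counts (for distributions).
    ``idr_residue_breakdown`` S/T/Y split of phospho sites inside IDRs,
                   per class.
    """
    sites = list(sites)
    per_protein_counts: dict[tuple[str, str], int] = {}
    inside: dict[tuple[str, str], int] = {}
    total_by: dict[tuple[str, str], int] = {}
    sty_inside: dict[tuple[str, str], int] = {}
    for s in sites:
        if s.protein_id not in idp_labels:
            continue
        cls = idp_labels[s.protein_id]
        key = (cls, s.mod_type)
        total_by[key] = total_by.get(key, 0) + 1
        per_protein_counts[(s.protein_id, s.mod_type)] = (
            per_protein_counts.get((s.protein_id, s.mod_type), 0) + 1
        )
        if _in_idr(s, idrs_by_protein.get(s.protein_id, [])):
            inside[key] = inside.get(key, 0) + 1
            if s.mod_type == PHOSPHO:
                k2 = (cls, s.residue)
                sty_inside[k2] = sty_inside.get(k2, 0) + 1

    classes = (IDP, FOP)
    summary_rows = []
    per_protein_rows = []
    for cls in classes:
        members = [p for p, lbl in idp_labels.items() if lbl == cls]
        for mod in sorted(MOD_TYPES):
            counts = np.array(
                [per_protein_counts.get((p, mod), 0) for p in members]
            )
            lengths = np.array([records[p].length for p in members])
            n = len(members)
            tot = total_by.get((cls, mod), 0)
            ins = inside.get((cls, mod), 0)
            summary_rows.append(
                {
                    "class": cls,
                    "mod_type": mod,
                    "n_proteins": n,
                    "pct_with_site": (
                        100.0 * float((counts > 0).mean()) if n else float("nan")
                    ),
                    "mean_sites_per_protein": (
                        float(counts.mean()) if n else float("nan")
                    ),
                    "mean_pct_residues_modified": (
                        float((100.0 * counts / lengths).mean())
                        if n
                        else float("nan")
                    ),
                    "n_sites": tot,
                    "n_sites_in_idr": ins,
                    "pct_sites_in_idr": (
                        100.0 * ins / tot if tot else float("nan")
                    ),
                }
            )
            for p, c in zip(members, counts):
                per_protein_rows.append(
                    {"protein_id": p, "class": cls, "mod_type": mod, "n_sites": int(c)}
                )

    breakdown_rows = []
    for cls in classes:
        tot = sum(sty_inside.get((cls, r), 0) for r in "STY")
        for r in "STY":
            cnt = sty_inside.get((cls, r), 0)
            breakdown_rows.append(
                {
                    "class": cls,
                    "residue": r,
                    "n_sites_in_idr": cnt,
                    "pct_of_idr_phospho": (
                        100.0 * cnt / tot if tot else float("nan")
                    ),
                }
            )

    return {
        "summary": pd.DataFrame(summary_rows),
        "per_protein": pd.DataFrame(per_protein_rows),
        "idr_residue_breakdown": pd.DataFrame(breakdown_rows),
    }


def read_edges(path: str | Path) -> list[InteractionEdge]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["bait_id", "prey_id"]:
        raise ValueError(
            f"{path}: expected columns bait_id/prey_id, got {list(df.columns)}"
        )
    return [
        InteractionEdge(bait_id=str(r.bait_id), prey_id=str(r.prey_id))
        for r in df.itertuples()
    ]


def write_edges(edges: Iterable[InteractionEdge], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("bait_id\tprey_id\n")
        for e in edges:
            fh.write(f"{e.bait_id}\t{e.prey_id}\n")


def unique_partners(
    edges: Iterable[InteractionEdge],
) -> dict[str, set[str]]:
    """Partner sets with direction and duplicates collapsed, no self-loops."""
    partners: dict[str, set[str]] = {}
    for e in edges:
        if e.bait_id == e.prey_id:
            continue
        partners.setdefault(e.bait_id, set()).add(e.prey_id)
        partners.setdefault(e.prey_id, set()).add(e.bait_id)
    return partners


def degree_stats(
    edges: Iterable[InteractionEdge],
    idp_labels: Mapping[str, str],
) -> pd.DataFrame:
    """Per class: % of proteins with a partner and mean unique degree.

    Edge endpoints without a class label are kept as partners but do not
    themselves contribute rows.
    """
    partners = unique_partners(edges)
    rows = []
    for cls in (IDP, FOP):
        members = [p for p, lbl in idp_labels.items() if lbl == cls]
        degs = np.array([len(partners.get(p, ())) for p in members])
        n = len(members)
        rows.append(
            {
                "class": cls,
                "n_proteins": n,
                "pct_with_partner": (
                    100.0 * float((degs > 0).mean()) if n else float("nan")
                ),
                "mean_partners": float(degs.mean()) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def morf_per_protein(
    morfs_by_protein: Mapping[str, int],
    idp_labels: Mapping[str, str],
) -> pd.DataFrame:
    """MoRF counts per class, with both per-protein denominators.

    Reports the mean over all class members and the mean over members
    with at least one MoRF.
    """
    rows = []
    for cls in (IDP, FOP):
        members = [p for p, lbl in idp_labels.items() if lbl == cls]
        counts = np.array([morfs_by_protein.get(p, 0) for p in members])
        with_morf = counts[counts > 0]
        rows.append(
            {
                "class": cls,
                "n_proteins": len(members),
                "n_morfs": int(counts.sum()),
                "mean_per_protein": (
                    float(counts.mean()) if len(members) else float("nan")
                ),
                "mean_per_protein_with_morf": (
                    float(with_morf.mean()) if len(with_morf) else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)
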