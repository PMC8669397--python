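"""Shared tabular readers/writers and run reports.

All coordinates in every output are 0-based, half-open. TSV (with header
row) and JSON are the only output dialects.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from muklock.binding import TitrationSeries
from muklock.crosslink import Chain, ComplexTemplate, CrosslinkSite
from muklock.errors import DataError
from muklock.gelquant import BandWindow, LaneProfile, ReplicateSet
from muklock.genome import read_fasta, write_fasta  # re-exported
from muklock.motif import MotifHit, SiteFamilyRanking
from muklock.topology import DNAComponent, ThreadingConfig


def read_lane_profile(path: str | Path) -> LaneProfile:
    """Two-column (position_px, intensity) CSV, with or without header."""
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected two columns (position_px, intensity)")
    # tolerate headerless files where the first row parsed as header
    try:
        float(df.columns[0])
        df = pd.read_csv(path, header=None, comment="#")
    except (TypeError, ValueError):
        pass
    return LaneProfile(positions=df.iloc[:, 0].to_numpy(float),
                       intensities=df.iloc[:, 1].to_numpy(float))


def write_lane_profile(profile: LaneProfile, path: str | Path) -> None:
    pd.DataFrame({"position_px": profile.positions,
                  "intensity": profile.intensities}).to_csv(path, index=False)


def read_band_windows(path: str | Path) -> list[BandWindow]:
    """TSV with columns label, start_px, end_px."""
    df = pd.read_csv(path, sep="\t")
    required = {"label", "start_px", "end_px"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: band TSV needs columns {sorted(required)}")
    return [BandWindow(str(r.label), float(r.start_px), float(r.end_px))
            for r in df.itertuples()]


def read_replicates(path: str | Path, column: str = "value") -> ReplicateSet:
    df = pd.read_csv(path, sep="\t")
    col = column if column in df.columns else df.columns[0]
    return ReplicateSet(df[col].to_numpy(float))


def read_titration(path: str | Path, dna_total: float) -> TitrationSeries:
    """TSV with columns conc_nM, response."""
    df = pd.read_csv(path, sep="\t")
    required = {"conc_nM", "response"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: titration TSV needs columns {sorted(required)}")
    return TitrationSeries(protein_concs=df["conc_nM"].to_numpy(float),
                           dna_total=dna_total,
                           responses=df["response"].to_numpy(float))


def write_hits(hits: Sequence[MotifHit], path: str | Path,
               family: str | None = None) -> None:
    df = pd.DataFrame([asdict(h) for h in hits]).reindex(
        columns=["start", "length", "strand", "edit_distance", "matched_seq"])
    if family is not None:
        df.insert(0, "family_pattern", family)
    df.to_csv(path, sep="\t", index=False)


def read_hits(path: str | Path) -> list[MotifHit]:
    df = pd.read_csv(path, sep="\t")
    return [MotifHit(int(r.start), int(r.length), str(r.strand),
                     int(r.edit_distance), str(r.matched_seq))
            for r in df.itertuples()]


def read_hits_grouped(paths: Sequence[str | Path]) -> dict[str, list[MotifHit]]:
    """Hits TSVs (with a family_pattern column) grouped by family."""
    frames = [pd.read_csv(p, sep="\t") for p in paths]
    df = pd.concat(frames, ignore_index=True)
    if "family_pattern" not in df.columns:
        raise DataError("hits TSV lacks a family_pattern column")
    groups: dict[str, list[MotifHit]] = {}
    for r in df.itertuples():
        groups.setdefault(str(r.family_pattern), []).append(
            MotifHit(int(r.start), int(r.length), str(r.strand),
                     int(r.edit_distance), str(r.matched_seq)))
    return groups


def write_ranking(ranking: SiteFamilyRanking, path: str | Path) -> None:
    pd.DataFrame(ranking.entries,
                 columns=["family_pattern", "n_hits", "median_ter_distance",
                          "rank"]).to_csv(path, sep="\t", index=False)


def read_template(path: str | Path) -> ComplexTemplate:
    """Template JSON: {chains: [{chain_id,type,reporter}], sites: [...]}."""
    with open(path) as fh:
        cfg = json.load(fh)
    chains = tuple(Chain(c["chain_id"], c["type"], bool(c.get("reporter", False)))
                   for c in cfg["chains"])
    sites = tuple(
        CrosslinkSite(
            s["name"],
            tuple((e[0], float(e[1])) for e in s["endpoints"]),
            float(s["efficiency"]),
        )
        for s in cfg["sites"]
    )
    return ComplexTemplate(chains=chains, sites=sites)


def read_threading_config(path: str | Path) -> ThreadingConfig:
    with open(path) as fh:
        cfg = json.load(fh)
    comps = tuple(DNAComponent(c["component_id"], int(c["ring_crossings"]),
                               int(c["clamp_crossings"]))
                  for c in cfg["components"])
    return ThreadingConfig(cfg["name"], comps, cfg.get("note", ""))


def load_config_file(path: str | Path) -> dict[str, Any]:
    """Flat key-value config (YAML-compatible subset); flags win over it."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, Mapping):
        raise DataError(f"{path}: config must be a flat key-value mapping")
    return dict(cfg)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_report(
    out_dir: str | Path,
    subcommand: str,
    config: Mapping[str, Any],
    inputs: Sequence[str | Path],
    outputs: Sequence[str | Path],
    warnings: Sequence[str] = (),
) -> Path:
    """Machine-readable record of a run, written next to the outputs.

    The timestamp is isolated in its own field so that all other fields
    are byte-identical across repeated runs.
    """
    from muklock import __version__

    report = {
        "tool": "muklock",
        "version": __version__,
        "python": platform.python_version(),
        "subcommand": subcommand,
        "config": {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in sorted(config.items())},
        "inputs": {str(p): file_digest(p) for p in inputs if Path(p).exists()},
        "outputs": [str(p) for p in outputs],
        "warnings": list(warnings),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{subcommand}.report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
    return path
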