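"""File formats and configuration.

The native on-disk dialect is long-format CSV, one row per measurement,
mirroring the "state data" layout that HDX processing software exports:
``protein, peptide_id, sequence, start, end, max_uptake, state, exposure_s,
replicate, centroid_da, is_control`` (centroid tables) or the same with an
``uptake`` column (uptake tables).  Exposure is seconds on disk and in
memory; plot axes use minutes.

Evidence tables use ``sequence, protein_id, start, end, modifications,
area, score`` with modifications encoded ``"45:digly;52:acetyl"``.

Experiment configs are YAML; see :func:`load_system_config`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .exchange_model import StateDefinition
from .synthetic_data import DEFAULT_TIMEPOINTS, GroundTruthSystem
from .uptake_pipeline import CENTROID_COLUMNS, UptakeCurve

__all__ = [
    "read_fasta",
    "read_state_data",
    "write_state_data",
    "read_evidence",
    "write_evidence",
    "load_system_config",
    "plot_uptake_curves",
]

logger = logging.getLogger(__name__)

_REQUIRED_STATE_COLUMNS = [c for c in CENTROID_COLUMNS if c != "centroid_da"]


def read_fasta(path) -> dict[str, str]:
    """Read sequences from FASTA, keyed by record id."""
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_state_data(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_state_data(path) -> pd.DataFrame:
    """Read a long-format state-data CSV (centroid or uptake flavour).

    Malformed rows (uncoercible numerics, negative exposure/replicate) are
    dropped, counted and logged; a missing mandatory column is a hard
    failure naming the column; an empty file is a hard failure.
    """
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"state-data file {path} is empty") from exc
    if table.empty:
        raise ValueError(f"state-data file {path} contains no rows")
    missing = [c for c in _REQUIRED_STATE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"state-data file {path} lacks mandatory column(s): {missing}")
    value_cols = [c for c in ("centroid_da", "uptake") if c in table.columns]
    if not value_cols:
        raise ValueError(
            f"state-data file {path} lacks a value column (centroid_da or uptake)"
        )
    n0 = len(table)
    for col in ("start", "end", "max_uptake", "exposure_s", "replicate", *value_cols):
        table[col] = pd.to_numeric(table[col], errors="coerce")
    if table["is_control"].dtype != bool:
        table["is_control"] = (
            table["is_control"].astype(str).str.strip().str.lower().map(
                {"true": True, "1": True, "false": False, "0": False}
            )
        )
    ok = (
        table[["start", "end", "max_uptake", "exposure_s", "replicate"]].notna().all(axis=1)
        & table[value_cols].notna().all(axis=1)
        & table["is_control"].notna()
        & (table["exposure_s"] >= 0)
        & (table["replicate"] >= 1)
    )
    rejected = int((~ok).sum())
    if rejected:
        logger.warning("%s: rejected %d malformed row(s) of %d", path, rejected, n0)
    table = table[ok].copy()
    if table.empty:
        raise ValueError(f"state-data file {path}: no valid rows after validation")
    table["is_control"] = table["is_control"].astype(bool)
    for col in ("start", "end", "max_uptake", "replicate"):
        table[col] = table[col].astype(int)
    return table.reset_index(drop=True)


def _encode_mods(mods) -> str:
    return ";".join(f"{pos}:{kind}" for pos, kind in mods)


def _decode_mods(text) -> list[tuple[int, str]]:
    if not isinstance(text, str) or not text.strip():
        return []
    out = []
    for item in text.split(";"):
        pos, kind = item.split(":")
        out.append((int(pos), kind.strip()))
    return out


def write_evidence(evidence: pd.DataFrame, path) -> None:
    out = evidence.copy()
    out["modifications"] = out["modifications"].map(_encode_mods)
    out.to_csv(path, index=False)


def read_evidence(path) -> pd.DataFrame:
    """Read an evidence CSV (minimal PEAKS-style dialect)."""
    try:
        table = pd.read_csv(path, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"evidence file {path} is empty") from exc
    required = ["sequence", "protein_id", "start", "end", "modifications", "area", "score"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"evidence file {path} lacks mandatory column(s): {missing}")
    table["modifications"] = table["modifications"].map(_decode_mods)
    for col in ("start", "end"):
        table[col] = table[col].astype(int)
    for col in ("area", "score"):
        table[col] = table[col].astype(float)
    return table


def load_system_config(path) -> GroundTruthSystem:
    """Build a :class:`GroundTruthSystem` from a YAML config.

    Schema::

        sequence: ACDEFG...         # or  fasta: path, protein: record-id
        states:
          - name: apo
            protection:             # residue-interval -> log10 protection
              - {start: 20, end: 40, log10_P: 3.0}
          - name: bound
            protection: [...]
        back_exchange_fraction: 0.25
        centroid_noise_sd: 0.02
        timepoints: [15, 30, 45, 60, 120]
        n_replicates: 3
        disordered_terminal_window: 10
        uniform_k_int: null         # optional override, 1/s
    """
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a mapping")
    if "sequence" in cfg:
        sequence = cfg["sequence"]
    elif "fasta" in cfg:
        records = read_fasta(path.parent / cfg["fasta"])
        sequence = records[cfg["protein"]] if "protein" in cfg else next(iter(records.values()))
    else:
        raise ValueError("config must provide 'sequence' or 'fasta'")
    states = []
    for sc in cfg.get("states", [{"name": "state"}]):
        profile = np.zeros(len(sequence))
        for iv in sc.get("protection", []):
            profile[int(iv["start"]) - 1 : int(iv["end"])] = float(iv["log10_P"])
        states.append(StateDefinition(sc["name"], sequence, profile))
    kwargs = {}
    for key in (
        "back_exchange_fraction", "centroid_noise_sd", "n_replicates",
        "disordered_terminal_window", "pD", "temperature_K", "uniform_k_int",
    ):
        if key in cfg:
            kwargs[key] = cfg[key]
    timepoints = tuple(float(t) for t in cfg.get("timepoints", DEFAULT_TIMEPOINTS))
    return GroundTruthSystem(sequence=sequence, states=states, timepoints=timepoints, **kwargs)


def plot_uptake_curves(
    curves: list[UptakeCurve], out_dir, max_plots: int | None = None
) -> list[Path]:
    """Render uptake plots (deuterons vs time in minutes), one file per
    peptide with all states overlaid; Y limit is the peptide's maximum
    exchangeable-amide count."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_peptide: dict[str, list[UptakeCurve]] = {}
    for c in curves:
        by_peptide.setdefault(c.peptide_id, []).append(c)
    paths = []
    for i, (pid, group) in enumerate(sorted(by_peptide.items())):
        if max_plots is not None and i >= max_plots:
            break
        fig, ax = plt.subplots(figsize=(4, 3))
        for c in group:
            t_min = c.timepoints / 60.0
            ax.errorbar(t_min, c.mean_uptake, yerr=c.sem, marker="o", capsize=3,
                        label=c.state)
            if c.fit is not None and c.fit.rate is not None:
                tt = np.linspace(0, c.timepoints.max(), 200)
                ax.plot(tt / 60.0, c.fit.amplitude * -np.expm1(-c.fit.rate * tt),
                        lw=0.8, alpha=0.7)
        ax.set_ylim(0, group[0].max_uptake)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("deuterons")
        ax.set_title(f"{pid} ({group[0].start}-{group[0].end})", fontsize=9)
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = out_dir / f"{pid}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
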