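"""Serialization of experiment outputs and believer-curve plots.

Every run of :func:`emit_outputs` writes a ``manifest.json`` that lists
each emitted file with its SHA-256 checksum together with the settings
that produced it, so any number in any file can be regenerated from the
manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .experiments import DurationSample, SweepTable
from .model import Trajectory

__all__ = ["emit_outputs", "plot_trajectory"]

# Figure colour convention: susceptibles blue, believers red, fact-checkers green.
COLORS = {"S": "tab:blue", "I": "tab:red", "R": "tab:green"}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def plot_trajectory(traj: Trajectory, title: str, path: Path) -> None:
    """Plot the three compartments as percentages of the population."""
    fig, ax = plt.subplots(figsize=(7, 4))
    n = traj.n
    ax.plot(traj.days, 100.0 * traj.s / n, color=COLORS["S"], label="susceptible")
    ax.plot(traj.days, 100.0 * traj.i / n, color=COLORS["I"], label="believer")
    ax.plot(traj.days, 100.0 * traj.r / n, color=COLORS["R"], label="fact-checker")
    ax.set_xlabel("day")
    ax.set_ylabel("% of population")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=100, metadata={"Software": None})
    plt.close(fig)


def emit_outputs(
    sweep_table: SweepTable,
    samples: Sequence[DurationSample] = (),
    trajectories: Optional[Sequence[tuple[str, Trajectory]]] = None,
    out_dir="out",
    settings: Optional[dict] = None,
) -> dict:
    """Write sweep summary, duration samples, trajectories and plots.

    ``trajectories`` is an optional list of ``(label, trajectory)`` pairs;
    each gets a per-day CSV and a time-series plot.  Returns the manifest
    (also written to ``manifest.json``): per-file SHA-256 checksums plus
    the caller-provided settings.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    written: list[Path] = []

    sweep_csv = out / "sweep.csv"
    sweep_table.to_csv(sweep_csv)
    written.append(sweep_csv)
    sweep_json = out / "sweep.json"
    sweep_table.to_json(sweep_json)
    written.append(sweep_json)

    for sample in samples:
        p = out / f"durations_{sample.label}.csv"
        sample.to_csv(p)
        written.append(p)

    for label, traj in trajectories or []:
        csv_path = out / f"trajectory_{label}.csv"
        traj.to_csv(csv_path)
        written.append(csv_path)
        png_path = out / f"trajectory_{label}.png"
        plot_trajectory(traj, f"scenario {label}", png_path)
        written.append(png_path)

    manifest = {
        "settings": settings or {},
        "files": [
            {"path": p.name, "sha256": _sha256(p), "bytes": p.stat().st_size}
            for p in written
        ],
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
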