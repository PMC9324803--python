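"""Figure-style outputs: persistence heat maps, energy bars, time series."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .interactions import PersistenceProfile

__all__ = [
    "persistence_heatmap",
    "series_plot",
    "rmsf_plot",
    "sse_plot",
    "energy_term_bars",
]


def persistence_heatmap(profile: PersistenceProfile, path: str | Path,
                        threshold: float | None = None) -> None:
    """Residue-pair x interaction-type heat map of occupancy fractions."""
    entries = profile.entries
    if threshold is not None:
        entries = {k: v for k, v in entries.items() if v > threshold}
    if not entries:
        entries = dict(profile.entries)
    pairs = sorted({(r1, r2) for r1, r2, _ in entries})
    types = sorted({t for _, _, t in entries})
    grid = np.zeros((len(pairs), len(types)))
    for (r1, r2, t), v in entries.items():
        grid[pairs.index((r1, r2)), types.index(t)] = v
    fig, ax = plt.subplots(figsize=(2 + len(types), 1 + 0.3 * len(pairs)))
    im = ax.imshow(grid, aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(len(types)), types, rotation=45, ha="right")
    ax.set_yticks(range(len(pairs)),
                  [f"{a[0]}{a[1]}:{b[0]}{b[1]}" for a, b in pairs], fontsize=7)
    fig.colorbar(im, label="fraction of frames")
    ax.set_title("interaction persistence")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def series_plot(series: np.ndarray, path: str | Path, ylabel: str,
                title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(np.arange(len(series)), series, lw=0.8)
    ax.set_xlabel("frame")
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def rmsf_plot(values: dict, path: str | Path) -> None:
    """Per-residue RMSF bars, keys are (chain, author number)."""
    keys = sorted(values)
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar(range(len(keys)), [values[k] for k in keys])
    ax.set_xticks(range(len(keys)), [f"{c}{n}" for c, n in keys],
                  rotation=90, fontsize=6)
    ax.set_ylabel("RMSF (A)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def sse_plot(helix_fraction: np.ndarray, strand_fraction: np.ndarray,
             path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(helix_fraction, label="% helix")
    ax.plot(strand_fraction, label="% strand")
    ax.set_xlabel("frame")
    ax.set_ylabel("% residues")
    ax.set_ylim(0, 100)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def energy_term_bars(term_means: dict, term_sds: dict, path: str | Path) -> None:
    """Formation-energy term decomposition with SD error bars."""
    keys = list(term_means)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(range(len(keys)), [term_means[k] for k in keys],
           yerr=[term_sds[k] for k in keys], capsize=3)
    ax.set_xticks(range(len(keys)), keys, rotation=45, ha="right")
    ax.set_ylabel("energy (kcal/mol)")
    ax.axhline(0, color="k", lw=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
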