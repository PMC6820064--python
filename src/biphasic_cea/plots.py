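"""Optional figure companions to the CSV outputs.

Figures are generated from the already-computed data frames; no reported
number originates here.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_sweep", "plot_tornado", "plot_ceac"]


def plot_sweep(
    sweep: pd.DataFrame,
    path: str | Path,
    threshold: float | None = None,
    wtp: float | None = None,
) -> Path:
    """One-way sensitivity curve (ICER vs input), with optional break-even line."""
    param = sweep.columns[0]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(sweep[param], sweep["icer_per_biphasic"], color="tab:blue")
    if wtp is not None:
        ax.axhline(wtp, color="grey", ls=":", lw=1)
    if threshold is not None:
        ax.axvline(threshold, color="black", ls="--", lw=1)
    ax.set_xlabel(param)
    ax.set_ylabel("ICER, $ per biphasic episode observed")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_tornado(rows: pd.DataFrame, path: str | Path, base_icer: float) -> Path:
    """Horizontal span of the ICER over each input's range, widest on top."""
    rows = rows.iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.5 * len(rows) + 1.5))
    for i, (_, r) in enumerate(rows.iterrows()):
        lo, hi = sorted((r["icer_at_low"], r["icer_at_high"]))
        ax.barh(i, hi - lo, left=lo, color="tab:blue", alpha=0.7)
    ax.axvline(base_icer, color="black", lw=1)
    ax.set_yticks(range(len(rows)), rows["parameter"])
    ax.set_xlabel("ICER, $ per biphasic episode observed")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_ceac(curve: pd.DataFrame, path: str | Path) -> Path:
    """Acceptability of extended observation against willingness to pay."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["wtp"], curve["acceptability"], color="tab:blue")
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("Willingness to pay, $ per biphasic episode observed")
    ax.set_ylabel("Probability extended observation is cost-effective")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
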