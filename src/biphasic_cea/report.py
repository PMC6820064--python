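"""Rendering and output writers: results tables, CSV/JSON files, manifests.

Rounding happens exactly once, here: engine values are carried unrounded and
formatted to the reporting granularity (cents for costs, one decimal for
percentages, whole dollars for ICERs) when a table is rendered.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import CohortResult
from .params import ModelConfig, ValidationError
from .psa import PsaSummary

__all__ = ["render_results_table", "write_manifest", "write_json", "write_csv"]


def _fmt_icer(x: float):
    return int(round(x)) if math.isfinite(x) else math.nan


def render_results_table(
    cohort: CohortResult, psa: PsaSummary | None = None
) -> pd.DataFrame:
    """Main cost-effectiveness results table for one perspective.

    Cohort rows always; Monte Carlo mean (SD) rows when a probabilistic
    summary from the same perspective is supplied.
    """
    if psa is not None and psa.perspective != cohort.perspective:
        raise ValidationError(
            f"perspective mismatch: cohort {cohort.perspective!r} "
            f"vs simulation {psa.perspective!r}"
        )
    rows = [
        {
            "analysis": "cohort",
            "strategy": "1-h observation",
            "cost_usd": round(cohort.cost_short, 2),
            "cost_sd_usd": math.nan,
            "postdischarge_biphasic_pct": round(100 * cohort.p_postdischarge_short, 1),
            "postdischarge_biphasic_sd_pct": math.nan,
            "icer_per_biphasic_usd": _fmt_icer(cohort.icer_per_biphasic),
        },
        {
            "analysis": "cohort",
            "strategy": "extended observation",
            "cost_usd": round(cohort.cost_extended, 2),
            "cost_sd_usd": math.nan,
            "postdischarge_biphasic_pct": round(
                100 * cohort.p_postdischarge_extended, 1
            ),
            "postdischarge_biphasic_sd_pct": math.nan,
            "icer_per_biphasic_usd": math.nan,
        },
    ]
    if psa is not None:
        rows += [
            {
                "analysis": "monte_carlo",
                "strategy": "1-h observation",
                "cost_usd": round(psa.mean_cost_short, 2),
                "cost_sd_usd": round(psa.sd_cost_short, 2),
                "postdischarge_biphasic_pct": round(100 * psa.mean_p_short, 1),
                "postdischarge_biphasic_sd_pct": round(100 * psa.sd_p_short, 1),
                "icer_per_biphasic_usd": _fmt_icer(psa.icer_per_biphasic),
            },
            {
                "analysis": "monte_carlo",
                "strategy": "extended observation",
                "cost_usd": round(psa.mean_cost_extended, 2),
                "cost_sd_usd": round(psa.sd_cost_extended, 2),
                "postdischarge_biphasic_pct": round(100 * psa.mean_p_extended, 1),
                "postdischarge_biphasic_sd_pct": round(100 * psa.sd_p_extended, 1),
                "icer_per_biphasic_usd": math.nan,
            },
        ]
    return pd.DataFrame(rows)


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=str) + "\n")
    return path


def write_manifest(
    out_dir: str | Path,
    subcommand: str,
    config: ModelConfig,
    seed: int,
    n_iterations: int,
    outputs: list[str],
    config_path: str | None = None,
) -> Path:
    """Record everything needed to reproduce a run bit-for-bit."""
    manifest = {
        "subcommand": subcommand,
        "config_path": config_path,
        "config": config.to_dict(),
        "seed": seed,
        "n_iterations": n_iterations,
        "perspective": config.costs.perspective,
        "outputs": outputs,
        "software_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    return write_json(manifest, Path(out_dir) / f"manifest_{subcommand}.json")
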