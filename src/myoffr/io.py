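"""Serialisation of run results: CSV traces, JSON summaries, config snapshot."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

from .analysis import cycle_metrics
from .engine import RunResult

__all__ = ["write_outputs"]


def write_outputs(result: RunResult, out_dir: str | Path) -> dict[str, Path]:
    """Write ``traces.csv`` (time_ms then named signals), ``metrics.json``,
    ``balance.json`` and a ``config.yaml`` snapshot; field ordering is
    deterministic, so re-running an identical configuration reproduces the
    files byte for byte."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "traces": out / "traces.csv",
        "metrics": out / "metrics.json",
        "balance": out / "balance.json",
        "config": out / "config.yaml",
    }
    result.traces.to_csv(paths["traces"], index=False, float_format="%.10g")
    metrics = asdict(cycle_metrics(result.final_cycle))
    metrics.update(
        frequency=result.protocol.frequency,
        camp=result.camp,
        n_cycles_run=result.n_cycles_run,
        converged=result.converged,
        stop_reason=result.stop_reason,
    )
    paths["metrics"].write_text(json.dumps(metrics, indent=2, sort_keys=True))
    balance = {k: (bool(v) if isinstance(v, bool) else float(v))
               for k, v in result.balance.items()}
    paths["balance"].write_text(json.dumps(balance, indent=2, sort_keys=True))
    result.config.save(paths["config"])
    return paths
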