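"""Summary tables over proofreading sessions and threshold sweeps."""

from __future__ import annotations

import json
import statistics
from pathlib import Path
from typing import Iterable, List, Mapping

import pandas as pd

from .agglomeration import SweepSummary


def sessions_table(summaries: Iterable[Mapping]) -> pd.DataFrame:
    """Per-strategy effort table: initial score and median/mean effort (%).

    One row per strategy, aggregated over seeds.
    """
    rows = list(summaries)
    if not rows:
        raise ValueError("need at least one session summary")
    df = pd.DataFrame(rows)
    out = (
        df.groupby("strategy")
        .agg(
            initial_gpr=("initial_gpr", "median"),
            median_effort_pct=("effort", lambda s: 100.0 * statistics.median(s)),
            mean_effort_pct=("effort", lambda s: 100.0 * s.mean()),
            n_runs=("effort", "size"),
        )
        .reset_index()
    )
    return out


def sweep_table(summary: SweepSummary) -> pd.DataFrame:
    rows = []
    for r in summary.results:
        rows.append(
            {
                "threshold": r.threshold,
                "n_segments": r.n_segments,
                "gpr_vs_seg": r.gpr_vs_seg,
                "ari": r.ari,
            }
        )
    return pd.DataFrame(rows)


def load_session_summaries(paths: Iterable) -> List[dict]:
    return [json.loads(Path(p).read_text()) for p in paths]


def plot_effort_curves(summaries, path) -> None:
    """Score-vs-decisions figure, one line per session, colored by strategy."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"gpr": "tab:blue", "random": "tab:orange", "edge_probability": "tab:green"}
    fig, ax = plt.subplots(figsize=(6, 4))
    seen = set()
    for s in summaries:
        trace = s.get("trace", [])
        if not trace:
            continue
        strategy = s["strategy"]
        label = strategy if strategy not in seen else None
        seen.add(strategy)
        ax.plot(range(1, len(trace) + 1), trace,
                color=colors.get(strategy, "gray"), alpha=0.6, label=label)
    ax.set_xlabel("decisions")
    ax.set_ylabel("certainty score")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def effort_curves(summaries: Iterable[Mapping]) -> pd.DataFrame:
    """Long-form table of the score trace per session for plotting."""
    rows = []
    for s in summaries:
        for i, v in enumerate(s.get("trace", [])):
            rows.append(
                {
                    "strategy": s["strategy"],
                    "seed": s["seed"],
                    "decision": i + 1,
                    "gpr": v,
                }
            )
    return pd.DataFrame(rows)
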