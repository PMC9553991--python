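"""CSV/JSON report writers and the run manifest.

Monetary columns are written at 2 decimals and QALYs at 3, matching the
print precision of the source tables; raw machine-precision values stay
available through the result objects themselves.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .model import CEAResults
from .parameters import ParameterSet

__all__ = ["write_manifest", "write_base_case", "write_psa", "write_dsa", "write_scenarios"]

MONEY_FMT = "%.2f"
QALY_DECIMALS = 3


def params_hash(params: ParameterSet) -> str:
    blob = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(out_dir: Path, command: str, params: ParameterSet,
                   seeds: dict, outputs: list, scenario: str | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "parameter_hash": params_hash(params),
        "seeds": seeds,
        "scenario": scenario,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "outputs": [str(p) for p in outputs],
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def _round_money(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in df.columns:
        name = str(col).lower()
        if df[col].dtype.kind != "f":
            continue
        if "qaly" in name:
            df[col] = df[col].round(QALY_DECIMALS)
        else:
            df[col] = df[col].round(2)
    return df


def write_base_case(res: CEAResults, out_dir: Path) -> list:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    p = out_dir / "base_case_comparison.csv"
    _round_money(res.comparison_table()).to_csv(p, index_label="arm")
    paths.append(p)
    p = out_dir / "base_case_secondary.csv"
    _round_money(res.secondary_table()).to_csv(p, index=False)
    paths.append(p)
    for trace, name in ((res.trace_screen, "trace_screening.csv"),
                        (res.trace_none, "trace_no_screening.csv")):
        p = out_dir / name
        trace.to_dataframe().to_csv(p, index=False, float_format="%.6f")
        paths.append(p)
    summary = out_dir / "summary.json"
    summary.write_text(json.dumps(res.econ.as_dict(), indent=2))
    paths.append(summary)
    return paths


def write_psa(psa, out_dir: Path) -> list:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    p = out_dir / "psa_draws.csv"
    psa.draws_dataframe().to_csv(p, index=False, float_format="%.6f")
    paths.append(p)
    p = out_dir / "ceac.csv"
    psa.ceac_dataframe().to_csv(p, index=False, float_format="%.6f")
    paths.append(p)
    p = out_dir / "psa_summary.json"
    mean_cost, mean_qaly = psa.mean_increment()
    p.write_text(json.dumps({
        "n_iterations": psa.n_iterations,
        "seed": psa.seed,
        "mean_inc_cost": mean_cost,
        "mean_inc_qaly": mean_qaly,
        "prob_ce_at_1gdp": psa.prob_ce_at_1gdp,
        "prob_ce_at_3gdp": psa.prob_ce_at_3gdp,
        "scatter_below_3gdp": psa.scatter_below_3gdp,
    }, indent=2))
    paths.append(p)
    return paths


def write_dsa(entries, out_dir: Path) -> list:
    from .uncertainty import tornado_dataframe

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p = out_dir / "tornado.csv"
    tornado_dataframe(entries).to_csv(p, index=False, float_format="%.6f")
    return [p]


def write_scenarios(results: dict, out_dir: Path) -> list:
    from .scenarios import scenario_table, secondary_outcomes_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    p = out_dir / "scenario_comparison.csv"
    _round_money(scenario_table(results)).to_csv(p, index=False)
    paths.append(p)
    p = out_dir / "scenario_secondary.csv"
    _round_money(secondary_outcomes_table(results)).to_csv(p, index=False)
    paths.append(p)
    return paths


def plot_tornado(entries, base_nmb: float, ax=None, top: int = 12):
    """Horizontal tornado of NMB swings for the largest-impact parameters."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.4 * min(top, len(entries)) + 1))
    shown = entries[:top]
    names = [e.parameter for e in shown][::-1]
    for k, e in enumerate(reversed(shown)):
        lo, hi = sorted((e.nmb_low, e.nmb_high))
        ax.barh(k, hi - lo, left=lo, height=0.6, color="steelblue", alpha=0.8)
    ax.axvline(base_nmb, color="black", lw=1)
    ax.set_yticks(range(len(names)), names, fontsize=8)
    ax.set_xlabel("Net monetary benefit (USD per capita)")
    return ax
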