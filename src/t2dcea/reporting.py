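"""Report and figure generation.

Monetary values in reports are rounded to the nearest dollar except ICERs,
which are shown both at full precision and to the nearest $10 (the display
convention of the published tables).  All writers are plain CSV/JSON so
runs can be diffed; plotting is optional and uses the Agg backend.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cea import CEAResult
from .engine import PathwayResult
from .oneway import TornadoEntry
from .psa import CEACCurve, PSAResult


def _pkg_version() -> str:
    try:
        return version("t2dcea")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass
class RunManifest:
    """Audit record written next to every report set."""

    subcommand: str
    config: str
    seed: int | None
    output_dir: str
    package_version: str
    timestamp: str
    options: dict

    @classmethod
    def create(cls, subcommand: str, config: str | None, seed: int | None,
               output_dir: str | Path, **options) -> "RunManifest":
        return cls(
            subcommand=subcommand,
            config=str(config) if config else "<packaged base case>",
            seed=seed,
            output_dir=str(output_dir),
            package_version=_pkg_version(),
            timestamp=datetime.datetime.now().isoformat(timespec="seconds"),
            options=options,
        )

    def write(self, out_dir: str | Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path


def base_case_table(
    results: dict[str, PathwayResult],
    cea_discounted: CEAResult,
    cea_undiscounted: CEAResult,
    ref_key: str,
    alt_key: str,
) -> pd.DataFrame:
    """Two-strategy summary in the published layout: totals, increments,
    ICER, for discounted and undiscounted accrual."""
    rows = []
    for variant, cea in (("discounted", cea_discounted), ("undiscounted", cea_undiscounted)):
        disc = variant == "discounted"
        for key, cost, ly, inc_c, inc_e, icer in (
            (ref_key, cea.cost_ref, cea.effect_ref, None, None, None),
            (alt_key, cea.cost_alt, cea.effect_alt, cea.delta_cost, cea.delta_effect,
             cea.icer),
        ):
            rows.append({
                "variant": variant,
                "pathway": key,
                "total_cost": round(cost),
                "total_life_years": round(ly, 2),
                "incremental_cost": None if inc_c is None else round(inc_c),
                "incremental_life_years": None if inc_e is None else round(inc_e, 2),
                "icer": None if icer is None else icer,
                "icer_rounded_10": None if icer is None else round(icer / 10) * 10,
                "dominance": cea.dominance if key == alt_key else "",
            })
    return pd.DataFrame(rows)


def write_base_case_report(
    out_dir: str | Path,
    results: dict[str, PathwayResult],
    cea_discounted: CEAResult,
    cea_undiscounted: CEAResult,
    ref_key: str,
    alt_key: str,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = base_case_table(results, cea_discounted, cea_undiscounted, ref_key, alt_key)
    table.to_csv(out / "base_case.csv", index=False)
    payload = {
        "discounted": _cea_json(cea_discounted),
        "undiscounted": _cea_json(cea_undiscounted),
        "reference": ref_key,
        "alternative": alt_key,
    }
    (out / "base_case.json").write_text(json.dumps(payload, indent=2) + "\n")
    for key, res in results.items():
        res.trace.to_frame().to_csv(out / f"trace_{key}.csv", index=False)


def _cea_json(cea: CEAResult) -> dict:
    return {
        "cost_ref": cea.cost_ref,
        "cost_alt": cea.cost_alt,
        "effect_ref": cea.effect_ref,
        "effect_alt": cea.effect_alt,
        "delta_cost": cea.delta_cost,
        "delta_effect": cea.delta_effect,
        "icer": cea.icer,
        "icer_rounded_10": cea.icer_rounded,
        "dominance": cea.dominance,
    }


def oneway_table(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    rows = []
    for e in entries:
        for side, value, icer in (("low", e.low_value, e.icer_low),
                                  ("high", e.high_value, e.icer_high)):
            rows.append({
                "label": e.label,
                "side": side,
                "value": value,
                "icer": icer,
                "icer_rounded_10": round(icer / 10) * 10,
                "pct_change": 100.0 * (icer - e.base_icer) / e.base_icer,
                "swing": e.swing,
            })
    return pd.DataFrame(rows)


def write_oneway_report(out_dir: str | Path, entries: Sequence[TornadoEntry]) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    oneway_table(entries).to_csv(out / "oneway.csv", index=False)


def write_psa_report(out_dir: str | Path, result: PSAResult, ceac: CEACCurve,
                     ref_key: str, alt_key: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "draw": np.arange(len(result.delta_cost)),
        "delta_cost": result.delta_cost,
        "delta_effect": result.delta_effect,
    }).to_csv(out / "psa_samples.csv", index=False)
    pd.DataFrame({
        "wtp": ceac.wtp_grid,
        "probability_cost_effective": ceac.probability_cost_effective,
    }).to_csv(out / "ceac.csv", index=False)
    summary = {
        "reference": ref_key,
        "alternative": alt_key,
        "n_draws": int(len(result.delta_cost)),
        "seed": result.seed,
        "n_resampled": result.n_resampled,
        "mean_cost_ref": float(result.cost_ref.mean()),
        "mean_cost_alt": float(result.cost_alt.mean()),
        "mean_effect_ref": float(result.effect_ref.mean()),
        "mean_effect_alt": float(result.effect_alt.mean()),
        "mean_delta_cost": result.mean_delta_cost,
        "mean_delta_effect": result.mean_delta_effect,
        "sd_delta_cost": result.sd_delta_cost,
        "sd_delta_effect": result.sd_delta_effect,
        "icer_of_means": result.icer_of_means,
        "icer_of_means_rounded_10": round(result.icer_of_means / 10) * 10,
    }
    (out / "psa_summary.json").write_text(json.dumps(summary, indent=2) + "\n")


# -- figures -----------------------------------------------------------------

def tornado_plot(entries: Sequence[TornadoEntry], path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    entries = sorted(entries, key=lambda e: e.swing)
    labels = [e.label for e in entries]
    base = entries[0].base_icer if entries else 0.0
    fig, ax = plt.subplots(figsize=(8, 0.4 * max(len(entries), 4) + 1.5))
    for i, e in enumerate(entries):
        lo, hi = sorted((e.icer_low, e.icer_high))
        ax.barh(i, hi - lo, left=lo, color="#4878d0", height=0.6)
    ax.axvline(base, color="k", lw=1)
    ax.set_yticks(range(len(entries)), labels, fontsize=8)
    ax.set_xlabel("ICER ($ per life-year gained)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def ce_plane_plot(result: PSAResult, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(result.delta_effect, result.delta_cost, s=6, alpha=0.4)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("Incremental life-years")
    ax.set_ylabel("Incremental cost ($)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def ceac_plot(ceac: CEACCurve, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ceac.wtp_grid, ceac.probability_cost_effective)
    ax.axhline(0.5, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("Willingness to pay ($ per life-year)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
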