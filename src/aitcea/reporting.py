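"""Report writers: base-case tables, PSA exports, tornado, and run manifests."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .config import ALLERGOID, FIVE_GRASS, SYMPTOMATIC, ModelConfig
from .economics import COST_COMPONENTS, ArmResult, compare

__all__ = [
    "config_hash",
    "write_manifest",
    "qaly_table",
    "cost_component_table",
    "incremental_table",
    "icer_table",
    "write_base_case_reports",
]

CONTRAST_PAIRS = ((FIVE_GRASS, ALLERGOID), (FIVE_GRASS, SYMPTOMATIC))


def config_hash(config: ModelConfig) -> str:
    """Stable SHA-256 of the canonical JSON dump of a config."""
    canonical = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def write_manifest(
    out_dir: Path, config: ModelConfig, outputs: list[str], seed: int | None = None
) -> Path:
    manifest = {
        "config_hash": config_hash(config),
        "package_version": __version__,
        "seed": seed if seed is not None else config.settings.rng_seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "outputs": sorted(outputs),
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def qaly_table(results: dict[str, ArmResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "arm": k,
                "qalys_discounted": r.qalys_discounted,
                "qalys_undiscounted": r.qalys_undiscounted,
            }
            for k, r in results.items()
        ]
    )


def cost_component_table(results: dict[str, ArmResult]) -> pd.DataFrame:
    """Undiscounted cost components with column percentages, per arm."""
    rows = []
    for comp in COST_COMPONENTS:
        row: dict[str, object] = {"component": comp}
        for k, r in results.items():
            value = r.costs.undiscounted.get(comp, 0.0)
            total = r.costs.total_undiscounted
            row[f"{k}_eur"] = value
            row[f"{k}_pct"] = 100.0 * value / total if total else 0.0
        rows.append(row)
    total_row: dict[str, object] = {"component": "total"}
    for k, r in results.items():
        total_row[f"{k}_eur"] = r.costs.total_undiscounted
        total_row[f"{k}_pct"] = 100.0
    rows.append(total_row)
    return pd.DataFrame(rows)


def incremental_table(results: dict[str, ArmResult], wtp: float) -> pd.DataFrame:
    rows = []
    for discounted in (True, False):
        for ref, comp in CONTRAST_PAIRS:
            inc = compare(results[ref], results[comp], wtp=wtp, discounted=discounted)
            rows.append(
                {
                    "contrast": f"{ref} vs {comp}",
                    "discounted": discounted,
                    "delta_cost": inc.delta_cost,
                    "delta_qaly": inc.delta_qaly,
                    "nmb": inc.nmb,
                }
            )
    return pd.DataFrame(rows)


def icer_table(results: dict[str, ArmResult], wtp: float) -> pd.DataFrame:
    rows = []
    for discounted in (True, False):
        for ref, comp in CONTRAST_PAIRS:
            inc = compare(results[ref], results[comp], wtp=wtp, discounted=discounted)
            rows.append(
                {
                    "contrast": f"{ref} vs {comp}",
                    "discounted": discounted,
                    "icer": inc.icer,
                }
            )
    return pd.DataFrame(rows)


def write_base_case_reports(
    results: dict[str, ArmResult], config: ModelConfig, out_dir: str | Path
) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    wtp = config.settings.wtp_threshold
    written = []
    for name, df in (
        ("qalys.csv", qaly_table(results)),
        ("cost_components.csv", cost_component_table(results)),
        ("incrementals.csv", incremental_table(results, wtp)),
        ("icers.csv", icer_table(results, wtp)),
    ):
        path = out / name
        df.to_csv(path, index=False, float_format="%.6f")
        written.append(path)
    for k, r in results.items():
        path = out / f"trace_{k}.csv"
        r.trace.to_frame().to_csv(path, index=False, float_format="%.12f")
        written.append(path)
    written.append(write_manifest(out, config, [p.name for p in written]))
    return written
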