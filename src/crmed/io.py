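"""Delimited-text I/O and report rendering.

File formats
------------
Trial history: tab- or comma-delimited with header
``cohort_id, dose, n, n_success, forced`` — doses are matched to the grid by
exact decimal value. pH trace: two columns (seconds, pH), header optional.
Run configuration: YAML mapping with ``design`` and ``prior`` sections.
"""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import (
    DesignConfig,
    DoseGrid,
    PriorSpec,
    Skeleton,
    default_design,
    default_prior,
)
from .engine import CohortRecord, ReplayReport, TrialHistory
from .ph import PhTrace

__all__ = [
    "read_history",
    "write_history",
    "read_ph_trace",
    "write_ph_trace",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "dump_config",
    "replay_table",
    "replay_summary",
    "provenance_header",
]

_HISTORY_COLS = ["cohort_id", "dose", "n", "n_success", "forced"]


def _read_delimited(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_history(path, grid: DoseGrid, stratum_label: str | None = None) -> TrialHistory:
    """Parse a trial history file; malformed rows raise with the line number."""
    df = _read_delimited(path)
    missing = [c for c in _HISTORY_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for line, row in df.iterrows():
        try:
            records.append(
                CohortRecord(
                    cohort_id=int(row["cohort_id"]),
                    dose_index=grid.index_of(float(row["dose"])),
                    n=int(row["n"]),
                    n_success=int(row["n_success"]),
                    forced=bool(int(row["forced"])),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {line + 2}: {exc}") from exc
    label = stratum_label if stratum_label is not None else str(Path(path).stem)
    return TrialHistory(label, records)


def write_history(history: TrialHistory, grid: DoseGrid, path) -> None:
    rows = [
        {
            "cohort_id": r.cohort_id,
            "dose": grid.doses[r.dose_index],
            "n": r.n,
            "n_success": r.n_success,
            "forced": int(r.forced),
        }
        for r in history.records
    ]
    pd.DataFrame(rows, columns=_HISTORY_COLS).to_csv(path, sep="\t", index=False)


def read_ph_trace(path) -> PhTrace:
    """Two-column (seconds, pH) delimited text; header optional."""
    raw = Path(path).read_text()
    first = raw.splitlines()[0] if raw.strip() else ""
    has_header = any(c.isalpha() for c in first)
    df = pd.read_csv(
        _io.StringIO(raw), sep=None, engine="python", header=0 if has_header else None
    )
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (seconds, pH)")
    return PhTrace(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))


def write_ph_trace(trace: PhTrace, path) -> None:
    pd.DataFrame(
        {"seconds": trace.timestamps, "ph": trace.ph_values}
    ).to_csv(path, sep="\t", index=False)


def config_to_dict(config: DesignConfig, prior: PriorSpec) -> dict:
    return {
        "design": {
            "doses": list(config.grid.doses),
            "skeleton": list(config.skeleton.prior_probs),
            "target": config.target,
            "cohort_size": config.cohort_size,
            "max_n": config.max_n,
            "ci_level": config.ci_level,
            "stop_low_margin": config.stop_low_margin,
            "stop_low_confidence": config.stop_low_confidence,
            "predictive_gain_eps": config.predictive_gain_eps,
            "stage2_ci_halfwidth": config.stage2_ci_halfwidth,
            "estimator_variant": config.estimator_variant,
        },
        "prior": {"family": prior.family, "scale": float(prior.scale)},
    }


def config_from_dict(d: dict) -> tuple[DesignConfig, PriorSpec]:
    des = d.get("design", {})
    kwargs = {k: des[k] for k in (
        "target", "cohort_size", "max_n", "ci_level", "stop_low_margin",
        "stop_low_confidence", "predictive_gain_eps", "stage2_ci_halfwidth",
        "estimator_variant",
    ) if k in des}
    if "doses" in des or "skeleton" in des:
        config = DesignConfig(
            grid=DoseGrid(des["doses"]), skeleton=Skeleton(des["skeleton"]), **kwargs
        )
    else:
        config = default_design(**kwargs)
    pr = d.get("prior", {})
    prior = PriorSpec(pr["family"], pr["scale"]) if pr else default_prior()
    return config, prior


def load_config(path) -> tuple[DesignConfig, PriorSpec]:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def dump_config(config: DesignConfig, prior: PriorSpec, path=None) -> str:
    text = yaml.safe_dump(config_to_dict(config, prior), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def replay_table(report: ReplayReport, config: DesignConfig, decimals: int = 3) -> pd.DataFrame:
    """Table-shaped replay output: one row per cohort, per-dose posterior
    means (rounded half-up to ``decimals``), and an MED marker column."""
    grid = config.grid

    def _round(x: float) -> float:
        # round-half-up at the reporting precision
        return float(np.floor(x * 10**decimals + 0.5) / 10**decimals)

    rows = []
    for s in report.steps:
        row = {
            "cohort": s.cohort_id,
            "dose": grid.doses[s.dose_index],
            "success": f"{s.n_success}/{s.n}",
        }
        for lab, p in zip(grid.labels, s.mean_probs):
            row[f"p({lab})"] = _round(float(p))
        row["med"] = grid.doses[s.med_estimate]
        row["discrepancy"] = s.discrepancy
        rows.append(row)
    return pd.DataFrame(rows)


def replay_summary(report: ReplayReport, config: DesignConfig) -> dict:
    """Machine-readable replay summary."""
    return {
        "stratum": report.stratum_label,
        "final_med_dose": config.grid.doses[report.med],
        "final_med_index": report.med,
        "mean_prob_at_med": report.med_mean_prob,
        "ci_level": config.ci_level,
        "ci_lower": report.ci[0],
        "ci_upper": report.ci[1],
        "stop_reason": report.stop_reason,
        "n_total": sum(s.n for s in report.steps),
        "discrepant_cohorts": report.discrepancies,
    }


def provenance_header(config: DesignConfig, prior: PriorSpec, seed=None) -> str:
    """Comment block identifying the configuration a report came from."""
    from . import __version__

    digest = hashlib.sha256(
        dump_config(config, prior).encode()
    ).hexdigest()[:12]
    lines = [f"# crmed {__version__}", f"# config-hash {digest}"]
    if seed is not None:
        lines.append(f"# seed {seed}")
    return "\n".join(lines) + "\n"
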