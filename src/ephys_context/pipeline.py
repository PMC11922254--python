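"""End-to-end orchestration: synth -> metrics -> lfp -> compare -> report.

A single JSON run-config is the source of truth; the resolved config is
echoed into the output directory together with a run log recording seeds,
package versions and every exclusion count, so a run can be reproduced
byte-for-byte from its output directory alone.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from . import group_stats, lfp_analysis, session_model, spike_metrics, synth


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage tag."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Everything a full run needs, with the study's thresholds as defaults."""

    out_dir: str = "run_output"
    session_dir: Optional[str] = None        # read an existing session ...
    synth_config: Optional[str] = None       # ... or generate one
    seed: int = 0
    ssa_threshold: float = spike_metrics.SSA_THRESHOLD
    width_threshold_ms: float = spike_metrics.BS_NS_THRESHOLD_MS
    alpha_responsive: float = spike_metrics.RESPONSIVE_ALPHA
    alpha_compare: float = group_stats.COMPARE_ALPHA
    alpha_lfp: float = lfp_analysis.LFP_ALPHA
    n_perm: int = lfp_analysis.N_PERMUTATIONS
    lfp_baseline: str = "before"
    fmax_hz: float = lfp_analysis.FMAX_HZ
    ctx1: str = "solitary"
    ctx2: str = "social"
    sqrt_denominator: bool = True

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _write_rows_csv(rows: list[dict], path) -> None:
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the run log (also written to disk)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "exclusions": {},
    }

    # ---- stage: session ----
    try:
        if config.synth_config is not None:
            sim = synth.config_from_json(config.synth_config)
            sim.seed = config.seed
            session = synth.generate_session(sim)
            session_model.write_session(session, out_dir / "session")
            log["session_source"] = "synthesized"
        elif config.session_dir is not None:
            session = session_model.read_session(config.session_dir)
            log["session_source"] = str(config.session_dir)
        else:
            raise ValueError("config needs session_dir or synth_config")
    except Exception as err:
        raise PipelineError("session", str(err)) from err

    # ---- stage: spike metrics ----
    try:
        exclusions: dict = {}
        metrics = spike_metrics.compute_unit_metrics(
            session, alpha=config.alpha_responsive,
            sqrt_denominator=config.sqrt_denominator,
            exclusion_log=exclusions)
        n_trials = {m.unit_id: max((sc.n_trials
                                    for sc in m.per_stimulus.values()),
                                   default=0)
                    for m in metrics}
        if n_trials and max(n_trials.values()) < 10:
            raise ValueError(
                "SSA needs >= 10 presentations per stimulus; the session "
                f"provides at most {max(n_trials.values())}")
        session_model.write_metrics_table(metrics, out_dir / "metrics.csv")
        session_model.write_dprime_table(metrics, out_dir / "dprime.csv")
        selected = spike_metrics.select_analysis_units(
            metrics, ssa_threshold=config.ssa_threshold)
        exclusions["non_responsive_units"] = sum(
            1 for m in metrics if not m.responsive)
        exclusions["adapting_units_excluded"] = (
            len([m for m in metrics if m.responsive]) - len(selected))
        log["exclusions"].update(exclusions)
        log["n_units"] = len(metrics)
        log["n_units_selected"] = len(selected)
        log["units_by_class"] = {
            cls: sum(1 for m in metrics if m.unit_class == cls)
            for cls in ("BS", "NS")}
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError("metrics", str(err)) from err

    # ---- stage: LFP ----
    if session.lfp is not None:
        try:
            lfp_log: dict = {}
            rows = lfp_analysis.analyze_session_lfp(
                session.lfp, session.epochs, baseline=config.lfp_baseline,
                n_perm=config.n_perm, alpha=config.alpha_lfp,
                fmax_hz=config.fmax_hz, seed=config.seed,
                exclusion_log=lfp_log)
            _write_rows_csv(rows, out_dir / "lfp_results.csv")
            log["exclusions"].update(lfp_log)
        except Exception as err:
            raise PipelineError("lfp", str(err)) from err

    # ---- stage: context comparison ----
    contexts = {e.context for e in session.epochs}
    if config.ctx1 in contexts and config.ctx2 in contexts:
        try:
            cmp_log: dict = {}
            comparisons = group_stats.compare_contexts(
                selected, ctx1=config.ctx1, ctx2=config.ctx2,
                alpha=config.alpha_compare, exclusion_log=cmp_log)
            _write_rows_csv(group_stats.comparisons_to_rows(comparisons),
                            out_dir / "comparisons.csv")
            log["exclusions"].update(cmp_log)
        except Exception as err:
            raise PipelineError("compare", str(err)) from err

    config.to_json(out_dir / "resolved_config.json")
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
    return log
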