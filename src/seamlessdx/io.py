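"""Configuration, result serialization and deterministic test fixtures.

Run configurations round-trip through YAML; scenario results are written as
RFC-4180 CSV with a JSON metadata sidecar recording the seed, replicate
count, software version, tie rule and margin mode of the run.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accuracy import HypothesisPair
from .design import DesignSpec, composition_for_target_interim_total, interim_composition
from .scenarios import PerformanceSummary, results_to_dataframe
from .trial import TrialTruth, run_trial

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "write_results",
    "make_fixture_trials",
    "FIXTURE_PRESETS",
]


class ConfigError(ValueError):
    """Raised for a missing, unreadable or schema-invalid configuration."""


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a planning, analysis or simulation run."""

    design: DesignSpec
    truth: TrialTruth | None = None
    reps: int = 2000
    seed: int = 0
    out: str | None = None
    min_final_runs: int = 40

    def to_dict(self) -> dict:
        d: dict = {
            "design": {
                "final_n": self.design.final_n,
                "stopping_time": self.design.stopping_time,
                "prevalence": self.design.prevalence,
                "f_se": self.design.f_se,
                "f_sp": self.design.f_sp,
                "se0": self.design.hyp.se0,
                "sp0": self.design.hyp.sp0,
                "ci_level": self.design.ci_level,
                "margin_mode": self.design.margin_mode,
            },
            "reps": self.reps,
            "seed": self.seed,
            "min_final_runs": self.min_final_runs,
        }
        if self.truth is not None:
            d["truth"] = {
                "se_true": self.truth.se_true,
                "sp_true": self.truth.sp_true,
                "prevalence": self.truth.prevalence,
                "delta_add": self.truth.delta_add,
            }
        if self.out is not None:
            d["out"] = self.out
        return d


def _design_from_dict(d: dict) -> DesignSpec:
    required = ("final_n", "stopping_time", "prevalence", "f_se", "f_sp")
    for key in required:
        if key not in d:
            raise ConfigError(f"design section is missing required field {key!r}")
    try:
        hyp = HypothesisPair(d.get("se0", 0.8), d.get("sp0", 0.8))
        return DesignSpec(
            final_n=int(d["final_n"]),
            stopping_time=float(d["stopping_time"]),
            prevalence=float(d["prevalence"]),
            f_se=float(d["f_se"]),
            f_sp=float(d["f_sp"]),
            hyp=hyp,
            ci_level=float(d.get("ci_level", 0.95)),
            margin_mode=str(d.get("margin_mode", "fixed")),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid design parameters: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration, applying defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or "design" not in raw:
        raise ConfigError("config must be a mapping with a 'design' section")
    design = _design_from_dict(raw["design"])
    truth = None
    if "truth" in raw:
        t = raw["truth"]
        try:
            truth = TrialTruth(
                se_true=float(t["se_true"]),
                sp_true=float(t["sp_true"]),
                prevalence=float(t.get("prevalence", design.prevalence)),
                delta_add=float(t.get("delta_add", 0.0)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid truth parameters: {exc}") from exc
    return RunConfig(
        design=design,
        truth=truth,
        reps=int(raw.get("reps", 2000)),
        seed=int(raw.get("seed", 0)),
        out=raw.get("out"),
        min_final_runs=int(raw.get("min_final_runs", 40)),
    )


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def write_results(
    summaries: list[PerformanceSummary],
    path: str | Path,
    seed: int | None = None,
) -> Path:
    """Write one CSV row per scenario plus a JSON metadata sidecar.

    Missing conditional measures appear as empty cells.  The sidecar at
    ``<path>.meta.json`` records seed, replicate count, version, tie rule
    and margin mode so a results file is self-describing.
    """
    if not summaries:
        raise ValueError("summaries must be nonempty")
    path = Path(path)
    df = results_to_dataframe(summaries)
    df.to_csv(path, index=False, lineterminator="\r\n")
    meta = {
        "seed": seed,
        "reps": sorted({s.reps for s in summaries}),
        "n_scenarios": len(summaries),
        "version": __version__,
        "tie_rule": "continue only if strictly above; reject only if strictly above",
        "margin_mode": "fixed",
        "bias_pooling": "sensitivity and specificity pooled in percentile summaries",
    }
    meta_path = path.with_name(path.name + ".meta.json")
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


#: Named small designs used by the documentation and the test suite.  The
#: "worked_example" preset is the hypothetical study pair (se0=0.90,
#: sp0=0.85, boundaries ten points below, p=0.2, N=500, s=0.2); "balanced
#: interim_100" fixes the interim analysis population at 100 participants
#: split 1:1 at 10% prevalence.
FIXTURE_PRESETS: dict[str, dict] = {
    "worked_example": {
        "design": dict(
            final_n=500, stopping_time=0.2, prevalence=0.2,
            f_se=0.80, f_sp=0.75, se0=0.90, sp0=0.85,
        ),
        "truth": dict(se_true=0.85, sp_true=0.80, prevalence=0.2, delta_add=0.0),
        "n_trials": 5,
    },
    "interim_100": {
        "interim_total": 100,
        "prevalence": 0.1,
        "design": dict(
            final_n=500, stopping_time=0.2, prevalence=0.1,
            f_se=0.80, f_sp=0.75, se0=0.90, sp0=0.85,
        ),
        "truth": dict(se_true=0.90, sp_true=0.85, prevalence=0.1, delta_add=0.0),
        "n_trials": 3,
    },
}


def make_fixture_trials(preset_name: str, seed: int) -> dict:
    """Deterministic small trial set for a named preset, as plain data.

    Returns a JSON-serializable dict with the planned interim composition
    and a handful of simulated trials; the same seed always yields
    identical bytes after ``json.dumps(..., sort_keys=True)``.
    """
    if preset_name not in FIXTURE_PRESETS:
        raise KeyError(
            f"unknown preset {preset_name!r}; available: {sorted(FIXTURE_PRESETS)}"
        )
    preset = FIXTURE_PRESETS[preset_name]
    d = preset["design"]
    spec = _design_from_dict(d)
    truth = TrialTruth(**preset["truth"])
    if "interim_total" in preset:
        comp = composition_for_target_interim_total(
            preset["prevalence"], preset["interim_total"]
        )
    else:
        comp = interim_composition(
            spec.prevalence, spec.final_n, spec.stopping_time
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    trials = []
    for _ in range(preset["n_trials"]):
        outcome = run_trial(spec, truth, rng)
        entry: dict = {
            "stopped": bool(outcome.stopped),
            "interim_se_hat": outcome.interim_se_hat,
            "interim_sp_hat": outcome.interim_sp_hat,
        }
        if not outcome.stopped:
            c = outcome.final_counts
            entry["final_counts"] = {
                "n_tp": c.n_tp, "n_fp": c.n_fp, "n_tn": c.n_tn, "n_fn": c.n_fn,
            }
            entry["ci_se"] = [outcome.ci_se.lower, outcome.ci_se.upper]
            entry["ci_sp"] = [outcome.ci_sp.lower, outcome.ci_sp.upper]
            entry["reject_global"] = bool(outcome.rejections[spec.hyp])
        trials.append(entry)
    return {
        "preset": preset_name,
        "seed": int(seed),
        "composition": {
            "n1": comp.n1,
            "pop_cases": comp.pop_cases,
            "added_cases": comp.added_cases,
            "controls": comp.controls,
        },
        "trials": trials,
    }
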