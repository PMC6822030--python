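"""End-to-end orchestration: config, staged run, report bundle.

A run is fully specified by a declarative YAML config plus the data files
and a seed.  Defaults are the survey-design constants: 5-night occasions,
15 km state-space buffer, 1.5 km resolution.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .io import Dialect, SessionSet, read_encounters, read_traps
from .model import SCRModel
from .raster import write_ascii_grid, write_surface_csv
from .report import build_report
from .simulate import read_truth

__all__ = ["RunConfig", "PipelineError", "StageError", "run"]

_KNOWN_ESTIMATORS = ("scr", "m0", "mh", "mmdm")


class PipelineError(Exception):
    """Configuration/validation failure (before any computation)."""


class StageError(Exception):
    """Failure inside a named pipeline stage."""

    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative run specification.

    sessions: list of dicts with keys label, traps, encounters and
    optionally truth (a simulation sidecar for recovery diagnostics).
    sharing maps labels to detection-parameter groups.
    """

    sessions: list
    sharing: dict = field(default_factory=dict)
    occasion_length: int = 5
    buffer: float = 15000.0
    resolution: float = 1500.0
    estimators: tuple = _KNOWN_ESTIMATORS
    dialect_mode: str = "daily"
    seed: int = 0
    output: str = "lynxscr_run"

    def validate(self):
        if not self.sessions:
            raise PipelineError("config lists no sessions")
        for spec in self.sessions:
            for key in ("label", "traps", "encounters"):
                if key not in spec:
                    raise PipelineError(f"session spec missing {key!r}: {spec}")
            for key in ("traps", "encounters", "truth"):
                if key in spec and not Path(spec[key]).exists():
                    raise PipelineError(f"file not found: {spec[key]}")
        bad = set(self.estimators) - set(_KNOWN_ESTIMATORS)
        if bad:
            raise PipelineError(f"unknown estimators {sorted(bad)}")
        if self.occasion_length < 1:
            raise PipelineError("occasion_length must be >= 1")
        if self.buffer <= 0 or self.resolution <= 0:
            raise PipelineError("buffer and resolution must be positive")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(obj) - known
        if bad:
            raise PipelineError(f"unknown config keys {sorted(bad)}")
        cfg = cls(**obj)
        if isinstance(cfg.estimators, (list, tuple)):
            cfg.estimators = tuple(cfg.estimators)
        return cfg.validate()


def run(config: RunConfig) -> dict:
    """Execute a full run: load, fit, report, export.

    Deterministic given the config and seed.  Returns a bundle dict with
    the report DataFrame, the fitted SCRModel (if requested) and output
    paths; writes summary.csv, per-session density rasters/CSVs, and a
    machine-readable run log.
    """
    config.validate()
    out = Path(config.output)
    out.mkdir(parents=True, exist_ok=True)
    dialect = Dialect(mode=config.dialect_mode, occasion_length=config.occasion_length)

    try:
        pairs, truths = [], {}
        for spec in config.sessions:
            traps = read_traps(spec["traps"], dialect)
            enc = read_encounters(
                spec["encounters"], traps, dialect, session=spec.get("session")
            )
            enc.session_id = spec["label"]
            pairs.append((traps, enc))
            if "truth" in spec:
                truths[spec["label"]] = read_truth(spec["truth"])
        sessions = SessionSet(pairs, dict(config.sharing))
    except Exception as e:  # noqa: BLE001 - stage-named rewrap
        raise StageError("load", e) from e

    fit = None
    if "scr" in config.estimators:
        try:
            fit = SCRModel(buffer=config.buffer, resolution=config.resolution).fit(
                sessions
            )
        except Exception as e:
            raise StageError("scr_fit", e) from e

    try:
        report = build_report(sessions, scr_fit=fit, estimators=config.estimators)
        if truths:
            report["true_n"] = [
                truths[s].n_true if s in truths else np.nan
                for s in report["session"]
            ]
            report["true_p0_logit"] = [
                float(np.log(t.p0_true / (1 - t.p0_true)))
                if (t := truths.get(s)) is not None and 0 < t.p0_true < 1
                else np.nan
                for s in report["session"]
            ]
            report["true_log_sigma"] = [
                np.log(truths[s].sigma_true) if s in truths else np.nan
                for s in report["session"]
            ]
        report.to_csv(out / "summary.csv", index=False, float_format="%.10g")
    except StageError:
        raise
    except Exception as e:
        raise StageError("report", e) from e

    surfaces = {}
    if fit is not None:
        try:
            for traps, enc in sessions.sessions:
                sid = enc.session_id
                surf = fit.density_surface(sid)
                ss = fit.statespaces_[sid]
                write_ascii_grid(surf, ss, out / f"density_{sid}.asc")
                write_surface_csv(surf, ss, out / f"density_{sid}.csv")
                surfaces[sid] = surf
        except Exception as e:
            raise StageError("density_surface", e) from e

    log = {
        "lynxscr_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "estimators": list(config.estimators),
        "sessions": [s["label"] for s in config.sessions],
        "sharing": sessions.sharing,
        "scr_converged": None if fit is None else fit.converged_,
        "scr_grad_norm": None if fit is None else fit.grad_norm_,
        "scr_loglik": None if fit is None else fit.loglik_,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, default=str)

    return {
        "report": report,
        "fit": fit,
        "surfaces": surfaces,
        "output_dir": out,
        "log": log,
    }
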