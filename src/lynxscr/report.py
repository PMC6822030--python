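"""Survey bookkeeping tallies and per-session estimate reports.

Ships two small reference tables transcribed from the published summary of
the French Jura/Vosges lynx camera-trap surveys (the raw encounter data are
not public): per-survey effort and detection counts, and the published
abundance/density estimates.  The tally functions reproduce the study-wide
totals from the per-survey table; `build_report` assembles the same column
structure (spatial and nonspatial estimates side by side) for any fitted
session set.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd

from .geometry import effective_trapping_area, mmdm, max_distance_moved, nonspatial_density
from .nonspatial import MhEstimator, M0Estimator, capture_frequencies

__all__ = [
    "load_survey_summary",
    "load_reported_estimates",
    "survey_tallies",
    "build_report",
]


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("lynxscr.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_survey_summary() -> pd.DataFrame:
    """Per-survey effort and detection counts (transcribed summary table).

    `trap_days`, where empty, is derivable as cameras x mean days / 2
    (two cameras per site; effort is counted per site-night).
    """
    return _load_csv("jura_survey_summary.csv")


def load_reported_estimates() -> pd.DataFrame:
    """Published per-survey abundance/density estimates (transcription)."""
    return _load_csv("jura_reported_estimates.csv")


def survey_tallies(summary: pd.DataFrame | None = None) -> dict:
    """Study-wide totals from a per-survey summary table.

    Trap days per survey use the explicit `trap_days` column where present,
    otherwise n_cameras * mean_trap_days / 2 (paired cameras at one site
    form a single detector, so effort is site-nights).
    """
    if summary is None:
        summary = load_survey_summary()
    computed = summary["n_cameras"] * summary["mean_trap_days"] / 2.0
    if "trap_days" in summary.columns:
        days = summary["trap_days"].where(summary["trap_days"].notna(), computed)
    else:
        days = computed
    return {
        "individuals": int(summary["n_individuals"].sum()),
        "detections": int(summary["n_detections"].sum()),
        "trap_days": int(round(days.sum())),
    }


def build_report(
    sessions,
    scr_fit=None,
    estimators: tuple = ("scr", "m0", "mh", "mmdm"),
) -> pd.DataFrame:
    """Per-session estimate table combining SCR and nonspatial results.

    Columns mirror the published layout: SCR abundance/density and
    detection parameters, M0/Mh abundances, MMDM, and the MMDM/HMMDM
    effective trapping areas with the corresponding nonspatial densities
    (per 100 km2).
    """
    rows = []
    for traps, enc in sessions.sessions:
        row: dict = {"session": enc.session_id, "n_individuals": enc.n_individuals}
        if "scr" in estimators and scr_fit is not None:
            s = scr_fit.summary_
            srow = s[s["session"] == enc.session_id]
            if len(srow):
                for c in (
                    "abundance", "abundance_se", "density_100km2", "density_se",
                    "p0_logit", "p0_logit_se", "log_sigma", "log_sigma_se",
                ):
                    row[f"scr_{c}"] = float(srow.iloc[0][c])
        freq = capture_frequencies(enc) if enc.n_individuals else None
        if "m0" in estimators and freq is not None:
            m0 = M0Estimator().fit(freq)
            row.update(m0_abundance=m0.N_, m0_abundance_se=m0.N_se_, m0_p=m0.p_)
        if "mh" in estimators and freq is not None:
            mh = MhEstimator().fit(freq)
            row.update(mh_abundance=mh.N_, mh_abundance_se=mh.N_se_)
        if "mmdm" in estimators and enc.n_individuals:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                m = mmdm(enc, traps)
            row["mmdm_m"] = m
            if np.isfinite(m):
                n_used = int(np.isfinite(max_distance_moved(enc, traps)).sum())
                for tag, w in (("mmdm", m), ("hmmdm", m / 2.0)):
                    eta = effective_trapping_area(
                        traps, w, mmdm_value=m, n_individuals_used=n_used
                    )
                    row[f"eta_{tag}_km2"] = eta.eta_km2
                    for est in ("m0", "mh"):
                        if f"{est}_abundance" in row:
                            d, sd = nonspatial_density(
                                row[f"{est}_abundance"],
                                row[f"{est}_abundance_se"],
                                eta,
                            )
                            row[f"{est}_density_{tag}"] = d
                            row[f"{est}_density_{tag}_se"] = sd
        rows.append(row)
    return pd.DataFrame(rows)
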