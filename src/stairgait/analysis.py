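"""Gait evaluation metrics from rollout traces.

Quantifies how closely a simulated rollout reproduces the reference motion
and summarises the physical output of the simulation:

* per-joint Pearson correlation between simulated and reference joint
  angles, excluding the final 0.5 s of the rollout (the fall at the end of
  the terrain), and their mean;
* the reward fraction — mean per-step reward as a percentage of the
  per-step maximum (1.0), i.e. how "accurate" the gait is to the imitation
  data;
* per-muscle mean and peak fiber force against the (scaled) maximum
  isometric force;
* per-foot vertical ground reaction force series with peak, mean over
  contact samples (zeros excluded) and contact-episode counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "joint_correlation",
    "reward_fraction",
    "muscle_summary",
    "grf_report",
    "gait_report",
]

TAIL_EXCLUSION = 0.5  # s dropped from the end of the rollout


def joint_correlation(sim_series, ref_series, dt: float,
                      exclude_tail: float = TAIL_EXCLUSION):
    """Pearson correlation of two equal-length joint-angle series.

    The last ``exclude_tail`` seconds are dropped before correlating.
    Returns ``None`` (flagged undefined, never NaN) when either truncated
    series is constant or shorter than 3 samples.
    """
    a = np.asarray(sim_series, dtype=float)
    b = np.asarray(ref_series, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    n_drop = int(round(exclude_tail / dt))
    if n_drop > 0:
        a, b = a[:-n_drop] if n_drop < len(a) else a[:0], b[:-n_drop] if n_drop < len(b) else b[:0]
    if len(a) < 3:
        return None
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        return None
    return float(sstats.pearsonr(a, b)[0])


def reward_fraction(achieved_mean_reward: float, max_per_step: float = 1.0) -> float:
    """Achieved mean per-step reward as a percentage of the per-step maximum."""
    if achieved_mean_reward < 0:
        raise ValueError("mean reward must be non-negative")
    if max_per_step <= 0:
        raise ValueError("max_per_step must be positive")
    return 100.0 * achieved_mean_reward / max_per_step


def muscle_summary(force_traces: pd.DataFrame, specs) -> pd.DataFrame:
    """Per-muscle mean/peak fiber force against the scaled isometric maximum.

    ``force_traces`` has one column per muscle (N over the rollout);
    ``specs`` maps muscle name to its maximum isometric force (or is a
    ModelSpec whose muscles carry ``f_max``).
    """
    if hasattr(specs, "muscles"):
        fmax = {m.params.name: m.params.f_max for m in specs.muscles}
    else:
        fmax = dict(specs)
    rows = []
    for name in force_traces.columns:
        series = force_traces[name].to_numpy(dtype=float)
        peak = float(series.max()) if len(series) else 0.0
        mean = float(series.mean()) if len(series) else 0.0
        cap = float(fmax.get(name, np.nan))
        rows.append({
            "muscle": name,
            "mean_force": mean,
            "peak_force": peak,
            "f_max": cap,
            "exceeds_isometric": bool(peak > cap) if np.isfinite(cap) else False,
        })
    return pd.DataFrame(rows).set_index("muscle")


@dataclass
class GRFReport:
    """Vertical ground reaction summary for one foot."""

    series: np.ndarray           # signed GRF-Y (negative up, mocap convention)
    magnitude: np.ndarray        # |GRF-Y|
    peak: float                  # largest magnitude (N)
    nonzero_mean: float          # mean magnitude over contact samples; None if never
    episodes: int                # maximal runs of nonzero contact


def grf_report(contact_log: pd.DataFrame, foot: str = "l",
               column: str = None) -> GRFReport:
    """Summarise the vertical ground reaction of one foot from a contact log.

    ``contact_log`` is the columnar per-step trace with ``grf_<foot>_y``
    columns (upward-positive simulation convention).  The report keeps a
    signed series in the motion-capture convention (upward reaction printed
    negative) alongside magnitudes; the mean excludes zero (no-contact)
    samples, and an episode is a maximal run of nonzero contact.
    """
    col = column or f"grf_{foot}_y"
    fy = contact_log[col].to_numpy(dtype=float)
    mag = np.abs(fy)
    nz = mag > 0.0
    episodes = int(np.sum(nz[1:] & ~nz[:-1]) + (1 if len(nz) and nz[0] else 0))
    nonzero_mean = float(mag[nz].mean()) if nz.any() else None
    return GRFReport(
        series=-mag,
        magnitude=mag,
        peak=float(mag.max()) if len(mag) else 0.0,
        nonzero_mean=nonzero_mean,
        episodes=episodes,
    )


def gait_report(log: pd.DataFrame, reference, model_spec, dt: float,
                joints=("knee_l", "knee_r", "ankle_l", "ankle_r"),
                exclude_tail: float = TAIL_EXCLUSION) -> dict:
    """Full metric bundle for one rollout trace against its reference.

    Returns a JSON-serialisable dict: per-joint correlations and their mean,
    reward fraction, muscle force summary and per-foot GRF reports.
    """
    times = log["time"].to_numpy(dtype=float)
    corr = {}
    for j in joints:
        idx = [reference.index_at(min(t, reference.duration)) for t in times]
        ref_series = reference.column(j)[idx]
        corr[j] = joint_correlation(log[j].to_numpy(dtype=float), ref_series,
                                    dt, exclude_tail)
    defined = [v for v in corr.values() if v is not None]
    mus_cols = [c for c in log.columns if c.startswith("F_")]
    forces = log[mus_cols].rename(columns=lambda c: c[2:])
    summary = muscle_summary(forces, model_spec)
    out = {
        "joint_correlations": corr,
        "mean_correlation": float(np.mean(defined)) if defined else None,
        "reward_fraction": reward_fraction(float(log["reward"].mean())),
        "muscles": summary.reset_index().to_dict(orient="records"),
        "grf": {},
    }
    for foot in ("l", "r"):
        rep = grf_report(log, foot)
        out["grf"][foot] = {
            "peak": rep.peak,
            "nonzero_mean": rep.nonzero_mean,
            "episodes": rep.episodes,
        }
    return out
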