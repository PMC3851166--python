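"""Synthetic input files: river loads and station-style observations.

Everything downstream of the forcing readers and the skill module can be
exercised without any download: this module writes CSV files shaped like
the real inputs — a large river with daily discharge and concentrations
whose NO3:PO4 ratio sits in the 65–80 band characteristic of the river's
relative phosphorus deficit, the constant-concentration sources, a
sewage outfall, and fortnightly station observations subsampled from a
model trajectory with multiplicative lognormal noise (which preserves
positivity) and detection-limit censoring for phosphate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulator import Trajectory

__all__ = ["FixtureSpec", "make_river_fixture", "make_obs_fixture"]

#: Phosphate detection limit (µmol L⁻¹): measured precision of coastal
#: PO4 determinations is about ±0.02–0.03.
PO4_DETECTION_LIMIT = 0.025


@dataclass
class FixtureSpec:
    """Reproducible recipe for a set of synthetic input files."""

    seed: int = 0
    start: str = "2008-01-01"
    n_days: int = 365
    noise: float = 0.15          # lognormal sigma on concentrations
    rhone_mean_no3: float = 100.0   # umol L-1
    rhone_mean_discharge: float = 1700.0  # m3 s-1 (total, before 0.90)


def make_river_fixture(spec: FixtureSpec, outdir) -> dict[str, Path]:
    """Write rhone.csv, caronte.csv and wwtp.csv; returns their paths.

    The river file carries raw concentrations (DOC…POP, lability not yet
    applied); its daily NO3:PO4 ratio is drawn uniformly in [65, 80].
    Identical specs give identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    dates = pd.date_range(spec.start, periods=spec.n_days, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)

    def jitter(n: int) -> np.ndarray:
        return np.exp(rng.normal(0.0, spec.noise, n)
                      - 0.5 * spec.noise ** 2)

    n = len(dates)
    discharge = spec.rhone_mean_discharge * (
        1.0 + 0.45 * np.cos(2 * np.pi * (doy - 120.0) / 365.25)
    ) * jitter(n)
    no3 = spec.rhone_mean_no3 * jitter(n)
    ratio = rng.uniform(65.0, 80.0, n)
    rhone = pd.DataFrame({
        "date": dates,
        "discharge": discharge,
        "NO3": no3,
        "NH4": 2.0 * jitter(n),
        "PO4": no3 / ratio,
        "DOC": 150.0 * jitter(n),
        "DON": 12.0 * jitter(n),
        "DOP": 0.30 * jitter(n),
        "POC": 80.0 * jitter(n),
        "PON": 8.0 * jitter(n),
        "POP": 0.90 * jitter(n),
    })

    caronte = pd.DataFrame({"date": dates, "discharge": 20.0})
    wwtp = pd.DataFrame({
        "date": dates,
        "discharge": 1.5,
        "NO3": 30.0 * jitter(n),
        "NH4": 1500.0 * jitter(n),
    })

    paths = {}
    for name, df in (("rhone", rhone), ("caronte", caronte),
                     ("wwtp", wwtp)):
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths


def make_obs_fixture(truth: Trajectory, path, *, seed: int = 0,
                     noise: float = 0.15,
                     interval_days: float = 14.0,
                     start_date: str = "2008-01-01",
                     censor_po4: bool = True) -> pd.DataFrame:
    """Station-style observation CSV subsampled from a trajectory.

    Samples every ``interval_days`` (fortnightly station cadence); column
    runs are sampled at three depths (surface, mid, bottom), box runs at
    a single nominal depth.  Concentrations get multiplicative lognormal
    noise (exactly 1 when ``noise=0``); PO4 values below the detection
    limit are recorded at the limit with a censored flag.  Returns the
    written table.
    """
    rng = np.random.default_rng(seed)
    t0 = pd.Timestamp(start_date)
    sample_times = np.arange(truth.time[0], truth.time[-1] + 1e-9,
                             interval_days)
    levels = [0] if not truth.is_column else \
        sorted({0, truth.states.shape[1] // 2, truth.states.shape[1] - 1})

    rows = []
    for lev in levels:
        for var in truth.variables:
            series = truth.series(var, level=lev)
            vals = np.interp(sample_times, truth.time, series)
            if noise > 0.0:
                vals = vals * np.exp(
                    rng.normal(0.0, noise, len(vals)) - 0.5 * noise ** 2)
            for t, v in zip(sample_times, vals):
                censored = False
                if censor_po4 and var == "PO4" and v < PO4_DETECTION_LIMIT:
                    v = PO4_DETECTION_LIMIT
                    censored = True
                rows.append({
                    "date": t0 + pd.Timedelta(days=float(t)),
                    "level": lev,
                    "variable": var,
                    "value": v,
                    "censored": censored,
                })
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
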