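"""Model–observation skill statistics and target-diagram coordinates.

Paired model/observation series are summarized by the percentage bias
(PB), the cost function (CF, mean absolute error normalized by the
observations' standard deviation, rated on the OSPAR very good / good /
reasonable / poor scale), the average absolute error (AAE), the root
mean square deviation (RMSD), the Pearson correlation (R), and the
normalized target-diagram pair (Bias*, signed uRMSD*) whose distance to
the origin equals the total normalized RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSeries",
    "SkillReport",
    "percentage_bias",
    "cost_function",
    "classify_ospar",
    "aae",
    "rmsd",
    "correlation",
    "target_diagram_coords",
    "skill_report",
    "monthly_climatology",
    "pair_series",
]

#: Use the sample (n−1) standard deviation for normalizations.  This is
#: a documented convention; set to 0 for the population form.
STD_DDOF = 1


@dataclass(frozen=True)
class PairedSeries:
    """n matched (model, observation) pairs for one variable."""

    model: np.ndarray
    obs: np.ndarray
    variable: str = ""
    time: np.ndarray | None = None
    units: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "model",
                           np.asarray(self.model, dtype=float))
        object.__setattr__(self, "obs", np.asarray(self.obs, dtype=float))
        if self.model.shape != self.obs.shape or self.model.ndim != 1:
            raise ValueError("model and obs must be 1-D and equal length")
        if np.isnan(self.model).any() or np.isnan(self.obs).any():
            raise ValueError("missing values inside pairs are not allowed")

    @property
    def n(self) -> int:
        return len(self.model)


@dataclass(frozen=True)
class SkillReport:
    mean_obs: float
    mean_model: float
    std_obs: float
    std_model: float
    CF: float
    PB: float
    AAE: float
    RMSD: float
    R: float
    bias_star: float
    urmsd_star: float
    ospar_rating: str
    n: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n", "mean_obs", "mean_model", "std_obs", "std_model",
            "CF", "PB", "AAE", "RMSD", "R", "bias_star", "urmsd_star",
            "ospar_rating")}


def _std_obs(p: PairedSeries) -> float:
    s = float(np.std(p.obs, ddof=STD_DDOF))
    if s == 0.0:
        raise ValueError("observation series has zero variance")
    return s


def percentage_bias(p: PairedSeries) -> float:
    """PB = 100·Σ(O−M)/ΣO (%): negative when the model overestimates."""
    so = float(np.sum(p.obs))
    if so == 0.0:
        raise ValueError("observation sum is zero; PB undefined")
    return 100.0 * float(np.sum(p.obs - p.model)) / so


def aae(p: PairedSeries) -> float:
    """Average absolute error, (1/n)·Σ|M−O| (units of the variable)."""
    return float(np.mean(np.abs(p.model - p.obs)))


def rmsd(p: PairedSeries) -> float:
    """Root mean square deviation, √((1/n)·Σ(M−O)²); AAE ≤ RMSD always."""
    return float(np.sqrt(np.mean((p.model - p.obs) ** 2)))


def correlation(p: PairedSeries) -> float:
    """Pearson correlation coefficient of the pairs (needs n ≥ 2 and
    non-constant series)."""
    if p.n < 2:
        raise ValueError("correlation needs at least 2 pairs")
    if np.std(p.model) == 0.0 or np.std(p.obs) == 0.0:
        raise ValueError("correlation undefined for constant series")
    return float(stats.pearsonr(p.model, p.obs).statistic)


def cost_function(p: PairedSeries) -> float:
    """CF = AAE / σ_O: non-dimensional goodness of fit, 0 iff M ≡ O."""
    return aae(p) / _std_obs(p)


def classify_ospar(cf: float) -> str:
    """OSPAR rating of a cost function value.

    Bins are closed on the right: [0,1] very good, (1,2] good,
    (2,3] reasonable, >3 poor.
    """
    if cf < 0:
        raise ValueError("cost function cannot be negative")
    if cf <= 1.0:
        return "very good"
    if cf <= 2.0:
        return "good"
    if cf <= 3.0:
        return "reasonable"
    return "poor"


def target_diagram_coords(p: PairedSeries) -> tuple[float, float]:
    """(uRMSD*, Bias*): the target-diagram X and Y coordinates.

    Bias* = (mean_M − mean_O)/σ_O, so overestimated variables plot in
    the upper half; uRMSD* is the centred RMSD normalized by σ_O and
    signed by (σ_M − σ_O), so an over-dispersive model plots to the
    right.  The distance to the origin is RMSD/σ_O (total normalized
    RMSD), an identity the report asserts.
    """
    so = _std_obs(p)
    bias = float(np.mean(p.model) - np.mean(p.obs))
    m_c = p.model - np.mean(p.model)
    o_c = p.obs - np.mean(p.obs)
    urmsd = float(np.sqrt(np.mean((m_c - o_c) ** 2)))
    sign = 1.0 if float(np.std(p.model, ddof=STD_DDOF)) >= so else -1.0
    return sign * urmsd / so, bias / so


def skill_report(p: PairedSeries) -> SkillReport:
    """Assemble every statistic consistently (shared means and stds)."""
    so = _std_obs(p)
    x, y = target_diagram_coords(p)
    total = rmsd(p)
    # unbiased decomposition: RMSD² = bias² + uRMSD²
    assert abs((total / so) ** 2 - (x ** 2 + y ** 2)) < 1e-10 * max(
        1.0, (total / so) ** 2)
    try:
        r = correlation(p)
    except ValueError:
        r = float("nan")
    cf = cost_function(p)
    return SkillReport(
        mean_obs=float(np.mean(p.obs)),
        mean_model=float(np.mean(p.model)),
        std_obs=so,
        std_model=float(np.std(p.model, ddof=STD_DDOF)),
        CF=cf,
        PB=percentage_bias(p),
        AAE=aae(p),
        RMSD=total,
        R=r,
        bias_star=y,
        urmsd_star=x,
        ospar_rating=classify_ospar(cf),
        n=p.n,
    )


def monthly_climatology(series: pd.Series) -> pd.DataFrame:
    """Calendar-month means with the within-month standard deviation.

    ``series`` must be indexed by timestamps; the std column is the
    sub-monthly variability used as error bars on climatology plots.
    """
    if not isinstance(series.index, pd.DatetimeIndex):
        raise TypeError("series must have a DatetimeIndex")
    g = series.groupby(series.index.month)
    out = pd.DataFrame({
        "mean": g.mean(),
        "std": g.std(ddof=STD_DDOF).fillna(0.0),
        "n": g.count(),
    })
    out.index.name = "month"
    return out


def pair_series(model: pd.Series, obs: pd.Series, variable: str = "",
                tolerance: pd.Timedelta | str = "3D",
                units: str = "") -> PairedSeries:
    """Match observations to the nearest model time within a tolerance.

    Both inputs are time-indexed; observations with no model value within
    the tolerance are dropped.
    """
    model = model.sort_index()
    obs = obs.sort_index()
    matched = pd.merge_asof(
        obs.rename("obs").rename_axis("time").reset_index(),
        model.rename("model").rename_axis("time").reset_index(),
        on="time", direction="nearest",
        tolerance=pd.Timedelta(tolerance))
    matched = matched.dropna()
    return PairedSeries(model=matched["model"].to_numpy(),
                        obs=matched["obs"].to_numpy(),
                        variable=variable,
                        time=matched["time"].to_numpy(),
                        units=units)
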