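"""The cut-off respiratory cycle (CORC) statistic and apnea quantification.

An apneic cycle is an isolated respiratory cycle longer than the CORC -
the duration threshold separating the repetitive-breathing population
(a single-Gaussian cluster on the diagonal of the Poincare plot of
consecutive cycle durations) from isolated long cycles.  Two estimators
are provided:

* ``corc_poincare`` - cycles whose duration matches both neighbors form
  the repetitive set; a Gaussian is fitted to it and the CORC is placed
  ``k`` SDs above its mean (default k = 4).
* ``corc_logthd`` - the apneic time fraction ATF(ThD), the fraction of
  time in cycles longer than a threshold duration ThD, is close to linear
  in log(ThD) over the apneic range; the fit is extrapolated toward
  shorter ThD and the CORC is the largest ThD at which the observed ATF
  departs from the line by more than 3 residual SDs.

On well-separated series both estimators label the same apneic cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import CycleSeries

__all__ = [
    "CORCEstimate",
    "ApneaSummary",
    "CORCError",
    "poincare_points",
    "corc_poincare",
    "corc_logthd",
    "label_cycles",
    "apnea_summary",
    "atf_at_threshold",
]

MIN_CYCLES = 30
#: Poincare boundary: CORC = repetitive mean + K_SD * repetitive SD
K_SD = 4.0
#: a cycle is "repetitive" when both neighbor differences are below this
#: multiple of the robust SD of first differences
NEIGHBOR_TOL_SD = 3.0
#: log-ThD grid: N points log-spaced from GRID_TOP_S down to the
#: repetitive-cluster mean
GRID_POINTS = 40
GRID_TOP_S = 8.0
#: departure criterion for the log-ThD method, in residual SDs
DEPART_SD = 3.0
#: the apnea-range fit uses thresholds of at least this multiple of the
#: median cycle duration
FIT_MIN_MEDIAN_FACTOR = 3.0


class CORCError(RuntimeError):
    """The CORC could not be estimated; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class CORCEstimate:
    """A cut-off respiratory cycle duration with method diagnostics."""

    corc: float
    method: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.corc) or self.corc <= 0:
            raise ValueError("CORC must be finite and positive")


@dataclass
class ApneaSummary:
    """Apneic time fraction and apnea counts for one recording."""

    atf: float
    n_apneas: int
    durations: list
    corc: float
    method: str
    n_consecutive_flagged: int = 0
    atf_bh: float | None = None
    atf_cl: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.atf <= 1.0:
            raise ValueError("atf must lie in [0, 1]")
        if self.n_apneas != len(self.durations):
            raise ValueError("n_apneas must equal the number of durations")


def poincare_points(series: CycleSeries) -> np.ndarray:
    """Consecutive-duration pairs (T_n, T_{n+1}) of the Poincare plot."""
    d = series.durations
    if d.size < 2:
        raise ValueError("need at least 2 cycles for a Poincare plot")
    return np.column_stack([d[:-1], d[1:]])


def _repetitive_mask(d: np.ndarray) -> tuple[np.ndarray, float]:
    """Cycles whose duration is close to both neighbors' durations."""
    diffs = np.diff(d)
    mad = np.median(np.abs(diffs - np.median(diffs)))
    robust_sd = 1.4826 * mad
    tol = max(NEIGHBOR_TOL_SD * robust_sd, 0.01 * float(np.median(d)))
    prev_ok = np.abs(np.r_[diffs[0], diffs]) < tol      # |T_n - T_{n-1}|
    next_ok = np.abs(np.r_[diffs, diffs[-1]]) < tol     # |T_n - T_{n+1}|
    return prev_ok & next_ok, tol


def corc_poincare(series: CycleSeries, k_sd: float = K_SD) -> CORCEstimate:
    """CORC at the Poincare-plot boundary of the repetitive cluster.

    The repetitive set (cycles preceded and followed by cycles of about
    the same duration) is fitted by a single Gaussian; the CORC is its
    mean plus ``k_sd`` standard deviations.
    """
    d = series.durations
    if d.size < MIN_CYCLES:
        raise CORCError(f"need >= {MIN_CYCLES} cycles, got {d.size}")
    mask, tol = _repetitive_mask(d)
    n_rep = int(mask.sum())
    if n_rep < 10:
        raise CORCError(
            "no repetitive cluster identifiable",
            {"n_repetitive": n_rep, "neighbor_tol_s": tol})
    mu = float(np.mean(d[mask]))
    sd = float(np.std(d[mask], ddof=1))
    corc = mu + k_sd * sd
    return CORCEstimate(corc=corc, method="poincare", diagnostics={
        "repetitive_mean_s": mu, "repetitive_sd_s": sd,
        "n_repetitive": n_rep, "neighbor_tol_s": tol, "k_sd": k_sd})


def atf_at_threshold(series: CycleSeries, thd) -> np.ndarray | float:
    """ATF(ThD): fraction of recorded time in cycles longer than ThD."""
    d = series.durations
    thd_arr = np.atleast_1d(np.asarray(thd, dtype=float))
    atf = np.array([d[d > t].sum() for t in thd_arr]) / series.total_duration
    return atf if np.ndim(thd) else float(atf[0])


def corc_logthd(series: CycleSeries) -> CORCEstimate:
    """CORC from the departure point of the ATF-vs-log(ThD) relation.

    ATF(ThD) is evaluated on a descending log-spaced grid from
    ``GRID_TOP_S`` down to the repetitive-cluster mean; a line is fitted
    to ATF vs log(ThD) over the clearly apneic range (ThD at least three
    times the median cycle duration and with nonzero ATF) and the CORC is
    the largest grid ThD below that range where the observed ATF departs
    from the extrapolated line by more than ``DEPART_SD`` residual SDs.

    When no long cycle exists, or no departure is found, the grid floor is
    returned with ``diagnostics["flagged"]`` set.
    """
    d = series.durations
    if d.size < MIN_CYCLES:
        raise CORCError(f"need >= {MIN_CYCLES} cycles, got {d.size}")
    mask, _ = _repetitive_mask(d)
    floor = float(np.mean(d[mask])) if mask.any() else float(np.median(d))
    grid = np.geomspace(GRID_TOP_S, floor, GRID_POINTS)  # descending
    atf = np.asarray(atf_at_threshold(series, grid))
    median_d = float(np.median(d))

    diag: dict = {"thd_grid": grid, "atf_grid": atf, "grid_floor_s": floor}
    if float(d.max()) <= FIT_MIN_MEDIAN_FACTOR * median_d:
        diag["flagged"] = "no cycle exceeds 3x the median duration"
        return CORCEstimate(corc=floor, method="log_thd", diagnostics=diag)

    fit_mask = (grid >= FIT_MIN_MEDIAN_FACTOR * median_d) & (atf > 0)
    if fit_mask.sum() < 3:
        diag["flagged"] = "too few grid points in the apneic range to fit"
        return CORCEstimate(corc=floor, method="log_thd", diagnostics=diag)

    logt = np.log(grid)
    slope, icept = np.polyfit(logt[fit_mask], atf[fit_mask], 1)
    resid = atf[fit_mask] - (slope * logt[fit_mask] + icept)
    resid_sd = max(float(np.std(resid, ddof=2 if fit_mask.sum() > 2 else 0)),
                   1e-4)
    diag.update(fit_slope=float(slope), fit_intercept=float(icept),
                resid_sd=float(resid_sd))

    # scan below the fitted range, largest ThD first
    below = np.flatnonzero(~fit_mask & (grid < grid[fit_mask].min()))
    predicted = slope * logt + icept
    for i in below:
        if abs(atf[i] - predicted[i]) > DEPART_SD * resid_sd:
            diag["departure_thd_s"] = float(grid[i])
            return CORCEstimate(corc=float(grid[i]), method="log_thd",
                                diagnostics=diag)
    diag["flagged"] = "no departure found down to the grid floor"
    return CORCEstimate(corc=floor, method="log_thd", diagnostics=diag)


def label_cycles(series: CycleSeries, corc: CORCEstimate) -> np.ndarray:
    """Per-cycle label: ``apneic`` when longer than the CORC, else
    ``repetitive``."""
    return np.where(series.durations > corc.corc, "apneic", "repetitive")


def apnea_summary(series: CycleSeries, corc: CORCEstimate) -> ApneaSummary:
    """Apneic time fraction, apnea count and durations at the given CORC.

    Consecutive apneic cycles violate the isolated-apnea assumption; they
    are counted individually but flagged.
    """
    labels = label_cycles(series, corc)
    apneic = labels == "apneic"
    durations = series.durations[apneic]
    atf = float(durations.sum() / series.total_duration)
    consecutive = int(np.sum(apneic[1:] & apneic[:-1]))
    return ApneaSummary(atf=min(atf, 1.0), n_apneas=int(apneic.sum()),
                        durations=list(durations), corc=corc.corc,
                        method=corc.method,
                        n_consecutive_flagged=consecutive)
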