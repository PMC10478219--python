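"""Magnetization, susceptibility and finite-size scaling analysis.

The order parameter is the magnetization per occupied site
m = M / n_occ with M = sum of sigma over differentiated cells.  The
magnetic susceptibility per occupied site,

    chi^N = <n_occ> (<m^2> - <|m|>^2) / T,

uses the |m| convention standard for finite lattices, where sign
symmetry drives <m> to zero on long runs.  The peak of chi^N over a
temperature grid locates the finite-size critical point T_c^N; how peak
height, peak location and the critical magnetization vary with lattice
size L yields the finite-size scaling estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CPIMParams, run_simulation

SCAN_COLUMNS = ["T", "L", "replicate", "mean_abs_m", "mean_m2", "chi",
                "n_samples"]


class AnalysisError(ValueError):
    """Raised when an analysis has no valid data to work on."""


def _post_burn_in(series: pd.DataFrame, burn_in: int) -> pd.DataFrame:
    if burn_in < 0:
        raise AnalysisError("burn_in must be >= 0")
    window = series.iloc[burn_in:]
    window = window[window["n_occupied"] > 0]
    if window.empty:
        raise AnalysisError("no post-burn-in records with occupied sites")
    return window


def magnetization_stats(series: pd.DataFrame,
                        burn_in: int = 0) -> tuple[float, float]:
    """Time averages (<|m|>, <m^2>) over post-burn-in records."""
    window = _post_burn_in(series, burn_in)
    m = window["m_per_occupied"].to_numpy()
    return float(np.mean(np.abs(m))), float(np.mean(m * m))


def susceptibility(series: pd.DataFrame, T: float,
                   burn_in: int = 0) -> float:
    """Susceptibility per occupied site, chi^N = <n_occ>(<m^2>-<|m|>^2)/T."""
    if T <= 0:
        raise AnalysisError("T must be > 0")
    window = _post_burn_in(series, burn_in)
    mean_abs, mean_sq = magnetization_stats(series, burn_in)
    var = mean_sq - mean_abs ** 2
    if var < 0:
        if var < -1e-12:
            warnings.warn("negative magnetization variance clamped to 0")
        var = 0.0
    return float(np.mean(window["n_occupied"])) * var / T


def _measurement_start(series: pd.DataFrame, params: CPIMParams,
                       burn_in_frac: float,
                       min_occupancy_frac: float) -> int:
    """First record index at which measurement may begin.

    Pure Ising runs discard a burn-in fraction of the sweeps; CPIM runs
    additionally wait until the colony covers ``min_occupancy_frac`` of
    the lattice, so the early tiny colony does not dominate chi.
    """
    n = len(series)
    start = int(burn_in_frac * n)
    if params.mode == "cpim":
        occ = series["n_occupied"].to_numpy()
        thresh = min_occupancy_frac * params.L ** 2
        above = np.nonzero(occ >= thresh)[0]
        if above.size == 0:
            raise AnalysisError(
                f"colony never reached {min_occupancy_frac:.0%} occupancy")
        grow = int(above[0])
        # equilibrate after reaching the target occupancy
        start = grow + max(1, int(burn_in_frac * (n - grow)))
    return min(start, n - 1)


def temperature_scan(params: CPIMParams, T_grid: np.ndarray,
                     replicates: int = 5,
                     burn_in_frac: float = 0.2,
                     min_occupancy_frac: float = 0.5,
                     ordered_start: bool = True) -> pd.DataFrame:
    """Independent seeded runs over a temperature grid.

    Returns one row per (T, replicate) with columns `SCAN_COLUMNS`.
    Replicate seeds are spawned deterministically from ``params.seed``.
    Pure-Ising scans start from the fully ordered state by default:
    below the transition a random start would need of order L^2 sweeps
    of domain coarsening before equilibrium, inflating chi with a
    transient, while an ordered start relaxes quickly at every T.
    """
    T_grid = np.asarray(T_grid, dtype=float)
    if np.any(T_grid <= 0):
        raise AnalysisError("temperatures must be positive")
    if np.any(np.diff(T_grid) <= 0):
        raise AnalysisError("T grid must be strictly increasing")
    seeds = np.random.SeedSequence(params.seed).generate_state(
        T_grid.size * replicates, np.uint32).reshape(T_grid.size, replicates)
    initial = None
    if params.mode == "pure_ising" and ordered_start:
        from .core import LatticeState
        initial = LatticeState(np.ones((params.L, params.L), dtype=np.int8),
                               boundary="periodic", mode="pure_ising")
    rows = []
    for ti, T in enumerate(T_grid):
        for rep in range(replicates):
            p = params.with_(T=float(T), seed=int(seeds[ti, rep]))
            run = run_simulation(p, stop_at_edge=False, initial=initial)
            try:
                start = _measurement_start(run.series, p, burn_in_frac,
                                           min_occupancy_frac)
            except AnalysisError as e:
                # colony extinct or still tiny: a real CP outcome at
                # appreciable death rates -- drop this replicate
                warnings.warn(f"T={T:.3f} replicate {rep} skipped: {e}")
                continue
            mean_abs, mean_sq = magnetization_stats(run.series, start)
            chi = susceptibility(run.series, float(T), start)
            rows.append((float(T), p.L, rep, mean_abs, mean_sq, chi,
                         len(run.series) - start))
    if not rows:
        raise AnalysisError("all scan replicates failed to reach the "
                            "measurement occupancy")
    return pd.DataFrame(rows, columns=SCAN_COLUMNS)


def scan_summary(scan: pd.DataFrame) -> pd.DataFrame:
    """Average the per-replicate scan over replicates, per temperature."""
    g = scan.groupby("T", as_index=False).agg(
        L=("L", "first"), mean_abs_m=("mean_abs_m", "mean"),
        mean_m2=("mean_m2", "mean"), chi=("chi", "mean"),
        sem_abs_m=("mean_abs_m", "sem"), n_replicates=("replicate", "count"))
    return g.sort_values("T", ignore_index=True)


def _quadratic_peak(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Peak location/height by 3-point quadratic interpolation at argmax."""
    k = int(np.argmax(y))
    if k == 0 or k == len(y) - 1:
        return float(x[k]), float(y[k])
    x3, y3 = x[k - 1:k + 2], y[k - 1:k + 2]
    a, b, c = np.polyfit(x3, y3, 2)
    if a >= 0:  # degenerate: not locally concave
        return float(x[k]), float(y[k])
    xp = -b / (2 * a)
    return float(xp), float(np.polyval([a, b, c], xp))


@dataclass
class FssResult:
    """Per-size peak data and log-log scaling fits."""

    L: np.ndarray
    chi_max: np.ndarray          # X_max^N per lattice size
    T_c_N: np.ndarray            # susceptibility-peak location per size
    m_c: np.ndarray              # <|M|>_c^N per occupied site at T_c^N
    chi_slope: float             # d log chi_max / d log L  (gamma/nu)
    m_slope: float               # d log m_c / d log L      (-beta/nu)
    T_c: float                   # peak location extrapolated to L -> inf

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"L": self.L, "chi_max": self.chi_max,
                             "T_c_N": self.T_c_N, "m_c": self.m_c})


def finite_size_scaling(summaries: list[pd.DataFrame]) -> FssResult:
    """Finite-size scaling from per-size temperature-scan summaries.

    Each summary (from `scan_summary`) must share its T grid support and
    carry a distinct L.  Peak height X_max^N and location T_c^N come
    from quadratic interpolation around the chi grid maximum; slopes are
    least-squares fits on log-log axes; T_c extrapolates T_c^N linearly
    in 1/L.
    """
    if len(summaries) < 3:
        raise AnalysisError("need >= 3 lattice sizes")
    Ls, chi_max, tc_n, m_c = [], [], [], []
    for s in summaries:
        T = s["T"].to_numpy()
        chi = s["chi"].to_numpy()
        if len(T) >= 3:
            interior = np.argmax(chi)
            if 0 < interior < len(T) - 1:
                pass
            else:
                warnings.warn("chi peak at edge of T grid; using grid max")
        if np.sum(np.diff(np.sign(np.diff(chi))) != 0) > 1:
            warnings.warn("chi(T) is not unimodal; peak taken at global max")
        tp, cp = _quadratic_peak(T, chi)
        Ls.append(float(s["L"].iloc[0]))
        chi_max.append(cp)
        tc_n.append(tp)
        m_c.append(float(np.interp(tp, T, s["mean_abs_m"].to_numpy())))
    order = np.argsort(Ls)
    Ls = np.asarray(Ls)[order]
    if np.unique(Ls).size < len(Ls):
        raise AnalysisError("lattice sizes must be distinct")
    chi_max = np.asarray(chi_max)[order]
    tc_n = np.asarray(tc_n)[order]
    m_c = np.asarray(m_c)[order]
    chi_slope = float(np.polyfit(np.log(Ls), np.log(chi_max), 1)[0])
    m_slope = float(np.polyfit(np.log(Ls), np.log(np.maximum(m_c, 1e-12)),
                               1)[0])
    # T_c^N = T_c + a / L  (first finite-size correction)
    tc = float(np.polyfit(1.0 / Ls, tc_n, 1)[1])
    return FssResult(L=Ls, chi_max=chi_max, T_c_N=tc_n, m_c=m_c,
                     chi_slope=chi_slope, m_slope=m_slope, T_c=tc)
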