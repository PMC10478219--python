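"""Two-state thermodynamic promoter-occupancy model and dose-response fits.

Each dual-input promoter is modelled as a two-state system (active ON /
inactive OFF).  At ligand concentration L the equilibrium probability of
the active state is

    P_on = ( 1 + [ (1 + L/Kd_off) / (1 + L/Kd_on) ]^n * exp(-n*beta*dE) )^-1

where dE = E_off - E_on is the promoter energy gap without ligand,
Kd_on/Kd_off are the dissociation constants of the ligand for the
active/inactive promoter, and n is a Hill exponent for cooperative
binding.  Only the product n*beta*dE is identifiable, so it is treated
as one compound parameter; concentrations are handled in log10 space
internally for conditioning.

The module also provides weighted nonlinear least-squares fitting of
P_on to normalized synthesis-rate curves and a synthetic two-channel
(RFP/GFP) dose-response generator emulating a bistable toggle read out
through mutually exclusive reporters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize


class DoseFitError(RuntimeError):
    pass


@dataclass(frozen=True)
class PromoterParams:
    """Thermodynamic promoter parameters.

    n_beta_dE is the compound dimensionless gap n*beta*(E_off - E_on);
    positive values bias the promoter towards the active state at L=0.
    """

    n_beta_dE: float
    Kd_on: float
    Kd_off: float
    n: float = 1.0

    def __post_init__(self) -> None:
        if self.Kd_on <= 0 or self.Kd_off <= 0:
            raise ValueError("dissociation constants must be positive")
        if self.n <= 0:
            raise ValueError("Hill exponent must be positive")


def p_on(L, params: PromoterParams) -> np.ndarray | float:
    """Equilibrium probability of the active promoter state.

    Monotone increasing in L when Kd_on < Kd_off (the ligand prefers
    the active promoter), decreasing when Kd_on > Kd_off.
    """
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("ligand concentrations must be >= 0")
    ratio = (1.0 + L / params.Kd_off) / (1.0 + L / params.Kd_on)
    out = 1.0 / (1.0 + ratio ** params.n * np.exp(-params.n_beta_dE))
    return float(out) if out.ndim == 0 else out


@dataclass
class DoseResponseCurve:
    """Ligand titration of one reporter channel.

    Concentrations in molar (strictly increasing), synthesis rates
    normalized to the per-system maximum, optional replicate SDs.
    """

    L: np.ndarray
    rate: np.ndarray
    sd: np.ndarray | None = None
    channel: str = "RFP"
    system: str = "reporter"

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
        if np.any(np.diff(self.L) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.L.shape != self.rate.shape:
            raise ValueError("L and rate must have the same length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "L_molar": self.L, "rate_norm": self.rate,
            "sd": self.sd if self.sd is not None else np.nan,
            "channel": self.channel, "system": self.system})


@dataclass
class DoseResponseFit:
    params: PromoterParams
    stderr: dict[str, float]
    rss: float
    identifiable: bool = True
    notes: list[str] = field(default_factory=list)


def fit_dose_response(curve: DoseResponseCurve,
                      init: PromoterParams | None = None,
                      fix_n: float | None = 1.0,
                      weighted: bool = True) -> DoseResponseFit:
    """Fit the promoter-occupancy model to a normalized dose-response.

    Free parameters are (n_beta_dE, log10 Kd_on, log10 Kd_off) and,
    when ``fix_n`` is None, the Hill exponent.  Weights are 1/SD^2 when
    replicate SDs are present and ``weighted``.  Kd confidence
    intervals spanning more than 3 decades flag non-identifiability.
    """
    x = curve.L
    y = curve.rate
    if len(x) < 5:
        raise DoseFitError("need >= 5 concentrations")
    positive = x[x > 0]
    if positive.size and np.log10(positive.max() / positive.min()) < 3:
        raise DoseFitError("concentrations must span >= 3 decades")
    if init is None:
        increasing = y[-1] >= y[0]
        mid = float(np.sqrt(positive.min() * positive.max()))
        init = PromoterParams(
            n_beta_dE=-2.0 if increasing else 2.0,
            Kd_on=mid / 30 if increasing else mid * 30,
            Kd_off=mid * 30 if increasing else mid / 30,
            n=fix_n if fix_n is not None else 1.0)

    def unpack(theta):
        if fix_n is None:
            e, lkon, lkoff, n = theta
        else:
            e, lkon, lkoff = theta
            n = fix_n
        return PromoterParams(n_beta_dE=e, Kd_on=10.0 ** lkon,
                              Kd_off=10.0 ** lkoff, n=n)

    def model(xx, *theta):
        return p_on(xx, unpack(theta))

    theta0 = [init.n_beta_dE, np.log10(init.Kd_on), np.log10(init.Kd_off)]
    names = ["n_beta_dE", "log10_Kd_on", "log10_Kd_off"]
    if fix_n is None:
        theta0.append(init.n)
        names.append("n")
    sigma = None
    if weighted and curve.sd is not None and np.all(curve.sd > 0):
        sigma = curve.sd
    try:
        popt, pcov = optimize.curve_fit(model, x, y, p0=theta0, sigma=sigma,
                                        absolute_sigma=False, maxfev=50000)
    except (RuntimeError, ValueError) as e:
        raise DoseFitError(f"dose-response fit failed: {e}") from e
    se = np.sqrt(np.diag(pcov))
    stderr = dict(zip(names, se.tolist()))
    fitted = unpack(popt)
    notes = []
    identifiable = True
    for nm in ("log10_Kd_on", "log10_Kd_off"):
        if not np.isfinite(stderr[nm]) or 2 * 1.96 * stderr[nm] > 3:
            identifiable = False
            notes.append(f"{nm} CI spans more than 3 decades")
    resid = y - p_on(x, fitted)
    return DoseResponseFit(params=fitted, stderr=stderr,
                           rss=float(resid @ resid),
                           identifiable=identifiable, notes=notes)


def simulate_dose_response(params: PromoterParams,
                           L_grid: np.ndarray,
                           noise_sd: float = 0.03,
                           replicates: int = 4,
                           seed: int = 0,
                           system: str = "ferro"
                           ) -> tuple[DoseResponseCurve, DoseResponseCurve]:
    """Synthetic two-channel dose-response (RFP = P_on, GFP = 1 - P_on).

    Emulates a bistable toggle read out through mutually exclusive
    fluorescent reporters: before noise and normalization the two
    channels sum to one at every concentration, and the channels cross
    where P_on = 1/2.  Gaussian replicate noise is clipped at zero and
    each channel is normalized by its own maximum mean.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    L_grid = np.asarray(L_grid, dtype=float)
    rng = np.random.default_rng(seed)
    base_r = p_on(L_grid, params)
    base_g = 1.0 - base_r
    curves = []
    for channel, base in (("RFP", base_r), ("GFP", base_g)):
        reps = base[None, :] + rng.normal(0.0, noise_sd,
                                          (replicates, L_grid.size))
        reps = np.clip(reps, 0.0, None)
        mean = reps.mean(axis=0)
        sd = reps.std(axis=0, ddof=1) if replicates > 1 else \
            np.zeros_like(mean)
        peak = mean.max() if mean.max() > 0 else 1.0
        curves.append(DoseResponseCurve(L=L_grid, rate=mean / peak,
                                        sd=sd / peak, channel=channel,
                                        system=system))
    return curves[0], curves[1]


def crossover_concentration(params: PromoterParams,
                            lo: float = 1e-12, hi: float = 1e-3) -> float:
    """Concentration where the two channels intersect (P_on = 1/2)."""
    def f(log_l):
        return p_on(10.0 ** log_l, params) - 0.5
    a, b = np.log10(lo), np.log10(hi)
    if f(a) * f(b) > 0:
        raise ValueError("no crossover in the given range")
    return float(10.0 ** optimize.brentq(f, a, b, xtol=1e-10))
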