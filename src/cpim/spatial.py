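"""Spatial statistics of two-state patterns.

Covers the radial spatial autocorrelation function (sACF) of a signed
+1/-1 field under an arbitrary mask, the exponential-decay and
critical power-law fits to it, connected-cluster extraction, and
discrete power-law estimation of the cluster-size distribution (both a
Clauset-style maximum-likelihood estimator with automatic low-end
cutoff and a least-squares fit on log-binned densities).

Conventions
-----------
* The sACF is computed on the signed field: C(r) is the overlap-
  normalized covariance of mean-subtracted state values over all
  in-mask site pairs at distance r, scaled so C(0) = 1; +1 means
  perfect correlation, -1 perfect anticorrelation.
* Radial bins are Euclidean with half-unit width by default: bin k
  collects pair separations with |r - k*bin_width| < bin_width/2, so
  the first occupied bin beyond r=0 holds exactly the axis-distance-1
  lags (the sqrt(2) diagonals fall in the next bin).
* Cluster labelling defaults to 4-connectivity, matching the lattice
  adjacency of the simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal, special, stats


class FitError(RuntimeError):
    """Raised when a nonlinear fit cannot be performed or fails."""


class SpatialAnalysisError(ValueError):
    """Raised for degenerate inputs (e.g. constant fields)."""


# ---------------------------------------------------------------------------
# radial autocorrelation
# ---------------------------------------------------------------------------

@dataclass
class RadialACF:
    """Radial autocorrelation: correlation per distance bin."""

    r: np.ndarray
    C: np.ndarray
    n_pairs: np.ndarray
    bin_width: float = 1.0
    mask_description: str = ""

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=np.int64)


def spin_field(grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map a pattern grid onto a signed field and a mask.

    State-code grids (codes 0/2/+1/-1) map differentiated sites to
    +1/-1 and mask out the rest; binary {0,1} grids map to 2*x-1 with a
    full mask.
    """
    grid = np.asarray(grid)
    values = set(np.unique(grid).tolist())
    if values <= {0, 1} and 1 in values:
        return (2 * grid.astype(np.int8) - 1), np.ones(grid.shape, bool)
    mask = np.abs(grid) == 1
    return np.where(mask, grid, 0).astype(np.int8), mask


def _acf_surface_fft(f: np.ndarray, mask: np.ndarray):
    """Lag surface S(d) = sum of f(x) f(x+d) and pair counts via FFT."""
    S = signal.fftconvolve(f, f[::-1, ::-1], mode="full")
    cnt = signal.fftconvolve(mask.astype(float), mask[::-1, ::-1].astype(float),
                             mode="full")
    cnt = np.rint(cnt).astype(np.int64)
    return S, cnt


def _acf_surface_direct(f: np.ndarray, mask: np.ndarray):
    """Brute-force lag surface; O(n^2) in in-mask sites (small grids)."""
    H, W = f.shape
    S = np.zeros((2 * H - 1, 2 * W - 1))
    cnt = np.zeros((2 * H - 1, 2 * W - 1), dtype=np.int64)
    pts = np.argwhere(mask)
    for ai, aj in pts:
        for bi, bj in pts:
            di, dj = ai - bi, aj - bj
            S[di + H - 1, dj + W - 1] += f[ai, aj] * f[bi, bj]
            cnt[di + H - 1, dj + W - 1] += 1
    return S, cnt


def radial_autocorrelation(grid: np.ndarray, mask: np.ndarray | None = None,
                           bin_width: float = 0.5, r_max: float | None = None,
                           method: str = "fft") -> RadialACF:
    """Masked radial sACF of a two-state grid.

    Parameters
    ----------
    grid : state-code or binary grid; mapped with `spin_field` unless an
        explicit mask is given, in which case grid must already be the
        signed field.
    mask : boolean region of valid sites; pairs with either endpoint
        outside the mask are excluded (overlap-normalized estimate).
    method : "fft" (fast path) or "direct" (brute-force oracle).
    """
    if mask is None:
        f, mask = spin_field(grid)
    else:
        mask = np.asarray(mask, bool)
        f = np.where(mask, grid, 0).astype(float)
    if mask.sum() < 2:
        raise SpatialAnalysisError("mask must cover at least 2 sites")
    fm = f.astype(float)
    mean = fm[mask].mean()
    if np.allclose(fm[mask], fm[mask][0]):
        raise SpatialAnalysisError("constant field inside mask: ACF undefined")
    fm = np.where(mask, fm - mean, 0.0)

    if method == "fft":
        S, cnt = _acf_surface_fft(fm, mask)
    elif method == "direct":
        S, cnt = _acf_surface_direct(fm, mask)
    else:
        raise ValueError(f"unknown method {method!r}")

    H, W = f.shape
    di = np.arange(-(H - 1), H)[:, None]
    dj = np.arange(-(W - 1), W)[None, :]
    dist = np.hypot(di, dj)
    bins = np.rint(dist / bin_width).astype(np.int64)
    if r_max is None:
        r_max = float(dist.max())
    nb = int(np.rint(r_max / bin_width)) + 1
    valid = (cnt > 0) & (bins < nb)
    num = np.bincount(bins[valid], weights=S[valid], minlength=nb)
    den = np.bincount(bins[valid], weights=cnt[valid], minlength=nb)
    var = S[H - 1, W - 1] / cnt[H - 1, W - 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(den > 0, num / np.maximum(den, 1) / var, np.nan)
    # few-pair bins at extreme lags can overshoot the perfect-correlation
    # bound under overlap normalization; clip to the statistic's range
    C = np.clip(C, -1.0, 1.0)
    keep = den > 0
    r = np.arange(nb) * bin_width
    return RadialACF(r=r[keep], C=C[keep], n_pairs=den[keep].astype(np.int64),
                     bin_width=bin_width,
                     mask_description=f"{int(mask.sum())} sites of "
                                      f"{mask.size}")


def ensemble_radial_autocorrelation(grids: list[np.ndarray],
                                    bin_width: float = 0.5,
                                    r_max: float | None = None
                                    ) -> RadialACF:
    """Radial sACF of an ensemble of patterns, pooled before normalizing.

    Lag surfaces and pair counts are summed across patterns and the
    *pooled* in-mask mean is subtracted, instead of each pattern's own
    mean.  For a symmetric ensemble (both states equally likely) the
    pooled mean vanishes, so this estimates the true state-state
    correlation; per-pattern mean subtraction would instead remove each
    pattern's net magnetization from every lag, biasing long-range
    correlations downward.  Use `radial_autocorrelation` +
    `average_acfs` for the single-pattern (colony-by-colony) workflow.
    """
    if not grids:
        raise SpatialAnalysisError("no grids to pool")
    pooled_sum = 0.0
    pooled_n = 0
    fields = []
    for g in grids:
        f, mask = spin_field(g)
        fields.append((f.astype(float), mask))
        pooled_sum += f[mask].sum()
        pooled_n += int(mask.sum())
    mean = pooled_sum / pooled_n
    S_tot = None
    cnt_tot = None
    for f, mask in fields:
        fm = np.where(mask, f - mean, 0.0)
        S, cnt = _acf_surface_fft(fm, mask)
        S_tot = S if S_tot is None else S_tot + S
        cnt_tot = cnt if cnt_tot is None else cnt_tot + cnt
    H, W = fields[0][0].shape
    di = np.arange(-(H - 1), H)[:, None]
    dj = np.arange(-(W - 1), W)[None, :]
    dist = np.hypot(di, dj)
    bins = np.rint(dist / bin_width).astype(np.int64)
    if r_max is None:
        r_max = float(dist.max())
    nb = int(np.rint(r_max / bin_width)) + 1
    valid = (cnt_tot > 0) & (bins < nb)
    num = np.bincount(bins[valid], weights=S_tot[valid], minlength=nb)
    den = np.bincount(bins[valid], weights=cnt_tot[valid].astype(float),
                      minlength=nb)
    var = S_tot[H - 1, W - 1] / cnt_tot[H - 1, W - 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(den > 0, num / np.maximum(den, 1) / var, np.nan)
    C = np.clip(C, -1.0, 1.0)
    keep = den > 0
    r = np.arange(nb) * bin_width
    return RadialACF(r=r[keep], C=C[keep], n_pairs=den[keep].astype(np.int64),
                     bin_width=bin_width,
                     mask_description=f"pooled ensemble of {len(grids)}")


def average_acfs(acfs: list[RadialACF]) -> RadialACF:
    """Pair-count-weighted ensemble average over common bins."""
    if not acfs:
        raise SpatialAnalysisError("no ACFs to average")
    bw = acfs[0].bin_width
    nb = max(int(np.rint(a.r.max() / bw)) + 1 for a in acfs)
    num = np.zeros(nb)
    den = np.zeros(nb)
    for a in acfs:
        idx = np.rint(a.r / bw).astype(int)
        num[idx] += a.C * a.n_pairs
        den[idx] += a.n_pairs
    keep = den > 0
    r = np.arange(nb) * bw
    return RadialACF(r=r[keep], C=num[keep] / den[keep],
                     n_pairs=den[keep].astype(np.int64), bin_width=bw,
                     mask_description=f"ensemble of {len(acfs)}")


# ---------------------------------------------------------------------------
# decay fits
# ---------------------------------------------------------------------------

@dataclass
class ExpDecayFit:
    """Fit of y = y0 * exp(-r/b) + C; b is the length constant."""

    y0: float
    b: float
    C: float
    rss: float
    stderr: np.ndarray = field(default_factory=lambda: np.full(3, np.nan))

    def __iter__(self):
        return iter((self.y0, self.b, self.C))


def fit_exponential_decay(acf: RadialACF,
                          r_max: float | None = None) -> ExpDecayFit:
    """One-phase exponential-decay fit to the sACF.

    The length constant b estimates the mean size of same-state
    domains.  Initial values: offset = tail mean, amplitude = C(0) -
    offset, b = first crossing of 1/e of the amplitude.
    """
    r, y = acf.r, acf.C
    if r_max is not None:
        keep = r <= r_max
        r, y = r[keep], y[keep]
    if len(r) < 5:
        raise FitError("need at least 5 bins for the exponential fit")
    c0 = float(np.mean(y[-max(3, len(y) // 10):]))
    y0 = float(y[0] - c0)
    target = c0 + y0 / np.e
    below = np.nonzero(y <= target)[0]
    b0 = float(r[below[0]]) if below.size and r[below[0]] > 0 else \
        float(max(r.max() / 3, acf.bin_width))
    try:
        popt, pcov = optimize.curve_fit(
            lambda x, y0_, b_, c_: y0_ * np.exp(-x / b_) + c_,
            r, y, p0=[y0, b0, c0],
            bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000)
    except (RuntimeError, ValueError) as e:
        raise FitError(f"exponential decay fit failed: {e}") from e
    resid = y - (popt[0] * np.exp(-r / popt[1]) + popt[2])
    return ExpDecayFit(y0=float(popt[0]), b=float(popt[1]), C=float(popt[2]),
                       rss=float(resid @ resid),
                       stderr=np.sqrt(np.diag(pcov)))


@dataclass
class PowerLawAcfFit:
    """Fit of C(r) = A * exp(-r/B) / r**eta over a radial range."""

    A: float
    B: float
    eta: float
    eta_stderr: float
    fit_range: tuple[float, float]
    rss: float


def fit_powerlaw_acf(acf: RadialACF,
                     fit_range: tuple[float, float] | None = None
                     ) -> PowerLawAcfFit:
    """Least-squares fit of the critical form A*exp(-r/B)/r^eta.

    The fit range must exclude r = 0; the default upper end is a
    quarter of the largest tabulated distance, beyond which boundary
    effects dominate.
    """
    if fit_range is None:
        fit_range = (acf.bin_width, float(acf.r.max()) / 4)
    lo, hi = fit_range
    if lo <= 0:
        raise FitError("fit range must exclude r = 0")
    keep = (acf.r >= lo) & (acf.r <= hi)
    r, y = acf.r[keep], acf.C[keep]
    if len(r) < 4:
        raise FitError("fewer points than parameters in fit range")

    def model(x, A, B, eta):
        return A * np.exp(-x / B) / np.power(x, eta)

    p0 = [max(float(y[0]), 1e-3), 10.0 * hi, 0.25]
    try:
        popt, pcov = optimize.curve_fit(
            model, r, y, p0=p0,
            bounds=([1e-12, 1e-9, 0.0], [np.inf, np.inf, 5.0]),
            maxfev=50000)
    except (RuntimeError, ValueError) as e:
        raise FitError(f"power-law ACF fit failed: {e}") from e
    resid = y - model(r, *popt)
    return PowerLawAcfFit(A=float(popt[0]), B=float(popt[1]),
                          eta=float(popt[2]),
                          eta_stderr=float(np.sqrt(pcov[2, 2])),
                          fit_range=(float(lo), float(hi)),
                          rss=float(resid @ resid))


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------

@dataclass
class ClusterSizeSample:
    """Connected same-state cluster sizes pooled over states."""

    sizes: np.ndarray
    connectivity: int = 4
    min_size: int = 1
    per_state: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int64)


def label_clusters(grid: np.ndarray, connectivity: int = 4,
                   states: tuple[int, ...] = (1, -1),
                   min_size: int = 1) -> ClusterSizeSample:
    """Label connected same-state regions and collect their sizes.

    Each state's clusters are labelled separately; sizes from all
    requested states are pooled (a per-state breakdown is kept).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    grid = np.asarray(grid)
    if set(np.unique(grid).tolist()) <= {0, 1}:
        grid = np.where(grid > 0, 1, -1)  # binary pattern -> signed states
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4
                                                  else 2)
    per_state: dict[int, np.ndarray] = {}
    pooled = []
    for s in states:
        lab, n = ndimage.label(grid == s, structure=structure)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
        else:
            sizes = np.zeros(0, dtype=np.int64)
        sizes = sizes[sizes >= min_size]
        per_state[s] = sizes.astype(np.int64)
        pooled.append(sizes)
    sizes = np.concatenate(pooled) if pooled else np.zeros(0, np.int64)
    return ClusterSizeSample(sizes=sizes, connectivity=connectivity,
                             min_size=min_size, per_state=per_state)


def cluster_size_distribution(sample: ClusterSizeSample | np.ndarray
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Empirical P(S): unique sizes and their probabilities (sum to 1)."""
    sizes = sample.sizes if isinstance(sample, ClusterSizeSample) else \
        np.asarray(sample, dtype=np.int64)
    if sizes.size == 0:
        raise SpatialAnalysisError("empty cluster sample")
    s, counts = np.unique(sizes, return_counts=True)
    return s, counts / counts.sum()


def log_binned_pdf(sizes: np.ndarray, bins_per_decade: int = 5
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Logarithmically binned probability density of integer sizes.

    Returns geometric bin centres and densities (count / total / bin
    width); empty bins are dropped.
    """
    sizes = np.asarray(sizes, dtype=float)
    lo, hi = sizes.min(), sizes.max()
    n_bins = max(int(np.ceil(np.log10(hi / lo) * bins_per_decade)), 1) + 1
    edges = np.logspace(np.log10(lo * 0.999), np.log10(hi * 1.001), n_bins + 1)
    counts, _ = np.histogram(sizes, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    dens = counts / counts.sum() / widths
    keep = counts > 0
    return centers[keep], dens[keep]


# ---------------------------------------------------------------------------
# discrete power-law estimation
# ---------------------------------------------------------------------------

@dataclass
class PowerLawFit:
    """Power-law exponent estimate P(s) ~ s**-gamma above x_min."""

    gamma: float
    x_min: int
    estimator: str                     # "mle" or "lsq"
    stderr: float = np.nan
    ks_distance: float = np.nan
    n_tail: int = 0
    plausible: bool = True             # KS diagnostic below threshold

    @property
    def ci(self) -> tuple[float, float]:
        return (self.gamma - 1.96 * self.stderr,
                self.gamma + 1.96 * self.stderr)


def _zeta_nll(gamma: float, log_sum: float, n: int, x_min: int) -> float:
    return n * np.log(special.zeta(gamma, x_min)) + gamma * log_sum


def _mle_gamma(tail: np.ndarray, x_min: int) -> tuple[float, float]:
    """Discrete MLE of gamma for sizes >= x_min, with asymptotic stderr."""
    n = tail.size
    log_sum = float(np.sum(np.log(tail)))
    res = optimize.minimize_scalar(
        _zeta_nll, bounds=(1.01, 8.0), args=(log_sum, n, x_min),
        method="bounded", options={"xatol": 1e-7})
    gamma = float(res.x)
    h = 1e-4
    d2 = (_zeta_nll(gamma + h, log_sum, n, x_min)
          - 2 * _zeta_nll(gamma, log_sum, n, x_min)
          + _zeta_nll(gamma - h, log_sum, n, x_min)) / h ** 2
    stderr = float(1.0 / np.sqrt(d2)) if d2 > 0 else np.nan
    return gamma, stderr


def _ks_distance(tail: np.ndarray, gamma: float, x_min: int) -> float:
    s = np.arange(x_min, tail.max() + 1)
    pmf = s ** (-gamma) / special.zeta(gamma, x_min)
    cdf = np.cumsum(pmf)
    emp = np.searchsorted(np.sort(tail), s, side="right") / tail.size
    return float(np.max(np.abs(emp - cdf)))


def fit_powerlaw_mle(sample: ClusterSizeSample | np.ndarray,
                     x_min: int | str = "auto",
                     min_tail: int = 50,
                     min_tail_frac: float = 0.05,
                     ks_threshold: float | None = None) -> PowerLawFit:
    """Discrete maximum-likelihood power-law fit with low-end cutoff.

    With ``x_min="auto"`` the cutoff minimizing the Kolmogorov-Smirnov
    distance between the tail and its fitted power law is chosen
    (Clauset-style), among cutoffs retaining at least ``min_tail``
    points and a fraction ``min_tail_frac`` of the sample (a cutoff
    deep in the tail can always chase a locally straight stretch of a
    non-power-law distribution).  The fit is flagged implausible when
    the KS distance exceeds ``ks_threshold`` (default 1.6/sqrt(n_tail),
    roughly the 1% one-sample KS critical value).
    """
    sizes = sample.sizes if isinstance(sample, ClusterSizeSample) else \
        np.asarray(sample, dtype=np.int64)
    if sizes.size == 0:
        raise FitError("empty sample")
    if x_min == "auto":
        cands = np.unique(sizes)
        floor = max(min_tail, int(min_tail_frac * sizes.size))
        best = None
        for xm in cands:
            tail = sizes[sizes >= xm]
            if tail.size < floor or tail.max() == xm:
                continue
            g, se = _mle_gamma(tail, int(xm))
            ks = _ks_distance(tail, g, int(xm))
            if best is None or ks < best[0]:
                best = (ks, int(xm), g, se, tail.size)
        if best is None:
            raise FitError(f"no cutoff leaves >= {min_tail} tail points")
        ks, xm, gamma, stderr, n_tail = best
    else:
        xm = int(x_min)
        tail = sizes[sizes >= xm]
        if tail.size < min_tail:
            raise FitError(f"only {tail.size} sizes >= x_min={xm} "
                           f"(need {min_tail})")
        gamma, stderr = _mle_gamma(tail, xm)
        ks = _ks_distance(tail, gamma, xm)
        n_tail = tail.size
    if ks_threshold is None:
        ks_threshold = 1.6 / np.sqrt(n_tail)
    return PowerLawFit(gamma=gamma, x_min=xm, estimator="mle", stderr=stderr,
                       ks_distance=ks, n_tail=n_tail,
                       plausible=ks <= ks_threshold)


def fit_powerlaw_lsq(s: np.ndarray, pdf: np.ndarray) -> PowerLawFit:
    """Least-squares power-law exponent from a tabulated/binned P(S).

    Straight-line fit of log10 P against log10 S; zero-probability
    entries are removed before fitting.
    """
    s = np.asarray(s, dtype=float)
    pdf = np.asarray(pdf, dtype=float)
    keep = pdf > 0
    s, pdf = s[keep], pdf[keep]
    if len(s) < 4:
        raise FitError("need >= 4 nonzero bins for the least-squares fit")
    res = stats.linregress(np.log10(s), np.log10(pdf))
    return PowerLawFit(gamma=float(-res.slope), x_min=int(round(s.min())),
                       estimator="lsq", stderr=float(res.stderr),
                       n_tail=len(s))


def fit_powerlaw_lsq_from_sizes(sizes: np.ndarray,
                                bins_per_decade: int = 5) -> PowerLawFit:
    """Least-squares exponent from raw sizes via log-binned density."""
    centers, dens = log_binned_pdf(np.asarray(sizes), bins_per_decade)
    return fit_powerlaw_lsq(centers, dens)
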