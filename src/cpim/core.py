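"""Stochastic simulation of the contact-process Ising model (CPIM).

The CPIM couples two processes on a 2-D lattice:

* a contact process describing colony demography — vacant sites are
  colonized by occupied neighbours, cells die spontaneously, and
  newborn (undifferentiated) cells commit to one of two gene-expression
  states — and
* Ising/Metropolis dynamics among committed cells, whose states
  sigma = +1/-1 interact with coupling J under a noise parameter T
  (k_B == 1 throughout).

Site codes: 0 = vacant, 2 = undifferentiated, +1/-1 = differentiated.
A pure Ising mode (fully occupied, periodic boundary, spin flips only)
is provided as the reference system.

The per-sweep update discipline is asynchronous random sequential
updating: one sweep performs L*L single-site attempts at uniformly
random sites.  A compiled (numba) kernel executes sweeps; the
single-site operations are also exposed as plain Python functions so
their algebra can be checked directly against the Hamiltonian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from numba import njit

VACANT = 0
UNDIFF = 2

#: observable columns recorded once per sweep
OBSERVABLE_COLUMNS = [
    "sweep", "n_occupied", "n_plus", "n_minus", "M", "m_per_occupied",
    "energy", "colonizations", "deaths", "differentiations",
    "flip_attempts", "flips_accepted",
]

_VON_NEUMANN = np.array([(-1, 0), (1, 0), (0, -1), (0, 1)], dtype=np.int64)
_MOORE = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)


class ConfigurationError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass(frozen=True)
class CPIMParams:
    """Full control set for one simulation run.

    Parameters
    ----------
    L : lattice side length (sites).
    T : coupling-noise control parameter, dimensionless (units |J|/k_B).
    J : +1 (ferromagnetic) or -1 (anti-ferromagnetic).
    b : colonization probability per occupied neighbour per attempt.
    d : death probability per attempt.
    g : differentiation probability per attempt for undifferentiated cells.
    neighborhood : 4 (von Neumann) or 8 (Moore, the next-nearest variant).
    sweeps : sweep budget (one sweep = L*L site attempts).
    seed : RNG seed; every run is a pure function of (params, seed).
    mode : "cpim" or "pure_ising".
    """

    L: int = 128
    T: float = 2.27
    J: int = 1
    b: float = 0.03
    d: float = 1e-5
    g: float = 0.1
    neighborhood: int = 4
    sweeps: int = 1000
    seed: int = 0
    mode: Literal["cpim", "pure_ising"] = "cpim"

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ConfigurationError(f"L must be >= 2, got {self.L}")
        if self.T <= 0:
            raise ConfigurationError(f"T must be > 0, got {self.T}")
        if self.J not in (1, -1):
            raise ConfigurationError(f"J must be +1 or -1, got {self.J}")
        for name in ("b", "d", "g"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        if self.neighborhood not in (4, 8):
            raise ConfigurationError("neighborhood must be 4 or 8")
        if self.mode not in ("cpim", "pure_ising"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.sweeps < 0:
            raise ConfigurationError("sweeps must be >= 0")

    @property
    def offsets(self) -> np.ndarray:
        return _VON_NEUMANN if self.neighborhood == 4 else _MOORE

    def with_(self, **kw) -> "CPIMParams":
        return replace(self, **kw)


@dataclass
class LatticeState:
    """2-D grid of site codes plus geometry metadata."""

    grid: np.ndarray
    boundary: Literal["open", "periodic"] = "open"
    sweep_count: int = 0
    mode: Literal["cpim", "pure_ising"] = "cpim"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int8)
        codes = np.unique(self.grid)
        if not np.all(np.isin(codes, [VACANT, UNDIFF, 1, -1])):
            bad = sorted(set(codes) - {VACANT, UNDIFF, 1, -1})
            raise ValueError(f"illegal site codes {bad}")
        if self.mode == "pure_ising":
            if np.any(np.abs(self.grid) != 1):
                raise ValueError("pure Ising lattices contain only +1/-1")
            if self.boundary != "periodic":
                raise ValueError("pure Ising mode uses periodic boundaries")

    @property
    def L(self) -> int:
        return self.grid.shape[0]

    @property
    def occupied(self) -> np.ndarray:
        return self.grid != VACANT

    @property
    def differentiated(self) -> np.ndarray:
        return np.abs(self.grid) == 1

    @property
    def spins(self) -> np.ndarray:
        """Signed state field: +1/-1 at differentiated sites, 0 elsewhere."""
        return np.where(self.differentiated, self.grid, 0).astype(np.int8)

    def copy(self) -> "LatticeState":
        return LatticeState(self.grid.copy(), self.boundary,
                            self.sweep_count, self.mode)


@dataclass
class EventCounts:
    """Tallied events for a block of sweeps."""

    colonizations: int = 0
    differentiations: int = 0
    deaths: int = 0
    flip_attempts: int = 0
    flips_accepted: int = 0

    def __iadd__(self, other: "EventCounts") -> "EventCounts":
        self.colonizations += other.colonizations
        self.differentiations += other.differentiations
        self.deaths += other.deaths
        self.flip_attempts += other.flip_attempts
        self.flips_accepted += other.flips_accepted
        return self


@dataclass
class SimulationResult:
    """Final lattice, per-sweep observables and optional snapshots."""

    lattice: LatticeState
    series: pd.DataFrame
    snapshots: list[tuple[int, np.ndarray]] = field(default_factory=list)
    params: CPIMParams | None = None
    stopped_at_edge: bool = False


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

def init_lattice(params: CPIMParams) -> LatticeState:
    """Build the initial lattice.

    CPIM mode seeds a single undifferentiated cell at the lattice centre
    on an otherwise vacant open-boundary lattice; pure Ising mode fills a
    periodic lattice with iid +1/-1 spins.
    """
    L = params.L
    if params.mode == "cpim":
        grid = np.zeros((L, L), dtype=np.int8)
        grid[L // 2, L // 2] = UNDIFF
        return LatticeState(grid, boundary="open", mode="cpim")
    rng = np.random.default_rng(params.seed)
    grid = rng.choice(np.array([1, -1], dtype=np.int8), size=(L, L))
    return LatticeState(grid, boundary="periodic", mode="pure_ising")


# ---------------------------------------------------------------------------
# single-site operations (reference implementations)
# ---------------------------------------------------------------------------

def _neighbor_spin_sum(lattice: LatticeState, i: int, j: int,
                       offsets: np.ndarray) -> int:
    L = lattice.L
    periodic = lattice.boundary == "periodic"
    total = 0
    for di, dj in offsets:
        ni, nj = i + di, j + dj
        if periodic:
            ni %= L
            nj %= L
        elif not (0 <= ni < L and 0 <= nj < L):
            continue
        v = int(lattice.grid[ni, nj])
        if v * v == 1:
            total += v
    return total


def hamiltonian(lattice: LatticeState, J: int,
                neighborhood: int = 4) -> float:
    """Interaction energy H = -J * sum over neighbouring pairs sigma_i sigma_j.

    Each unordered pair counts once; only pairs where both sites are
    differentiated (+1/-1) contribute.
    """
    s = lattice.spins.astype(np.int64)
    L = lattice.L
    total = 0
    offsets = _VON_NEUMANN if neighborhood == 4 else _MOORE
    # keep each unordered pair once: drop the mirror of any offset seen
    seen: set[tuple[int, int]] = set()
    fw = []
    for di, dj in offsets:
        di, dj = int(di), int(dj)
        if (-di, -dj) in seen:
            continue
        seen.add((di, dj))
        fw.append((di, dj))
    for di, dj in fw:
        if lattice.boundary == "periodic":
            total += int(np.sum(s * np.roll(np.roll(s, -di, axis=0), -dj, axis=1)))
        else:
            a = s[max(di, 0):L + min(di, 0), max(dj, 0):L + min(dj, 0)]
            b = s[max(-di, 0):L + min(-di, 0), max(-dj, 0):L + min(-dj, 0)]
            total += int(np.sum(a * b))
    return -float(J) * total


def delta_energy(lattice: LatticeState, site: tuple[int, int], J: int,
                 neighborhood: int = 4) -> float:
    """Energy change of flipping the spin at ``site``.

    dH = 2 * J * sigma_site * sum of differentiated-neighbour spins.
    """
    i, j = site
    s = int(lattice.grid[i, j])
    if s * s != 1:
        raise ValueError(f"site {site} is not differentiated (code {s})")
    offsets = _VON_NEUMANN if neighborhood == 4 else _MOORE
    return 2.0 * J * s * _neighbor_spin_sum(lattice, i, j, offsets)


def metropolis_flip(lattice: LatticeState, site: tuple[int, int], T: float,
                    J: int, rng: np.random.Generator,
                    neighborhood: int = 4) -> bool:
    """Attempt a Metropolis spin flip; mutates the lattice on acceptance.

    Acceptance probability min(1, exp(-dH/T)).
    """
    if T <= 0:
        raise ConfigurationError("T must be > 0")
    dH = delta_energy(lattice, site, J, neighborhood)
    if dH <= 0 or rng.random() < math.exp(-dH / T):
        i, j = site
        lattice.grid[i, j] = -lattice.grid[i, j]
        return True
    return False


def cp_event(lattice: LatticeState, site: tuple[int, int],
             params: CPIMParams, rng: np.random.Generator) -> EventCounts:
    """Apply one contact-process/flip attempt at a single site.

    Vacant sites are colonized with probability 1-(1-b)^k for k occupied
    neighbours; undifferentiated cells die with probability d, else
    differentiate with probability g into +1/-1 uniformly; differentiated
    cells die with probability d, else attempt a Metropolis flip.
    """
    i, j = site
    s = int(lattice.grid[i, j])
    out = EventCounts()
    offsets = params.offsets
    if s == VACANT:
        k = 0
        L = lattice.L
        for di, dj in offsets:
            ni, nj = i + di, j + dj
            if 0 <= ni < L and 0 <= nj < L and lattice.grid[ni, nj] != VACANT:
                k += 1
        if k > 0 and rng.random() < 1.0 - (1.0 - params.b) ** k:
            lattice.grid[i, j] = UNDIFF
            out.colonizations = 1
    elif s == UNDIFF:
        if rng.random() < params.d:
            lattice.grid[i, j] = VACANT
            out.deaths = 1
        elif rng.random() < params.g:
            lattice.grid[i, j] = 1 if rng.random() < 0.5 else -1
            out.differentiations = 1
    else:
        if rng.random() < params.d:
            lattice.grid[i, j] = VACANT
            out.deaths = 1
        else:
            out.flip_attempts = 1
            if metropolis_flip(lattice, site, params.T, params.J, rng,
                               params.neighborhood):
                out.flips_accepted = 1
    return out


def sweep(lattice: LatticeState, params: CPIMParams,
          rng: np.random.Generator) -> EventCounts:
    """One sweep of L*L random-sequential single-site attempts (pure Python).

    Reference implementation used for contract tests; `run_simulation`
    uses the compiled kernel.
    """
    L = lattice.L
    out = EventCounts()
    for _ in range(L * L):
        i = int(rng.integers(L))
        j = int(rng.integers(L))
        if lattice.mode == "pure_ising":
            out.flip_attempts += 1
            if metropolis_flip(lattice, (i, j), params.T, params.J, rng,
                               params.neighborhood):
                out.flips_accepted += 1
        else:
            out += cp_event(lattice, (i, j), params, rng)
    lattice.sweep_count += 1
    return out


# ---------------------------------------------------------------------------
# compiled sweep kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _seed_kernel_rng(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def _spin_sum(grid, i, j, offs, periodic, L):
    total = 0
    for q in range(offs.shape[0]):
        ni = i + offs[q, 0]
        nj = j + offs[q, 1]
        if periodic:
            ni %= L
            nj %= L
        elif ni < 0 or ni >= L or nj < 0 or nj >= L:
            continue
        v = grid[ni, nj]
        if v == 1 or v == -1:
            total += v
    return total


@njit(cache=True)
def _scan_counters(grid, J, offs, periodic):
    """Occupancy/magnetization counters and total energy of a grid."""
    L = grid.shape[0]
    n_occ = 0
    n_plus = 0
    n_minus = 0
    for i in range(L):
        for j in range(L):
            v = grid[i, j]
            if v != 0:
                n_occ += 1
            if v == 1:
                n_plus += 1
            elif v == -1:
                n_minus += 1
    energy = 0.0
    for i in range(L):
        for j in range(L):
            v = grid[i, j]
            if v == 1 or v == -1:
                energy += -J * v * _spin_sum(grid, i, j, offs, periodic, L)
    energy *= 0.5  # each pair visited twice
    return n_occ, n_plus, n_minus, energy


@njit(cache=True)
def _run_sweeps(grid, T, J, pcol, d, g, offs, periodic, cpim_mode,
                n_sweeps, stop_at_edge, rec, rec_offset, sweep0,
                accept_only_downhill):
    """Run up to ``n_sweeps`` sweeps in place; returns sweeps completed.

    ``rec`` is a (>= rec_offset+n_sweeps, 12) float64 array filled with
    one observable row per completed sweep.  The kernel RNG must have
    been seeded beforehand with `_seed_kernel_rng`.
    """
    L = grid.shape[0]
    n_occ, n_plus, n_minus, energy = _scan_counters(grid, J, offs, periodic)
    M = n_plus - n_minus
    edge = False
    done = 0
    for sw in range(n_sweeps):
        colonizations = 0
        deaths = 0
        differentiations = 0
        flip_attempts = 0
        flips_accepted = 0
        for _ in range(L * L):
            i = np.random.randint(0, L)
            j = np.random.randint(0, L)
            s = grid[i, j]
            if s == 0:
                if not cpim_mode:
                    continue
                k = 0
                for q in range(offs.shape[0]):
                    ni = i + offs[q, 0]
                    nj = j + offs[q, 1]
                    if periodic:
                        ni %= L
                        nj %= L
                    elif ni < 0 or ni >= L or nj < 0 or nj >= L:
                        continue
                    if grid[ni, nj] != 0:
                        k += 1
                if k > 0 and np.random.random() < pcol[k]:
                    grid[i, j] = 2
                    n_occ += 1
                    colonizations += 1
                    if i == 0 or i == L - 1 or j == 0 or j == L - 1:
                        edge = True
            elif s == 2:
                if np.random.random() < d:
                    grid[i, j] = 0
                    n_occ -= 1
                    deaths += 1
                elif np.random.random() < g:
                    ss = _spin_sum(grid, i, j, offs, periodic, L)
                    if np.random.random() < 0.5:
                        spin = 1
                    else:
                        spin = -1
                    grid[i, j] = spin
                    energy += -J * spin * ss
                    M += spin
                    if spin == 1:
                        n_plus += 1
                    else:
                        n_minus += 1
                    differentiations += 1
            else:
                if cpim_mode and np.random.random() < d:
                    ss = _spin_sum(grid, i, j, offs, periodic, L)
                    # remove the spin: its bonds disappear
                    energy += J * s * ss
                    grid[i, j] = 0
                    n_occ -= 1
                    M -= s
                    if s == 1:
                        n_plus -= 1
                    else:
                        n_minus -= 1
                    deaths += 1
                else:
                    flip_attempts += 1
                    ss = _spin_sum(grid, i, j, offs, periodic, L)
                    dH = 2.0 * J * s * ss
                    accept = False
                    if accept_only_downhill:
                        accept = dH <= 0.0
                    elif dH <= 0.0:
                        accept = True
                    elif np.random.random() < np.exp(-dH / T):
                        accept = True
                    if accept:
                        grid[i, j] = -s
                        energy += dH
                        M -= 2 * s
                        if s == 1:
                            n_plus -= 1
                            n_minus += 1
                        else:
                            n_plus += 1
                            n_minus -= 1
                        flips_accepted += 1
        row = rec_offset + sw
        rec[row, 0] = sweep0 + sw + 1
        rec[row, 1] = n_occ
        rec[row, 2] = n_plus
        rec[row, 3] = n_minus
        rec[row, 4] = M
        rec[row, 5] = M / n_occ if n_occ > 0 else 0.0
        rec[row, 6] = energy
        rec[row, 7] = colonizations
        rec[row, 8] = deaths
        rec[row, 9] = differentiations
        rec[row, 10] = flip_attempts
        rec[row, 11] = flips_accepted
        done = sw + 1
        if stop_at_edge and edge:
            break
    return done, edge


def _kernel_seed_from(seed: int) -> int:
    # numba's legacy RNG takes a 32-bit seed
    return int(np.random.SeedSequence(seed).generate_state(1, np.uint32)[0])


def run_simulation(params: CPIMParams,
                   snapshot_every: int | None = None,
                   stop_at_edge: bool = True,
                   initial: LatticeState | None = None,
                   accept_only_downhill: bool = False) -> SimulationResult:
    """Run a full CPIM (or pure Ising) simulation.

    Parameters
    ----------
    snapshot_every : record a copy of the grid every that many sweeps.
    stop_at_edge : in CPIM mode, stop once the colony touches the lattice
        edge (in addition to the sweep budget).
    initial : optional starting lattice (defaults to `init_lattice`).
    accept_only_downhill : restrict flips to dH <= 0 (a T -> 0 quench).
    """
    lattice = initial.copy() if initial is not None else init_lattice(params)
    cpim_mode = params.mode == "cpim"
    periodic = lattice.boundary == "periodic"
    nmax = params.offsets.shape[0]
    pcol = np.zeros(nmax + 1)
    for k in range(1, nmax + 1):
        pcol[k] = 1.0 - (1.0 - params.b) ** k
    rec = np.zeros((params.sweeps, 12))
    _seed_kernel_rng(_kernel_seed_from(params.seed))

    snapshots: list[tuple[int, np.ndarray]] = []
    sweeps_done = 0
    edge = False
    chunk = snapshot_every if snapshot_every else params.sweeps
    stop = stop_at_edge and cpim_mode
    while sweeps_done < params.sweeps:
        n = min(chunk, params.sweeps - sweeps_done)
        done, edge = _run_sweeps(
            lattice.grid, params.T, params.J, pcol, params.d, params.g,
            params.offsets, periodic, cpim_mode, n, stop, rec,
            sweeps_done, lattice.sweep_count + sweeps_done,
            accept_only_downhill)
        sweeps_done += done
        if snapshot_every:
            snapshots.append((sweeps_done, lattice.grid.copy()))
        if (stop and edge) or done < n:
            break
    lattice.sweep_count += sweeps_done
    series = pd.DataFrame(rec[:sweeps_done], columns=OBSERVABLE_COLUMNS)
    for c in ("sweep", "n_occupied", "n_plus", "n_minus", "M",
              "colonizations", "deaths", "differentiations",
              "flip_attempts", "flips_accepted"):
        series[c] = series[c].astype(np.int64)
    return SimulationResult(lattice=lattice, series=series,
                            snapshots=snapshots, params=params,
                            stopped_at_edge=bool(edge))


def run_pure_ising(params: CPIMParams,
                   snapshot_every: int | None = None,
                   initial: LatticeState | None = None) -> SimulationResult:
    """Metropolis dynamics on a fully occupied periodic lattice."""
    if params.mode != "pure_ising":
        params = params.with_(mode="pure_ising")
    return run_simulation(params, snapshot_every=snapshot_every,
                          stop_at_edge=False, initial=initial)
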