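"""Two-state empirical valence bond (EVB) energetics and free-energy profiles.

The reaction is represented by two diabatic states — a reactant-like force
field with per-frame energy ``eps1`` and a product-like one with energy
``eps2`` (origin-shifted by the gas-phase calibration constant before it
enters any computation here).  Sampling is driven window by window under a
linear mapping potential ``eps_m = (1-lam)*eps1 + lam*eps2``; the free energy
along the energy-gap coordinate ``X = eps1 - eps2`` is recovered by free
energy perturbation between adjacent windows followed by umbrella
recombination onto the adiabatic ground state

    E_g = (eps1+eps2)/2 - sqrt((eps1-eps2)^2 + 4*H12^2)/2 ,

the lower eigenvalue of the 2x2 EVB Hamiltonian with constant coupling H12.

All energies are kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .constants import R_KCAL

__all__ = [
    "EVBParams",
    "MappingSchedule",
    "WindowLog",
    "FreeEnergyProfile",
    "ReplicaSummary",
    "mapping_potential",
    "ground_state_energy",
    "fep_increment",
    "build_free_energy_profile",
    "extract_barrier",
    "aggregate_replicas",
]


@dataclass(frozen=True)
class EVBParams:
    """Constants of the two-state EVB Hamiltonian.

    Parameters
    ----------
    off_diagonal
        Coupling H12 between the diabatic states, kcal/mol.  Defaults to the
        value calibrated for serotonin oxidation by MAO-A.
    gas_shift
        Additive origin shift of the product diabat (alpha), kcal/mol.
        Applied exactly once to raw product energies before they are stored
        in a :class:`WindowLog`.
    temperature
        Simulation temperature, K.
    """

    off_diagonal: float = 44.28
    gas_shift: float = 103.94
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if self.off_diagonal < 0:
            raise ValueError(f"off_diagonal must be >= 0, got {self.off_diagonal}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")

    @property
    def rt(self) -> float:
        """Thermal energy R*T, kcal/mol."""
        return R_KCAL * self.temperature


@dataclass(frozen=True)
class MappingSchedule:
    """Ordered coupling-parameter schedule for the mapping potential."""

    lambdas: tuple[float, ...]
    frames_per_window: int = 1000

    def __post_init__(self) -> None:
        lams = np.asarray(self.lambdas, dtype=float)
        if lams.size < 2:
            raise ValueError("schedule needs at least two windows")
        if lams[0] != 0.0 or lams[-1] != 1.0:
            raise ValueError("schedule must start at lambda=0 and end at lambda=1")
        if not np.all(np.diff(lams) > 0):
            raise ValueError("lambdas must be strictly increasing")
        if self.frames_per_window < 1:
            raise ValueError("frames_per_window must be >= 1")

    @classmethod
    def uniform(cls, n_windows: int = 51, frames_per_window: int = 1000) -> "MappingSchedule":
        """Uniform schedule; the default 51 windows give a 0.02 lambda step."""
        lams = np.linspace(0.0, 1.0, n_windows)
        return cls(lambdas=tuple(float(x) for x in lams), frames_per_window=frames_per_window)

    @property
    def n_windows(self) -> int:
        return len(self.lambdas)

    def total_sampling_time_ps(self, window_ps: float = 100.0) -> float:
        """Cumulative simulated time for one replica at `window_ps` per window."""
        return self.n_windows * window_ps


@dataclass
class WindowLog:
    """Per-frame diabatic and mapping energies for one lambda window.

    ``eps2`` is the *shifted* product diabat: the gas-phase origin shift has
    already been added.  ``eps_map`` must be consistent with
    ``mapping_potential(eps1, eps2, lam)`` to 1e-6 kcal/mol.
    """

    lam: float
    eps1: np.ndarray
    eps2: np.ndarray
    eps_map: np.ndarray

    def __post_init__(self) -> None:
        self.eps1 = np.asarray(self.eps1, dtype=float)
        self.eps2 = np.asarray(self.eps2, dtype=float)
        self.eps_map = np.asarray(self.eps_map, dtype=float)
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError(f"lambda must lie in [0, 1], got {self.lam}")
        n = self.eps1.size
        if n < 1:
            raise ValueError("window log must contain at least one frame")
        if self.eps2.size != n or self.eps_map.size != n:
            raise ValueError("eps1, eps2 and eps_map must have equal length")
        regen = mapping_potential(self.eps1, self.eps2, self.lam)
        if not np.allclose(regen, self.eps_map, atol=1e-6, rtol=0.0):
            raise ValueError(
                "eps_map inconsistent with (1-lambda)*eps1 + lambda*eps2 "
                f"at lambda={self.lam} (max deviation "
                f"{np.max(np.abs(regen - self.eps_map)):.3g} kcal/mol)"
            )

    @property
    def n_frames(self) -> int:
        return self.eps1.size

    def energy_at(self, lam: float) -> np.ndarray:
        """Mapping-potential energy of the stored frames at another lambda."""
        return mapping_potential(self.eps1, self.eps2, lam)

    @property
    def gap(self) -> np.ndarray:
        """Energy-gap reaction coordinate X = eps1 - eps2 per frame."""
        return self.eps1 - self.eps2


@dataclass
class FreeEnergyProfile:
    """Free energy along the energy-gap coordinate, zeroed at the reactant minimum."""

    bin_centers: np.ndarray
    free_energy: np.ndarray
    bin_counts: np.ndarray
    barrier: float | None = None
    reaction_free_energy: float | None = None

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        self.bin_counts = np.asarray(self.bin_counts)
        if not np.all(np.diff(self.bin_centers) > 0):
            raise ValueError("bin centers must be strictly increasing")
        if self.bin_centers.size != self.free_energy.size != self.bin_counts.size:
            raise ValueError("profile arrays must have equal length")

    def to_frame(self):
        """Profile as a pandas DataFrame (bin_center, free_energy, count)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "free_energy": self.free_energy,
                "count": self.bin_counts,
            }
        )


@dataclass(frozen=True)
class ReplicaSummary:
    """Replica-averaged barrier and reaction free energy with SEMs."""

    barriers: tuple[float, ...]
    mean_barrier: float
    sem_barrier: float
    reaction_free_energies: tuple[float, ...] | None = None
    mean_reaction_free_energy: float | None = None
    sem_reaction_free_energy: float | None = None

    @property
    def n(self) -> int:
        return len(self.barriers)

    @property
    def sem_defined(self) -> bool:
        """SEM is undefined for a single replica."""
        return self.n >= 2


def mapping_potential(eps1, eps2, lam: float):
    """Linear mapping potential (1-lam)*eps1 + lam*eps2 driving the transformation."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    return (1.0 - lam) * np.asarray(eps1, dtype=float) + lam * np.asarray(eps2, dtype=float)


def ground_state_energy(eps1, eps2, h12: float):
    """Lower eigenvalue of the 2x2 EVB Hamiltonian [[eps1, h12], [h12, eps2]]."""
    if h12 < 0:
        raise ValueError(f"off-diagonal coupling must be >= 0, got {h12}")
    e1 = np.asarray(eps1, dtype=float)
    e2 = np.asarray(eps2, dtype=float)
    return 0.5 * (e1 + e2) - 0.5 * np.sqrt((e1 - e2) ** 2 + 4.0 * h12 * h12)


def fep_increment(delta_series, temperature: float) -> float:
    """Zwanzig free-energy increment -RT*ln<exp(-d/RT)> from a sampled gap series.

    Stabilised with log-sum-exp so arbitrarily large gaps stay finite.
    """
    delta = np.asarray(delta_series, dtype=float)
    if delta.size == 0:
        raise ValueError("no samples: cannot estimate a free-energy increment")
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    rt = R_KCAL * temperature
    return float(-rt * (logsumexp(-delta / rt) - np.log(delta.size)))


def _locate_stationary_points(g: np.ndarray) -> tuple[int, int, int]:
    """Indices (reactant_min, ts_max, product_min) on a binned profile.

    The transition state is the global maximum among interior points that
    have a strictly lower value somewhere on both sides; the reactant
    minimum is the lowest point left of it (more negative X), the product
    minimum the lowest point right of it.
    """
    n = g.size
    if n < 3:
        raise ValueError("profile needs at least 3 reported bins")
    left_min = np.minimum.accumulate(g)
    right_min = np.minimum.accumulate(g[::-1])[::-1]
    interior = np.arange(1, n - 1)
    mask = (left_min[interior - 1] < g[interior]) & (right_min[interior + 1] < g[interior])
    candidates = interior[mask]
    if candidates.size == 0:
        raise ValueError("no transition state: profile is monotone")
    ts = int(candidates[np.argmax(g[candidates])])
    i_react = int(np.argmin(g[:ts]))
    i_prod = ts + 1 + int(np.argmin(g[ts + 1 :]))
    return i_react, ts, i_prod


def extract_barrier(profile: FreeEnergyProfile) -> tuple[float, float]:
    """Activation and reaction free energy from a binned profile.

    Returns ``(barrier, reaction_free_energy)`` with the reactant basin on
    the negative-gap side.  Raises ``ValueError`` for a monotone profile.
    """
    i_r, i_ts, i_p = _locate_stationary_points(profile.free_energy)
    g = profile.free_energy
    return float(g[i_ts] - g[i_r]), float(g[i_p] - g[i_r])


def build_free_energy_profile(
    logs: Sequence[WindowLog],
    params: EVBParams,
    n_bins: int = 50,
    min_count: int = 10,
) -> FreeEnergyProfile:
    """Combine lambda-window logs into a ground-state free-energy profile.

    The cumulative window free energies come from forward Zwanzig
    perturbation between adjacent windows, accumulated from lambda=0.  Each
    bin of the energy-gap coordinate is then estimated from the window that
    contributes the most frames to it (ties go to the lower lambda) via the
    standard umbrella reweighting onto the adiabatic surface,

        dG(bin) = dG_m - RT * ln( (1/N_m) * sum_{frames in bin} exp(-(E_g - eps_m)/RT) ),

    where the sum runs over the owner window's frames in the bin and N_m is
    that window's total frame count, so sparsely visited bins carry their
    correct occupancy weight.  Bins whose owner contributes fewer than
    `min_count` frames are omitted.  The profile is shifted so the reactant
    minimum sits at zero, and barrier / reaction free energy are extracted
    when an interior maximum exists.
    """
    if len(logs) < 2:
        raise ValueError("need at least two lambda windows to build a profile")
    logs = sorted(logs, key=lambda w: w.lam)
    lams = np.array([w.lam for w in logs])
    if np.any(np.diff(lams) <= 0):
        raise ValueError("window lambdas must be distinct")
    rt = params.rt

    # Cumulative FEP free energy of each window, dG[0] = 0 at lambda=0.
    dg = np.zeros(len(logs))
    for m in range(len(logs) - 1):
        delta = logs[m].energy_at(logs[m + 1].lam) - logs[m].eps_map
        dg[m + 1] = dg[m] + fep_increment(delta, params.temperature)

    gaps = [w.gap for w in logs]
    x_all = np.concatenate(gaps)
    x_lo, x_hi = float(x_all.min()), float(x_all.max())
    if x_lo == x_hi:
        raise ValueError("energy-gap coordinate is constant; cannot bin")
    edges = np.linspace(x_lo, x_hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = np.zeros((n_bins, len(logs)), dtype=int)
    bin_idx = []
    exponents = []
    for m, w in enumerate(logs):
        idx = np.clip(np.digitize(gaps[m], edges) - 1, 0, n_bins - 1)
        bin_idx.append(idx)
        counts[:, m] = np.bincount(idx, minlength=n_bins)
        e_g = ground_state_energy(w.eps1, w.eps2, params.off_diagonal)
        exponents.append(-(e_g - w.eps_map) / rt)

    owner = np.argmax(counts, axis=1)  # argmax takes the first (lower-lambda) tie
    owner_counts = counts[np.arange(n_bins), owner]
    keep = owner_counts >= min_count
    if not np.any(keep):
        raise ValueError("all bins fall below min_count; increase sampling or bin width")

    g = np.full(n_bins, np.nan)
    for b in np.nonzero(keep)[0]:
        m = owner[b]
        sel = bin_idx[m] == b
        g[b] = dg[m] - rt * (logsumexp(exponents[m][sel]) - np.log(logs[m].n_frames))

    centers = centers[keep]
    g = g[keep]
    kept_counts = owner_counts[keep]

    barrier: float | None
    dg_rxn: float | None
    try:
        i_r, i_ts, i_p = _locate_stationary_points(g)
        barrier = float(g[i_ts] - g[i_r])
        dg_rxn = float(g[i_p] - g[i_r])
        g = g - g[i_r]
    except ValueError:
        barrier = None
        dg_rxn = None
        g = g - g.min()

    return FreeEnergyProfile(
        bin_centers=centers,
        free_energy=g,
        bin_counts=kept_counts,
        barrier=barrier,
        reaction_free_energy=dg_rxn,
    )


def aggregate_replicas(
    barriers: Sequence[float],
    reaction_free_energies: Sequence[float] | None = None,
) -> ReplicaSummary:
    """Mean and standard error of the mean over independent replicas.

    SEM is the sample standard deviation (ddof=1) divided by sqrt(n); it is
    reported as NaN (and flagged undefined) for a single replica.
    """
    b = np.asarray(barriers, dtype=float)
    if b.size == 0:
        raise ValueError("no replica barriers to aggregate")

    def _sem(v: np.ndarray) -> float:
        return float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size >= 2 else float("nan")

    out = dict(
        barriers=tuple(float(x) for x in b),
        mean_barrier=float(b.mean()),
        sem_barrier=_sem(b),
    )
    if reaction_free_energies is not None:
        r = np.asarray(reaction_free_energies, dtype=float)
        if r.size != b.size:
            raise ValueError("reaction free energies must match barriers in length")
        out.update(
            reaction_free_energies=tuple(float(x) for x in r),
            mean_reaction_free_energy=float(r.mean()),
            sem_reaction_free_energy=_sem(r),
        )
    return ReplicaSummary(**out)
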