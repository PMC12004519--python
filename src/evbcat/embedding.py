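"""Charge-embedding "enzyme ON/OFF" barrier decomposition.

A reacting moiety (for MAO-A: serotonin plus the lumiflavin analog of the
flavin cofactor) is evaluated over reactant (R) and transition-state (TS)
snapshot ensembles twice: with the surrounding protein point charges
active (ON) and with them removed (OFF).  The drop in the TS-minus-R
barrier on switching the charges on,

    ddE = dE_ON - dE_OFF,

measures the catalytic effect of the enzyme's electrostatic preorganization;
a negative value means the environment stabilizes the transition state more
than the reactants.

The energy backend is a behavioural contract: any engine that returns a
deterministic energy for (snapshot, active charge subset) plugs in.  The
shipped :class:`CoulombBackend` is a fixed-charge surrogate — per-state
internal energy plus bare Coulomb interaction with the selected point
charges — which keeps the decomposition algebra exact and additive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
from scipy.spatial.distance import cdist

from .constants import COULOMB_CONST

__all__ = [
    "AtomTable",
    "Snapshot",
    "SnapshotEnsemble",
    "ChargeSelector",
    "CoulombBackend",
    "BarrierDecomposition",
    "coulomb_interaction",
    "surrogate_energy",
    "decompose_barrier",
]

STATE_LABELS = ("R", "TS")

#: Which environment charges are active: "all", "none", or residue ids.
ChargeSelector = Union[str, Iterable[int]]


@dataclass
class AtomTable:
    """Flat table of atoms: positions (n,3) Å, charges (n,) e, identity columns."""

    positions: np.ndarray
    charges: np.ndarray
    residue_ids: np.ndarray
    residue_names: tuple[str, ...]
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        n = self.positions.shape[0]
        if not (self.charges.size == self.residue_ids.size == n):
            raise ValueError("atom table columns must have equal length")
        if len(self.residue_names) != n or len(self.atom_names) != n or len(self.elements) != n:
            raise ValueError("atom table name columns must have equal length")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def empty(cls) -> "AtomTable":
        return cls(
            positions=np.zeros((0, 3)),
            charges=np.zeros(0),
            residue_ids=np.zeros(0, dtype=int),
            residue_names=(),
            atom_names=(),
            elements=(),
        )


@dataclass
class Snapshot:
    """One configuration of the reacting moiety in its point-charge environment."""

    state_label: str
    moiety: AtomTable
    environment: AtomTable
    label: str = ""

    def __post_init__(self) -> None:
        if self.state_label not in STATE_LABELS:
            raise ValueError(
                f"unknown state label {self.state_label!r}; expected one of {STATE_LABELS}"
            )
        if self.moiety.n_atoms == 0:
            raise ValueError("snapshot must contain a non-empty reacting moiety")
        if self.environment.n_atoms and np.any(self.environment.residue_ids < 1):
            raise ValueError("environment residue ids must be >= 1")

    @property
    def residue_ids(self) -> np.ndarray:
        """Sorted unique environment residue ids."""
        return np.unique(self.environment.residue_ids)


@dataclass
class SnapshotEnsemble:
    """A bag of R and/or TS snapshots."""

    snapshots: list[Snapshot] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)

    def __add__(self, other: "SnapshotEnsemble") -> "SnapshotEnsemble":
        return SnapshotEnsemble(self.snapshots + other.snapshots)

    def by_state(self, state_label: str) -> list[Snapshot]:
        return [s for s in self.snapshots if s.state_label == state_label]

    @property
    def states(self) -> set[str]:
        return {s.state_label for s in self.snapshots}


def _selection_mask(environment: AtomTable, selector: ChargeSelector) -> np.ndarray:
    if isinstance(selector, str):
        if selector == "all":
            return np.ones(environment.n_atoms, dtype=bool)
        if selector == "none":
            return np.zeros(environment.n_atoms, dtype=bool)
        raise ValueError(f"unknown selector {selector!r}; use 'all', 'none' or residue ids")
    ids = np.asarray(sorted(set(int(i) for i in selector)), dtype=int)
    return np.isin(environment.residue_ids, ids)


def coulomb_interaction(
    moiety: AtomTable,
    environment: AtomTable,
    selector: ChargeSelector = "all",
) -> float:
    """Bare Coulomb energy between the moiety and selected environment charges.

    E = sum_ij C * q_i * q_j / r_ij with C = 332.0636 kcal Å / (mol e^2);
    no cutoff, no periodicity.  A coincident moiety/environment pair raises
    an error naming both atoms.
    """
    mask = _selection_mask(environment, selector)
    if not np.any(mask) or moiety.n_atoms == 0:
        return 0.0
    pos_env = environment.positions[mask]
    r = cdist(moiety.positions, pos_env)
    if np.any(r < 1e-9):
        i, j = np.argwhere(r < 1e-9)[0]
        env_idx = np.nonzero(mask)[0][j]
        raise ValueError(
            "coincident atoms: moiety atom "
            f"{moiety.atom_names[i]} and environment atom "
            f"{environment.atom_names[env_idx]} of residue "
            f"{environment.residue_ids[env_idx]} overlap"
        )
    q = np.outer(moiety.charges, environment.charges[mask])
    return float(COULOMB_CONST * np.sum(q / r))


@dataclass
class CoulombBackend:
    """Fixed-charge surrogate energy engine.

    Total energy is a configured per-state internal constant, an optional
    harmonic restraint on the moiety coordinates, and the Coulomb
    interaction with whichever environment charges are active.  With an
    empty active set the result is the isolated-moiety energy, and a
    zero-charge atom never changes it — the contract any plugged-in quantum
    engine must also honour.
    """

    state_energies: Mapping[str, float] = field(
        default_factory=lambda: {"R": 0.0, "TS": 0.0}
    )
    harmonic_k: float = 0.0  # kcal/mol/Å^2 per atom coordinate
    reference_positions: Mapping[str, np.ndarray] | None = None

    def internal_energy(self, snapshot: Snapshot) -> float:
        try:
            e = float(self.state_energies[snapshot.state_label])
        except KeyError:
            raise ValueError(
                f"unknown state label {snapshot.state_label!r}; backend knows "
                f"{sorted(self.state_energies)}"
            ) from None
        if self.harmonic_k and self.reference_positions is not None:
            ref = np.asarray(self.reference_positions[snapshot.state_label], dtype=float)
            disp = snapshot.moiety.positions - ref
            e += 0.5 * self.harmonic_k * float(np.sum(disp * disp))
        return e

    def evaluate(self, snapshot: Snapshot, selector: ChargeSelector = "all") -> float:
        return self.internal_energy(snapshot) + coulomb_interaction(
            snapshot.moiety, snapshot.environment, selector
        )


def surrogate_energy(
    snapshot: Snapshot,
    charges_on: bool,
    backend: CoulombBackend | None = None,
) -> float:
    """Single-point surrogate energy with the environment switched on or off."""
    backend = backend if backend is not None else CoulombBackend()
    return backend.evaluate(snapshot, "all" if charges_on else "none")


def _sem(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1) / np.sqrt(values.size)) if values.size >= 2 else float("nan")


@dataclass
class BarrierDecomposition:
    """ON/OFF barriers and the electrostatic catalytic effect for one variant.

    ``catalytic_effect`` is barrier_on - barrier_off by definition; negative
    values mean the active charges lower the barrier.
    """

    barrier_off: float
    barrier_on: float
    catalytic_effect: float = field(init=False)
    mean_energies: dict = field(default_factory=dict)
    sems: dict = field(default_factory=dict)
    n_reactant: int = 0
    n_transition: int = 0

    def __post_init__(self) -> None:
        self.catalytic_effect = self.barrier_on - self.barrier_off

    @property
    def sem_catalytic_effect(self) -> float:
        """Quadrature-combined SEM of the four state means, NaN if undefined."""
        keys = [("R", "off"), ("TS", "off"), ("R", "on"), ("TS", "on")]
        if any(k not in self.sems for k in keys):
            return float("nan")
        return float(np.sqrt(sum(self.sems[k] ** 2 for k in keys)))

    @classmethod
    def from_state_means(
        cls,
        mean_r_off: float,
        mean_ts_off: float,
        mean_r_on: float,
        mean_ts_on: float,
    ) -> "BarrierDecomposition":
        """Decomposition algebra on externally supplied per-state mean energies."""
        dec = cls(
            barrier_off=mean_ts_off - mean_r_off,
            barrier_on=mean_ts_on - mean_r_on,
        )
        dec.mean_energies = {
            ("R", "off"): mean_r_off,
            ("TS", "off"): mean_ts_off,
            ("R", "on"): mean_r_on,
            ("TS", "on"): mean_ts_on,
        }
        return dec


def decompose_barrier(
    snapshots: SnapshotEnsemble,
    backend: CoulombBackend,
    selector: ChargeSelector = "all",
) -> BarrierDecomposition:
    """ON/OFF barrier decomposition over an R + TS snapshot ensemble.

    Each snapshot is evaluated with the environment charges off and with the
    selected subset on; barriers are differences of unweighted arithmetic
    means over snapshots, per state.
    """
    per_state: dict[str, dict[str, list[float]]] = {}
    for state in STATE_LABELS:
        members = snapshots.by_state(state)
        if not members:
            raise ValueError(f"missing state {state!r}: ensemble has no such snapshots")
        e_off, e_on = [], []
        for i, snap in enumerate(members):
            tag = snap.label or f"{state}[{i}]"
            try:
                e_off.append(backend.evaluate(snap, "none"))
                e_on.append(backend.evaluate(snap, selector))
            except Exception as exc:
                raise RuntimeError(f"backend failed on snapshot {tag}: {exc}") from exc
        per_state[state] = {"off": e_off, "on": e_on}

    means, sems = {}, {}
    for state in STATE_LABELS:
        for mode in ("off", "on"):
            v = np.asarray(per_state[state][mode])
            means[(state, mode)] = float(v.mean())
            sems[(state, mode)] = _sem(v)

    dec = BarrierDecomposition(
        barrier_off=means[("TS", "off")] - means[("R", "off")],
        barrier_on=means[("TS", "on")] - means[("R", "on")],
    )
    dec.mean_energies = means
    dec.sems = sems
    dec.n_reactant = len(per_state["R"]["off"])
    dec.n_transition = len(per_state["TS"]["off"])
    return dec
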