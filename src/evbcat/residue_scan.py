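"""Per-residue electrostatic contributions, classification, and geometry profiles.

Repeating the ON/OFF barrier decomposition with only a single residue's
point charges active yields that residue's contribution to the barrier.
A residue is *catalytic* when its electrostatics lowers the barrier
(contribution <= -threshold), *anticatalytic* when it raises it, and
*negligible* when the magnitude stays below the threshold (default
0.1 kcal/mol).  Geometry is tracked as the mean distance between the
unweighted centroid of the reacting moiety and that of each residue,
averaged over all snapshots; differential profiles compare a mutant
against a reference variant residue by residue.

Result tables are pandas DataFrames so they serialize directly to the CSV
interfaces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .embedding import CoulombBackend, Snapshot, SnapshotEnsemble, decompose_barrier

__all__ = [
    "ResidueContribution",
    "ScanResult",
    "classify_contribution",
    "per_residue_contribution",
    "count_scan_jobs",
    "scan_all",
    "residue_moiety_distance",
    "differential_profile",
    "sequence_domains",
    "plot_differential_profile",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.1  # kcal/mol, |contribution| below which a residue is negligible


@dataclass(frozen=True)
class ResidueContribution:
    residue_id: int
    residue_name: str
    contribution: float  # kcal/mol, single-residue ON barrier minus OFF barrier
    classification: str
    mean_distance: float | None = None  # Å, centroid-to-centroid, snapshot-averaged


@dataclass(frozen=True)
class ScanResult:
    """Scan output: the planned single-point job count and the result table."""

    planned_jobs: int
    table: pd.DataFrame


def classify_contribution(contribution: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    if contribution <= -threshold:
        return "catalytic"
    if contribution >= threshold:
        return "anticatalytic"
    return "negligible"


def _check_residue(snapshots: SnapshotEnsemble, residue_id: int) -> str:
    """Residue must appear in every snapshot; returns its name."""
    name = None
    for i, snap in enumerate(snapshots):
        mask = snap.environment.residue_ids == residue_id
        if not np.any(mask):
            raise ValueError(
                f"residue {residue_id} missing from snapshot {snap.label or i}"
            )
        if name is None:
            name = snap.environment.residue_names[int(np.nonzero(mask)[0][0])]
    return name or ""


def per_residue_contribution(
    snapshots: SnapshotEnsemble,
    residue_id: int,
    backend: CoulombBackend,
    threshold: float = DEFAULT_THRESHOLD,
) -> ResidueContribution:
    """Barrier decomposition restricted to one residue's charges."""
    name = _check_residue(snapshots, residue_id)
    dec = decompose_barrier(snapshots, backend, selector=[residue_id])
    return ResidueContribution(
        residue_id=int(residue_id),
        residue_name=name,
        contribution=dec.catalytic_effect,
        classification=classify_contribution(dec.catalytic_effect, threshold),
        mean_distance=residue_moiety_distance(snapshots, residue_id),
    )


def count_scan_jobs(n_residues: int, n_snapshots: int, n_variants: int) -> int:
    """Single-point evaluations a full scan enumerates (product rule)."""
    return int(n_residues) * int(n_snapshots) * int(n_variants)


def _consistent_residues(snapshots: SnapshotEnsemble, variant: str) -> np.ndarray:
    ids = None
    for i, snap in enumerate(snapshots):
        cur = snap.residue_ids
        if ids is None:
            ids = cur
        elif not np.array_equal(ids, cur):
            raise ValueError(
                f"inconsistent residue numbering in variant {variant!r}: "
                f"snapshot {snap.label or i} disagrees with the first snapshot"
            )
    if ids is None or ids.size == 0:
        raise ValueError(f"variant {variant!r} has no environment residues")
    return ids


def scan_all(
    variants: Mapping[str, SnapshotEnsemble],
    backend: CoulombBackend,
    threshold: float = DEFAULT_THRESHOLD,
) -> ScanResult:
    """Per-residue contribution scan over residues x snapshots x variants.

    The planned single-point job count is computed and logged before any
    evaluation runs; results are keyed by (variant, residue).
    """
    residue_sets = {v: _consistent_residues(ens, v) for v, ens in variants.items()}
    planned = sum(len(residue_sets[v]) * len(variants[v]) for v in variants)
    logger.info(
        "residue scan planned: %d single-point jobs over %d variant(s)",
        planned,
        len(variants),
    )

    rows = []
    for variant, ens in variants.items():
        for rid in residue_sets[variant]:
            rc = per_residue_contribution(ens, int(rid), backend, threshold)
            rows.append(
                {
                    "variant": variant,
                    "residue_id": rc.residue_id,
                    "residue_name": rc.residue_name,
                    "contribution": rc.contribution,
                    "classification": rc.classification,
                    "mean_distance": rc.mean_distance,
                }
            )
    table = pd.DataFrame(rows).sort_values(["variant", "residue_id"]).reset_index(drop=True)
    return ScanResult(planned_jobs=planned, table=table)


def residue_moiety_distance(
    snapshots: SnapshotEnsemble,
    residue_id: int,
    state: str | None = None,
) -> float:
    """Mean centroid distance (Å) between the moiety and one residue.

    Per snapshot, the unweighted centroid over all moiety atoms and over all
    atoms of the residue (hydrogens included, no mass weighting) are taken
    and their Euclidean distance computed; the result is the arithmetic
    mean over the combined R+TS ensemble, or over one state if requested.
    """
    members = list(snapshots) if state is None else snapshots.by_state(state)
    if not members:
        raise ValueError("no snapshots to average over")
    dists = []
    for i, snap in enumerate(members):
        mask = snap.environment.residue_ids == residue_id
        if not np.any(mask):
            raise ValueError(f"residue {residue_id} missing from snapshot {snap.label or i}")
        c_moiety = snap.moiety.positions.mean(axis=0)
        c_res = snap.environment.positions[mask].mean(axis=0)
        dists.append(float(np.linalg.norm(c_moiety - c_res)))
    return float(np.mean(dists))


def differential_profile(variant: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Residue-by-residue (variant - reference) contribution and distance changes.

    Both inputs are single-variant tables as produced by :func:`scan_all`.
    Only residues present in both variants enter the profile; fully
    disjoint residue sets raise an error.
    """
    merged = variant.merge(
        reference,
        on="residue_id",
        suffixes=("", "_ref"),
        how="inner",
    )
    if merged.empty:
        raise ValueError("variant and reference share no residues")
    out = merged[["residue_id", "residue_name", "contribution", "mean_distance"]].copy()
    out["d_contribution"] = merged["contribution"] - merged["contribution_ref"]
    out["d_distance"] = merged["mean_distance"] - merged["mean_distance_ref"]
    return out.sort_values("residue_id").reset_index(drop=True)


def sequence_domains(
    differential: pd.DataFrame,
    threshold: float = 0.25,
) -> list[tuple[int, int]]:
    """Contiguous residue runs whose |contribution change| reaches `threshold`.

    A descriptive convenience for highlighting sequence regions perturbed by
    a mutation; returns inclusive (first_id, last_id) pairs.
    """
    hot = differential.loc[
        differential["d_contribution"].abs() >= threshold, "residue_id"
    ].sort_values()
    runs: list[tuple[int, int]] = []
    for rid in hot:
        if runs and rid == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], int(rid))
        else:
            runs.append((int(rid), int(rid)))
    return runs


def plot_differential_profile(differential: pd.DataFrame, path: str) -> None:
    """Two-panel figure: contribution change and distance change vs residue id."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(8, 5))
    ax1.plot(differential["residue_id"], differential["d_contribution"], "o-", ms=3, color="tab:blue")
    ax1.axhline(0.0, color="k", lw=0.5)
    ax1.set_ylabel("Δ contribution (kcal/mol)")
    ax2.plot(differential["residue_id"], differential["d_distance"], "o-", ms=3, color="tab:red")
    ax2.axhline(0.0, color="k", lw=0.5)
    ax2.set_ylabel("Δ distance (Å)")
    ax2.set_xlabel("residue id")
    for lo, hi in sequence_domains(differential):
        ax1.axvspan(lo - 0.5, hi + 0.5, color="0.85", zorder=0)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
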