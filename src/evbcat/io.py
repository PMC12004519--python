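"""Readers and writers for the on-disk interchange formats.

* Window logs: TSV with a ``# lambda=<value>`` header line and columns
  ``frame  eps1  eps2  eps_map`` (kcal/mol); one file per window, one
  directory per replica.
* Structures: fixed-column PDB, one file per snapshot, with the reacting
  moiety identified by residue name (default SRO and LFN).  Charges come
  from a companion TSV table ``residue_id  residue_name  atom_name
  charge_e``; PQR input (charges embedded) is also accepted.
* Profiles and result tables: CSV with unit-bearing headers.
* Run configuration: a YAML file whose defaults reproduce the production
  settings (51 windows at a 0.02 lambda step, H12 = 44.28 and gas shift
  103.94 kcal/mol, 300 K, 100+100 snapshots, 0.1 kcal/mol classification
  threshold).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.PDB import PDBParser
from Bio.PDB.StructureBuilder import StructureBuilder
from Bio.PDB.PDBIO import PDBIO

from .embedding import AtomTable, Snapshot, SnapshotEnsemble
from .evb_core import FreeEnergyProfile, MappingSchedule, WindowLog

__all__ = [
    "write_window_log",
    "read_window_log",
    "write_window_dir",
    "read_window_dir",
    "write_profile_csv",
    "read_profile_csv",
    "write_snapshot_pdb",
    "write_charge_table",
    "read_charge_table",
    "read_pdb_snapshot",
    "read_pqr_snapshot",
    "write_snapshot_set",
    "read_snapshot_set",
    "RunConfig",
]

DEFAULT_MOIETY_NAMES = ("SRO", "LFN")


# --------------------------------------------------------------------------
# Window logs
# --------------------------------------------------------------------------


def write_window_log(log: WindowLog, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# lambda={log.lam:.10g}\n")
        fh.write("frame\teps1\teps2\teps_map\n")
        for i in range(log.n_frames):
            fh.write(
                f"{i}\t{log.eps1[i]:.10g}\t{log.eps2[i]:.10g}\t{log.eps_map[i]:.10g}\n"
            )


def read_window_log(path: str | Path) -> WindowLog:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
    if not first.startswith("#") or "lambda=" not in first:
        raise ValueError(f"{path}: missing '# lambda=<value>' header line")
    lam = float(first.split("lambda=")[1])
    df = pd.read_csv(path, sep="\t", comment="#")
    return WindowLog(
        lam=lam,
        eps1=df["eps1"].to_numpy(),
        eps2=df["eps2"].to_numpy(),
        eps_map=df["eps_map"].to_numpy(),
    )


def write_window_dir(logs: list[WindowLog], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, log in enumerate(logs):
        write_window_log(log, directory / f"window_{i:03d}.tsv")


def read_window_dir(directory: str | Path) -> list[WindowLog]:
    directory = Path(directory)
    files = sorted(directory.glob("window_*.tsv"))
    if not files:
        raise FileNotFoundError(f"no window_*.tsv files in {directory}")
    logs = [read_window_log(f) for f in files]
    return sorted(logs, key=lambda w: w.lam)


# --------------------------------------------------------------------------
# Profiles
# --------------------------------------------------------------------------


def write_profile_csv(profile: FreeEnergyProfile, path: str | Path) -> None:
    df = profile.to_frame()
    df.columns = ["bin_center_kcal_mol", "free_energy_kcal_mol", "count"]
    df.to_csv(path, index=False, float_format="%.10g")


def read_profile_csv(path: str | Path) -> FreeEnergyProfile:
    df = pd.read_csv(path)
    return FreeEnergyProfile(
        bin_centers=df.iloc[:, 0].to_numpy(),
        free_energy=df.iloc[:, 1].to_numpy(),
        bin_counts=df.iloc[:, 2].to_numpy(),
    )


# --------------------------------------------------------------------------
# Structures and charges
# --------------------------------------------------------------------------


def _snapshot_atoms(snapshot: Snapshot):
    """Yield (table, index) over moiety then environment atoms."""
    for table in (snapshot.moiety, snapshot.environment):
        for i in range(table.n_atoms):
            yield table, i


def write_snapshot_pdb(snapshot: Snapshot, path: str | Path) -> None:
    """Write moiety + environment as a fixed-column PDB file."""
    builder = StructureBuilder()
    builder.init_structure("S")
    builder.init_model(0)
    builder.init_chain("A")
    builder.init_seg("    ")
    serial = 1
    current_res = None
    for table, i in _snapshot_atoms(snapshot):
        key = (int(table.residue_ids[i]), table.residue_names[i])
        if key != current_res:
            builder.init_residue(table.residue_names[i], " ", int(table.residue_ids[i]), " ")
            current_res = key
        name = table.atom_names[i]
        builder.init_atom(
            name,
            np.asarray(table.positions[i], dtype=float),
            0.0,
            1.0,
            " ",
            name.ljust(4) if len(name) < 4 else name,
            serial,
            element=table.elements[i],
        )
        serial += 1
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


def write_charge_table(snapshot: Snapshot, path: str | Path) -> None:
    """TSV charge table covering every atom of the snapshot."""
    rows = []
    for table, i in _snapshot_atoms(snapshot):
        rows.append(
            {
                "residue_id": int(table.residue_ids[i]),
                "residue_name": table.residue_names[i],
                "atom_name": table.atom_names[i],
                "charge_e": table.charges[i],
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_charge_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"residue_id", "residue_name", "atom_name", "charge_e"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: charge table must have columns {sorted(required)}")
    return df


def _validate_pdb_records(path: Path) -> None:
    """Light pre-scan so a malformed ATOM record fails with its line number."""
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                    int(line[22:26])
                except (ValueError, IndexError) as exc:
                    raise ValueError(
                        f"{path}: malformed ATOM record at line {lineno}: {exc}"
                    ) from exc


def read_pdb_snapshot(
    path: str | Path,
    charge_table: str | Path | pd.DataFrame,
    state_label: str,
    moiety_names: tuple[str, ...] = DEFAULT_MOIETY_NAMES,
    label: str = "",
) -> Snapshot:
    """Parse a PDB snapshot and attach charges from a companion table.

    Atoms are partitioned into moiety vs environment by residue name.
    Every atom must have a charge entry keyed (residue_id, atom_name), and
    every charge-table entry must match a PDB atom; either mismatch raises
    an error naming the offending atom.
    """
    path = Path(path)
    _validate_pdb_records(path)
    if not isinstance(charge_table, pd.DataFrame):
        charge_table = read_charge_table(charge_table)
    charges = {
        (int(r.residue_id), str(r.atom_name)): float(r.charge_e)
        for r in charge_table.itertuples()
    }
    structure = PDBParser(QUIET=True).get_structure("S", str(path))
    seen = set()
    moiety_cols = {k: [] for k in ("pos", "q", "rid", "rname", "aname", "elem")}
    env_cols = {k: [] for k in ("pos", "q", "rid", "rname", "aname", "elem")}
    for residue in structure.get_residues():
        resid = residue.get_id()[1]
        resname = residue.get_resname().strip()
        cols = moiety_cols if resname in moiety_names else env_cols
        for atom in residue.get_atoms():
            key = (int(resid), atom.get_name())
            if key not in charges:
                raise ValueError(
                    f"{path}: no charge for atom {atom.get_name()} of residue "
                    f"{resname} {resid}"
                )
            seen.add(key)
            cols["pos"].append(atom.get_coord())
            cols["q"].append(charges[key])
            cols["rid"].append(int(resid))
            cols["rname"].append(resname)
            cols["aname"].append(atom.get_name())
            cols["elem"].append(atom.element or "")
    missing = set(charges) - seen
    if missing:
        rid, aname = sorted(missing)[0]
        raise ValueError(
            f"{path}: charge table atom {aname} of residue {rid} is absent from the PDB"
        )
    if not moiety_cols["pos"]:
        raise ValueError(
            f"{path}: no moiety residues found (expected residue names {moiety_names})"
        )

    def _table(cols) -> AtomTable:
        if not cols["pos"]:
            return AtomTable.empty()
        return AtomTable(
            positions=np.array(cols["pos"], dtype=float),
            charges=np.array(cols["q"], dtype=float),
            residue_ids=np.array(cols["rid"], dtype=int),
            residue_names=tuple(cols["rname"]),
            atom_names=tuple(cols["aname"]),
            elements=tuple(cols["elem"]),
        )

    return Snapshot(
        state_label=state_label,
        moiety=_table(moiety_cols),
        environment=_table(env_cols),
        label=label or path.stem,
    )


def read_pqr_snapshot(
    path: str | Path,
    state_label: str,
    moiety_names: tuple[str, ...] = DEFAULT_MOIETY_NAMES,
    label: str = "",
) -> Snapshot:
    """Parse a whitespace-delimited PQR file (charges embedded, radii ignored)."""
    path = Path(path)
    moiety_cols = {k: [] for k in ("pos", "q", "rid", "rname", "aname", "elem")}
    env_cols = {k: [] for k in ("pos", "q", "rid", "rname", "aname", "elem")}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            parts = line.split()
            try:
                aname, rname, rid = parts[2], parts[3], int(parts[4])
                x, y, z, q = (float(v) for v in parts[5:9])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed PQR record at line {lineno}") from exc
            cols = moiety_cols if rname in moiety_names else env_cols
            cols["pos"].append((x, y, z))
            cols["q"].append(q)
            cols["rid"].append(rid)
            cols["rname"].append(rname)
            cols["aname"].append(aname)
            cols["elem"].append(aname[0])
    if not moiety_cols["pos"]:
        raise ValueError(
            f"{path}: no moiety residues found (expected residue names {moiety_names})"
        )

    def _table(cols) -> AtomTable:
        if not cols["pos"]:
            return AtomTable.empty()
        return AtomTable(
            positions=np.array(cols["pos"], dtype=float),
            charges=np.array(cols["q"], dtype=float),
            residue_ids=np.array(cols["rid"], dtype=int),
            residue_names=tuple(cols["rname"]),
            atom_names=tuple(cols["aname"]),
            elements=tuple(cols["elem"]),
        )

    return Snapshot(
        state_label=state_label,
        moiety=_table(moiety_cols),
        environment=_table(env_cols),
        label=label or path.stem,
    )


def write_snapshot_set(ensemble: SnapshotEnsemble, directory: str | Path) -> None:
    """One PDB per snapshot plus one charge table per state."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written_states = set()
    counters: dict[str, int] = {}
    for snap in ensemble:
        i = counters.get(snap.state_label, 0)
        counters[snap.state_label] = i + 1
        write_snapshot_pdb(snap, directory / f"{snap.state_label}_{i:04d}.pdb")
        if snap.state_label not in written_states:
            write_charge_table(snap, directory / f"charges_{snap.state_label}.tsv")
            written_states.add(snap.state_label)


def read_snapshot_set(
    directory: str | Path,
    moiety_names: tuple[str, ...] = DEFAULT_MOIETY_NAMES,
) -> SnapshotEnsemble:
    directory = Path(directory)
    snaps = []
    for state in ("R", "TS"):
        table_path = directory / f"charges_{state}.tsv"
        pdbs = sorted(directory.glob(f"{state}_*.pdb"))
        if not pdbs:
            continue
        table = read_charge_table(table_path)
        for p in pdbs:
            snaps.append(
                read_pdb_snapshot(p, table, state_label=state, moiety_names=moiety_names)
            )
    if not snaps:
        raise FileNotFoundError(f"no R_*.pdb or TS_*.pdb snapshots in {directory}")
    return SnapshotEnsemble(snaps)


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated pipeline configuration; defaults match the production setup."""

    temperature: float = 300.0
    off_diagonal: float = 44.28
    gas_shift: float = 103.94
    n_windows: int = 51
    frames_per_window: int = 2000
    n_replicas: int = 4
    n_bins: int = 50
    min_count: int = 10
    # The toy diabats carry their own, much smaller coupling: the production
    # off-diagonal element is calibrated for the enzyme's diabatic surfaces
    # and would erase the toy system's 16 kcal/mol reorganization barrier.
    toy: dict = field(
        default_factory=lambda: {
            "force_constant": 2.0, "q1": 0.0, "q2": 4.0, "dg0": 0.0, "h12": 1.0,
        }
    )
    toy_variants: list = field(
        default_factory=lambda: [{"name": "MUT", "dg0": 8.0}]
    )
    n_residues: int = 20
    atoms_per_residue: int = 4
    planted_effect: float = -14.4
    negligible_fraction: float = 0.6
    n_reactant_snapshots: int = 100
    n_transition_snapshots: int = 100
    thermal_jitter: float = 0.1
    mutants: list = field(
        default_factory=lambda: [
            {"name": "MUT", "residue_id": 7, "charge_scale": -1.0, "jitter": 0.2}
        ]
    )
    threshold: float = 0.1
    moiety_names: tuple[str, ...] = DEFAULT_MOIETY_NAMES
    seed: int = 1

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_windows < 2:
            raise ValueError("need at least two lambda windows")
        for f in ("frames_per_window", "n_replicas", "n_bins", "min_count",
                  "n_residues", "atoms_per_residue",
                  "n_reactant_snapshots", "n_transition_snapshots"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")
        if self.threshold <= 0:
            raise ValueError("classification threshold must be positive")
        self.moiety_names = tuple(self.moiety_names)

    def schedule(self) -> MappingSchedule:
        return MappingSchedule.uniform(self.n_windows, self.frames_per_window)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["moiety_names"] = list(self.moiety_names)
        return data

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
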