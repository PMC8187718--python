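"""Domain–domain communication scan: contacts, salt bridges, pair energies.

A contact scan filters residue pairs across two groups by trajectory-mean
minimum heavy-atom distance; candidate charged pairs are classified as
salt bridges (charged-group distance ≤ 4 Å); pairwise interaction energies
are screened Coulomb (constant dielectric, default ε = 20 for charged
surface residues) plus Lennard-Jones with Lorentz–Berthelot combining.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .geometry import CHARGED_GROUP_ATOMS, min_residue_distance
from .stats import replica_aggregate
from .structure_io import Structure, Trajectory

__all__ = ["ParameterTable", "InteractionProfile", "load_default_parameters",
           "contact_scan", "salt_bridge_classify", "salt_bridge_occupancy",
           "interaction_energy", "interaction_energy_series", "pair_profile",
           "compare_pair_profiles", "SALT_BRIDGE_CUTOFF", "COULOMB_CONSTANT"]

#: kJ·mol⁻¹·nm·e⁻², the electric conversion factor of molecular mechanics.
COULOMB_CONSTANT = 138.935

#: Å; charged-group pairs at or below this distance count as salt-bridged.
SALT_BRIDGE_CUTOFF = 4.0

ACIDIC = {"ASP", "GLU"}
BASIC = {"ARG", "LYS", "HIS"}

BACKBONE_ATOMS = {"N", "CA", "C", "O"}


class ParameterTable:
    """Per (residue_name, atom_name) partial charges and LJ parameters.

    Plain-text format: whitespace-separated columns
    ``residue atom charge sigma epsilon`` (e, Å, kJ/mol); ``#`` comments.
    A ``*`` residue row parameterises backbone atoms of any residue.
    Missing atoms fail loudly rather than defaulting to zero.
    """

    def __init__(self, entries: dict[tuple[str, str], tuple[float, float, float]]):
        self.entries = dict(entries)

    @classmethod
    def from_file(cls, path: str | Path) -> "ParameterTable":
        entries: dict[tuple[str, str], tuple[float, float, float]] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            res, atom, q, sig, eps = parts
            entries[(res.upper(), atom.upper())] = (float(q), float(sig), float(eps))
        return cls(entries)

    def lookup(self, residue_name: str, atom_name: str) -> tuple[float, float, float]:
        key = (residue_name.upper(), atom_name.upper())
        if key in self.entries:
            return self.entries[key]
        fallback = ("*", atom_name.upper())
        if fallback in self.entries:
            return self.entries[fallback]
        raise KeyError(f"atom {atom_name} of residue {residue_name} is not parameterised")

    def side_chain_charge(self, residue_name: str) -> float:
        """Net charge of the residue's parameterised side-chain atoms."""
        total = 0.0
        for (res, atom), (q, _, _) in self.entries.items():
            if res == residue_name.upper() and atom not in BACKBONE_ATOMS:
                total += q
        return total


def load_default_parameters() -> ParameterTable:
    """The bundled minimal table (backbone + Arg/Lys/His⁺/Asp/Glu side chains)."""
    with resources.as_file(resources.files("allotrace.data") / "charges.dat") as p:
        return ParameterTable.from_file(p)


@dataclass
class InteractionProfile:
    """Distance/energy time series and replica summaries for one residue pair."""

    pair: tuple[int, int]
    distance_series: list[np.ndarray]  # one array per replica, Å
    energy_series: list[np.ndarray]  # one array per replica, kJ/mol
    occupancy: float  # pooled salt-bridge occupancy over all replicas
    mean_distance: float
    sd_distance: float | None
    mean_energy: float
    sd_energy: float | None
    bonded: bool  # occupancy ≥ 0.1 (documented threshold)


def contact_scan(
    traj: Trajectory,
    group_A: list[int],
    group_B: list[int],
    mean_cutoff: float = 3.0,
) -> list[tuple[int, int, float]]:
    """Residue pairs (a, b, mean distance) with trajectory-mean minimum
    heavy-atom distance below ``mean_cutoff`` Å, sorted ascending.

    Groups are residue-id lists; they must be non-empty and disjoint.
    """
    if not group_A or not group_B:
        raise ValueError("contact groups must be non-empty")
    if set(group_A) & set(group_B):
        raise ValueError("contact groups must be disjoint")
    out: list[tuple[int, int, float]] = []
    for a in group_A:
        for b in group_B:
            dists = [
                min_residue_distance(traj.frames[f], traj.topology, a, b, "heavy")
                for f in range(traj.n_frames)
            ]
            mean = float(np.mean(dists))
            if mean < mean_cutoff:
                out.append((a, b, mean))
    out.sort(key=lambda t: t[2])
    return out


def _check_ionizable_pair(resname_A: str, resname_B: str) -> None:
    a, b = resname_A.upper(), resname_B.upper()
    if not ((a in ACIDIC and b in BASIC) or (a in BASIC and b in ACIDIC)):
        raise ValueError(
            f"{resname_A}–{resname_B} is not an acidic/basic pair; no salt bridge possible"
        )


def salt_bridge_classify(distance: float, resname_A: str, resname_B: str) -> bool:
    """True when an acid/base charged-group distance is ≤ 4.0 Å (inclusive)."""
    _check_ionizable_pair(resname_A, resname_B)
    return bool(distance <= SALT_BRIDGE_CUTOFF)


def salt_bridge_occupancy(distances, resname_A: str, resname_B: str) -> float:
    """Fraction of frames whose charged-group distance qualifies as bridged."""
    _check_ionizable_pair(resname_A, resname_B)
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance series")
    return float((d <= SALT_BRIDGE_CUTOFF).mean())


def interaction_energy(
    frame: np.ndarray,
    topology: Structure,
    residue_A: int,
    residue_B: int,
    table: ParameterTable | None = None,
    dielectric: float = 20.0,
    include_lj: bool = True,
) -> float:
    """Screened Coulomb + LJ interaction energy (kJ/mol) between two residues.

    ``E = Σ_ij [ f·q_i·q_j / (ε·r_ij) + 4ε_ij((σ_ij/r_ij)¹² − (σ_ij/r_ij)⁶) ]``
    with f = 138.935 kJ·mol⁻¹·nm·e⁻² and Lorentz–Berthelot combining.
    Distances below 0.5 Å abort (clash guard); unparameterised atoms raise.
    """
    if table is None:
        table = load_default_parameters()
    if dielectric <= 0:
        raise ValueError("dielectric must be positive")

    def params(resid: int):
        idx = topology.residue_atom_indices(resid)
        if not idx:
            raise ValueError(f"residue {resid} not found in topology")
        rows = []
        for i in idx:
            a = topology.atoms[i]
            q, sig, eps = table.lookup(a.residue_name, a.name)
            rows.append((i, q, sig, eps))
        return rows

    pa, pb = params(residue_A), params(residue_B)
    energy = 0.0
    for i, qi, si, ei in pa:
        for j, qj, sj, ej in pb:
            r = float(np.linalg.norm(frame[i] - frame[j]))
            if r < 0.5:
                raise ValueError(
                    f"atoms {topology.atoms[i].name}/{topology.atoms[j].name} at {r:.2f} Å: clash"
                )
            energy += COULOMB_CONSTANT * qi * qj / (dielectric * (r / 10.0))
            if include_lj:
                sij = 0.5 * (si + sj)
                eij = np.sqrt(ei * ej)
                sr6 = (sij / r) ** 6
                energy += 4.0 * eij * (sr6 * sr6 - sr6)
    return float(energy)


def interaction_energy_series(
    traj: Trajectory, residue_A: int, residue_B: int,
    table: ParameterTable | None = None, dielectric: float = 20.0,
) -> np.ndarray:
    if table is None:
        table = load_default_parameters()
    return np.array([
        interaction_energy(traj.frames[f], traj.topology, residue_A, residue_B, table, dielectric)
        for f in range(traj.n_frames)
    ])


def pair_profile(
    trajs: list[Trajectory],
    pair: tuple[int, int],
    table: ParameterTable | None = None,
    dielectric: float = 20.0,
    bond_threshold: float = 0.1,
) -> InteractionProfile:
    """Distance/energy profile of one charged pair over replicas of a condition.

    Distances are minimum charged-group heavy-atom distances; "no bond" is
    reported when pooled bridge occupancy falls below ``bond_threshold``.
    """
    if not trajs:
        raise ValueError("at least one replica trajectory required")
    if table is None:
        table = load_default_parameters()
    ra, rb = pair
    top = trajs[0].topology

    def resname(resid: int) -> str:
        idx = top.residue_atom_indices(resid)
        if not idx:
            raise ValueError(f"residue {resid} not found in topology")
        return top.atoms[idx[0]].residue_name

    name_a, name_b = resname(ra), resname(rb)
    _check_ionizable_pair(name_a, name_b)
    dist_series: list[np.ndarray] = []
    energy_series: list[np.ndarray] = []
    for t in trajs:
        d = np.array([
            min_residue_distance(t.frames[f], t.topology, ra, rb, "charged-group")
            for f in range(t.n_frames)
        ])
        dist_series.append(d)
        energy_series.append(interaction_energy_series(t, ra, rb, table, dielectric))
    pooled = np.concatenate(dist_series)
    occupancy = float((pooled <= SALT_BRIDGE_CUTOFF).mean())
    mean_d, sd_d = replica_aggregate(dist_series)
    mean_e, sd_e = replica_aggregate(energy_series)
    return InteractionProfile(
        pair=(ra, rb), distance_series=dist_series, energy_series=energy_series,
        occupancy=occupancy, mean_distance=mean_d, sd_distance=sd_d,
        mean_energy=mean_e, sd_energy=sd_e, bonded=occupancy >= bond_threshold,
    )


def compare_pair_profiles(
    trajs_A: list[Trajectory], trajs_B: list[Trajectory], pair: tuple[int, int],
    table: ParameterTable | None = None, dielectric: float = 20.0,
) -> dict[str, InteractionProfile]:
    """Condition-A vs condition-B profile of the same pair (e.g. WT vs mutant)."""
    if table is None:
        table = load_default_parameters()
    return {
        "A": pair_profile(trajs_A, pair, table, dielectric),
        "B": pair_profile(trajs_B, pair, table, dielectric),
    }
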