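"""Synthetic multi-helix trajectories with planted, recorded ground truth.

The toy protein mimics the architecture the pipeline analyses: a long
transmembrane helix with a kink pivot and an acidic residue at its
cytoplasmic end ("helix 10"), a loop and a second helix forming an
interhelical opening angle ("helix 11"/ECL5), and a nucleotide-binding
block carrying a short helix with a His/Arg pair ("s5/h2"), another helix
("Walker A") and a two-strand antiparallel hairpin ("Q-loop"/"Walker B"
strands). Residue numbering follows the human MRP1 convention so the
analysis defaults (anchors 571/574/577, pivot 553, pair 521–1364/1367)
apply unchanged.

Every planted quantity — state schedule and occupancies, per-frame opening
and kink angles, collective-mode variance and displacement field, charged
pair distances, unwound segments — is returned in a :class:`GroundTruth`
that the analysis modules can be checked against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .structure_io import AtomRecord, Structure, Trajectory

__all__ = ["StateSpec", "SyntheticSpec", "GroundTruth", "SEGMENTS",
           "build_ideal_helix", "build_ideal_sheet", "generate_trajectory",
           "generate_replicas", "paper_scenario", "planted_label_maps"]

# ---------------------------------------------------------------------------
# Toy-protein layout (MRP1-style numbering)
# ---------------------------------------------------------------------------

SEGMENTS = {
    "helix10": (521, 571),
    "loop": (572, 576),
    "helix11": (577, 600),
    "walkerA": (1328, 1340),
    "s5h2": (1358, 1371),
    "qloop_strand": (1372, 1377),
    "walkerB_strand": (1451, 1456),
}

CHARGED_RESIDUES = {521: "GLU", 1364: "HIS", 1367: "ARG"}

SIDE_CHAIN_ATOMS = {
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
}

CHARGED_GROUP = {"GLU": ("OE1", "OE2"), "HIS": ("ND1", "NE2"), "ARG": ("NE", "NH1", "NH2")}

ANCHORS = (571, 574, 577)
KINK_PIVOT = 553

# backbone internal coordinates (Å / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8


# ---------------------------------------------------------------------------
# Internal-coordinate chain building (NeRF)
# ---------------------------------------------------------------------------

def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom d with |cd| = bond, ∠(b,c,d) = angle, τ(a,b,c,d) = torsion."""
    ang, tor = math.radians(angle_deg), math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        -bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(torsions: list[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    """Backbone N/CA/C/O per residue from (φ, ψ) lists; ω fixed trans."""
    n_res = len(torsions)
    if n_res < 1:
        raise ValueError("need at least one residue")
    res: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = res[i - 1]
        psi_prev = torsions[i - 1][1]
        n_i = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi_prev)
        ca_i = _place(prev["CA"], prev["C"], n_i, _B_N_CA, _A_C_N_CA, 180.0)
        phi_i = torsions[i][0]
        c_i = _place(prev["C"], n_i, ca_i, _B_CA_C, _A_N_CA_C, phi_i)
        res.append({"N": n_i, "CA": ca_i, "C": c_i})
    for i in range(n_res):
        psi = torsions[i][1]
        r = res[i]
        r["O"] = _place(r["N"], r["CA"], r["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
    return res


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = math.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(t) * k + (1 - math.cos(t)) * (k @ k)


def _residues_to_structure(
    residues: list[dict[str, np.ndarray]], first_id: int, resnames=None, chain: str = "A"
) -> Structure:
    atoms = []
    serial = 1
    for k, r in enumerate(residues):
        rid = first_id + k
        rname = (resnames or {}).get(rid, "GLY")
        for name in ("N", "CA", "C", "O"):
            el = name[0]
            atoms.append(AtomRecord(serial, name, rname, rid, chain, r[name], el))
            serial += 1
    return Structure(atoms)


def build_ideal_helix(n_res: int, phi: float = -57.0, psi: float = -47.0,
                      first_id: int = 1) -> Structure:
    """Backbone of an ideal helix (default α: φ = −57°, ψ = −47°).

    φ = ψ = 180° yields a fully extended chain. Rise ≈ 1.5 Å/residue and
    consecutive Cα distances ≈ 3.8 Å at α-helical torsions.
    """
    if n_res < 4:
        raise ValueError("an ideal helix needs at least 4 residues")
    residues = _build_backbone([(phi, psi)] * n_res)
    return Structure(_residues_to_structure(residues, first_id).atoms)


@lru_cache(maxsize=8)
def _sheet_offsets(n_res: int) -> tuple[float, float, int]:
    """Grid-searched placement (axial shift, separation, flip) maximising
    inter-strand backbone H-bonds for two antiparallel extended strands."""
    from .secondary_structure import _BackboneFrame, _hbond_matrix

    from .secondary_structure import HB_ENERGY_FACTOR

    def bond_depth(s) -> float:
        """Summed depth of inter-strand H-bond energies (lower = better)."""
        bb = _BackboneFrame(s.coordinates, s)
        total = 0.0
        for i in range(n_res):
            for j in range(n_res, 2 * n_res):
                for acc, don in ((i, j), (j, i)):
                    h = bb.residues[don]["H"]
                    if h is None:
                        continue
                    c, o = bb.residues[acc]["C"], bb.residues[acc]["O"]
                    nn = bb.residues[don]["N"]
                    r = (np.linalg.norm(o - nn), np.linalg.norm(c - h),
                         np.linalg.norm(o - h), np.linalg.norm(c - nn))
                    if min(r) < 0.5:
                        return np.inf
                    e = HB_ENERGY_FACTOR * (1 / r[0] + 1 / r[1] - 1 / r[2] - 1 / r[3])
                    total += min(0.0, e)
        return total

    best = (0.0, 4.8, 0)
    best_score = np.inf
    for flip in (0, 1):
        for dy in np.arange(3.8, 5.7, 0.1):
            for dx in np.arange(-3.6, 3.7, 0.15):
                score = bond_depth(_assemble_sheet(n_res, float(dx), float(dy), flip))
                if score < best_score:
                    best_score = score
                    best = (float(dx), float(dy), flip)
    return best


def _assemble_sheet(n_res: int, dx: float, dy: float, flip: int,
                    first_id_1: int = 1, first_id_2: int | None = None) -> Structure:
    if first_id_2 is None:
        first_id_2 = first_id_1 + n_res + 50  # numbering gap = chain break
    strand = _build_backbone([(-139.0, 135.0)] * n_res)
    rot = _rotation_about(np.array([0.0, 1.0, 0.0]), 180.0)
    if flip:
        rot = _rotation_about(np.array([1.0, 0.0, 0.0]), 180.0) @ rot
    centre = np.mean([r["CA"] for r in strand], axis=0)
    strand2 = [
        {k: rot @ (v - centre) + centre + np.array([dx, dy, 0.0]) for k, v in r.items()}
        for r in strand
    ]
    atoms = (
        _residues_to_structure(strand, first_id_1).atoms
        + _residues_to_structure(strand2, first_id_2).atoms
    )
    # renumber serials
    renum = [AtomRecord(i + 1, a.name, a.residue_name, a.residue_id, a.chain,
                        a.coordinates, a.element) for i, a in enumerate(atoms)]
    return Structure(renum)


def build_ideal_sheet(n_res: int = 6, first_id_1: int = 1, first_id_2: int | None = None) -> Structure:
    """Two-strand antiparallel β-sheet fixture (backbone only).

    The relative placement of the second strand is grid-searched once per
    strand length to maximise mutual inter-strand H-bonds, then cached;
    the result is deterministic.
    """
    dx, dy, flip = _sheet_offsets(n_res)
    return _assemble_sheet(n_res, dx, dy, flip, first_id_1, first_id_2)


# ---------------------------------------------------------------------------
# Specs and ground truth
# ---------------------------------------------------------------------------

@dataclass
class StateSpec:
    """One conformational state of the synthetic ensemble."""

    occupancy: float
    angle_mean: float = 85.4  # interhelical opening angle, degrees
    angle_sd: float = 0.0
    kink_mean: float = 0.0  # helix-10 kink at the pivot, degrees
    kink_sd: float = 0.0
    #: target min charged-group distance (Å) per planted pair
    bridge_distances: dict = field(default_factory=lambda: {"HIS": 2.4, "ARG": 3.2})


@dataclass
class SyntheticSpec:
    """Full recipe for one synthetic trajectory."""

    states: list = field(default_factory=lambda: [StateSpec(occupancy=1.0)])
    n_frames: int = 100
    seed: int = 0
    noise_sigma: float = 0.1  # Å, isotropic Gaussian on every atom
    mode_variance_nm2: float = 0.0  # planted mode-1 variance (Cα subspace)
    mode_profile: str = "gaussian"  # or "linear" (deterministic ramp)
    mode_region: str = "walkerA"
    mode_orthogonalize: bool = True
    #: (first_resid, last_resid, onset_frame) segments losing their structure
    unwound_segments: list = field(default_factory=list)
    mean_dwell: int = 20  # frames, geometric dwell blocks
    state_separation: float = 22.0  # Å, rigid NBD offset per state index
    # (superposition absorbs ~70% of a block offset into the global fit;
    # 22 Å leaves > 6 Å backbone RMSD between adjacent states, i.e. twice
    # the 3 Å clustering cutoff)

    def validate(self) -> None:
        occ = np.array([s.occupancy for s in self.states], dtype=float)
        if occ.size == 0 or abs(occ.sum() - 1.0) > 1e-9 or np.any(occ < 0):
            raise ValueError("state occupancies must be non-negative and sum to 1")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be ≥ 0")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.mode_profile not in ("gaussian", "linear"):
            raise ValueError("mode_profile must be 'gaussian' or 'linear'")


@dataclass
class GroundTruth:
    """Everything planted into one generated trajectory."""

    state_labels: np.ndarray  # (n_frames,), 0-based state index
    occupancies: np.ndarray  # planted fractions, exact over the schedule
    angle_targets: np.ndarray  # per-frame opening angle, degrees
    kink_targets: np.ndarray  # per-frame pivot kink, degrees
    mode_variance_nm2: float
    mode_amplitudes: np.ndarray  # realized amplitudes, Å
    mode_field_residue_ids: np.ndarray
    mode_field_vectors: np.ndarray  # (n_residues, 3) per-residue displacement field
    bridge_targets: dict  # pair name → per-frame target distance, Å
    bridged: dict  # pair name → per-frame bool at the 4 Å rule
    unwound_segments: list


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

def _seg_ids(name: str) -> list[int]:
    lo, hi = SEGMENTS[name]
    return list(range(lo, hi + 1))


_ALL_RESIDUE_IDS = (
    _seg_ids("helix10") + _seg_ids("loop") + _seg_ids("helix11")
    + _seg_ids("walkerA") + _seg_ids("s5h2") + _seg_ids("qloop_strand")
    + _seg_ids("walkerB_strand")
)

_NBD_SEGMENTS = ("walkerA", "s5h2", "qloop_strand", "walkerB_strand")

_HELIX_TORSION = (-57.0, -47.0)
_LOOP_TORSION = (-70.0, 140.0)
_STRAND_TORSION = (-139.0, 135.0)


def _coil_torsion(rng: np.random.Generator) -> tuple[float, float]:
    # irregular bridge region, clearly outside both the α basin (ψ ≈ −47°)
    # and the β basin (ψ ≈ +135°), so unwound residues keep neither helical
    # i→i+4 H-bonds nor inter-strand bridge geometry
    return (float(rng.uniform(-160.0, -100.0)), float(rng.uniform(-20.0, 60.0)))


def _state_schedule(spec: SyntheticSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Contiguous dwell blocks with *exact* per-state frame quotas."""
    occ = np.array([s.occupancy for s in spec.states], dtype=float)
    n = spec.n_frames
    quotas = np.floor(occ * n).astype(int)
    remainder = occ * n - quotas
    for k in np.argsort(-remainder)[: n - quotas.sum()]:
        quotas[k] += 1
    labels = np.empty(n, dtype=int)
    pos = 0
    prev = -1
    remaining = quotas.copy()
    while pos < n:
        avail = np.flatnonzero(remaining > 0)
        choices = avail[avail != prev] if avail.size > 1 else avail
        probs = remaining[choices] / remaining[choices].sum()
        s = int(rng.choice(choices, p=probs))
        dwell = int(min(1 + rng.geometric(1.0 / max(spec.mean_dwell, 1)), remaining[s]))
        labels[pos:pos + dwell] = s
        remaining[s] -= dwell
        pos += dwell
        prev = s
    return labels, quotas / n


def _torsions_for_frame(unwound_now: set[int], rng: np.random.Generator) -> dict[int, tuple[float, float]]:
    tor: dict[int, tuple[float, float]] = {}
    for name, (lo, hi) in SEGMENTS.items():
        base = _LOOP_TORSION if name == "loop" else (
            _STRAND_TORSION if name.endswith("strand") else _HELIX_TORSION
        )
        for rid in range(lo, hi + 1):
            tor[rid] = _coil_torsion(rng) if rid in unwound_now else base
    return tor


def _build_segment(ids: list[int], torsions: dict[int, tuple[float, float]]) -> list[dict]:
    return _build_backbone([torsions[r] for r in ids])


def _transform(residues: list[dict], rot: np.ndarray | None = None,
               shift: np.ndarray | None = None, about: np.ndarray | None = None) -> list[dict]:
    out = []
    for r in residues:
        d = {}
        for k, v in r.items():
            w = v.copy()
            if rot is not None:
                origin = about if about is not None else np.zeros(3)
                w = rot @ (w - origin) + origin
            if shift is not None:
                w = w + shift
            d[k] = w
        out.append(d)
    return out


def _orient_along_z(residues: list[dict]) -> list[dict]:
    """Rotate so the CA end-to-end direction is +z, first CA at the origin."""
    cas = np.array([r["CA"] for r in residues])
    axis = cas[-1] - cas[0]
    axis /= np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    if s < 1e-12:
        rot = np.eye(3)
    else:
        c = float(axis @ z)
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)
    out = _transform(residues, rot=rot, about=cas[0])
    return _transform(out, shift=-out[0]["CA"])


def _build_side_chain(backbone: dict, resname: str,
                      direction: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Simple geometric side chain extending from CA.

    By default it points away from the local backbone; pass ``direction``
    to aim the charged tip at an interaction partner (keeps the rod atoms
    behind the tip so planted tip–tip distances are the closest contacts).
    """
    n_at, ca, c = backbone["N"], backbone["CA"], backbone["C"]
    if direction is None:
        away = ca - 0.5 * (n_at + c)
    else:
        away = np.asarray(direction, dtype=float).copy()
    away /= np.linalg.norm(away)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(away @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    perp = np.cross(away, ref)
    perp /= np.linalg.norm(perp)
    # (along, perpendicular) local offsets from CA, Å — rough but
    # non-degenerate geometry with the charged tip farthest out
    layouts = {
        "GLU": [("CB", 1.5, 0.0), ("CG", 3.0, 0.0), ("CD", 4.3, 0.0),
                ("OE1", 5.3, 1.0), ("OE2", 5.3, -1.0)],
        "HIS": [("CB", 1.5, 0.0), ("CG", 2.9, 0.0), ("ND1", 3.9, 1.1),
                ("CD2", 3.9, -1.1), ("CE1", 4.7, 0.7), ("NE2", 5.9, 0.0)],
        "ARG": [("CB", 1.5, 0.0), ("CG", 3.0, 0.0), ("CD", 4.5, 0.0),
                ("NE", 5.8, 0.0), ("CZ", 7.0, 0.0),
                ("NH1", 7.8, 1.0), ("NH2", 7.8, -1.0)],
    }
    return {
        name: ca + away * along + perp * off
        for name, along, off in layouts[resname]
    }


def _min_group_distance(ga: np.ndarray, gb: np.ndarray) -> tuple[float, int, int]:
    d = np.linalg.norm(ga[:, None, :] - gb[None, :, :], axis=2)
    i, j = np.unravel_index(int(np.argmin(d)), d.shape)
    return float(d[i, j]), int(i), int(j)


def _adjust_side_chain(side: dict[str, np.ndarray], group_names, target: float,
                       acid_group: np.ndarray, axis: np.ndarray) -> dict[str, np.ndarray]:
    """Rigidly slide a side chain along its own rod ``axis`` until the
    min charged-group distance to the acid group equals ``target``.

    Scan-then-bisect: sliding toward the acid monotonically closes the gap
    until the groups pass each other, so the first sign change brackets the
    root robustly (a min-pair translation scheme oscillates when the
    closest atom pair switches).
    """
    axis = axis / np.linalg.norm(axis)
    gb0 = np.array([side[n] for n in group_names])

    def gap(t: float) -> float:
        d, _, _ = _min_group_distance(acid_group, gb0 + t * axis)
        return d - target

    d0, _, _ = _min_group_distance(acid_group, gb0)
    t_min = -(abs(target - d0) + 15.0)
    t_max = d0 + 15.0
    t_lo, g_lo = t_min, gap(t_min)
    t_hi = None
    t = t_lo
    while t < t_max:
        t += 0.5
        g = gap(t)
        if g < 0.0:
            t_hi = t
            break
        t_lo, g_lo = t, g
    if t_hi is None:
        # target unreachable along this axis: use the closest approach
        ts = np.arange(t_min, t_max, 0.25)
        t_best = float(ts[int(np.argmin([gap(x) for x in ts]))])
    else:
        for _ in range(60):
            mid = 0.5 * (t_lo + t_hi)
            if gap(mid) > 0.0:
                t_lo = mid
            else:
                t_hi = mid
        t_best = 0.5 * (t_lo + t_hi)
    return {k: v + t_best * axis for k, v in side.items()}


def _rigid_modes(points: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 6 rigid-body displacement modes (3n vectors)."""
    n = points.shape[0]
    centred = points - points.mean(axis=0)
    modes = []
    for ax in range(3):
        m = np.zeros((n, 3))
        m[:, ax] = 1.0
        modes.append(m.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        modes.append(np.cross(np.broadcast_to(e, (n, 3)), centred).ravel())
    basis = []
    for m in modes:
        for b in basis:
            m = m - (m @ b) * b
        norm = np.linalg.norm(m)
        if norm > 1e-10:
            basis.append(m / norm)
    return np.array(basis)


def generate_trajectory(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Emit a trajectory realising the spec, plus its full ground truth.

    Deterministic: the same spec (including seed) reproduces the output
    bit-for-bit.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_frames = spec.n_frames
    states = spec.states

    labels, occupancies = _state_schedule(spec, rng)
    angle_targets = np.array([
        states[s].angle_mean + (rng.normal(0.0, states[s].angle_sd) if states[s].angle_sd > 0 else 0.0)
        for s in labels
    ])
    kink_targets = np.array([
        states[s].kink_mean + (rng.normal(0.0, states[s].kink_sd) if states[s].kink_sd > 0 else 0.0)
        for s in labels
    ])

    pair_names = sorted({name for s in states for name in s.bridge_distances})
    bridge_targets = {
        p: np.array([states[s].bridge_distances.get(p, np.nan) for s in labels])
        for p in pair_names
    }

    # mode amplitudes (Å): variance of the planted collective coordinate
    v_a2 = spec.mode_variance_nm2 * 100.0
    if v_a2 > 0:
        if spec.mode_profile == "gaussian":
            amps = rng.normal(0.0, math.sqrt(v_a2), size=n_frames)
        else:
            half = math.sqrt(v_a2) * 0.5
            amps = np.linspace(-half, half, n_frames)
    else:
        amps = np.zeros(n_frames)

    # one reference geometry defines the mode field and residue order
    frames = np.empty((n_frames, len(_ALL_RESIDUE_IDS) * 4 + sum(
        len(SIDE_CHAIN_ATOMS[r]) for r in CHARGED_RESIDUES.values()), 3))

    mode_ids = np.array(_seg_ids(spec.mode_region))
    field_vectors = None
    topology: Structure | None = None

    for f in range(n_frames):
        s = labels[f]
        unwound_now = {
            rid
            for (lo, hi, onset) in spec.unwound_segments
            if f >= onset
            for rid in range(lo, hi + 1)
        }
        torsions = _torsions_for_frame(unwound_now, rng)

        # --- TMD assembly: helix10 + loop + helix11 built as one chain ---
        tmd_ids = _seg_ids("helix10") + _seg_ids("loop") + _seg_ids("helix11")
        tmd = _build_segment(tmd_ids, torsions)
        tmd = _orient_along_z(tmd)
        idx = {rid: k for k, rid in enumerate(tmd_ids)}

        # kink: rotate helix-10 residues past the pivot about the pivot CA
        kink = kink_targets[f]
        if abs(kink) > 1e-12:
            pivot_ca = tmd[idx[KINK_PIVOT]]["CA"]
            cas = np.array([tmd[idx[r]]["CA"] for r in range(521, KINK_PIVOT)])
            haxis = cas[-1] - cas[0]
            haxis /= np.linalg.norm(haxis)
            ref = np.array([1.0, 0.0, 0.0])
            kaxis = np.cross(haxis, ref)
            kaxis /= np.linalg.norm(kaxis)
            rot = _rotation_about(kaxis, kink)
            lo, hi = KINK_PIVOT + 1, SEGMENTS["helix10"][1]
            for rid in range(lo, hi + 1):
                tmd[idx[rid]] = {k: rot @ (v - pivot_ca) + pivot_ca for k, v in tmd[idx[rid]].items()}

        # opening angle: rotate everything past the loop anchor so that the
        # anchor construction hits the per-frame target exactly
        a = tmd[idx[ANCHORS[0]]]["CA"]
        b = tmd[idx[ANCHORS[1]]]["CA"]
        c = tmd[idx[ANCHORS[2]]]["CA"]
        v1, v2 = a - b, c - b
        cur = math.degrees(math.acos(np.clip(
            v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1)))
        naxis = np.cross(v1, v2)
        if np.linalg.norm(naxis) < 1e-9:
            naxis = np.cross(v1, np.array([0.0, 1.0, 0.0]))
        rot = _rotation_about(naxis, angle_targets[f] - cur)
        for rid in range(ANCHORS[1] + 1, SEGMENTS["helix11"][1] + 1):
            tmd[idx[rid]] = {k: rot @ (v - b) + b for k, v in tmd[idx[rid]].items()}

        # --- NBD block ---
        nbd: dict[int, dict[str, np.ndarray]] = {}
        wa = _orient_along_z(_build_segment(_seg_ids("walkerA"), torsions))
        wa = _transform(wa, rot=_rotation_about(np.array([0.0, 1.0, 0.0]), 90.0))
        wa = _transform(wa, shift=np.array([14.0, 12.0, -8.0]))
        for rid, r in zip(_seg_ids("walkerA"), wa):
            nbd[rid] = r
        sh = _orient_along_z(_build_segment(_seg_ids("s5h2"), torsions))
        sh = _transform(sh, rot=_rotation_about(np.array([0.0, 1.0, 0.0]), 90.0))
        # far enough that the acid tip never touches the s5/h2 backbone even
        # when unwinding lets the rebuilt segment wander; the basic side
        # chains slide to realise the planted pair distances
        sh = _transform(sh, shift=np.array([-6.0, 18.0, -6.0]))
        for rid, r in zip(_seg_ids("s5h2"), sh):
            nbd[rid] = r
        dx, dy, flip = _sheet_offsets(len(_seg_ids("qloop_strand")))
        q_ids, w_ids = _seg_ids("qloop_strand"), _seg_ids("walkerB_strand")
        s1 = _build_segment(q_ids, torsions)
        rot2 = _rotation_about(np.array([0.0, 1.0, 0.0]), 180.0)
        if flip:
            rot2 = _rotation_about(np.array([1.0, 0.0, 0.0]), 180.0) @ rot2
        centre = np.mean([r["CA"] for r in s1], axis=0)
        s2 = _build_segment(w_ids, torsions)
        s2 = [{k: rot2 @ (v - centre) + centre + np.array([dx, dy, 0.0]) for k, v in r.items()}
              for r in s2]
        hairpin = _transform(s1, shift=np.array([-16.0, 12.0, -10.0]))
        hairpin2 = _transform(s2, shift=np.array([-16.0, 12.0, -10.0]))
        for rid, r in zip(q_ids, hairpin):
            nbd[rid] = r
        for rid, r in zip(w_ids, hairpin2):
            nbd[rid] = r

        # per-state rigid NBD offset guarantees cluster separability
        offset = np.array([0.0, spec.state_separation * s, 0.0])
        for rid in nbd:
            nbd[rid] = {k: v + offset for k, v in nbd[rid].items()}

        backbone = {rid: tmd[idx[rid]] for rid in tmd_ids}
        backbone.update(nbd)

        # --- collective mode ---
        if field_vectors is None:
            # per-residue field, unit norm over CA components, rigid modes removed
            all_ids = np.array(_ALL_RESIDUE_IDS)
            raw = np.zeros((all_ids.size, 3))
            raw[np.isin(all_ids, mode_ids), 0] = 1.0
            if spec.mode_orthogonalize:
                cas = np.array([backbone[r]["CA"] for r in _ALL_RESIDUE_IDS])
                basis = _rigid_modes(cas)
                flat = raw.ravel()
                for bvec in basis:
                    flat = flat - (flat @ bvec) * bvec
                raw = flat.reshape(-1, 3)
            norm = np.linalg.norm(raw)
            if norm > 1e-12:
                raw /= norm
            field_vectors = raw
        if amps[f] != 0.0:
            for k, rid in enumerate(_ALL_RESIDUE_IDS):
                shift = amps[f] * field_vectors[k]
                backbone[rid] = {kk: vv + shift for kk, vv in backbone[rid].items()}

        # --- side chains + planted charged-pair distances ---
        side_chains: dict[int, dict[str, np.ndarray]] = {}
        # the acid side chain points toward the NBD block but well short of
        # the s5/h2 backbone; the basic side chains aim back at its tip, so
        # the planted tip-tip distances are the closest interatomic contacts
        acid_dir = np.array([0.0, 1.0, -1.0])
        side_chains[521] = _build_side_chain(backbone[521], "GLU", acid_dir)
        acid_group = np.array([side_chains[521][n] for n in CHARGED_GROUP["GLU"]])
        acid_tip = acid_group.mean(axis=0)
        basic_axes = {}
        for rid in (1364, 1367):
            basic_axes[rid] = acid_tip - backbone[rid]["CA"]
            side_chains[rid] = _build_side_chain(
                backbone[rid], CHARGED_RESIDUES[rid], basic_axes[rid])
        for p in pair_names:
            rid = 1364 if p == "HIS" else 1367
            rname = CHARGED_RESIDUES[rid]
            target = bridge_targets[p][f]
            if np.isfinite(target):
                side_chains[rid] = _adjust_side_chain(
                    side_chains[rid], CHARGED_GROUP[rname], float(target),
                    acid_group, basic_axes[rid])

        # --- flatten to the fixed atom order ---
        coords: list[np.ndarray] = []
        for rid in _ALL_RESIDUE_IDS:
            r = backbone[rid]
            for name in ("N", "CA", "C", "O"):
                coords.append(r[name])
            if rid in CHARGED_RESIDUES:
                for name in SIDE_CHAIN_ATOMS[CHARGED_RESIDUES[rid]]:
                    coords.append(side_chains[rid][name])
        frame = np.array(coords)
        if spec.noise_sigma > 0:
            frame = frame + rng.normal(0.0, spec.noise_sigma, size=frame.shape)
        frames[f] = frame

        if topology is None:
            atoms = []
            serial = 1
            k = 0
            for rid in _ALL_RESIDUE_IDS:
                rname = CHARGED_RESIDUES.get(rid, "GLY")
                names = ("N", "CA", "C", "O") + (
                    SIDE_CHAIN_ATOMS[rname] if rid in CHARGED_RESIDUES else ())
                for name in names:
                    el = name[0] if name[0] in ("N", "C", "O") else "C"
                    atoms.append(AtomRecord(serial, name, rname, rid, "A", frame[k], el))
                    serial += 1
                    k += 1
            topology = Structure(atoms)

    traj = Trajectory(topology, frames, frame_times=np.arange(n_frames, dtype=float))
    truth = GroundTruth(
        state_labels=labels,
        occupancies=occupancies,
        angle_targets=angle_targets,
        kink_targets=kink_targets,
        mode_variance_nm2=spec.mode_variance_nm2,
        mode_amplitudes=amps,
        mode_field_residue_ids=np.array(_ALL_RESIDUE_IDS),
        mode_field_vectors=field_vectors,
        bridge_targets=bridge_targets,
        bridged={p: bridge_targets[p] <= 4.0 for p in pair_names},
        unwound_segments=list(spec.unwound_segments),
    )
    return traj, truth


def generate_replicas(spec: SyntheticSpec, n_replicas: int = 3):
    """Independent replicas differing only in seed (seed, seed+1, …)."""
    out = []
    for r in range(n_replicas):
        import dataclasses
        rspec = dataclasses.replace(spec, seed=spec.seed + r)
        out.append(generate_trajectory(rspec))
    return out


# ---------------------------------------------------------------------------
# Bundled study-style scenarios
# ---------------------------------------------------------------------------

#: Mode-1 variances are the study's 116/161 nm² contrast scaled down 1000×
#: (desk-scale trajectories cannot carry nm²-hundreds of collective variance);
#: the ordering mutant > WT is what the scenario plants.
WT_MODE_VARIANCE_NM2 = 0.116
MUT_MODE_VARIANCE_NM2 = 0.161

MOTIFS = [
    ("walkerA", (1333, 1334)),
    ("s5h2", (1363, 1369)),
    ("qloop", (1372, 1374)),
    ("walkerB", (1453, 1454)),
]

#: Torsion windows the mutant scenario randomises so each motif unravels.
#: Helix motifs need upstream padding: the i→i+4 H-bonds that label a
#: residue helical are anchored up to four residues before it.
_UNWOUND_WINDOWS = [(1329, 1335), (1359, 1370), (1372, 1375), (1452, 1455)]


def paper_scenario(condition: str, seed: int = 0, n_frames: int = 100) -> tuple[Trajectory, GroundTruth]:
    """WT-style or mutant-style bundle mirroring the study's qualitative contrasts.

    WT: one dominant state (94% occupancy), open angle 85.4°, kink 19°,
    both charged pairs bridged. Mutant: four states (top 32%), closed angle
    82.2°, kink 11°, His pair broken (5.9 Å), four motif segments unwinding
    at 30% of the run. The numbers parameterise the generator; they are not
    claims about real MRP1.
    """
    if condition in ("wt", "WT"):
        spec = SyntheticSpec(
            states=[
                StateSpec(occupancy=0.94, angle_mean=85.4, angle_sd=2.0,
                          kink_mean=19.0, kink_sd=1.0,
                          bridge_distances={"HIS": 2.4, "ARG": 3.2}),
                StateSpec(occupancy=0.06, angle_mean=84.0, angle_sd=2.0,
                          kink_mean=17.0, kink_sd=1.0,
                          bridge_distances={"HIS": 2.6, "ARG": 3.4}),
            ],
            n_frames=n_frames, seed=seed, noise_sigma=0.15,
            mode_variance_nm2=WT_MODE_VARIANCE_NM2,
        )
    elif condition in ("mutant", "mut", "f583a", "F583A"):
        onset = int(0.3 * n_frames)
        spec = SyntheticSpec(
            states=[
                StateSpec(occupancy=0.32, angle_mean=82.2, angle_sd=2.0,
                          kink_mean=11.0, kink_sd=1.0,
                          bridge_distances={"HIS": 5.9, "ARG": 3.6}),
                StateSpec(occupancy=0.28, angle_mean=81.5, angle_sd=2.0,
                          kink_mean=12.0, kink_sd=1.0,
                          bridge_distances={"HIS": 5.5, "ARG": 3.7}),
                StateSpec(occupancy=0.22, angle_mean=83.0, angle_sd=2.0,
                          kink_mean=10.0, kink_sd=1.0,
                          bridge_distances={"HIS": 6.3, "ARG": 3.5}),
                StateSpec(occupancy=0.18, angle_mean=80.8, angle_sd=2.0,
                          kink_mean=13.0, kink_sd=1.0,
                          bridge_distances={"HIS": 6.0, "ARG": 3.8}),
            ],
            n_frames=n_frames, seed=seed, noise_sigma=0.15,
            mode_variance_nm2=MUT_MODE_VARIANCE_NM2,
            unwound_segments=[(lo, hi, onset) for lo, hi in _UNWOUND_WINDOWS],
        )
    else:
        raise ValueError(f"unknown condition '{condition}' (use wt|mutant)")
    return generate_trajectory(spec)


def planted_label_maps(
    n_frames: int = 50,
    helix_losses: int = 5,
    strand_losses: int = 1,
    turn_gains: int = 3,
) -> tuple:
    """A WT/mutant map pair with exact planted per-class residue-count deltas.

    Residues losing helix or strand class in the mutant convert to turns
    (up to ``turn_gains``) and otherwise to coil, so the deltas are exactly
    (−helix_losses H, −strand_losses E, +turn_gains T) with C balancing.
    """
    from .secondary_structure import SecondaryStructureMap

    rids = np.array(_ALL_RESIDUE_IDS)
    wt = np.full((rids.size, n_frames), "C", dtype="<U1")

    def block(name: str, label: str) -> None:
        lo, hi = SEGMENTS[name]
        wt[(rids >= lo + 1) & (rids <= hi - 1)] = label

    for name in ("helix10", "helix11", "walkerA", "s5h2"):
        block(name, "H")
    for name in ("qloop_strand", "walkerB_strand"):
        block(name, "E")

    mut = wt.copy()
    h_res = np.flatnonzero((wt[:, 0] == "H"))
    e_res = np.flatnonzero((wt[:, 0] == "E"))
    converted = 0
    for r in h_res[:helix_losses]:
        mut[r, :] = "T" if converted < turn_gains else "C"
        converted += 1
    for r in e_res[:strand_losses]:
        mut[r, :] = "T" if converted < turn_gains else "C"
        converted += 1
    map_wt = SecondaryStructureMap(labels=wt, residue_ids=rids)
    map_mut = SecondaryStructureMap(labels=mut, residue_ids=rids)
    return map_wt, map_mut
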