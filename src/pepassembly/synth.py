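"""Synthetic peptide conformations and multi-chain systems.

This module is the stand-in for molecular-dynamics snapshots: it builds
all-backbone-atom chains from internal coordinates (bond length, bond
angle, torsion — NeRF-style sequential placement), plants canonical
secondary-structure motifs, samples random-coil ensembles from Ramachandran
basins, and packs many chains into a box either dispersed (random
rigid-body placement with a minimum-distance constraint) or micellar
(hydrophobic Ala ends toward a common axis, Lys side chains outward).

Every generator is a pure function of its inputs and seed.  Side chains
are deliberately minimal: a Cβ on every non-Gly residue, plus the Lys
ammonium nitrogen as a pseudo-atom NZ on the Cα→Cβ direction — enough to
carry charges and radial (core/shell) analysis without a rotamer library.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import place_atom, random_rotation
from .model import Atom, Conformation, PeptideSystem, Residue
from .peptide import PeptideSpec

__all__ = [
    "DihedralSet",
    "GeometryParams",
    "MOTIFS",
    "COIL_BASINS",
    "build_chain",
    "make_motif",
    "sample_coil",
    "make_system",
    "PackingError",
]


class PackingError(RuntimeError):
    """Rigid-body placement exhausted its attempt budget."""


@dataclass
class DihedralSet:
    """Per-residue backbone torsions in degrees; NaN where undefined.

    ``phi[0]`` and ``omega[0]`` are undefined (no preceding peptide bond)
    and ``psi[-1]`` is undefined (no following amide nitrogen); ω is the
    torsion about the peptide bond *preceding* each residue.
    """

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        n = len(self.phi)
        if len(self.psi) != n or len(self.omega) != n:
            raise ValueError("phi, psi, omega must have equal length")
        for arr, name in ((self.phi, "phi"), (self.psi, "psi"), (self.omega, "omega")):
            defined = arr[~np.isnan(arr)]
            if np.any((defined <= -180.0) | (defined > 180.0)):
                raise ValueError(f"{name} angles must lie in (-180, 180]")

    def __len__(self) -> int:
        return len(self.phi)

    @classmethod
    def from_phi_psi(
        cls, phi_psi: list[tuple[float, float]], omega: float = 180.0
    ) -> "DihedralSet":
        """Build a set from per-residue (φ, ψ) pairs with uniform trans ω.

        Terminal entries that are geometrically absent are overwritten with
        NaN regardless of what the pairs say.
        """
        n = len(phi_psi)
        phi = np.array([p for p, _ in phi_psi], dtype=float)
        psi = np.array([s for _, s in phi_psi], dtype=float)
        om = np.full(n, float(omega))
        phi[0] = np.nan
        om[0] = np.nan
        psi[-1] = np.nan
        return cls(phi, psi, om)


@dataclass(frozen=True)
class GeometryParams:
    """Idealized backbone internal coordinates (Å, degrees)."""

    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329
    bond_c_o: float = 1.231
    bond_n_h: float = 1.01
    bond_ca_cb: float = 1.521
    dist_ca_nz: float = 4.9  # Lys pseudo-NZ along Cα→Cβ
    angle_n_ca_c: float = 111.2
    angle_ca_c_n: float = 116.2
    angle_c_n_ca: float = 121.7
    angle_ca_c_o: float = 120.8
    angle_c_ca_cb: float = 110.1
    # NeRF torsion N–C′–CA–CB giving L-chirality (improper N–CA–C–CB < 0)
    torsion_cb: float = 122.6
    omega_trans: float = 180.0


DEFAULT_GEOMETRY = GeometryParams()

#: Canonical (φ, ψ) templates.  Turn templates give residues i+1 and i+2 of
#: a four-residue window; whole-chain templates repeat one pair.
MOTIFS: dict[str, dict] = {
    "alpha_helix": {"kind": "uniform", "phi_psi": (-57.0, -47.0)},
    "extended": {"kind": "uniform", "phi_psi": (-139.0, 135.0)},
    "ppII": {"kind": "uniform", "phi_psi": (-75.0, 145.0)},
    "beta_turn_I": {"kind": "turn", "window": [(-60.0, -30.0), (-90.0, 0.0)]},
    "beta_turn_II": {"kind": "turn", "window": [(-60.0, 120.0), (80.0, 0.0)]},
}

#: Ramachandran basins for random-coil sampling: (φ range, ψ range).
COIL_BASINS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "beta": ((-180.0, -60.0), (60.0, 180.0)),
    "alphaR": ((-90.0, -40.0), (-60.0, -10.0)),
    "alphaL": ((40.0, 90.0), (10.0, 60.0)),
}

DEFAULT_BASIN_WEIGHTS = {"beta": 0.5, "alphaR": 0.4, "alphaL": 0.1}


def build_chain(
    peptide: PeptideSpec,
    dihedrals: DihedralSet,
    geom: GeometryParams = DEFAULT_GEOMETRY,
    chain_id: str = "A",
) -> Conformation:
    """Build backbone coordinates for one chain from its torsions.

    Atoms placed per residue: N, H (except residue 1 and Pro), CA, CB
    (except Gly), C, O; the C-terminal residue gains OXT when the C-terminus
    is free, and Lys gains the NZ pseudo-atom.  Placement is sequential
    NeRF construction, so measuring the dihedrals of the built chain
    reproduces the inputs to numerical precision.
    """
    n = len(peptide.sequence)
    if n < 2:
        raise ValueError("need at least 2 residues: no backbone dihedral is definable")
    if len(dihedrals) != n:
        raise ValueError(
            f"dihedral set length {len(dihedrals)} does not match sequence length {n}"
        )

    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))

    # first residue: N at origin, CA on +x, C in the xy-plane
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (geom.bond_n_ca, 0.0, 0.0)
    theta = np.radians(geom.angle_n_ca_c)
    C[0] = CA[0] + geom.bond_ca_c * np.array([-np.cos(theta), np.sin(theta), 0.0])

    for i in range(n - 1):
        psi = dihedrals.psi[i]
        if np.isnan(psi):
            raise ValueError(f"psi undefined for non-terminal residue {i + 1}")
        omega = dihedrals.omega[i + 1]
        phi = dihedrals.phi[i + 1]
        if np.isnan(omega) or np.isnan(phi):
            raise ValueError(f"phi/omega undefined for residue {i + 2}")
        N[i + 1] = place_atom(N[i], CA[i], C[i], geom.bond_c_n, geom.angle_ca_c_n, psi)
        CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], geom.bond_n_ca, geom.angle_c_n_ca, omega)
        C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], geom.bond_ca_c, geom.angle_n_ca_c, phi)

    residues: list[Residue] = []
    for i, letter in enumerate(peptide.sequence):
        atoms = [Atom("N", "N", N[i])]
        if i > 0 and letter != "P":
            # amide H in the C'(prev)–N–CA plane, bisecting, pointing outward
            u = C[i - 1] - N[i]
            v = CA[i] - N[i]
            h_dir = -(u / np.linalg.norm(u) + v / np.linalg.norm(v))
            h_dir /= np.linalg.norm(h_dir)
            atoms.append(Atom("H", "H", N[i] + geom.bond_n_h * h_dir))
        atoms.append(Atom("CA", "C", CA[i]))
        if letter != "G":
            cb = place_atom(
                N[i], C[i], CA[i], geom.bond_ca_cb, geom.angle_c_ca_cb, geom.torsion_cb
            )
            atoms.append(Atom("CB", "C", cb))
            if letter == "K":
                nz_dir = (cb - CA[i]) / np.linalg.norm(cb - CA[i])
                atoms.append(Atom("NZ", "N", CA[i] + geom.dist_ca_nz * nz_dir))
        atoms.append(Atom("C", "C", C[i]))
        if i < n - 1:
            o = place_atom(
                N[i], CA[i], C[i], geom.bond_c_o, geom.angle_ca_c_o,
                dihedrals.psi[i] + 180.0,
            )
            atoms.append(Atom("O", "O", o))
        else:
            # C-terminal carbonyl/carboxylate: torsion convention fixed so the
            # terminus is deterministic (ψ of the last residue is undefined)
            o = place_atom(N[i], CA[i], C[i], geom.bond_c_o, geom.angle_ca_c_o, 0.0)
            atoms.append(Atom("O", "O", o))
            if peptide.c_term_free:
                oxt = place_atom(
                    N[i], CA[i], C[i], geom.bond_c_o + 0.04, 117.0, 180.0
                )
                atoms.append(Atom("OXT", "O", oxt))
        residues.append(Residue(i + 1, letter, atoms))
    return Conformation(chain_id=chain_id, residues=residues, peptide=peptide)


def _default_turn_position(n: int) -> int:
    return max(1, (n - 3) // 2 + 1)


def motif_dihedrals(
    peptide: PeptideSpec, motif: str, turn_position: int | None = None
) -> DihedralSet:
    """The (φ, ψ) torsion set a named motif prescribes for ``peptide``.

    Whole-chain motifs repeat their template pair; turn motifs place the
    template at residues ``turn_position + 1`` and ``turn_position + 2`` of
    the four-residue window starting at ``turn_position`` (1-based), with
    extended flanks.
    """
    if motif not in MOTIFS:
        raise ValueError(f"unknown motif {motif!r}; choose from {sorted(MOTIFS)}")
    n = len(peptide.sequence)
    spec = MOTIFS[motif]
    ext = MOTIFS["extended"]["phi_psi"]
    if spec["kind"] == "uniform":
        pairs = [spec["phi_psi"]] * n
    else:
        i = _default_turn_position(n) if turn_position is None else turn_position
        if not 1 <= i <= n - 3:
            raise ValueError(
                f"turn window {i}..{i + 3} does not fit a {n}-residue chain"
            )
        pairs = [ext] * n
        pairs[i] = spec["window"][0]      # residue i+1 (0-based index i)
        pairs[i + 1] = spec["window"][1]  # residue i+2
    return DihedralSet.from_phi_psi(pairs)


def make_motif(
    peptide: PeptideSpec,
    motif: str,
    turn_position: int | None = None,
    geom: GeometryParams = DEFAULT_GEOMETRY,
    chain_id: str = "A",
) -> Conformation:
    """Build a chain with a canonical motif planted (deterministic)."""
    return build_chain(
        peptide, motif_dihedrals(peptide, motif, turn_position), geom, chain_id
    )


def sample_coil(
    peptide: PeptideSpec,
    seed: int | np.random.Generator,
    basin_weights: dict[str, float] | None = None,
    geom: GeometryParams = DEFAULT_GEOMETRY,
    chain_id: str = "A",
) -> Conformation:
    """Sample a random-coil conformation from Ramachandran basins.

    Each residue independently draws a basin with the given weights, then
    (φ, ψ) uniformly within it; ω stays trans.  Reproducible given a seed.
    """
    weights = dict(DEFAULT_BASIN_WEIGHTS if basin_weights is None else basin_weights)
    if set(weights) != set(COIL_BASINS):
        raise ValueError(f"basin weights must cover exactly {sorted(COIL_BASINS)}")
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"basin weights must sum to 1 (got {total})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = sorted(COIL_BASINS)
    p = np.array([weights[b] for b in names])
    pairs = []
    for _ in peptide.sequence:
        basin = names[rng.choice(len(names), p=p)]
        (phi_lo, phi_hi), (psi_lo, psi_hi) = COIL_BASINS[basin]
        pairs.append((rng.uniform(phi_lo, phi_hi), rng.uniform(psi_lo, psi_hi)))
    return build_chain(peptide, DihedralSet.from_phi_psi(pairs), geom, chain_id)


_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def _conformer_for(
    peptide: PeptideSpec,
    motif: str | None,
    rng: np.random.Generator,
    geom: GeometryParams,
    chain_id: str,
) -> Conformation:
    if motif is None or motif == "coil":
        return sample_coil(peptide, rng, geom=geom, chain_id=chain_id)
    return make_motif(peptide, motif, geom=geom, chain_id=chain_id)


def make_system(
    peptide: PeptideSpec,
    n_chains: int,
    box_nm: float = 8.0,
    placement: str = "dispersed",
    min_dist_A: float = 4.0,
    seed: int = 0,
    per_chain_motif: str | list[str | None] | None = None,
    n_frames: int = 1,
    geom: GeometryParams = DEFAULT_GEOMETRY,
    max_attempts: int = 5000,
) -> PeptideSystem:
    """Pack ``n_chains`` conformers into a cubic box, one or more frames.

    ``placement='dispersed'`` does rejection-sampled rigid-body placement
    (uniform position and orientation) enforcing a minimum inter-chain
    heavy-atom distance of ``min_dist_A``.  ``placement='micellar'``
    arranges chains around the box's central z axis with each chain's
    hydrophobic (Ala) end toward the axis and its Lys side chain pointing
    outward — the idealized amphiphilic aggregate geometry.

    ``per_chain_motif`` is a motif name applied to every chain, a per-chain
    list of names (``None``/'coil' entries sample a random coil), or None
    for an all-coil system.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if placement not in ("dispersed", "micellar"):
        raise ValueError(f"placement must be 'dispersed' or 'micellar', got {placement!r}")
    if isinstance(per_chain_motif, list):
        if len(per_chain_motif) != n_chains:
            raise ValueError("per_chain_motif list length must equal n_chains")
        motifs: list[str | None] = list(per_chain_motif)
    else:
        motifs = [per_chain_motif] * n_chains

    root = np.random.SeedSequence(seed)
    frame_seeds = root.spawn(n_frames)
    edge_A = box_nm * 10.0
    frames: list[list[Conformation]] = []
    for fseed in frame_seeds:
        rng = np.random.default_rng(fseed)
        confs = [
            _conformer_for(peptide, motifs[k], rng, geom, _CHAIN_IDS[k % len(_CHAIN_IDS)])
            for k in range(n_chains)
        ]
        if placement == "dispersed":
            frames.append(_place_dispersed(confs, edge_A, min_dist_A, rng, max_attempts))
        else:
            frames.append(_place_micellar(confs, edge_A, rng))
    return PeptideSystem(frames=frames, box_nm=(box_nm, box_nm, box_nm))


def _place_dispersed(
    confs: list[Conformation],
    edge_A: float,
    min_dist_A: float,
    rng: np.random.Generator,
    max_attempts: int,
) -> list[Conformation]:
    from scipy.spatial import cKDTree

    placed: list[Conformation] = []
    occupied: np.ndarray | None = None
    for conf in confs:
        coords0 = conf.heavy_atom_coords()
        center0 = coords0.mean(axis=0)
        ok = False
        for _ in range(max_attempts):
            rot = random_rotation(rng)
            target = rng.uniform(0.0, edge_A, size=3)
            moved = (coords0 - center0) @ rot.T + target
            if occupied is None or not cKDTree(occupied).query_ball_point(
                moved, r=min_dist_A, return_length=True
            ).any():
                placed.append(conf.transformed(rot, target - rot @ center0))
                occupied = moved if occupied is None else np.vstack([occupied, moved])
                ok = True
                break
        if not ok:
            raise PackingError(
                f"could not place chain {conf.chain_id} after {max_attempts} "
                f"attempts; try a larger box (edge {edge_A / 10:.1f} nm) or a "
                f"smaller minimum distance ({min_dist_A} Å)"
            )
    return placed


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180° about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, perp)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _amphiphilic_vector(conf: Conformation) -> np.ndarray:
    """Unit vector from the chain's hydrophobic body toward its Lys head.

    Falls back to the N→C Cα vector when the chain has no Lys.
    """
    ca = conf.atom_coords(("CA",))
    heads = [
        r.coords_of("NZ") for r in conf.residues if r.letter == "K" and r.atom("NZ")
    ]
    tip = np.mean(heads, axis=0) if heads else ca[-1]
    v = tip - ca.mean(axis=0)
    return v / np.linalg.norm(v)


def _place_micellar(
    confs: list[Conformation], edge_A: float, rng: np.random.Generator
) -> list[Conformation]:
    center = np.full(3, edge_A / 2.0)
    n = len(confs)
    # chain extent sets the mid-radius so that the Ala body sits near the axis
    extent = max(np.ptp(c.atom_coords(("CA",)), axis=0).max() for c in confs)
    r_mid = 0.55 * extent
    placed = []
    for k, conf in enumerate(confs):
        theta = 2.0 * np.pi * k / n + rng.normal(scale=0.05)
        outward = np.array([np.cos(theta), np.sin(theta), 0.0])
        z = rng.normal(scale=0.15 * extent)
        rot = _rotation_between(_amphiphilic_vector(conf), outward)
        ca_center = conf.atom_coords(("CA",)).mean(axis=0)
        radial_jitter = rng.normal(scale=0.03 * extent)
        target = center + (r_mid + radial_jitter) * outward + np.array([0.0, 0.0, z])
        placed.append(conf.transformed(rot, target - rot @ ca_center))
    return placed
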