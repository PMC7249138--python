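"""Multi-chain organization: contact clusters, size/shape, amphiphilic
ordering, and coarse pH-dependent electrostatic interaction scores.

Chains belong to the same aggregate when they are connected through the
contact graph (minimum heavy-atom inter-chain distance at or below a
cutoff, single linkage).  For each aggregate the module reports its size,
mass-weighted radius of gyration, principal axis, and the amphiphilic
order — the mean radial distance of Lys NZ atoms from the axis minus that
of Ala CB atoms.  A positive order means hydrophobic core / hydrophilic
shell, the geometry expected of an amphiphile micelle or fiber.

The electrostatic score places the fractional charges of the titration
model on representative atoms (N-terminal N, Lys NZ, C-terminal
carboxylate midpoint) and sums screened Coulomb terms between chains.  It
ranks attraction against repulsion across pH; it is not a free energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .charge import BJELLQVIST, PKaSet, fractional_charge, ionizable_sites
from .model import ATOMIC_MASS, Conformation

__all__ = [
    "ClusterLabeling",
    "AggregateReport",
    "contact_clusters",
    "radius_of_gyration",
    "principal_axis",
    "amphiphilic_profile",
    "pair_electrostatic_score",
    "analyze_frame",
]

#: Coulomb constant e^2/(4 pi eps0), in kJ mol^-1 Å e^-2.
COULOMB_KJ_MOL_A = 1389.35458


@dataclass(frozen=True)
class ClusterLabeling:
    """Partition of a frame's chains into contact-connected aggregates."""

    labels: tuple[int, ...]  # per-chain aggregate id, 0-based
    cutoff_A: float

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels))

    def members(self, cluster_id: int) -> list[int]:
        return [i for i, lab in enumerate(self.labels) if lab == cluster_id]


@dataclass(frozen=True)
class AggregateReport:
    """Geometry of one aggregate within a frame."""

    chain_indices: tuple[int, ...]
    size: int
    radius_of_gyration: float  # Å
    axis: tuple[float, float, float]
    mean_radial_ala_cb: float  # Å
    mean_radial_lys_nz: float  # Å
    amphiphilic_order: float   # Å, NZ minus CB


def contact_clusters(frame: list[Conformation], cutoff_A: float = 4.5) -> ClusterLabeling:
    """Single-linkage contact clustering of one frame's chains.

    Two chains are adjacent when their minimum heavy-atom distance is at
    most ``cutoff_A``; aggregates are the connected components.  Cluster
    ids are renumbered by first chain occurrence, so the labeling is
    deterministic and independent of library internals.
    """
    if cutoff_A <= 0:
        raise ValueError("cutoff must be positive")
    if not frame:
        raise ValueError("empty frame")
    n = len(frame)
    coords = [c.heavy_atom_coords() for c in frame]
    trees = [cKDTree(x) for x in coords]
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if any(trees[i].query_ball_tree(trees[j], r=cutoff_A)):
                rows += [i, j]
                cols += [j, i]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, raw = connected_components(adj, directed=False)
    remap: dict[int, int] = {}
    labels = []
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap)
        labels.append(remap[lab])
    return ClusterLabeling(labels=tuple(labels), cutoff_A=cutoff_A)


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Mass-weighted RMS distance from the center of mass, in Å."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.size == 0:
        raise ValueError("need at least one atom")
    m = np.ones(len(coords)) if masses is None else np.asarray(masses, dtype=float)
    com = np.average(coords, axis=0, weights=m)
    d2 = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt(np.average(d2, weights=m)))


def principal_axis(coords: np.ndarray) -> np.ndarray:
    """First principal component of a point cloud, as a unit vector.

    The sign is fixed lexicographically (first nonzero component positive)
    so repeated runs report the same direction.
    """
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-10:
        raise ValueError("degenerate point cloud: no principal axis")
    axis = vt[0]
    for comp in axis:
        if abs(comp) > 1e-12:
            if comp < 0:
                axis = -axis
            break
    return axis


def _radial_distances(points: np.ndarray, origin: np.ndarray, axis: np.ndarray) -> np.ndarray:
    rel = points - origin
    along = rel @ axis
    perp = rel - np.outer(along, axis)
    return np.linalg.norm(perp, axis=1)


def amphiphilic_profile(
    chains: list[Conformation],
    axis: np.ndarray | None = None,
    chain_indices: tuple[int, ...] | None = None,
) -> AggregateReport:
    """Radial core/shell analysis of one aggregate.

    The reference axis is the first principal component of all Cα positions
    unless one is supplied (required when fewer than 3 chains are given or
    the cloud is degenerate).  Radial distance is perpendicular distance to
    the axis through the Cα centroid.
    """
    if not chains:
        raise ValueError("empty aggregate")
    ca = np.vstack([c.atom_coords(("CA",)) for c in chains])
    origin = ca.mean(axis=0)
    if axis is None:
        if len(chains) < 3:
            raise ValueError(
                "principal-axis mode needs >= 3 chains; pass an explicit axis"
            )
        axis = principal_axis(ca)
    else:
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)

    cb_pts, nz_pts = [], []
    for c in chains:
        for r in c.residues:
            if r.letter == "A" and r.atom("CB"):
                cb_pts.append(r.coords_of("CB"))
            if r.letter == "K" and r.atom("NZ"):
                nz_pts.append(r.coords_of("NZ"))
    if not cb_pts or not nz_pts:
        raise ValueError("aggregate lacks Ala CB or Lys NZ marker atoms")
    r_cb = float(np.mean(_radial_distances(np.array(cb_pts), origin, axis)))
    r_nz = float(np.mean(_radial_distances(np.array(nz_pts), origin, axis)))

    all_coords, all_masses = [], []
    for c in chains:
        for r in c.residues:
            for a in r.atoms:
                all_coords.append(a.coords)
                all_masses.append(ATOMIC_MASS.get(a.element, 12.011))
    rg = radius_of_gyration(np.array(all_coords), np.array(all_masses))

    return AggregateReport(
        chain_indices=chain_indices or tuple(range(len(chains))),
        size=len(chains),
        radius_of_gyration=rg,
        axis=tuple(float(x) for x in axis),
        mean_radial_ala_cb=r_cb,
        mean_radial_lys_nz=r_nz,
        amphiphilic_order=r_nz - r_cb,
    )


def _charge_sites(conf: Conformation, pH: float, pka_set: PKaSet):
    """(position, fractional charge) pairs for one chain's ionizable sites."""
    out = []
    for site in ionizable_sites(conf.peptide, pka_set):
        res = conf.residues[site.residue_index - 1]
        if site.site_kind == "n_terminus":
            pos = res.coords_of("N")
        elif site.site_kind == "c_terminus":
            o, oxt = res.coords_of("O"), res.coords_of("OXT")
            pos = 0.5 * (o + oxt) if (o is not None and oxt is not None) else o
        else:
            pos = next(
                (p for p in (res.coords_of("NZ"), res.coords_of("CB"),
                             res.coords_of("CA")) if p is not None),
                None,
            )
        if pos is None:
            raise ValueError(
                f"chain {conf.chain_id}: no atom to carry the {site.site_kind} "
                f"charge of residue {site.residue_index}"
            )
        out.append((np.asarray(pos, dtype=float), fractional_charge(site, pH)))
    return out


def pair_electrostatic_score(
    chain_a: Conformation,
    chain_b: Conformation,
    pH: float,
    pka_set: PKaSet = BJELLQVIST,
    dielectric: float = 78.5,
    cutoff_nm: float = 1.4,
) -> float:
    """Screened Coulomb score between two chains' charge sites, kJ/mol.

    Fractional site charges come from the titration model at ``pH``;
    cross-chain pairs beyond ``cutoff_nm`` are omitted.  Positive values
    mean net repulsion, negative net attraction.  Symmetric in its
    arguments.
    """
    cutoff_A = cutoff_nm * 10.0
    sites_a = _charge_sites(chain_a, pH, pka_set)
    sites_b = _charge_sites(chain_b, pH, pka_set)
    terms = []
    for pa, qa in sites_a:
        for pb, qb in sites_b:
            r = float(np.linalg.norm(pa - pb))
            if r > cutoff_A or r == 0.0:
                continue
            terms.append(COULOMB_KJ_MOL_A * qa * qb / (dielectric * r))
    # summation in sorted order makes the score exactly symmetric in its
    # arguments (the term set is identical either way)
    return float(sum(sorted(terms)))


def analyze_frame(
    frame: list[Conformation],
    cutoff_A: float = 4.5,
    pH: float | None = None,
    pka_set: PKaSet = BJELLQVIST,
    dielectric: float = 78.5,
    coulomb_cutoff_nm: float = 1.4,
    min_axis_chains: int = 3,
) -> dict:
    """Cluster one frame and report per-aggregate geometry (and, when a pH
    is given, pairwise electrostatic scores between contacting chains)."""
    labeling = contact_clusters(frame, cutoff_A)
    aggregates = []
    for cid in sorted(set(labeling.labels)):
        members = labeling.members(cid)
        chains = [frame[i] for i in members]
        entry: dict = {"id": cid, "size": len(members), "chains": members}
        coords, masses = [], []
        for c in chains:
            for r in c.residues:
                for a in r.atoms:
                    coords.append(a.coords)
                    masses.append(ATOMIC_MASS.get(a.element, 12.011))
        entry["radius_of_gyration_A"] = radius_of_gyration(
            np.array(coords), np.array(masses)
        )
        if len(chains) >= min_axis_chains:
            try:
                rep = amphiphilic_profile(chains, chain_indices=tuple(members))
                entry["amphiphilic_order_A"] = rep.amphiphilic_order
                entry["mean_radial_ala_cb_A"] = rep.mean_radial_ala_cb
                entry["mean_radial_lys_nz_A"] = rep.mean_radial_lys_nz
                entry["axis"] = rep.axis
            except ValueError:
                entry["amphiphilic_order_A"] = None
        aggregates.append(entry)

    result = {
        "cutoff_A": cutoff_A,
        "n_chains": len(frame),
        "cluster_labels": list(labeling.labels),
        "aggregates": aggregates,
    }
    if pH is not None:
        scores = []
        for i in range(len(frame)):
            for j in range(i + 1, len(frame)):
                if labeling.labels[i] == labeling.labels[j]:
                    scores.append(
                        {
                            "chains": (i, j),
                            "score_kJ_mol": pair_electrostatic_score(
                                frame[i], frame[j], pH, pka_set,
                                dielectric, coulomb_cutoff_nm,
                            ),
                        }
                    )
        result["pH"] = pH
        result["pair_electrostatics"] = scores
    return result
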