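"""Backbone dihedrals, coarse secondary structure, and β-turn detection.

A β-turn is a four-residue chain reversal over residues i..i+3.  Two
classical geometric diagnoses are implemented:

* criterion A — a backbone hydrogen bond between the carbonyl C=O of
  residue i and the amide N-H of residue i+3;
* criterion B — a Cα(i)–Cα(i+3) distance strictly below 7 Å.

A window qualifies under either criterion by default (configurable to
require both), and windows whose central residues are helical are rejected
by default since a run of α-helix trivially satisfies both geometries.

Per-residue secondary structure comes from a deliberately simple
Ramachandran-region classifier (helix / sheet / turn / coil); it stands in
for hydrogen-bond-energy assignment algorithms such as STRIDE and is
comparable in spirit, not numerically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import dihedral
from .model import Conformation, PeptideSystem
from .synth import DihedralSet

__all__ = [
    "TurnCriteria",
    "HBond",
    "TurnRecord",
    "TurnContent",
    "backbone_dihedrals",
    "classify_ss",
    "find_hbonds",
    "detect_beta_turns",
    "turn_content",
]


@dataclass(frozen=True)
class TurnCriteria:
    """Thresholds and switches for β-turn detection."""

    ca_dist_max: float = 7.0       # Å, strict upper bound for criterion B
    hbond_ON_max: float = 3.5      # Å, donor N to acceptor O
    hbond_angle_min: float = 120.0  # degrees, N-H···O
    combine: str = "either"        # 'either' or 'both'
    exclude_helix: bool = True

    def __post_init__(self) -> None:
        if min(self.ca_dist_max, self.hbond_ON_max, self.hbond_angle_min) <= 0:
            raise ValueError("criteria thresholds must be positive")
        if self.combine not in ("either", "both"):
            raise ValueError(f"combine must be 'either' or 'both', got {self.combine!r}")


@dataclass(frozen=True)
class HBond:
    """A backbone N-H···O=C hydrogen bond (donor is the N-H residue)."""

    donor: int      # 1-based residue index
    acceptor: int
    distance_ON: float  # Å
    angle_NHO: float    # degrees


@dataclass(frozen=True)
class TurnRecord:
    """Evidence that the window start..start+3 is a β-turn."""

    start: int  # 1-based index of residue i
    evidence: str  # 'hbond', 'ca_distance', or 'both'
    ca_dist: float
    hbond: HBond | None = None


@dataclass(frozen=True)
class TurnContent:
    """Ensemble turn statistics over the frames of a system."""

    turn_percent: float        # mean over frames
    beta_turn_percent: float   # mean over frames
    turn_percent_sd: float
    beta_turn_percent_sd: float
    per_frame_turn: tuple[float, ...]
    per_frame_beta_turn: tuple[float, ...]


def backbone_dihedrals(conf: Conformation) -> DihedralSet:
    """Measure φ, ψ, ω for every residue; NaN at termini and around
    residues flagged unusable (missing backbone atoms)."""
    n = len(conf)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    omega = np.full(n, np.nan)
    get = [
        (r.coords_of("N"), r.coords_of("CA"), r.coords_of("C")) for r in conf.residues
    ]
    unusable = [i for i, r in enumerate(conf.residues) if not r.usable]
    if unusable:
        warnings.warn(
            f"chain {conf.chain_id}: residues {[i + 1 for i in unusable]} lack "
            "backbone atoms; their dihedrals are undefined",
            stacklevel=2,
        )
    for i in range(n):
        N_i, CA_i, C_i = get[i]
        if N_i is None or CA_i is None or C_i is None:
            continue
        if i > 0:
            N_p, CA_p, C_p = get[i - 1]
            if C_p is not None:
                phi[i] = dihedral(C_p, N_i, CA_i, C_i)
                if CA_p is not None:
                    omega[i] = dihedral(CA_p, C_p, N_i, CA_i)
        if i < n - 1:
            N_n = get[i + 1][0]
            if N_n is not None:
                psi[i] = dihedral(N_i, CA_i, C_i, N_n)
    return DihedralSet(phi, psi, omega)


def _in_helix_region(phi: float, psi: float) -> bool:
    return -100.0 <= phi <= -30.0 and -80.0 <= psi <= -5.0


def _in_beta_region(phi: float, psi: float) -> bool:
    return -180.0 <= phi <= -60.0 and (60.0 <= psi <= 180.0 or -180.0 < psi <= -150.0)


def _runs(mask: np.ndarray, min_len: int) -> np.ndarray:
    """Mark positions inside runs of True at least ``min_len`` long."""
    out = np.zeros_like(mask)
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= min_len:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def classify_ss(
    dihedrals: DihedralSet, conf: Conformation, criteria: TurnCriteria | None = None
) -> list[str]:
    """Per-residue labels in {helix, sheet, turn, coil}.

    Helix requires ≥4 consecutive residues in the α_R Ramachandran region,
    sheet ≥2 consecutive in the β region.  Remaining residues at the centre
    (i+1, i+2) of a window with Cα(i)–Cα(i+3) below the turn threshold are
    labelled turn; everything else (including termini with undefined
    dihedrals) is coil.
    """
    criteria = criteria or TurnCriteria()
    n = len(dihedrals)
    defined = ~(np.isnan(dihedrals.phi) | np.isnan(dihedrals.psi))
    helix_mask = np.array(
        [
            defined[i] and _in_helix_region(dihedrals.phi[i], dihedrals.psi[i])
            for i in range(n)
        ]
    )
    beta_mask = np.array(
        [
            defined[i] and _in_beta_region(dihedrals.phi[i], dihedrals.psi[i])
            for i in range(n)
        ]
    )
    labels = np.array(["coil"] * n, dtype=object)
    labels[_runs(beta_mask, 2)] = "sheet"
    labels[_runs(helix_mask, 4)] = "helix"

    ca = [r.coords_of("CA") for r in conf.residues]
    for i in range(n - 3):
        if ca[i] is None or ca[i + 3] is None:
            continue
        if np.linalg.norm(ca[i] - ca[i + 3]) < criteria.ca_dist_max:
            for j in (i + 1, i + 2):
                if labels[j] == "coil":
                    labels[j] = "turn"
    return list(labels)


def _amide_h(conf: Conformation, i: int) -> np.ndarray | None:
    """Amide H of residue i (0-based); reconstructed in the C'(prev)-N-CA
    plane when the file carries no hydrogens.  None for Pro and residue 1."""
    res = conf.residues[i]
    h = res.coords_of("H")
    if h is not None:
        return h
    if i == 0 or res.letter == "P":
        return None
    N_i = res.coords_of("N")
    CA_i = res.coords_of("CA")
    C_p = conf.residues[i - 1].coords_of("C")
    if N_i is None or CA_i is None or C_p is None:
        return None
    u = C_p - N_i
    v = CA_i - N_i
    d = -(u / np.linalg.norm(u) + v / np.linalg.norm(v))
    return N_i + 1.01 * d / np.linalg.norm(d)


def find_hbonds(conf: Conformation, criteria: TurnCriteria | None = None) -> list[HBond]:
    """All backbone N-H···O=C hydrogen bonds under the geometric criterion.

    A donor/acceptor pair qualifies when the O···N distance is at most
    ``hbond_ON_max`` and the N-H···O angle at least ``hbond_angle_min``;
    pairs closer than two residues apart in sequence are excluded, as are
    donors without an amide hydrogen (proline, the free N-terminus).
    """
    criteria = criteria or TurnCriteria()
    n = len(conf)
    out: list[HBond] = []
    for acc in range(n):
        O = conf.residues[acc].coords_of("O")
        if O is None:
            warnings.warn(
                f"chain {conf.chain_id}: residue {acc + 1} has no carbonyl O; "
                "skipped as acceptor",
                stacklevel=2,
            )
            continue
        for don in range(n):
            if abs(don - acc) < 2:
                continue
            N = conf.residues[don].coords_of("N")
            H = _amide_h(conf, don)
            if N is None or H is None:
                continue
            d_ON = float(np.linalg.norm(O - N))
            if d_ON > criteria.hbond_ON_max:
                continue
            u = N - H
            v = O - H
            cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if ang >= criteria.hbond_angle_min:
                out.append(HBond(don + 1, acc + 1, d_ON, ang))
    return out


def detect_beta_turns(
    conf: Conformation,
    criteria: TurnCriteria | None = None,
    ss: list[str] | None = None,
) -> list[TurnRecord]:
    """Scan all i..i+3 windows of one chain for β-turn evidence.

    Criterion A is an i(C=O) → i+3(N-H) hydrogen bond, criterion B a
    Cα(i)–Cα(i+3) distance strictly below ``ca_dist_max``; the window
    qualifies per ``criteria.combine``.  With ``exclude_helix`` (default),
    windows whose residue i+1 or i+2 carries a helix label are rejected.
    """
    criteria = criteria or TurnCriteria()
    n = len(conf)
    if n < 4:
        return []
    if ss is None:
        ss = classify_ss(backbone_dihedrals(conf), conf, criteria)
    hbonds = {
        (hb.acceptor, hb.donor): hb
        for hb in find_hbonds(conf, criteria)
        if hb.donor - hb.acceptor == 3
    }
    records: list[TurnRecord] = []
    for i in range(n - 3):
        ca_i = conf.residues[i].coords_of("CA")
        ca_j = conf.residues[i + 3].coords_of("CA")
        if ca_i is None or ca_j is None:
            continue
        ca_dist = float(np.linalg.norm(ca_i - ca_j))
        hit_b = ca_dist < criteria.ca_dist_max
        hb = hbonds.get((i + 1, i + 4))
        hit_a = hb is not None
        ok = (hit_a and hit_b) if criteria.combine == "both" else (hit_a or hit_b)
        if not ok:
            continue
        if criteria.exclude_helix and ("helix" in (ss[i + 1], ss[i + 2])):
            continue
        evidence = "both" if (hit_a and hit_b) else ("hbond" if hit_a else "ca_distance")
        records.append(TurnRecord(i + 1, evidence, ca_dist, hb))
    return records


def turn_content(
    system: PeptideSystem,
    criteria: TurnCriteria | None = None,
    denominator: str = "residues",
) -> TurnContent:
    """Ensemble turn and β-turn percentages over the frames of a system.

    Per frame, ``turn_percent`` is the share of residues labelled turn by
    the secondary-structure classifier and ``beta_turn_percent`` the share
    of residues lying inside qualifying β-turn windows (the two central
    criteria differ, so neither bounds the other).  With
    ``denominator='windows'`` the β-turn figure is instead the share of
    qualifying i..i+3 windows among all windows.
    """
    criteria = criteria or TurnCriteria()
    if denominator not in ("residues", "windows"):
        raise ValueError("denominator must be 'residues' or 'windows'")
    if not system.frames:
        raise ValueError("empty system")
    turn_pc: list[float] = []
    beta_pc: list[float] = []
    for frame in system.frames:
        n_res = sum(len(c) for c in frame)
        n_windows = sum(max(0, len(c) - 3) for c in frame)
        n_turn = 0
        beta_residues = 0
        n_qual = 0
        for conf in frame:
            ss = classify_ss(backbone_dihedrals(conf), conf, criteria)
            n_turn += sum(1 for s in ss if s == "turn")
            records = detect_beta_turns(conf, criteria, ss)
            n_qual += len(records)
            covered: set[int] = set()
            for rec in records:
                covered.update(range(rec.start, rec.start + 4))
            beta_residues += len(covered)
        turn_pc.append(100.0 * n_turn / n_res)
        if denominator == "residues":
            beta_pc.append(100.0 * beta_residues / n_res)
        else:
            beta_pc.append(100.0 * n_qual / n_windows if n_windows else 0.0)
    t = np.array(turn_pc)
    b = np.array(beta_pc)
    return TurnContent(
        turn_percent=float(t.mean()),
        beta_turn_percent=float(b.mean()),
        turn_percent_sd=float(t.std(ddof=0)),
        beta_turn_percent_sd=float(b.std(ddof=0)),
        per_frame_turn=tuple(turn_pc),
        per_frame_beta_turn=tuple(beta_pc),
    )
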