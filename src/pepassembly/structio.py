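"""Reading and writing multi-model, multi-chain peptide coordinate files.

Two dialects are supported: fixed-width PDB with optional MODEL/ENDMDL
blocks (one frame per MODEL) and single-configuration GROMACS GRO files.
Coordinates are Å internally; GRO's nm fields are converted at the
boundary.  Only blank and 'A' alternate locations are honoured; insertion
codes are rejected.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .model import Atom, Conformation, PeptideSystem, Residue, element_for
from .peptide import ONE_TO_THREE, THREE_TO_ONE, PeptideSpec

__all__ = ["read_pdb", "write_pdb", "read_gro", "write_gro", "ParseError"]


class ParseError(ValueError):
    """A coordinate file could not be parsed; the message names the line."""


def _finish_chain(
    chain_id: str,
    residues: list[tuple[int, str, list[Atom]]],
    n_term_free: bool,
    c_term_free: bool,
) -> Conformation:
    seq = "".join(letter for _, letter, _ in residues)
    renumbered = [
        Residue(i, letter, atoms)
        for i, (_, letter, atoms) in enumerate(residues, start=1)
    ]
    peptide = PeptideSpec(seq, n_term_free=n_term_free, c_term_free=c_term_free)
    return Conformation(chain_id=chain_id, residues=renumbered, peptide=peptide)


def read_pdb(
    path: str | Path, n_term_free: bool = True, c_term_free: bool = True
) -> PeptideSystem:
    """Read a (multi-model) PDB file into a :class:`PeptideSystem`.

    Each MODEL block becomes one frame (a single frame if the file has no
    MODEL records).  Chains are split on chain ID and TER records; residues
    are renumbered 1..n per chain.  Termini blocking state is not encoded
    in PDB coordinates, so it is supplied by the caller (free by default).
    Alternate locations other than blank/'A' are ignored; residues missing
    backbone atoms are kept but flagged unusable downstream.
    """
    path = Path(path)
    frames: list[list[Conformation]] = []
    box: tuple[float, float, float] | None = None

    chains: list[Conformation] = []
    cur_chain: str | None = None
    cur_residues: list[tuple[int, str, list[Atom]]] = []
    in_model = False
    saw_model = False

    def flush_chain() -> None:
        nonlocal cur_residues, cur_chain
        if cur_residues:
            chains.append(
                _finish_chain(cur_chain or "A", cur_residues, n_term_free, c_term_free)
            )
        cur_residues = []
        cur_chain = None

    def flush_frame() -> None:
        nonlocal chains
        flush_chain()
        if chains:
            frames.append(chains)
        chains = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "CRYST1":
                try:
                    box = tuple(float(line[6 + 9 * i : 15 + 9 * i]) / 10.0 for i in range(3))
                except ValueError as exc:
                    raise ParseError(f"{path.name}:{lineno}: bad CRYST1 record") from exc
            elif rec == "MODEL":
                if in_model:
                    flush_frame()
                in_model = True
                saw_model = True
            elif rec == "ENDMDL":
                flush_frame()
                in_model = False
            elif rec == "TER":
                flush_chain()
            elif rec == "ATOM" or rec == "HETATM":
                if len(line.rstrip("\n")) < 54:
                    raise ParseError(
                        f"{path.name}:{lineno}: ATOM record shorter than 54 columns"
                    )
                altloc = line[16]
                if altloc not in (" ", "A"):
                    continue
                if line[26] != " ":
                    raise ParseError(
                        f"{path.name}:{lineno}: insertion codes are unsupported"
                    )
                name = line[12:16].strip()
                resname = line[17:20].strip()
                chain_id = line[21].strip() or "A"
                try:
                    resseq = int(line[22:26])
                    xyz = np.array(
                        [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                    )
                except ValueError as exc:
                    raise ParseError(
                        f"{path.name}:{lineno}: malformed ATOM record"
                    ) from exc
                letter = THREE_TO_ONE.get(resname)
                if letter is None:
                    raise ParseError(
                        f"{path.name}:{lineno}: unknown residue name {resname!r}"
                    )
                if cur_chain is not None and chain_id != cur_chain:
                    flush_chain()
                if cur_chain is None:
                    cur_chain = chain_id
                if not cur_residues or cur_residues[-1][0] != resseq:
                    cur_residues.append((resseq, letter, []))
                elem = (line[76:78].strip() if len(line) >= 78 else "") or element_for(name)
                cur_residues[-1][2].append(Atom(name, elem, xyz))
    flush_frame()

    if not frames:
        raise ParseError(f"{path.name}: no ATOM records found")
    if saw_model and len({len(f) for f in frames}) > 1:
        raise ParseError(f"{path.name}: MODEL blocks have differing chain counts")
    return PeptideSystem(frames=frames, box_nm=box)


_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def write_pdb(system: PeptideSystem, path: str | Path) -> None:
    """Write a :class:`PeptideSystem` as fixed-width PDB.

    One MODEL/ENDMDL block per frame, TER after each chain, CRYST1 when the
    box is known.  Chain IDs cycle through [A-Za-z0-9] when a frame holds
    more chains than one character can name.
    """
    if not system.frames:
        raise ValueError("cannot write an empty system")
    path = Path(path)
    lines: list[str] = []
    if system.box_nm is not None:
        a, b, c = (10.0 * e for e in system.box_nm)
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
        )
    multi = system.n_frames > 1
    for iframe, frame in enumerate(system.frames, start=1):
        if multi:
            lines.append(f"MODEL     {iframe:4d}")
        serial = 1
        for ichain, conf in enumerate(frame):
            cid = _CHAIN_IDS[ichain % len(_CHAIN_IDS)]
            for res in conf.residues:
                resname = ONE_TO_THREE[res.letter]
                for atom in res.atoms:
                    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                    x, y, z = atom.coords
                    lines.append(
                        f"ATOM  {serial:5d} {name}{'':1s}{resname:>3s} {cid}"
                        f"{res.index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
                    )
                    serial += 1
            lines.append(f"TER   {serial:5d}      {ONE_TO_THREE[conf.residues[-1].letter]:>3s} {cid}{conf.residues[-1].index:4d}")
            serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def read_gro(
    path: str | Path, n_term_free: bool = True, c_term_free: bool = True
) -> PeptideSystem:
    """Read a single-configuration GRO file (via MDAnalysis); nm → Å.

    GRO carries no chain identifiers, so a new chain starts whenever the
    residue number fails to increase.  Velocity columns are ignored.
    """
    import MDAnalysis as mda

    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except (ValueError, OSError, EOFError) as exc:
        raise ParseError(f"{path.name}: malformed GRO file ({exc})") from exc

    chains: list[Conformation] = []
    cur: list[tuple[int, str, list[Atom]]] = []
    prev_resid = None
    for res in u.residues:
        letter = THREE_TO_ONE.get(res.resname.strip().upper())
        if letter is None:
            raise ParseError(f"{path.name}: unknown residue name {res.resname!r}")
        if prev_resid is not None and res.resid <= prev_resid:
            chains.append(
                _finish_chain(_CHAIN_IDS[len(chains) % len(_CHAIN_IDS)], cur,
                              n_term_free, c_term_free)
            )
            cur = []
        prev_resid = res.resid
        atoms = [
            Atom(a.name, element_for(a.name), a.position.astype(float))
            for a in res.atoms
        ]
        cur.append((int(res.resid), letter, atoms))
    if cur:
        chains.append(
            _finish_chain(_CHAIN_IDS[len(chains) % len(_CHAIN_IDS)], cur,
                          n_term_free, c_term_free)
        )
    box = None
    if u.dimensions is not None and np.all(u.dimensions[:3] > 0):
        box = tuple(float(e) / 10.0 for e in u.dimensions[:3])
    return PeptideSystem(frames=[chains], box_nm=box)


def write_gro(system: PeptideSystem, path: str | Path, frame: int = 0) -> None:
    """Write one frame as a GRO configuration (Å → nm, 3 decimals)."""
    if not system.frames:
        raise ValueError("cannot write an empty system")
    conf_list = system.frames[frame]
    lines = ["pepassembly generated configuration"]
    atoms: list[str] = []
    serial = 1
    for conf in conf_list:
        for res in conf.residues:
            # per-chain 1-based numbering; the reader splits chains where the
            # residue number fails to increase
            resid = res.index
            for atom in res.atoms:
                x, y, z = atom.coords / 10.0
                atoms.append(
                    f"{resid:5d}{ONE_TO_THREE[res.letter]:<5s}{atom.name:>5s}"
                    f"{serial:5d}{x:8.3f}{y:8.3f}{z:8.3f}"
                )
                serial += 1
    lines.append(f"{len(atoms):5d}")
    lines.extend(atoms)
    box = system.box_nm or (0.0, 0.0, 0.0)
    lines.append(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}")
    Path(path).write_text("\n".join(lines) + "\n")
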