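"""Per-site protonation and net-charge model for short peptides.

Each ionizable group (free N-terminal amine, free C-terminal carboxyl, and
the ionizable side chains D, E, H, C, Y, K, R) carries a fractional charge
given by the Henderson–Hasselbalch relation,

    base:  q(pH) = +1 / (1 + 10**(pH - pKa))
    acid:  q(pH) = -1 / (1 + 10**(pKa - pH))

and the peptide net charge is the sum over sites.  Both forms are strictly
decreasing in pH, so the net charge is too, which makes the isoelectric
point (pH of zero net charge) a bisection root.

The default pKa table is the Bjellqvist set used by the ExPAsy Compute
pI/Mw tool: residue-specific N-terminal amine values, C-terminal carboxyl
3.55 (4.55/4.75 when the last residue is D/E), and the usual side-chain
values (K 10.00, etc.).  For the uncapped heptapeptide AAAAAAK this model
gives rounded net charges +2, +1, 0, -1 at pH 2, 7, 8, 11 and a pI of 8.8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .peptide import PeptideSpec, PeptideValidationError

__all__ = [
    "IonizableSite",
    "PKaSet",
    "TitrationPoint",
    "ChargeModel",
    "BJELLQVIST",
    "ionizable_sites",
    "fractional_charge",
    "net_charge",
    "isoelectric_point",
    "molecular_weight",
    "charge_state_model",
    "titration_curve",
    "NoIsoelectricPointError",
]


class NoIsoelectricPointError(ValueError):
    """The net-charge function has no zero on pH [0, 14]."""


@dataclass(frozen=True)
class IonizableSite:
    """One titratable group on a peptide.

    ``site_kind`` is one of ``n_terminus``, ``c_terminus``, ``side_chain``;
    ``residue_index`` is the 1-based position of the residue carrying the
    group; ``polarity`` is ``base`` (charge in [0, +1]) or ``acid`` (charge
    in [-1, 0]).
    """

    site_kind: str
    residue_index: int
    pKa: float
    polarity: str

    def __post_init__(self) -> None:
        if self.site_kind not in ("n_terminus", "c_terminus", "side_chain"):
            raise ValueError(f"bad site_kind {self.site_kind!r}")
        if self.polarity not in ("acid", "base"):
            raise ValueError(f"bad polarity {self.polarity!r}")
        if not 0.0 < self.pKa < 14.0:
            raise ValueError(f"pKa {self.pKa} outside (0, 14)")


# Side chains that titrate, with polarity.
_SIDE_CHAIN_POLARITY = {
    "D": "acid", "E": "acid", "C": "acid", "Y": "acid",
    "H": "base", "K": "base", "R": "base",
}


@dataclass(frozen=True)
class PKaSet:
    """A named table of pKa values keyed by (site kind, residue letter).

    ``entries`` maps ``("n_terminus", letter)``, ``("c_terminus", letter)``
    and ``("side_chain", letter)`` to pKa values; the special letter ``"*"``
    is the default for a terminus when no residue-specific entry exists.
    """

    name: str
    entries: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def lookup(self, site_kind: str, letter: str) -> float:
        key = (site_kind, letter)
        if key in self.entries:
            return self.entries[key]
        fallback = (site_kind, "*")
        if fallback in self.entries:
            return self.entries[fallback]
        raise KeyError(f"pKa set {self.name!r} has no entry for {key}")

    def has_side_chain(self, letter: str) -> bool:
        return ("side_chain", letter) in self.entries


#: Bjellqvist/ExPAsy pKa table (Compute pI/Mw conventions).
BJELLQVIST = PKaSet(
    name="bjellqvist",
    entries={
        ("n_terminus", "*"): 7.50,
        ("n_terminus", "A"): 7.59,
        ("n_terminus", "M"): 7.00,
        ("n_terminus", "S"): 6.93,
        ("n_terminus", "P"): 8.36,
        ("n_terminus", "T"): 6.82,
        ("n_terminus", "V"): 7.44,
        ("n_terminus", "E"): 7.70,
        ("n_terminus", "G"): 7.50,
        ("c_terminus", "*"): 3.55,
        ("c_terminus", "D"): 4.55,
        ("c_terminus", "E"): 4.75,
        ("side_chain", "D"): 4.05,
        ("side_chain", "E"): 4.45,
        ("side_chain", "H"): 5.98,
        ("side_chain", "C"): 9.00,
        ("side_chain", "Y"): 10.00,
        ("side_chain", "K"): 10.00,
        ("side_chain", "R"): 12.00,
    },
)


@dataclass(frozen=True)
class TitrationPoint:
    pH: float
    net_charge: float
    rounded_net_charge: int


# Site-label thresholds on |fractional charge|; chosen so that the model's
# verbal categories track everyday usage ("substantially uncharged" etc.).
LABEL_THRESHOLDS = {
    "charged": 0.9,
    "mostly_charged": 0.7,
    "mixed": 0.3,
    "mostly_neutral": 0.1,
}


@dataclass(frozen=True)
class ChargeModel:
    """Per-site fractional charges of a peptide at one pH."""

    pH: float
    site_charges: tuple[tuple[IonizableSite, float], ...]
    net_charge: float
    rounded_net_charge: int
    site_labels: tuple[str, ...]


def _check_ph(pH: float) -> None:
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH {pH} outside the supported range [0, 14]")


def ionizable_sites(
    peptide: PeptideSpec, pka_set: PKaSet = BJELLQVIST
) -> list[IonizableSite]:
    """Enumerate the titratable groups of ``peptide`` in N→C order.

    One site per free terminus plus one per ionizable side chain; blocked
    termini contribute no site.
    """
    sites: list[IonizableSite] = []
    seq = peptide.sequence
    if peptide.n_term_free:
        sites.append(
            IonizableSite(
                "n_terminus", 1, pka_set.lookup("n_terminus", seq[0]), "base"
            )
        )
    for idx, letter in enumerate(seq, start=1):
        if letter in _SIDE_CHAIN_POLARITY and pka_set.has_side_chain(letter):
            sites.append(
                IonizableSite(
                    "side_chain",
                    idx,
                    pka_set.lookup("side_chain", letter),
                    _SIDE_CHAIN_POLARITY[letter],
                )
            )
    if peptide.c_term_free:
        sites.append(
            IonizableSite(
                "c_terminus",
                len(seq),
                pka_set.lookup("c_terminus", seq[-1]),
                "acid",
            )
        )
    return sites


def fractional_charge(site: IonizableSite, pH: float) -> float:
    """Henderson–Hasselbalch fractional charge of one site at ``pH``, in e."""
    _check_ph(pH)
    if site.polarity == "base":
        return 1.0 / (1.0 + 10.0 ** (pH - site.pKa))
    return -1.0 / (1.0 + 10.0 ** (site.pKa - pH))


def _round_half_away(x: float) -> int:
    # nearest integer, ties away from zero (matches the integer charge
    # labels written under the charge-distribution models)
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


def net_charge(
    peptide: PeptideSpec, pH: float, pka_set: PKaSet = BJELLQVIST
) -> TitrationPoint:
    """Net charge of ``peptide`` at ``pH``: the sum of site fractional charges."""
    sites = ionizable_sites(peptide, pka_set)
    q = sum(fractional_charge(s, pH) for s in sites)
    return TitrationPoint(pH=pH, net_charge=q, rounded_net_charge=_round_half_away(q))


def titration_curve(
    peptide: PeptideSpec,
    pH_grid: Sequence[float] | Iterable[float],
    pka_set: PKaSet = BJELLQVIST,
) -> list[TitrationPoint]:
    """Pointwise net charge over ``pH_grid``, in input order."""
    return [net_charge(peptide, ph, pka_set) for ph in pH_grid]


def isoelectric_point(
    peptide: PeptideSpec,
    pka_set: PKaSet = BJELLQVIST,
    tol: float = 1e-4,
    decimals: int | None = 1,
) -> float:
    """pH of zero net charge, by bisection on [0, 14].

    The net-charge function is strictly decreasing in pH, so a sign change
    over [0, 14] brackets a unique root.  Bisection runs until
    ``|net_charge| < tol``; the result is rounded to ``decimals`` places
    (pass ``None`` for the raw root).

    Raises
    ------
    NoIsoelectricPointError
        If the net charge does not change sign on [0, 14] (e.g. a peptide
        with base sites only never goes negative).
    """
    lo, hi = 0.0, 14.0
    q_lo = net_charge(peptide, lo, pka_set).net_charge
    q_hi = net_charge(peptide, hi, pka_set).net_charge
    if not (q_lo > 0.0 > q_hi):
        raise NoIsoelectricPointError(
            "no isoelectric point: net charge does not change sign on pH [0, 14]"
        )
    mid = 0.5 * (lo + hi)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(peptide, mid, pka_set).net_charge
        if abs(q) < tol:
            break
        if q > 0.0:
            lo = mid
        else:
            hi = mid
    return round(mid, decimals) if decimals is not None else mid


def molecular_weight(peptide: PeptideSpec, mode: str = "average") -> float:
    """Molecular mass in g/mol (see :meth:`PeptideSpec.molecular_weight`)."""
    return peptide.molecular_weight(mode)


def label_for_charge(q: float) -> str:
    """Verbal category for a site's |fractional charge|."""
    a = abs(q)
    if a >= LABEL_THRESHOLDS["charged"]:
        return "charged"
    if a >= LABEL_THRESHOLDS["mostly_charged"]:
        return "mostly_charged"
    if a > LABEL_THRESHOLDS["mixed"]:
        return "mixed"
    if a > LABEL_THRESHOLDS["mostly_neutral"]:
        return "mostly_neutral"
    return "neutral"


def charge_state_model(
    peptide: PeptideSpec, pH: float, pka_set: PKaSet = BJELLQVIST
) -> ChargeModel:
    """Full per-site charge state of ``peptide`` at ``pH``, with labels."""
    sites = ionizable_sites(peptide, pka_set)
    if not sites:
        raise PeptideValidationError("peptide has no ionizable sites")
    charges = tuple((s, fractional_charge(s, pH)) for s in sites)
    q = sum(c for _, c in charges)
    return ChargeModel(
        pH=pH,
        site_charges=charges,
        net_charge=q,
        rounded_net_charge=_round_half_away(q),
        site_labels=tuple(label_for_charge(c) for _, c in charges),
    )
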