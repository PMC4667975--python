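"""Force-field parameter tables and pairwise coefficient assembly.

The pairwise energy model is the AutoDock4 function: a weighted sum of a
12-6 van der Waals term (replaced by a 12-10 term for hydrogen-bonding
pairs), a screened Coulomb term with a sigmoidal distance-dependent
dielectric, and a Gaussian-damped pairwise desolvation term.  Per-type
parameters (equilibrium diameters Rii, well depths epsii, atomic volumes,
solvation parameters, hydrogen-bond classes) ship as a packaged data file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "AtomTypeRecord",
    "FFParameters",
    "UnknownAtomTypeError",
    "load_default_parameters",
]

# hbond codes from the parameter file
_DONOR_CODES = {1, 2}
_ACCEPTOR_CODES = {3, 4, 5}


class UnknownAtomTypeError(KeyError):
    """An AutoDock atom-type code has no record in the parameter table."""

    def __init__(self, ad_type: str):
        super().__init__(ad_type)
        self.ad_type = ad_type

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"unparameterized AutoDock atom type: {self.ad_type!r}"


@dataclass(frozen=True)
class AtomTypeRecord:
    ad_type: str
    Rii: float          # equilibrium diameter, A
    epsii: float        # well depth, kcal/mol
    vol: float          # atomic volume, A^3
    solpar: float       # atomic solvation parameter
    Rij_hb: float       # equilibrium H-bond distance, A (acceptors)
    epsij_hb: float     # H-bond well depth, kcal/mol (acceptors)
    hbond: int          # 0 none / 1-2 donor-H / 3-5 acceptor

    @property
    def is_donor_h(self) -> bool:
        return self.hbond in _DONOR_CODES

    @property
    def is_acceptor(self) -> bool:
        return self.hbond in _ACCEPTOR_CODES


@dataclass
class FFParameters:
    """Parameter set: per-type records, term weights and global constants."""

    records: dict[str, AtomTypeRecord]
    # AD4.1 "bound" free-energy model weights
    w_vdw: float = 0.1662
    w_hbond: float = 0.1209
    w_elec: float = 0.1406
    w_sol: float = 0.1322
    # desolvation width (A) and charge-dependent solvation parameter
    sigma: float = 3.6
    qsolpar: float = 0.01097
    # Coulomb constant for q in e, r in A, E in kcal/mol
    coulomb: float = 332.06363
    # Mehler-Solmajer sigmoidal dielectric eps(r) = A + B / (1 + k exp(-lam B r))
    diel_A: float = -8.5525
    diel_eps0: float = 78.4
    diel_lambda: float = 0.003627
    diel_k: float = 7.7839
    # explicit-pair nonbonded cutoff and vdW clash ceiling
    nb_cutoff: float = 8.0
    vdw_clamp: float = 1.0e5
    _pair_cache: dict = field(default_factory=dict, repr=False)

    def record(self, ad_type: str) -> AtomTypeRecord:
        try:
            return self.records[ad_type]
        except KeyError:
            raise UnknownAtomTypeError(ad_type) from None

    def has_type(self, ad_type: str) -> bool:
        return ad_type in self.records

    def vdw_radius(self, ad_type: str) -> float:
        """van der Waals radius Rii/2 (used e.g. by the clash rule)."""
        return 0.5 * self.record(ad_type).Rii

    def epsilon(self, r):
        """Sigmoidal distance-dependent dielectric eps(r); vectorized."""
        B = self.diel_eps0 - self.diel_A
        return self.diel_A + B / (1.0 + self.diel_k * np.exp(-self.diel_lambda * B * np.asarray(r, dtype=float)))

    def pair_coefficients(self, ti: str, tj: str) -> tuple[float, float, bool]:
        """Return (repulsive, attractive, is_hbond) coefficients for a type pair.

        For a normal pair these are the 12-6 coefficients (A, B) with the
        minimum at Rij = (Rii+Rjj)/2 and depth sqrt(epsii*epsjj); for a
        donor-H/acceptor pair the 12-10 coefficients (C, D) with the minimum
        at the acceptor's Rij_hb and depth epsij_hb.
        """
        key = (ti, tj) if ti <= tj else (tj, ti)
        hit = self._pair_cache.get(key)
        if hit is not None:
            return hit
        ri, rj = self.record(ti), self.record(tj)
        hb = (ri.is_donor_h and rj.is_acceptor) or (rj.is_donor_h and ri.is_acceptor)
        if hb:
            acc = rj if rj.is_acceptor else ri
            req, eps = acc.Rij_hb, acc.epsij_hb
            # 12-10 with minimum of depth eps at req
            out = (5.0 * eps * req**12, 6.0 * eps * req**10, True)
        else:
            req = 0.5 * (ri.Rii + rj.Rii)
            eps = math.sqrt(ri.epsii * rj.epsii)
            out = (eps * req**12, 2.0 * eps * req**6, False)
        self._pair_cache[key] = out
        return out

    def solvation_s(self, ad_type: str, charge: float) -> float:
        """Charge-augmented atomic solvation parameter S_i."""
        rec = self.record(ad_type)
        return rec.solpar + self.qsolpar * abs(charge)


def load_default_parameters() -> FFParameters:
    """Load the packaged AutoDock4 parameter table."""
    text = resources.files("flexdock").joinpath("data/ad4_params.dat").read_text()
    records: dict[str, AtomTypeRecord] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        t, rii, eps, vol, sol, rhb, ehb, hb = line.split()
        records[t] = AtomTypeRecord(t, float(rii), float(eps), float(vol),
                                    float(sol), float(rhb), float(ehb), int(hb))
    if not all(r.epsii > 0 for r in records.values()):
        raise ValueError("parameter table contains non-positive well depths")
    return FFParameters(records=records)


_DEFAULT: FFParameters | None = None


def default_parameters() -> FFParameters:
    """Shared default parameter set (loaded once)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_default_parameters()
    return _DEFAULT
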