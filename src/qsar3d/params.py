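"""Element parameter tables for lattice field evaluation.

Van der Waals radii R (Å) and well depths ε (kcal/mol) follow the
Tripos-force-field style parameterisation commonly used for molecular
interaction fields: the 6-12 potential between probe and atom uses the
sum of radii and the geometric mean of well depths. Elements absent
from the table raise rather than silently defaulting.
"""

from __future__ import annotations

# element symbol -> (vdW radius Å, well depth kcal/mol)
LJ_PARAMS: dict[str, tuple[float, float]] = {
    "H": (1.50, 0.042),
    "C": (1.70, 0.107),
    "N": (1.55, 0.095),
    "O": (1.52, 0.116),
    "F": (1.47, 0.109),
    "P": (1.80, 0.314),
    "S": (1.80, 0.314),
    "Cl": (1.75, 0.314),
    "Br": (1.85, 0.434),
    "I": (1.98, 0.623),
}

#: sp3-carbon CoMFA probe: (radius Å, well depth kcal/mol, charge e)
COMFA_PROBE = (1.70, 0.107, 1.0)

#: Coulomb constant converting e²/Å to kcal/mol.
COULOMB_KCAL = 332.0636


def lj_params(element: str) -> tuple[float, float]:
    """Return (vdW radius, well depth) for *element*; raise on unknown."""
    try:
        return LJ_PARAMS[element]
    except KeyError:
        raise KeyError(
            f"no Lennard-Jones parameters for element {element!r}; "
            f"known elements: {sorted(LJ_PARAMS)}"
        ) from None


def vdw_radius(element: str) -> float:
    return lj_params(element)[0]
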