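"""Antioxidant registry: identities, spectral coefficients, stoichiometries.

The chain-breaking antioxidants handled here fall into three headgroup
classes with distinct radical-trapping stoichiometries:

``chromanol``
    alpha-tocopherol and analogues.  Neither the chromanol nor its
    chromanoxyl radical reacts appreciably with oxygen, so each molecule
    traps two peroxyl radicals (n = 2); chromanols are the conventional
    reference for calibrating the radical flux of an azo initiator.
``ubiquinol``
    methoxy-substituted quinols (ubiquinol-6/-10 and decyl/TPP-linked
    analogues).  Semiquinone autooxidation is slow, n is slightly below 2.
``plastoquinol``
    methyl-substituted quinols (SkQ1H2, decPQH2).  Their semiquinones are
    readily oxidized by dissolved oxygen, which roughly halves the
    stoichiometry (n ~ 1).

Quinol quantitation uses the 290-nm absorbance maximum of the reduced
form; kinetic monitoring of antioxidant expenditure uses the
oxidized-minus-reduced difference band near 281 nm.  The two coefficients
are stored separately: published quantitation values are exact, while the
281-nm difference coefficients default to the 290-nm values as a
provisional stand-in and should be overridden when measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import ValidationError

ANTIOXIDANT_CLASSES = ("ubiquinol", "plastoquinol", "chromanol")

#: Default radicals trapped per molecule, by headgroup class.
DEFAULT_STOICHIOMETRY = {"chromanol": 2.0, "ubiquinol": 1.8, "plastoquinol": 1.0}

#: Standard literature quantitation coefficient for chromanols (M^-1 cm^-1,
#: alpha-tocopherol near 292 nm in ethanol); not used for quinols.
CHROMANOL_EPSILON = 3270.0


@dataclass
class AntioxidantSpec:
    """Identity and spectral/stoichiometric parameters of one antioxidant.

    Parameters
    ----------
    name : str
        Compound label, e.g. ``"Q10H2"``.
    aox_class : {"ubiquinol", "plastoquinol", "chromanol"}
        Headgroup class; determines the default stoichiometry.
    epsilon_quinol_290 : float
        Molar absorptivity of the reduced form at the 290-nm quantitation
        wavelength, M^-1 cm^-1.  Must be positive.
    nominal_stoichiometry : float, optional
        Radicals trapped per molecule; defaults by class (chromanol -> 2).
    monitor_wavelength : float
        Wavelength (nm) used for oxidized-minus-reduced kinetic tracking.
    epsilon_diff_monitor : float or None
        Difference ("oxidized minus reduced") molar absorptivity at the
        monitor wavelength, M^-1 cm^-1.  ``None`` means not configured.
    """

    name: str
    aox_class: str
    epsilon_quinol_290: float
    nominal_stoichiometry: float | None = None
    monitor_wavelength: float = 281.0
    epsilon_diff_monitor: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.aox_class not in ANTIOXIDANT_CLASSES:
            raise ValidationError(
                f"unknown antioxidant class {self.aox_class!r}; "
                f"expected one of {ANTIOXIDANT_CLASSES}"
            )
        if not self.epsilon_quinol_290 > 0:
            raise ValidationError("epsilon_quinol_290 must be > 0")
        if self.nominal_stoichiometry is None:
            self.nominal_stoichiometry = DEFAULT_STOICHIOMETRY[self.aox_class]
        if self.nominal_stoichiometry < 0:
            raise ValidationError("nominal_stoichiometry must be >= 0")
        if self.epsilon_diff_monitor is not None and not self.epsilon_diff_monitor > 0:
            raise ValidationError("epsilon_diff_monitor must be > 0 when given")

    def with_(self, **changes) -> "AntioxidantSpec":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


def _spec(name, cls, eps):
    return AntioxidantSpec(
        name=name,
        aox_class=cls,
        epsilon_quinol_290=eps,
        epsilon_diff_monitor=eps,  # provisional: 290-nm value reused at 281 nm
    )


#: Built-in registry of the compounds handled by the pipeline.
REGISTRY: dict[str, AntioxidantSpec] = {
    s.name: s
    for s in (
        _spec("Q10H2", "ubiquinol", 3940.0),
        _spec("Q6H2", "ubiquinol", 4890.0),
        _spec("decUQH2", "ubiquinol", 4140.0),
        _spec("MitoQH2", "ubiquinol", 4140.0),
        _spec("SkQ1H2", "plastoquinol", 3540.0),
        _spec("decPQH2", "plastoquinol", 3540.0),
        _spec("alpha-tocopherol", "chromanol", CHROMANOL_EPSILON),
        _spec("HPMC", "chromanol", CHROMANOL_EPSILON),
    )
}


def get_antioxidant(name: str) -> AntioxidantSpec:
    """Look up a registry entry by name (case-sensitive)."""
    try:
        return REGISTRY[name]
    except KeyError:
        raise ValidationError(
            f"unknown antioxidant {name!r}; known: {sorted(REGISTRY)}"
        ) from None
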