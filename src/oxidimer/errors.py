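"""Exception hierarchy."""


class OxidimerError(Exception):
    """Base class for all package errors."""


class MissingDataError(OxidimerError):
    """A required energy field or species is absent."""


class MissingSpeciesError(MissingDataError):
    """A reaction participant is not present in the species registry."""


class HeptaneProtonError(OxidimerError):
    """Raised when a bare-proton free energy is requested in heptane.

    No literature value exists for the proton solvation free energy in
    heptane; protonation/deprotonation stages must be evaluated as summed
    pairs there (the proton cancels).
    """


class DuplicateRecordError(OxidimerError):
    """Duplicate (species, phase, level) key in a registry."""


class RegistryFormatError(OxidimerError):
    """A species/reaction/TS file violates the documented format."""


class StoichiometryError(OxidimerError):
    """Two routes compared by a Hess check have different net stoichiometry,
    or a coupling's H-atom bookkeeping does not match the O2 reduction."""


class DoubleCorrectionError(OxidimerError):
    """A BSSE correction was applied twice to the same stage energy."""
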