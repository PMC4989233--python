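"""Exception hierarchy for refinecomplex.

Every named failure mode of the library maps onto one of these classes so
that callers (and the CLI) can translate them into distinct exit codes.
"""


class RefineComplexError(Exception):
    """Base class for all refinecomplex errors."""


# --- structure I/O ---------------------------------------------------------
class MalformedPDB(RefineComplexError):
    """A PDB line or file could not be parsed."""


class ChainCountError(RefineComplexError):
    """Fewer than two protein chains in the input complex."""


class IncompleteBackbone(RefineComplexError):
    """A residue is missing one of its N/CA/C/O backbone atoms."""


class SequenceMismatch(RefineComplexError):
    """Chains expected to be sequence-identical differ."""


class DegenerateGeometry(RefineComplexError):
    """Too few atoms to define a rigid superposition."""


class GroupMismatch(RefineComplexError):
    """Symmetry group incompatible with the structure (chain count/size)."""


# --- interface / restraints ------------------------------------------------
class MissingCA(RefineComplexError):
    """A residue lacks a CA atom required for interface detection."""


class WeightError(RefineComplexError):
    """Restraint weights non-positive or mis-ordered."""


# --- energy ----------------------------------------------------------------
class ParameterMissing(RefineComplexError):
    """An atom or residue type is absent from the force-field tables."""


class AtomMismatch(RefineComplexError):
    """A restraint refers to an atom the structure does not contain."""


class NonFiniteEnergy(RefineComplexError):
    """Energy or coordinates became non-finite (geometry blow-up)."""


# --- sampling / protocol ---------------------------------------------------
class EmptyLibrary(RefineComplexError):
    """A residue type has no entry in the rotamer library."""


class AllRunsFailed(RefineComplexError):
    """Every ensemble member of a refinement pipeline failed."""


# --- assessment ------------------------------------------------------------
class MappingError(RefineComplexError):
    """Model and reference chains/residues cannot be put in correspondence."""


class EmptyInterface(RefineComplexError):
    """The reference complex has no interface residues."""


class NoNativeContacts(RefineComplexError):
    """The reference complex has no inter-chain residue contacts."""


class DomainError(RefineComplexError):
    """Metric values outside their mathematical domain."""


# --- synthetic fixtures ----------------------------------------------------
class PackingFailure(RefineComplexError):
    """Could not place chains without steric clash within bounded retries."""
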