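"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`MedcrosswalkError`, so callers can catch domain failures without
swallowing programming errors.
"""


class MedcrosswalkError(Exception):
    """Base class for all package errors."""


class FormatError(MedcrosswalkError, ValueError):
    """An input file or code string does not have the expected shape."""


class NDCAmbiguityError(FormatError):
    """An undashed 10-digit NDC: the deficient segment cannot be located."""


class IntegrityError(MedcrosswalkError, ValueError):
    """Input data violate a structural invariant (e.g. duplicate item ids)."""


class ConfigurationError(MedcrosswalkError, ValueError):
    """A parameter references something that does not exist (vocabulary,
    attribute, hub system) or is internally inconsistent."""


class ConceptNotFoundError(MedcrosswalkError, KeyError):
    """A (vocabulary, concept_id) pair is absent from the vocabulary graph."""


class ValidationError(MedcrosswalkError, ValueError):
    """A user-supplied object (criteria, config) fails its invariants."""
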