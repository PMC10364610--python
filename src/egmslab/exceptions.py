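"""Exception hierarchy for egmslab."""


class EgmslabError(Exception):
    """Base class for all egmslab errors."""


class InvalidParameterError(EgmslabError, ValueError):
    """A physical parameter violates its domain (e.g. non-positive conductivity)."""


class SingularPointError(EgmslabError, ValueError):
    """Evaluation requested exactly at a source singularity."""


class OutOfDomainError(EgmslabError, ValueError):
    """Evaluation requested outside the domain of validity of a formula."""


class InvalidPoseError(EgmslabError, ValueError):
    """Catheter pose places an electrode below the endocardium."""


class DegenerateSignalError(EgmslabError, ValueError):
    """A signal operation was applied to an identically-zero trace."""


class InvalidWindowError(EgmslabError, ValueError):
    """A requested time window lies outside the overlap of the traces."""


class GridError(EgmslabError, ValueError):
    """Finite-difference grid is inconsistent with the slab geometry."""
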