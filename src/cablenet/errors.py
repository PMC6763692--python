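"""Exception hierarchy shared across the simulator."""


class CablenetError(Exception):
    """Base class for all simulator errors."""


class InvalidGeometryError(CablenetError):
    """Non-positive length/diameter/Ra/cm/nseg in a section specification."""


class InvalidTopologyError(CablenetError):
    """Section graph is not a rooted tree (cycle, multiple roots, bad parent)."""


class ConfigurationError(CablenetError):
    """Inconsistent run or network configuration."""


class ParameterError(CablenetError):
    """Out-of-range mechanism or solver parameter (dt <= 0, tau <= 0, ...)."""


class RegistrationError(CablenetError):
    """Duplicate or malformed mechanism registration."""


class WiringError(CablenetError):
    """Dangling event wiring: unknown source gid, unpaired gap instance."""


class NumericalStateError(CablenetError):
    """Non-finite voltage or state handed to a kernel."""


class SingularSystemError(CablenetError):
    """Zero pivot during tree Gaussian elimination."""


class IntegrityError(CablenetError):
    """Cross-reference violation: stale node index, model/archive mismatch."""


class ArchiveError(CablenetError):
    """Unreadable, truncated or version-mismatched on-disk archive."""


class StateError(CablenetError):
    """Operation invoked at an illegal simulation time (e.g. mid-step checkpoint)."""
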