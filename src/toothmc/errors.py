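"""Exception hierarchy for toothmc."""


class ToothMCError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ToothMCError):
    """Invalid parameters, infeasible geometry requests, or bad config files."""


class EmptyGeometryError(ToothMCError):
    """A voxel grid contains no tooth voxels where some are required."""


class VacuumMediumError(ConfigurationError):
    """A medium with mu_t <= 0 was encountered where transport needs mu_t > 0."""


class NoDetectionError(ToothMCError):
    """An analysis was requested on a run that detected no photons."""


class ReplayIntegrityError(ToothMCError):
    """A replayed photon did not reproduce its recorded exit state."""


class ComparisonError(ToothMCError):
    """Two runs were compared whose configurations differ beyond the WSR flag."""
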