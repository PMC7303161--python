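"""Exception hierarchy shared across the pipeline stages."""


class RVKinergyError(Exception):
    """Base class for all package errors."""


class ParameterError(RVKinergyError):
    """An argument is outside its valid range (e.g. non-positive BSA)."""


class SpecificationError(RVKinergyError):
    """A phantom or cohort specification is internally inconsistent."""


class SizingError(RVKinergyError):
    """Requested geometry does not fit in the voxel grid."""


class GeometryError(RVKinergyError):
    """Degenerate or invalid geometric input (empty mask, bad polygon)."""


class CoverageError(RVKinergyError):
    """A resampling operation left the region of interest outside the FOV."""


class TimingError(RVKinergyError):
    """Cardiac phase detection failed (e.g. monotone volume curve)."""


class StatisticsError(RVKinergyError):
    """A statistic is undefined for the given input (constant series etc.)."""
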