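"""Exception hierarchy.

All package errors derive from :class:`TidalMarshError` so callers can catch
one base class; the subclasses mirror the distinct failure contracts of the
individual stages (bad configuration, co-registration problems, degenerate
statistics, numerical stability).
"""


class TidalMarshError(Exception):
    """Base class for all tidalmarsh errors."""


class InvalidConfigError(TidalMarshError, ValueError):
    """A configuration value violates its documented constraint."""


class InvalidArgumentError(TidalMarshError, ValueError):
    """An operation argument violates its precondition."""


class CoRegistrationError(TidalMarshError, ValueError):
    """Grids that must share shape/resolution/origin do not."""


class SemanticTypeError(TidalMarshError, TypeError):
    """A raster of the wrong semantic kind was supplied (e.g. slope of a
    reflectance grid)."""


class UndefinedMetricError(TidalMarshError, ValueError):
    """A metric is undefined for the given input (e.g. skipped fraction with
    no high tides)."""


class InsufficientDataError(TidalMarshError, ValueError):
    """Too few valid observations to compute the requested statistic."""


class UnimodalDistributionError(TidalMarshError, ValueError):
    """Fewer than two density modes were found where a bimodal distribution
    is required (NDVI thresholding). Callers may fall back to a manual
    threshold."""


class StabilityError(TidalMarshError, ValueError):
    """An explicit time step exceeds the scheme's stability bound.

    Carries the largest admissible step in :attr:`admissible_dt`.
    """

    def __init__(self, dt: float, admissible_dt: float):
        self.dt = dt
        self.admissible_dt = admissible_dt
        super().__init__(
            f"time step dt={dt:g} exceeds the stability bound; "
            f"largest admissible dt is {admissible_dt:g}"
        )
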