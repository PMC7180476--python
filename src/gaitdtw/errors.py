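"""Exception hierarchy.

All package errors derive from :class:`GaitDtwError` so callers can catch
one type. The two degenerate numerical situations the method runs into —
a constant series (zero variance, so z-normalisation is undefined) and a
warping band too narrow to admit any path — get their own classes because
callers need to distinguish them: the first is a data problem, the second
a parameter problem.
"""


class GaitDtwError(Exception):
    """Base class for all errors raised by gaitdtw."""


class DegenerateSeriesError(GaitDtwError):
    """A series is constant (sigma = 0) or too short to z-normalise."""


class BandInfeasibleError(GaitDtwError):
    """No warping path exists under the requested band width.

    Raised when ``|len(u) - len(v)| > maxsamp``: the boundary-anchored
    path cannot stay within the band.
    """


class RefinementInfeasibleError(GaitDtwError):
    """Every lag in the refinement scan produced an invalid window."""


class ValidationError(GaitDtwError):
    """A domain object violates one of its invariants."""


class FileFormatError(GaitDtwError):
    """A delimited-text input file could not be parsed."""
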