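"""Exception types raised by the strip-reading pipeline.

Failures that a caller is expected to handle programmatically (a photo in
which no card can be found, a strip crop in which too few fields are
visible) are distinct classes carrying diagnostics, so they can be told
apart from programming errors and from invalid configuration.
"""

from __future__ import annotations


class UristripError(Exception):
    """Base class for all package-specific errors."""


class LayoutError(UristripError):
    """A strip/card layout document violates the schema or its invariants."""


class DetectionFailure(UristripError):
    """Template (reference card or strip) could not be located in the scene.

    Attributes
    ----------
    n_matches_kept, n_inliers : int
        Matching diagnostics at the point of failure.
    reason : str
        Human-readable cause (too few matches, degenerate quad, ...).
    """

    def __init__(self, reason: str, n_matches_kept: int = 0, n_inliers: int = 0):
        super().__init__(f"detection failed: {reason} "
                         f"(matches_kept={n_matches_kept}, inliers={n_inliers})")
        self.reason = reason
        self.n_matches_kept = n_matches_kept
        self.n_inliers = n_inliers


class FieldDetectionFailure(UristripError):
    """Too few candidate squares to localize the strip's test fields."""


class GridCompletionFailure(UristripError):
    """A detected field grid cannot be completed to the expected count
    without extrapolating implausibly many points."""
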