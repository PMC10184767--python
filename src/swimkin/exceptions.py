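"""Exception hierarchy for the swimkin pipeline."""


class SwimkinError(Exception):
    """Base class for all swimkin errors."""


class FormatError(SwimkinError):
    """A file does not conform to the expected on-disk format."""


class TrialRejected(SwimkinError):
    """A trial fails the steady-swimming acceptance rule (≥3 locomotor cycles).

    Carries a list of human-readable reasons.
    """

    def __init__(self, *reasons: str):
        self.reasons = list(reasons)
        super().__init__("; ".join(reasons) if reasons else "trial rejected")


class MidlineError(SwimkinError):
    """Midline extraction failed for a frame."""


class AmbiguousSilhouette(MidlineError):
    """More than one large foreground component in a binarized frame."""


class MissingLandmark(SwimkinError):
    """A required landmark (e.g. a pectoral fin tip) is absent from the track."""


class FilterError(SwimkinError):
    """Invalid filtering request (e.g. cutoff at or above Nyquist)."""


class FlatSeries(SwimkinError):
    """No oscillation detectable in a scalar series."""
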