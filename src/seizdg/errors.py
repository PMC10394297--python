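"""Exception types shared across the package."""


class SeizdgError(Exception):
    """Base class for package errors."""


class ValidationError(SeizdgError, ValueError):
    """Invalid values (NaN/Inf, out-of-range labels, bad parameters)."""


class ConfigurationError(SeizdgError, ValueError):
    """Structurally impossible configuration (odd feature split, one patient)."""


class MissingChannelError(SeizdgError, KeyError):
    """A requested channel name is absent from the recording."""


class UnsupportedFormatError(SeizdgError, ValueError):
    """File layout the reader does not support (e.g. mixed sampling rates)."""


class EmptyBatchError(SeizdgError, ValueError):
    """Segmentation would produce no segments."""


class LabelingError(SeizdgError, ValueError):
    """Annotation does not cover a segment window."""


class StateError(SeizdgError, RuntimeError):
    """Operation requires state that is not initialized (centers, training)."""


class TrainingDivergenceError(SeizdgError, RuntimeError):
    """A loss term became non-finite during training."""

    def __init__(self, term: str, epoch: int):
        super().__init__(f"non-finite loss term {term!r} at epoch {epoch}")
        self.term = term
        self.epoch = epoch
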