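"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """Invalid configuration (HU tables, geometry, protocol parameters)."""


class InsufficientCyclesError(RuntimeError):
    """Surrogate trace does not contain enough breathing cycles to anchor phase."""


class EmptyPhaseBinError(ValueError):
    """A phase bin contains no projections and cannot be reconstructed."""

    def __init__(self, bin_index: int, n_bins: int):
        self.bin_index = bin_index
        self.n_bins = n_bins
        super().__init__(
            f"phase bin {bin_index} of {n_bins} holds no projections; "
            "cannot reconstruct an empty bin"
        )


class InsertDetectionError(RuntimeError):
    """A tracked insert could not be detected in a reconstructed volume."""


class MtfFitError(RuntimeError):
    """Gaussian MTF fit failed or had too few valid points."""


class NoiseAlreadyAppliedError(RuntimeError):
    """Poisson noise was requested on a projection set that already carries noise."""
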