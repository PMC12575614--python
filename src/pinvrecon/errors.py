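"""Exception types shared across the package.

Invalid arguments raise plain :class:`ValueError`; the classes below cover the
domain-specific failure modes that callers may want to handle separately.
"""


class PinvReconError(Exception):
    """Base class for package-specific errors."""


class DegenerateInputError(PinvReconError, ValueError):
    """An input is structurally valid but degenerate (e.g. an empty mask)."""


class DegenerateRegularizationError(PinvReconError, ValueError):
    """Regularization removed every singular value / eigenvalue."""


class NotPositiveDefiniteError(PinvReconError, ValueError):
    """Cholesky factorization failed; the Gram matrix is not positive-definite.

    Increase ``lambda_rel`` (Tikhonov) to restore positive-definiteness.
    """


class NumericalConsistencyError(PinvReconError, ValueError):
    """A numerical sanity check failed (e.g. a significantly negative eigenvalue
    of a Hermitian PSD matrix)."""


class SingularMatrixError(PinvReconError, ValueError):
    """A triangular factor is numerically singular and no regularization was
    requested."""


class ResourceLimitError(PinvReconError, MemoryError):
    """Predicted memory use exceeds the configured cap.

    Remedies: mask the image grid (``circular_mask``), accumulate the Gram
    matrix coil-by-coil (``coilwise_gram``), or use the block-wise Cholesky
    route (``pinv_cholesky_block``).
    """
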