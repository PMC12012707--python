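"""Exception types shared across the package."""


class DegenerateDataError(ValueError):
    """Raised when an estimator receives input it cannot fit.

    Examples: no labeled observations for the labeled-moments base learner,
    or a numerically singular within-class covariance in the E step.
    """
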