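"""Exception types shared across the pipeline.

``ValueError`` is raised for plain invalid arguments; the classes here mark
failures that callers (and the CLI exit codes) treat specially.
"""


class ValidationError(ValueError):
    """An input file or panel violates the pipeline's schema contract.

    The message names the offending file/site/row where known. Mapped to
    CLI exit code 2.
    """


class EstimationError(RuntimeError):
    """A statistical fit could not be carried out (rank deficiency,
    degenerate sample, non-concave response where concavity is required).
    Mapped to CLI exit code 3.
    """
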