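"""Exception types shared across the pipeline stages."""


class CountyPrevError(Exception):
    """Base class for package-specific errors."""


class SchemaError(CountyPrevError):
    """A file or table violates its documented schema.

    Carries enough context (file, row, column) to locate the offending value.
    """

    def __init__(self, message, *, file=None, row=None, column=None):
        parts = [message]
        if file is not None:
            parts.append(f"file={file!r}")
        if row is not None:
            parts.append(f"row={row}")
        if column is not None:
            parts.append(f"column={column!r}")
        super().__init__("; ".join(str(p) for p in parts))
        self.file, self.row, self.column = file, row, column


class DataError(CountyPrevError):
    """Inputs are structurally valid but unusable (e.g. empty after filtering)."""


class DegenerateFitError(CountyPrevError):
    """A regression cannot be fit (too few cells, zero variance, constant outcome)."""


class CollinearityError(DegenerateFitError):
    """Design matrix is rank deficient."""

    def __init__(self, columns):
        super().__init__(f"design matrix is rank deficient; dependent columns: {list(columns)}")
        self.columns = list(columns)


class ConvergenceError(CountyPrevError):
    """Iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message, trace=None, stage=None):
        prefix = f"[{stage}] " if stage else ""
        super().__init__(prefix + message)
        self.trace = trace or []
        self.stage = stage


class SeparationError(ConvergenceError):
    """Complete or quasi-complete separation diagnosed during a logistic fit."""


class UndefinedMetricError(CountyPrevError):
    """A validation metric is undefined for the given inputs."""


class ValidationInfeasibleError(CountyPrevError):
    """No county qualifies as a gold standard under the given threshold."""
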