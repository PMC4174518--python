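"""Exception hierarchy shared across the pipeline stages."""


class DhmError(Exception):
    """Base class for all package errors."""


class ValidationError(DhmError):
    """A configuration value or input violates its contract (exit code 2)."""


class StageError(DhmError):
    """A pipeline stage failed on otherwise valid input (exit code 3)."""

    def __init__(self, stage: str, message: str, frame: int | None = None):
        self.stage = stage
        self.frame = frame
        where = f"{stage}" if frame is None else f"{stage} (frame {frame})"
        super().__init__(f"[{where}] {message}")


class NoBlobError(StageError):
    """No cell-like blob found in a phase image handed to the sphere fitter."""

    def __init__(self, message: str):
        super().__init__("sphere_fit", message)


class FitConvergenceError(StageError):
    """Nonlinear least squares did not converge; carries residual diagnostics."""

    def __init__(self, message: str, rmse: float | None = None):
        self.rmse = rmse
        super().__init__("sphere_fit", message)


class CarrierError(StageError):
    """No usable off-axis carrier peak could be found in a hologram spectrum."""

    def __init__(self, message: str):
        super().__init__("holography", message)
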