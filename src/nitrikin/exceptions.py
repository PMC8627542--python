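"""Exception hierarchy for nitrikin."""


class NitrikinError(Exception):
    """Base class for all package-specific failures."""


class ValidationError(NitrikinError):
    """Input data or configuration violates a documented invariant."""


class FitConvergenceError(NitrikinError):
    """Nonlinear least squares failed to converge after all restarts.

    Carries the per-restart diagnostics so the failure is auditable.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class SimulationError(NitrikinError):
    """ODE integration produced a non-finite or otherwise invalid solution."""
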