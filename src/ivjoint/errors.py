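"""Exception hierarchy shared across the package."""


class IVJointError(Exception):
    """Base class for all package-specific errors."""


class InputError(IVJointError, ValueError):
    """Malformed or inconsistent user input (labels, shapes, counts)."""


class DegenerateGeometryError(IVJointError, ValueError):
    """Point/landmark configuration does not determine the requested frame."""


class TopologyError(IVJointError, ValueError):
    """Mesh is not a closed, consistently oriented surface."""


class AssemblyError(IVJointError, ValueError):
    """Multibody chain specification is not a valid single-ground simple path."""


class SingularJointError(IVJointError, ValueError):
    """A loaded degree of freedom has zero stiffness; equilibrium is undefined."""


class ConvergenceError(IVJointError, RuntimeError):
    """Solver failed to reach the requested residual tolerance."""

    def __init__(self, message, residual_force=None, residual_torque=None):
        super().__init__(message)
        self.residual_force = residual_force
        self.residual_torque = residual_torque


class StepSizeError(IVJointError, RuntimeError):
    """Transient integration became unstable (energy growth without input)."""


class ConfigError(IVJointError, ValueError):
    """Configuration file failed schema validation."""

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))
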