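"""Exception hierarchy for changesim."""


class ChangesimError(Exception):
    """Base class for all changesim errors."""


class CyclicGraphError(ChangesimError):
    """The path set contains a directed cycle; no variable can cause itself."""


class OverExplainedNodeError(ChangesimError):
    """A node's parents explain more than its total (unit) variance."""

    def __init__(self, node: str, explained: float):
        self.node = node
        self.explained = explained
        super().__init__(
            f"node {node!r} is over-explained: parents account for "
            f"{explained:.4f} of a unit variance, leaving a non-positive residual"
        )


class UnknownNodeError(ChangesimError):
    """A referenced variable is not a node of the model."""


class CollinearityError(ChangesimError):
    """The predictor (co)variance matrix is singular."""


class DegenerateDifferenceError(ChangesimError):
    """The difference score has zero variance, so its correlation is undefined."""


class CalibrationError(ChangesimError):
    """Calibration targets are missing, inconsistent, or infeasible."""


class SampleSizeError(ChangesimError):
    """Too few rows for the requested operation."""


class AggregateFitError(ChangesimError):
    """Every requested analysis failed; carries the per-analysis errors."""

    def __init__(self, errors: dict):
        self.errors = dict(errors)
        detail = "; ".join(f"{k}: {v}" for k, v in self.errors.items())
        super().__init__(f"all analyses failed ({detail})")
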