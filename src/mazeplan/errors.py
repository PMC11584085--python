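"""Exception hierarchy shared across the package."""


class MazeplanError(Exception):
    """Base class for all package errors."""


class InvalidLocationError(MazeplanError):
    """A tile coordinate is out of bounds or on a wall."""


class InvalidMoveError(MazeplanError):
    """An agent move targets a wall or a non-adjacent tile."""


class NoPathError(MazeplanError):
    """Two tiles are not connected by any walkable path."""


class UnobservableRoomError(MazeplanError):
    """A room cannot be fully observed from any reachable tile."""


class MazeValidationError(MazeplanError):
    """A maze violates a structural invariant."""


class ParameterError(MazeplanError):
    """A model parameter is outside its allowed range."""


class NumericalError(MazeplanError):
    """An iterative numerical procedure failed to converge."""


class InsufficientDataError(MazeplanError):
    """Too few decisions for the requested fit."""


class ConfigError(MazeplanError):
    """A configuration file or grid specification is invalid."""


class FixtureError(MazeplanError):
    """A hand-coded fixture maze fails its declared property check."""


class GenerationError(MazeplanError):
    """Random maze generation exceeded its rejection cap."""


class TreeSizeError(MazeplanError):
    """Decision-tree expansion exceeded the configured node cap."""
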