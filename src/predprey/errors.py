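"""Exception types raised by the simulator and analysis layers."""


class PredPreyError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(PredPreyError, ValueError):
    """A configuration violates an invariant (e.g. more agents than cells)."""


class InvalidActionError(PredPreyError, ValueError):
    """An action outside the nine-move encoding was supplied."""


class StaleAgentError(PredPreyError, KeyError):
    """An operation referenced a dead or unknown agent id."""


class NoDataError(PredPreyError, RuntimeError):
    """A training update was requested but the buffer holds no records."""


class UndefinedStatisticError(PredPreyError, ValueError):
    """A spatial statistic was requested on a degenerate configuration."""
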