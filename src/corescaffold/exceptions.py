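"""Typed error signals shared across modules."""


class CoreScaffoldError(Exception):
    """Base class for package errors."""


class UndefinedMetricError(CoreScaffoldError, ValueError):
    """A network metric is mathematically undefined on this graph.

    Raised instead of returning NaN so that degenerate values (e.g.
    assortativity on a regular graph, path length of an empty graph) can
    never silently propagate into downstream statistics. The ``metric``
    attribute names the offending quantity.
    """

    def __init__(self, metric: str, reason: str):
        self.metric = metric
        self.reason = reason
        super().__init__(f"{metric} undefined: {reason}")
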