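"""Exception types shared across the pipeline stages."""


class HubgradError(ValueError):
    """Base class for all package-specific errors."""


class InvalidParameterError(HubgradError):
    """A parameter is outside its documented domain."""


class ModalityError(HubgradError):
    """An operation received a connectivity modality it does not support."""


class DegenerateNodeError(HubgradError):
    """A node has no usable signal (zero row, zero variance, ...)."""

    def __init__(self, nodes, message=None):
        self.nodes = list(nodes)
        super().__init__(message or f"degenerate node(s): {self.nodes}")


class DisconnectedGraphError(HubgradError):
    """The affinity graph splits into several connected components."""

    def __init__(self, labels, message=None):
        self.component_labels = labels
        super().__init__(message or "affinity graph is disconnected")
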