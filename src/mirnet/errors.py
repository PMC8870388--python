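"""Exception types shared across the pipeline stages."""


class MirnetError(Exception):
    """Base class for all package-specific errors."""


class TableFormatError(MirnetError, ValueError):
    """A tabular input file does not match the expected column layout."""


class OntologyStructureError(MirnetError, ValueError):
    """The ontology violates a structural contract (cycle, dangling parent)."""


class NoTestableGenesError(MirnetError, ValueError):
    """The query gene set is empty after intersection with the universe."""


class UndefinedSummaryError(MirnetError, ValueError):
    """Degree statistics requested on a network with no gene nodes."""
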