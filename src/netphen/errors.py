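"""Exception hierarchy shared by all netphen modules."""


class NetphenError(Exception):
    """Base class for all netphen errors."""


class ConfigurationError(NetphenError):
    """A run parameter is out of range or otherwise unusable (user error)."""


class DataIntegrityError(NetphenError):
    """Input tables are internally inconsistent (missing terms, duplicate
    conflicting edges, documents absent from a profile, ...)."""


class UnscorableGeneError(NetphenError):
    """A candidate complex has no linked documents (m = 0) and therefore no
    defined enrichment score."""

    def __init__(self, gene_id: str):
        self.gene_id = gene_id
        super().__init__(f"gene {gene_id!r} has no linked documents (m = 0); "
                         "its complex cannot be scored")
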