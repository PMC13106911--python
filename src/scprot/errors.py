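"""Exception hierarchy shared across the pipeline stages."""


class ScprotError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ScprotError, ValueError):
    """An input file violates its declared format."""


class ParameterError(ScprotError, ValueError):
    """A configuration or algorithm parameter is out of range."""


class IntegrityError(ScprotError, ValueError):
    """Input data violates an integrity constraint (e.g. duplicate keys)."""


class AnnotationLookupError(ScprotError, KeyError):
    """A protein accession has no annotation."""


class PipelineError(ScprotError, RuntimeError):
    """A pipeline stage cannot proceed (e.g. every cell was filtered out)."""
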