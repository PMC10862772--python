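"""Exception hierarchy for graphsv."""


class GraphSVError(Exception):
    """Base class for all graphsv errors."""


class GfaParseError(GraphSVError):
    """Malformed GFA record; message names the offending line number."""


class GafParseError(GraphSVError):
    """Malformed GAF record; message names the offending line number."""
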