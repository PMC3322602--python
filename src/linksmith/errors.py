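"""Exception hierarchy.

Everything raised on purpose derives from :class:`LinksmithError` so callers
can catch the package's failures with a single except clause.
"""


class LinksmithError(Exception):
    """Base class for all errors raised by linksmith."""


class LibraryParseError(LinksmithError):
    """A CIF document could not be parsed into a restraint library."""


class ConsistencyError(LinksmithError):
    """A library violates the dialect's internal cross-references."""


class SerializationError(LinksmithError):
    """An entry cannot be written because an internal reference dangles."""


class EditError(LinksmithError):
    """A graph edit refers to a missing atom/bond or would corrupt the graph."""


class ValenceError(LinksmithError):
    """A heavy atom carries more bond order than its element allows."""


class EmbedError(LinksmithError):
    """Coordinates cannot be generated (e.g. disconnected graph)."""


class CoordinateError(LinksmithError):
    """A restrained atom has no coordinate, or atoms overlap."""


class GroupMismatchError(LinksmithError):
    """A link's side constraint (comp code or group) is not satisfied."""


class SessionError(LinksmithError):
    """A composite-session operation was called out of order or is blocked."""
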