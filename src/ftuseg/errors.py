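"""Exception hierarchy shared across the package."""


class FtusegError(Exception):
    """Base class for all package-specific errors."""


class MaskFormatError(FtusegError, ValueError):
    """A mask or annotation file violates its format contract."""


class UnsupportedGeometryError(MaskFormatError):
    """An annotation feature carries a geometry type other than Polygon."""


class DegeneratePolygonError(FtusegError, ValueError):
    """A polygon ring has fewer than 3 distinct vertices or zero area."""


class PackingError(FtusegError, RuntimeError):
    """The synthetic generator could not place the requested objects."""


class UndefinedDensityError(FtusegError, ValueError):
    """FTU density is requested but the cortex area is zero or absent."""
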