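"""Exception hierarchy.

Input problems (unreadable files, empty images, bad masks) and degenerate-data
problems (nothing measurable) are distinguished so the CLI can map them to
distinct exit codes (2 and 3 respectively).
"""


class VesselMorphError(Exception):
    """Base class for all vesselmorph errors."""


class InputError(VesselMorphError):
    """Unreadable, mis-shaped or otherwise invalid input."""


class NoVesselsError(InputError):
    """A binary vessel image with no foreground pixels."""


class LesionMaskError(InputError):
    """A lesion mask that cannot support region analysis."""


class DegenerateDataError(VesselMorphError):
    """Valid input that yields nothing measurable (e.g. no bifurcations)."""
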