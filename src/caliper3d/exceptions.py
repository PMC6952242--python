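"""Exception hierarchy for caliper3d."""


class Caliper3DError(Exception):
    """Base class for all caliper3d errors."""


class SceneStructureError(Caliper3DError):
    """The scene graph would become invalid (cycle, orphan, duplicate child)."""


class TransformError(Caliper3DError):
    """A transform cannot be represented or decomposed as requested."""


class AnisotropicScaleError(TransformError):
    """A node on the reference-scale path carries a non-uniform scale.

    The zoom correction applied to measured distances is defined only for
    uniform (isotropic) zoom, so anisotropic scale on that path is an error
    rather than a silent approximation.
    """


class ConfigurationError(Caliper3DError):
    """The scene is missing a required piece of configuration
    (e.g. no reference-scale node on the measurement's ancestor path)."""


class GrabStateError(Caliper3DError):
    """Invalid grab/release sequence (e.g. grabbing an element twice)."""


class EdgeNotFoundError(Caliper3DError):
    """The caliper could not locate an intensity edge within the volume."""


class VolumeFormatError(Caliper3DError):
    """A volume file could not be read or written."""


class PhantomSpecError(Caliper3DError):
    """A phantom specification is geometrically or physically invalid."""
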