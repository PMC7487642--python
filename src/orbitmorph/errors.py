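"""Exception vocabulary for the pipeline.

Each stage raises a named error so batch drivers can tabulate failures
per subject instead of aborting the whole run.
"""


class OrbitMorphError(Exception):
    """Base class for all package errors."""


# synthetic phantoms
class DegeneratePhantom(OrbitMorphError):
    """Requested wall displacement exceeds the bone-shell thickness."""


class GridTooSmall(OrbitMorphError):
    """The voxel grid cannot contain the requested cavity plus shell."""


class CalibrationFailed(OrbitMorphError):
    """Bump calibration did not converge within the iteration budget."""


# segmentation
class SeedOutsideWindow(OrbitMorphError):
    """A seed voxel's intensity lies outside the propagation window."""


class EmptySegmentation(OrbitMorphError):
    """Segmentation produced (or was given) an empty mask."""


# cropping
class DegeneratePlane(OrbitMorphError):
    """Three collinear points cannot define a cut plane."""


class AmbiguousSide(OrbitMorphError):
    """The interior reference point lies on the cut plane."""


class OpenMeshError(OrbitMorphError):
    """Operation requires a closed (watertight) mesh."""


class EmptyClip(OrbitMorphError):
    """Plane clip removed the entire mesh."""


class MissingLandmark(OrbitMorphError):
    """A required named landmark is absent."""


class DegenerateCrop(OrbitMorphError):
    """Anterior/posterior planes leave no slab containing the interior."""


# registration
class DegenerateGeometry(OrbitMorphError):
    """Point set too degenerate (e.g. coplanar) for a rigid fit."""


# deviation
class EmptyDeviation(OrbitMorphError):
    """No distance samples available."""


# volumetry
class DegenerateMesh(OrbitMorphError):
    """Mesh has (near-)zero surface area."""


class SectionMismatch(OrbitMorphError):
    """Palatal junction points do not lie on the same coronal section."""


# statistics
class SampleSizeError(OrbitMorphError):
    """Sample size (or variance) inadmissible for the requested test."""


class DegenerateTest(OrbitMorphError):
    """Test statistic undefined (zero variance)."""
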