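"""Exception hierarchy for cytogate.

All package errors derive from :class:`CytogateError` so callers can catch
one base class. User-facing errors (bad files, bad parameters) are kept
distinct from internal invariant failures.
"""


class CytogateError(Exception):
    """Base class for all cytogate errors."""


# --- FCS parsing / writing ------------------------------------------------

class FCSError(CytogateError):
    """Base class for FCS file errors."""


class UnsupportedVersion(FCSError):
    """FCS version string is not one of FCS2.0 / FCS3.0 / FCS3.1."""


class MalformedHeader(FCSError):
    """A header offset field is non-numeric and non-blank."""


class MissingRequiredKeyword(FCSError):
    """A required TEXT keyword ($TOT, $PAR, $DATATYPE, $BYTEORD, $MODE) is absent."""


class UnterminatedValue(FCSError):
    """TEXT segment ended inside a keyword value."""


class LengthMismatch(FCSError):
    """DATA segment byte length disagrees with $TOT/$PAR/$PnB beyond tolerance."""


class UnsupportedBitWidth(FCSError):
    """Integer parameter with non-byte-aligned $PnB."""


class InvalidAmplification(FCSError):
    """$PnE log amplification with non-positive $PnR."""


class SourceUnavailable(CytogateError):
    """Requested event state (comp/xform) has not been computed."""


class DuplicateChannelName(CytogateError):
    """Channel names passed to a Sample constructor are not unique."""


class ShapeMismatch(CytogateError):
    """Matrix shape inconsistent with channel names or metadata."""


class NTooLarge(CytogateError):
    """Subsample size exceeds the number of events."""


# --- Compensation ---------------------------------------------------------

class CompensationError(CytogateError):
    """Base class for spillover/compensation errors."""


class MalformedSpill(CompensationError):
    """$SPILLOVER keyword token count inconsistent with declared n."""


class SingularMatrix(CompensationError):
    """Spillover matrix is not invertible."""


class NonSquare(CompensationError):
    """Matrix file body is not square."""


class HeaderMismatch(CompensationError):
    """Matrix file header width disagrees with the body."""


class UnknownDetector(CompensationError):
    """A spillover detector does not map to any sample channel."""


class DegenerateBeads(CompensationError):
    """Bead file has no separable positive population on its stain channel."""


# --- Transforms -----------------------------------------------------------

class TransformError(CytogateError):
    """Base class for transform errors."""


class InvalidParams(TransformError):
    """Transform parameters violate their bounds."""


class NonConvergence(TransformError):
    """Root finder failed to converge within the iteration cap."""


class NotInvertible(TransformError):
    """Transform has no inverse (ratio)."""


class UnknownChannel(TransformError):
    """Ratio transform references a channel absent from the sample."""


# --- Gating ---------------------------------------------------------------

class GatingError(CytogateError):
    """Base class for gating-model errors."""


class NonPositiveDefinite(GatingError):
    """Ellipsoid covariance matrix is not symmetric positive-definite."""


class UnresolvedReference(GatingError):
    """A gate/transform/compensation reference does not resolve."""


class ChannelMissing(GatingError):
    """Sample lacks a channel required by a gate dimension."""


class DuplicatePath(GatingError):
    """A gate already exists at the target path."""


class UnknownPath(GatingError):
    """No gate exists at the referenced path."""


class RemoveBlocked(GatingError):
    """Gate removal blocked by a boolean gate referencing it."""


# --- Serialization --------------------------------------------------------

class SerializationError(CytogateError):
    """Base class for XML I/O errors."""


class SchemaViolation(SerializationError):
    """Document is not valid Gating-ML 2.0."""


class UnresolvedId(SerializationError):
    """Dangling id reference inside an XML document."""


class UnsupportedElement(SerializationError):
    """Gating-ML element outside the supported subset."""


class NotExpressible(SerializationError):
    """Strategy content cannot be represented in the target dialect."""


class UnsupportedWorkspaceVersion(SerializationError):
    """WSP version attribute below FlowJo 10."""


class SampleFileMissing(SerializationError):
    """WSP references an FCS file not found in the search directory."""


# --- Session --------------------------------------------------------------

class SessionError(CytogateError):
    """Base class for session errors."""


class DuplicateSample(SessionError):
    """Sample id already present in the session."""
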