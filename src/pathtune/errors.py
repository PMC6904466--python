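"""Exception hierarchy shared across the package."""


class PathtuneError(Exception):
    """Base class for all package-specific errors."""


class PlanError(PathtuneError):
    """A simulation plan violates one of its invariants."""


class SizingError(PathtuneError):
    """Requested features cannot fit into the genome / available positions."""


class MonomorphicSNPError(PathtuneError):
    """LD is undefined for a SNP with zero dosage variance."""


class SNPLookupError(PathtuneError, KeyError):
    """A SNP id is absent from the genotype panel or summary statistics."""


class ConfigError(PathtuneError):
    """An analysis configuration value is invalid."""


class PlacementError(PathtuneError):
    """A shuffled feature cannot be placed anywhere in its allowed space."""


class DegenerateDesignError(PathtuneError):
    """A regression design matrix is rank-deficient (e.g. constant covariate)."""


class PairingError(PathtuneError):
    """Paired samples do not align."""


class EmptySetError(PathtuneError):
    """A gene set has no members in the ranked universe."""
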