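"""Exception hierarchy for cohort ingestion and analysis."""


class CamrspotError(Exception):
    """Base class for package errors."""


class SchemaError(CamrspotError):
    """An input file does not match the documented column schema."""


class IntegrityError(CamrspotError):
    """Input parsed but violates a cohort invariant (duplicates, ordering)."""


class ConfigError(CamrspotError):
    """Invalid configuration value or unknown rule/stage name."""


class PipelineError(CamrspotError):
    """A pipeline stage's prerequisites are not satisfied."""


class NotInterpretableError(CamrspotError):
    """Sample is nonviable or missing counts; no phenotype call possible."""


class MissingFollowUpError(CamrspotError):
    """No usable post-baseline observation in the follow-up window."""


class InsufficientDataError(CamrspotError):
    """Too few observations for the requested computation."""


class CapabilityError(CamrspotError):
    """Input exceeds what the exact algorithm can enumerate."""
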