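"""Exception hierarchy shared across the pipeline stages."""


class OgclustError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(OgclustError):
    """Invalid or infeasible configuration."""


class HitTableError(OgclustError):
    """Malformed homology / domain hit table row."""


class TaxonomyError(OgclustError):
    """Unknown species, unknown clade, or unclassifiable species set."""


class OntologyError(OgclustError):
    """Malformed ontology: cycles, dangling is_a targets, missing roots."""
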