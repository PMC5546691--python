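"""Exception types shared across bcflux."""


class ValidationError(ValueError):
    """Input data violates a structural contract (ids, shapes, signs)."""


class ConsistencyError(ValueError):
    """Numerically inconsistent inputs (e.g. impossible Venn counts)."""


class UndefinedSimilarityError(ValueError):
    """A similarity is requested between vectors for which it is undefined."""
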