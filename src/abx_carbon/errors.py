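"""Exception hierarchy shared across the package.

CLI exit-code mapping: :class:`SchemaError` and :class:`DataValidationError`
exit with 2; :class:`MissingFactorError` and :class:`UnmatchedKeyError`
(lookup failures against loaded reference data) exit with 3.
"""


class AbxCarbonError(Exception):
    """Base class for all errors raised by abx_carbon."""


class SchemaError(AbxCarbonError):
    """A table file does not have the required columns."""


class DataValidationError(AbxCarbonError):
    """A table parsed but its contents violate an invariant."""


class DanglingReferenceError(DataValidationError):
    """A row references an id that does not exist in its companion table."""


class MissingFactorError(AbxCarbonError):
    """No emission factor for a (material, disposal method) pair."""

    def __init__(self, material: str, method: str):
        self.material = material
        self.method = method
        super().__init__(
            f"no emission factor for material {material!r} under disposal "
            f"method {method!r}; add the pair to the factor table or change "
            "the disposal scenario"
        )


class UnmatchedKeyError(AbxCarbonError):
    """A usage record's key could not be matched to any factor row."""

    def __init__(self, key, candidates=()):
        self.key = key
        self.candidates = list(candidates)
        hint = f"; close matches: {', '.join(self.candidates)}" if self.candidates else ""
        super().__init__(f"no emission factor found for usage key {key!r}{hint}")


class UnitError(AbxCarbonError):
    """Unknown mass unit passed to a conversion."""
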