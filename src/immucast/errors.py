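"""Exception hierarchy.

All errors raised by the library derive from :class:`ImmucastError` so callers
(and the CLI) can distinguish library failures from programming errors.
"""


class ImmucastError(Exception):
    """Base class for all immucast errors."""


# --- rulebase loading -------------------------------------------------------

class MissingManifest(ImmucastError):
    """The rulebase directory has no manifest.json."""


class MalformedRuleFile(ImmucastError):
    def __init__(self, path, line, message):
        self.path = str(path)
        self.line = line
        super().__init__(f"{path}:{line}: {message}")


class DuplicateRuleId(ImmucastError):
    def __init__(self, rule_id):
        self.rule_id = rule_id
        super().__init__(f"duplicate rule id {rule_id!r}")


class UnknownCategoryReference(ImmucastError):
    def __init__(self, rule_id, category):
        super().__init__(f"rule {rule_id!r} references unknown category {category!r}")


class UnknownCategory(ImmucastError):
    def __init__(self, category):
        super().__init__(f"unknown category {category!r}")


class EmptyCategory(ImmucastError):
    def __init__(self, category):
        super().__init__(f"category {category!r} has no rules to chart")


class LogicParseError(ImmucastError):
    """A rule logic expression could not be parsed."""


# --- patient I/O ------------------------------------------------------------

class NoPatientResource(ImmucastError):
    """The bundle contains no Patient resource."""


class MultiplePatientResources(ImmucastError):
    """The bundle contains more than one Patient resource."""


class UnparseableResource(ImmucastError):
    def __init__(self, resource_id, message):
        self.resource_id = resource_id
        super().__init__(f"resource {resource_id!r}: {message}")


# --- engine -----------------------------------------------------------------

class AsOfBeforeBirth(ImmucastError):
    """The evaluation date precedes the recorded birth date."""


class RuleNotExecutable(ImmucastError):
    def __init__(self, rule_id):
        self.rule_id = rule_id
        super().__init__(f"rule {rule_id!r} is not executable")


class UnsupportedPredicateKind(ImmucastError):
    pass


# --- testkit ----------------------------------------------------------------

class UnsatisfiableRule(ImmucastError):
    def __init__(self, rule_id, message=""):
        self.rule_id = rule_id
        super().__init__(f"no positive fixture exists for rule {rule_id!r}: {message}")


class UnknownRuleId(ImmucastError):
    def __init__(self, rule_id):
        self.rule_id = rule_id
        super().__init__(f"unknown rule id {rule_id!r}")
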