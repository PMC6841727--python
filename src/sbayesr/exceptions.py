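"""Exception hierarchy shared across the package."""


class SBayesRError(Exception):
    """Base class for all package errors."""


class FormatError(SBayesRError):
    """A text input does not conform to the documented dialect."""


class DuplicateSNPError(FormatError):
    """Duplicate variant identifiers in an input that requires them unique."""

    def __init__(self, offenders):
        self.offenders = list(offenders)
        shown = ", ".join(self.offenders[:10])
        more = "" if len(self.offenders) <= 10 else f" (+{len(self.offenders) - 10} more)"
        super().__init__(f"duplicate snp_id values: {shown}{more}")


class EmptyResultError(SBayesRError):
    """A filtering or matching step removed every variant."""


class NumericError(SBayesRError):
    """A reconstruction produced a non-finite or invalid value."""


class CorruptLDError(SBayesRError):
    """An LD store failed its integrity checks on read."""


class DivergenceError(SBayesRError):
    """The Gibbs sampler diverged (h2 sample > 1 or non-finite state).

    Divergence is usually a symptom of inconsistent summary statistics
    (mismatched samples, allele-coding or frequency errors); tighten the
    summary-statistic QC (per-SNP sample-size percentile filter, frequency
    checks against the LD reference) before re-running.
    """
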