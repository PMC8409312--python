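"""Run-wide configuration.

All event-calling thresholds live here so the command line, the library
API and the tests share one set of defaults.  The defaults are the model's
published operating point: organism groups of at least four members on
both sides of a presence/absence split, and a 99% empirical-percentile
cutoff for the global duplication verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Minimum organisms on each side of a presence/absence split (|A| and the
#: implied |B| for mobility; |A*| and |B*| for a translocation).
DEFAULT_MIN_GROUP_SIZE = 4

#: Percentile of the |diff| distribution a domain must reach for a global
#: duplicated/nonduplicated verdict.
DEFAULT_DUPLICATION_PERCENTILE = 0.99

DUPLICATION_RULES = ("empirical", "cumsum-rank")
AMBIGUITY_POLICIES = ("exclude", "to_A", "to_B")


@dataclass
class RunConfig:
    """Thresholds and policies for one analysis run.

    Parameters
    ----------
    min_group_size:
        Smallest organism-group size that counts as evidence, applied to
        |A| (mobility) and to |A*|, |B*| (translocation).  Unitless count
        of organisms; default 4.
    duplication_percentile:
        Fraction in (0, 1); default 0.99.
    duplication_rule:
        ``"empirical"`` — two-sided empirical percentile on the signed
        duplicated-minus-nonduplicated KO count; ``"cumsum-rank"`` — the
        cutoff is taken where the descending cumulative sum of |diff|
        reaches the percentile of its total.
    ambiguity_policy:
        Where an organism carrying both domain-containing and
        domain-lacking paralogs goes: ``"exclude"`` (neither side, the
        default), ``"to_A"`` or ``"to_B"``.
    seed:
        Seed for any stochastic step (only the synthetic generator uses
        randomness).
    """

    min_group_size: int = DEFAULT_MIN_GROUP_SIZE
    duplication_percentile: float = DEFAULT_DUPLICATION_PERCENTILE
    duplication_rule: str = "empirical"
    ambiguity_policy: str = "exclude"
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.min_group_size < 1:
            raise ValueError("min_group_size must be >= 1")
        if not (0.0 < self.duplication_percentile < 1.0):
            raise ValueError("duplication_percentile must be in (0, 1)")
        if self.duplication_rule not in DUPLICATION_RULES:
            raise ValueError(f"unknown duplication_rule {self.duplication_rule!r}")
        if self.ambiguity_policy not in AMBIGUITY_POLICIES:
            raise ValueError(f"unknown ambiguity_policy {self.ambiguity_policy!r}")
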