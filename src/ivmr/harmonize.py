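"""Align exposure and outcome associations onto a common effect allele.

Two GWAS report the same biallelic SNP, possibly with the roles of the
two alleles exchanged, and possibly read off opposite DNA strands.
Before a Wald ratio can be formed, the outcome association must be
re-expressed per copy of the *exposure's* effect allele:

* same allele pair, same orientation — nothing to do (``identical``);
* same pair, roles exchanged — negate the outcome beta and complement
  its EAF (``flipped``);
* complementary pair (opposite strand) — relabel only
  (``strand_flipped``), or relabel and negate
  (``strand_flipped_and_flipped``);
* palindromic SNPs (A/T, C/G) — letters cannot distinguish a strand
  flip from an allele swap, so orientation falls back on effect-allele
  frequency; near 50% frequency the variant is unresolvable and is
  dropped;
* anything unresolvable is dropped with an explicit reason, never
  silently passed through.

Instrument tables that print only the effect allele are supported: when
the outcome's effect allele matches it, the pair passes through as
``assumed_aligned``; when the letters differ and are not strand
complements, they are taken to be the two alleles of one biallelic SNP
and the outcome is flipped.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

from .summary_stats import GwasRecord, InstrumentSet, OutcomePanel

__all__ = [
    "ACTIONS",
    "HarmonizationPolicy",
    "HarmonizedPair",
    "flip_record",
    "harmonize_pair",
    "harmonize_panel",
    "complement_allele",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

ACTIONS = (
    "identical",
    "flipped",
    "strand_flipped",
    "strand_flipped_and_flipped",
    "assumed_aligned",
    "dropped",
)

#: actions under which the outcome beta changes sign
_NEGATING = {"flipped", "strand_flipped_and_flipped"}


def complement_allele(base: str) -> str:
    return _COMPLEMENT[base]


@dataclasses.dataclass(frozen=True)
class HarmonizationPolicy:
    """Tunable rules for ambiguous harmonization cases.

    palindromic_eaf_window:
        Half-width around 0.5; a palindromic SNP whose EAF (in either
        dataset) falls inside the window is dropped because frequency
        cannot orient it reliably.
    allow_assumed_alignment:
        Permit pairs lacking an other allele to pass through on
        letter matching alone (required for instrument tables that
        print only the effect allele).
    strand_flip_enabled:
        Attempt complement-map resolution of non-matching allele pairs.
    """

    palindromic_eaf_window: float = 0.08
    allow_assumed_alignment: bool = True
    strand_flip_enabled: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.palindromic_eaf_window < 0.5):
            raise ValueError("palindromic_eaf_window must lie in [0, 0.5)")


DEFAULT_POLICY = HarmonizationPolicy()


@dataclasses.dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome associations on a common effect allele.

    ``beta_out``, ``se_out`` and ``eaf_out`` are the outcome values
    re-expressed per copy of the exposure's effect allele; ``action``
    records the transformation applied, and dropped pairs carry a
    ``drop_reason`` and must be excluded from estimation.
    """

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    action: str
    eaf_exp: float | None = None
    eaf_out: float | None = None
    drop_reason: str = ""

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        if self.action == "dropped":
            if not self.drop_reason:
                raise ValueError(f"{self.snp_id}: dropped pair needs a drop_reason")
        else:
            if not (self.se_exp > 0 and self.se_out > 0):
                raise ValueError(f"{self.snp_id}: SEs must be positive")

    @property
    def dropped(self) -> bool:
        return self.action == "dropped"


def flip_record(record: GwasRecord) -> GwasRecord:
    """Re-express a record on its other allele (negate beta, 1 − EAF).

    Requires the other allele to be known; flipping twice restores the
    original record exactly.
    """
    if record.other_allele is None:
        raise ValueError(f"{record.snp_id}: cannot flip without other_allele")
    return dataclasses.replace(
        record,
        effect_allele=record.other_allele,
        other_allele=record.effect_allele,
        beta=-record.beta,
        eaf=None if record.eaf is None else 1.0 - record.eaf,
    )


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


def _drop(exp: GwasRecord, out: GwasRecord, reason: str) -> HarmonizedPair:
    return HarmonizedPair(
        snp_id=exp.snp_id,
        beta_exp=exp.beta,
        se_exp=exp.se,
        beta_out=math.nan,
        se_out=math.nan,
        eaf_exp=exp.eaf,
        eaf_out=None,
        action="dropped",
        drop_reason=reason,
    )


def _classify_partial(exp: GwasRecord, out: GwasRecord, policy: HarmonizationPolicy):
    """Classification when at least one side lacks an other allele."""
    if not policy.allow_assumed_alignment:
        return None, "other allele missing and assumed alignment disabled"
    e1, o1 = exp.effect_allele, out.effect_allele
    if o1 == e1:
        return "assumed_aligned", None
    if _COMPLEMENT[o1] == e1:
        return None, (
            "effect alleles are strand complements and the other allele is "
            "unknown: strand flip vs. allele swap is ambiguous"
        )
    # Distinct, non-complementary letters at a biallelic SNP can only be
    # the two alleles of the same variant: the outcome is on the other one.
    return "flipped", None


def _classify_full(exp: GwasRecord, out: GwasRecord, policy: HarmonizationPolicy):
    e1, e2 = exp.effect_allele, exp.other_allele
    o1, o2 = out.effect_allele, out.other_allele
    if _is_palindromic(e1, e2):
        if {o1, o2} != {e1, e2}:
            return None, "allele pair mismatch at palindromic SNP"
        return _resolve_palindromic(exp, out, policy)
    if (o1, o2) == (e1, e2):
        return "identical", None
    if (o1, o2) == (e2, e1):
        return "flipped", None
    if policy.strand_flip_enabled:
        c1, c2 = _COMPLEMENT[o1], _COMPLEMENT[o2]
        if (c1, c2) == (e1, e2):
            return "strand_flipped", None
        if (c1, c2) == (e2, e1):
            return "strand_flipped_and_flipped", None
    return None, "allele pair mismatch: alleles cannot be reconciled"


def _resolve_palindromic(exp: GwasRecord, out: GwasRecord, policy: HarmonizationPolicy):
    """Orient a palindromic SNP by effect-allele frequency."""
    if exp.eaf is None or out.eaf is None:
        return None, "palindromic SNP and EAF unavailable: orientation ambiguous"
    window = policy.palindromic_eaf_window
    if min(abs(exp.eaf - 0.5), abs(out.eaf - 0.5)) <= window:
        return None, (
            "palindromic SNP with EAF too close to 0.5: "
            "orientation ambiguous within the policy window"
        )
    letters_swapped = out.effect_allele == exp.other_allele
    sides_agree = (exp.eaf < 0.5) == (out.eaf < 0.5)
    # Frequency alone decides whether the outcome effect allele is
    # physically the exposure's effect allele (sides agree: no sign
    # change) or its partner (sides disagree: negate).  The letters only
    # say whether the datasets printed the same strand.
    if sides_agree:
        return ("identical" if not letters_swapped else "strand_flipped"), None
    return ("flipped" if letters_swapped else "strand_flipped_and_flipped"), None


def harmonize_pair(
    exp: GwasRecord,
    out: GwasRecord,
    policy: HarmonizationPolicy = DEFAULT_POLICY,
) -> HarmonizedPair:
    """Harmonize one exposure/outcome record pair for the same SNP."""
    if exp.snp_id != out.snp_id:
        raise ValueError(f"snp_id mismatch: {exp.snp_id} vs {out.snp_id}")
    if exp.other_allele is None or out.other_allele is None:
        action, reason = _classify_partial(exp, out, policy)
    else:
        action, reason = _classify_full(exp, out, policy)
    if action is None:
        return _drop(exp, out, reason or "unresolvable")
    negate = action in _NEGATING
    beta_out = -out.beta if negate else out.beta
    eaf_out = out.eaf
    if eaf_out is not None and negate:
        eaf_out = 1.0 - eaf_out
    return HarmonizedPair(
        snp_id=exp.snp_id,
        beta_exp=exp.beta,
        se_exp=exp.se,
        beta_out=beta_out,
        se_out=out.se,
        eaf_exp=exp.eaf,
        eaf_out=eaf_out,
        action=action,
    )


def harmonize_panel(
    instruments: InstrumentSet,
    panel: OutcomePanel,
    policy: HarmonizationPolicy = DEFAULT_POLICY,
) -> list[HarmonizedPair]:
    """Harmonize every instrument against an outcome panel.

    Returns one pair per instrument, in instrument order; instruments
    absent from the panel yield dropped pairs with reason
    "missing in outcome".
    """
    if len(instruments) == 0:  # defensive; InstrumentSet forbids this
        raise ValueError("empty instrument set")
    pairs: list[HarmonizedPair] = []
    for exp in instruments:
        out = panel.get(exp.snp_id)
        if out is None:
            pairs.append(_drop(exp, exp, "missing in outcome"))
        else:
            pairs.append(harmonize_pair(exp, out, policy))
    return pairs
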