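"""Bundled instrument and outcome tables for diet/lifestyle exposures.

The package ships, as plain TSV, the per-SNP summary statistics used in
a published two-sample MR study of diet/lifestyle and glycemic traits:

* ``lifestyle_instruments.tsv`` — 15 instrument records across seven
  exposures (carbohydrate, protein and fat intake; number of cigarettes
  smoked; smoking initiation; smoking cessation; sleep duration), taken
  from the original GWAS reports of those traits.  Only the effect
  allele is printed in the source, so ``other_allele`` is absent.
* ``glycemic_outcomes.tsv`` — the same variants' associations with
  seven outcomes (T2D from the DIAGRAM consortium; HOMA-IR, HOMA-B,
  fasting insulin, fasting glucose, HbA1c and 2-hour glucose from
  MAGIC).  The source reports each outcome effect on the
  lifestyle-raising allele of the matching instrument row, so that
  allele is recorded as the effect allele here.
* ``published_mr_estimates.tsv`` — the pooled causal estimates the
  source study reported for every exposure-outcome pair, kept purely as
  a cross-check reference: the pipeline flags recomputed cells that
  disagree with these published numbers.

rs838145 appears twice on the instrument side (carbohydrate intake,
effect allele G; fat intake, effect allele A — the same variant read on
opposite alleles).  The outcome table transcribes both orientations as
printed; when a single outcome panel per trait is assembled, the first
orientation encountered (carbohydrate, allele G) is kept and the mirror
row is recovered by harmonization's allele flip.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping

import pandas as pd

from .summary_stats import (
    GwasRecord,
    InstrumentSet,
    OutcomePanel,
    read_summary_table,
)

__all__ = [
    "EXPOSURES",
    "OUTCOMES",
    "bundled_path",
    "load_instruments",
    "load_outcome_panels",
    "load_bundled_data",
    "load_published_estimates",
]

EXPOSURES: tuple[str, ...] = (
    "Carbohydrate",
    "Protein",
    "Fat",
    "Smoking (number)",
    "Smoking initiation",
    "Smoking cessation",
    "Sleep",
)

OUTCOMES: tuple[str, ...] = (
    "T2D",
    "HOMA-IR",
    "HOMA-B",
    "fasting insulin",
    "fasting glucose",
    "HbA1c",
    "2hGLU",
)


def bundled_path(name: str):
    """Filesystem path of a bundled data file (context-manager free)."""
    return resources.files(__package__) / "data" / name


def load_instruments() -> tuple[InstrumentSet, ...]:
    """Load the seven bundled instrument sets, in canonical order."""
    result = read_summary_table(
        bundled_path("lifestyle_instruments.tsv"), dialect={"trait": "exposure"}
    )
    if result.diagnostics:  # pragma: no cover - packaged data is valid
        raise RuntimeError(f"bundled instrument table invalid: {result.diagnostics}")
    by_exposure: dict[str, list[GwasRecord]] = {name: [] for name in EXPOSURES}
    for record in result.records:
        by_exposure[record.trait].append(record)
    return tuple(
        InstrumentSet(name, tuple(records)) for name, records in by_exposure.items()
    )


def load_outcome_panels() -> tuple[OutcomePanel, ...]:
    """Load the seven bundled outcome panels, deduplicated per rsID.

    The duplicated rs838145 row (fat-intake orientation) is dropped in
    favour of the first-seen carbohydrate orientation; harmonization
    re-derives the mirror orientation when the fat exposure is analysed.
    """
    result = read_summary_table(
        bundled_path("glycemic_outcomes.tsv"), dialect={"trait": "outcome"}
    )
    if result.diagnostics:  # pragma: no cover - packaged data is valid
        raise RuntimeError(f"bundled outcome table invalid: {result.diagnostics}")
    by_outcome: dict[str, list[GwasRecord]] = {name: [] for name in OUTCOMES}
    for record in result.records:
        kept = by_outcome[record.trait]
        if any(r.snp_id == record.snp_id for r in kept):
            continue
        kept.append(record)
    return tuple(
        OutcomePanel(name, tuple(records)) for name, records in by_outcome.items()
    )


def load_bundled_data() -> tuple[tuple[InstrumentSet, ...], tuple[OutcomePanel, ...]]:
    """Instrument sets and outcome panels for the bundled study data."""
    return load_instruments(), load_outcome_panels()


def load_published_estimates() -> Mapping[tuple[str, str], tuple[float, float, float]]:
    """Published pooled (beta, se, p) per (exposure, outcome) pair."""
    frame = pd.read_csv(bundled_path("published_mr_estimates.tsv"), sep="\t")
    return {
        (row.exposure, row.outcome): (float(row.beta), float(row.se), float(row.p))
        for row in frame.itertuples()
    }
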