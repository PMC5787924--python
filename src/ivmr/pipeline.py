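"""End-to-end analysis: inputs → harmonization → IVW → report files.

A run takes instrument tables and outcome tables (either the bundled
lifestyle/glycemic data or user TSVs), harmonizes every exposure against
every outcome, pools per-SNP Wald ratios by fixed-effect IVW, applies a
Bonferroni adjustment across the grid, and writes:

* ``results.tsv``   — exposure-by-outcome matrix (full precision plus a
  3-decimal display column);
* ``results_long.tsv`` — one row per cell with n_snps, heterogeneity
  and any flags;
* ``harmonization_audit.tsv`` — per-SNP action and drop reason;
* ``run_manifest.json`` — inputs, configuration and package version.

When the bundled data are analysed, each recomputed cell is compared
with the pooled estimate originally published for that pair; cells that
disagree beyond one unit in the third decimal (the published precision)
are flagged ``published_value_mismatch`` rather than silently reported.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .datasets import load_bundled_data, load_published_estimates
from .estimators import MRResult, ivw_fixed_effect, bonferroni, wald_ratio
from .harmonize import HarmonizationPolicy, HarmonizedPair, harmonize_panel
from .summary_stats import (
    InstrumentSet,
    OutcomePanel,
    read_summary_table,
    write_results_table,
)

__all__ = ["RunConfig", "AnalysisReport", "run_analysis", "PUBLISHED_TOLERANCE"]

BUNDLED = "bundled"

#: one unit in the last printed decimal of the published estimates
PUBLISHED_TOLERANCE = 1e-3


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    ``exposures``/``outcomes`` are either the string ``"bundled"`` (use
    the packaged lifestyle/glycemic tables) or sequences of TSV paths,
    one instrument table per exposure and one panel per outcome.
    ``bonferroni_family`` is ``"per_run"`` (family = number of cells
    actually estimated), an explicit integer, or ``None`` to skip
    adjustment.
    """

    exposures: str | Sequence[str] = BUNDLED
    outcomes: str | Sequence[str] = BUNDLED
    policy: HarmonizationPolicy = HarmonizationPolicy()
    se_order: str = "first"
    bonferroni_family: str | int | None = "per_run"
    output_dir: str | Path | None = None
    compare_published: bool = True

    def __post_init__(self) -> None:
        if not isinstance(self.exposures, str) and len(self.exposures) == 0:
            raise ValueError("at least one exposure is required")
        if not isinstance(self.outcomes, str) and len(self.outcomes) == 0:
            raise ValueError("at least one outcome is required")


@dataclasses.dataclass(frozen=True)
class AnalysisReport:
    """Everything a run produced, in memory."""

    results: tuple[MRResult, ...]
    not_estimable: tuple[tuple[str, str, str], ...]  # (exposure, outcome, reason)
    audit: tuple[tuple[str, str, str, str, str], ...]  # exposure, outcome, snp, action, reason

    def cell(self, exposure: str, outcome: str) -> MRResult | None:
        for res in self.results:
            if res.exposure == exposure and res.outcome == outcome:
                return res
        return None

    @property
    def flagged(self) -> tuple[tuple[str, str], ...]:
        return tuple(
            (r.exposure, r.outcome) for r in self.results if "published_value_mismatch" in r.flags
        )


def _load_inputs(config: RunConfig) -> tuple[list[InstrumentSet], list[OutcomePanel]]:
    if config.exposures == BUNDLED or config.outcomes == BUNDLED:
        bundled_instruments, bundled_panels = load_bundled_data()
    instruments: list[InstrumentSet]
    panels: list[OutcomePanel]
    if config.exposures == BUNDLED:
        instruments = list(bundled_instruments)
    else:
        instruments = []
        for path in config.exposures:
            result = read_summary_table(path, trait=Path(path).stem)
            records = tuple(result.records)
            instruments.append(InstrumentSet(records[0].trait if records else Path(path).stem, records))
    if config.outcomes == BUNDLED:
        panels = list(bundled_panels)
    else:
        panels = []
        for path in config.outcomes:
            result = read_summary_table(path, trait=Path(path).stem)
            records = tuple(result.records)
            panels.append(OutcomePanel(records[0].trait if records else Path(path).stem, records))
    return instruments, panels


def run_analysis(config: RunConfig) -> AnalysisReport:
    """Run the full two-sample MR analysis described by ``config``."""
    instruments, panels = _load_inputs(config)
    published: Mapping | None = None
    if (
        config.compare_published
        and config.exposures == BUNDLED
        and config.outcomes == BUNDLED
    ):
        published = load_published_estimates()

    results: list[MRResult] = []
    not_estimable: list[tuple[str, str, str]] = []
    audit: list[tuple[str, str, str, str, str]] = []
    for instrument_set in instruments:
        for panel in panels:
            pairs = harmonize_panel(instrument_set, panel, config.policy)
            for pair in pairs:
                audit.append(
                    (instrument_set.exposure_name, panel.outcome_name, pair.snp_id, pair.action, pair.drop_reason)
                )
            usable = [p for p in pairs if not p.dropped]
            if not usable:
                not_estimable.append(
                    (instrument_set.exposure_name, panel.outcome_name, "all instruments dropped")
                )
                continue
            estimates = [wald_ratio(p, se_order=config.se_order) for p in usable]
            result = ivw_fixed_effect(
                estimates, exposure=instrument_set.exposure_name, outcome=panel.outcome_name
            )
            if published is not None:
                result = _flag_against_published(result, published)
            results.append(result)

    results = _apply_bonferroni(results, config.bonferroni_family)
    if config.output_dir is not None:
        _write_outputs(config, results, not_estimable, audit)
    return AnalysisReport(tuple(results), tuple(not_estimable), tuple(audit))


def _flag_against_published(result: MRResult, published: Mapping) -> MRResult:
    ref = published.get((result.exposure, result.outcome))
    if ref is None:
        return result
    published_beta = ref[0]
    flags = result.flags
    if abs(result.beta - published_beta) > PUBLISHED_TOLERANCE:
        flags = flags + ("published_value_mismatch",)
    return dataclasses.replace(result, published_beta=published_beta, flags=flags)


def _apply_bonferroni(
    results: list[MRResult], family: str | int | None
) -> list[MRResult]:
    if family is None or not results:
        return results
    m = len(results) if family == "per_run" else int(family)
    adjusted = bonferroni([r.p for r in results], m=m)
    return [dataclasses.replace(r, p_adjusted=adj) for r, adj in zip(results, adjusted)]


def _config_digest(config: RunConfig) -> str:
    payload = json.dumps(
        {
            "exposures": list(config.exposures) if not isinstance(config.exposures, str) else config.exposures,
            "outcomes": list(config.outcomes) if not isinstance(config.outcomes, str) else config.outcomes,
            "policy": dataclasses.asdict(config.policy),
            "se_order": config.se_order,
            "bonferroni_family": config.bonferroni_family,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def _write_outputs(
    config: RunConfig,
    results: list[MRResult],
    not_estimable: list[tuple[str, str, str]],
    audit: list[tuple[str, str, str, str, str]],
) -> None:
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if results:
        write_results_table(results, out_dir / "results.tsv")
    long_rows = []
    for r in results:
        het = r.heterogeneity
        long_rows.append(
            {
                "exposure": r.exposure,
                "outcome": r.outcome,
                "n_snps": r.n_snps,
                "beta": repr(r.beta),
                "se": repr(r.se),
                "z": repr(r.z),
                "p": repr(r.p),
                "p_adjusted": "" if r.p_adjusted is None else repr(r.p_adjusted),
                "q": "" if het is None else repr(het.q),
                "i2": "" if het is None else repr(het.i2),
                "published_beta": "" if r.published_beta is None else repr(r.published_beta),
                "flags": ";".join(r.flags),
            }
        )
    for exposure, outcome, reason in not_estimable:
        long_rows.append(
            {"exposure": exposure, "outcome": outcome, "n_snps": 0, "flags": f"not_estimable:{reason}"}
        )
    pd.DataFrame(long_rows).to_csv(out_dir / "results_long.tsv", sep="\t", index=False)
    pd.DataFrame(
        audit, columns=["exposure", "outcome", "snp_id", "action", "drop_reason"]
    ).to_csv(out_dir / "harmonization_audit.tsv", sep="\t", index=False)
    manifest = {
        "package": "ivmr",
        "version": __version__,
        "config_sha256": _config_digest(config),
        "n_results": len(results),
        "n_not_estimable": len(not_estimable),
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
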