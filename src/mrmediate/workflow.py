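"""Panel screening workflow: forward screen, reverse MR, tiering, mediation hand-off.

For each exposure in a panel the workflow selects instruments, harmonizes
against the outcome, runs every applicable estimator plus the sensitivity
diagnostics, and assigns a significance tier from the IVW p-value:

* ``significant`` — IVW p below the Bonferroni threshold 0.05/n_tests;
* ``suggestive``  — p below 0.05 but above the Bonferroni threshold;
* ``null``        — otherwise;
* ``skipped``     — too few instruments survived selection.

``n_tests`` is the panel size (e.g. 91 cytokines or 1400 metabolites), not the number of non-skipped pairs. The reverse direction uses the
genome-wide 5×10⁻⁸ instrument threshold; a forward association whose reverse
screen is null is flagged unidirectional and eligible for mediation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from .estimators import MRResult, run_all
from .instruments import harmonize, select_instruments
from .sensitivity import SensitivityReport, sensitivity_report
from .summary_io import LDMatrix, SummaryDataset

logger = logging.getLogger(__name__)

__all__ = ["ScreenRecord", "bonferroni_threshold", "assign_tier", "screen_panel",
           "bidirectional_report", "forest_table", "write_manifest"]

FORWARD_P = 5e-6
REVERSE_P = 5e-8


def bonferroni_threshold(n_tests: int, family_alpha: float = 0.05) -> float:
    """Family-wise corrected significance threshold, ``family_alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return family_alpha / n_tests


def assign_tier(ivw_pval: float | None, bonferroni_alpha: float,
                suggestive_alpha: float = 0.05) -> str:
    """Pure tier rule on the IVW p-value."""
    if ivw_pval is None:
        return "skipped"
    if ivw_pval < bonferroni_alpha:
        return "significant"
    if ivw_pval < suggestive_alpha:
        return "suggestive"
    return "null"


@dataclasses.dataclass
class ScreenRecord:
    exposure: str
    outcome: str
    direction: str                      # "forward" | "reverse"
    results: list[MRResult]
    sensitivity: SensitivityReport | None
    tier: str
    thresholds_used: tuple[float, float, int]   # (suggestive, bonferroni, n_tests)
    n_snp: int
    error: str | None = None

    @property
    def ivw(self) -> MRResult | None:
        for r in self.results:
            if r.method in ("ivw", "wald_ratio"):
                return r
        return None

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure, "outcome": self.outcome,
            "direction": self.direction, "tier": self.tier,
            "n_snp": self.n_snp,
            "thresholds_used": list(self.thresholds_used),
            "results": [r.to_dict() for r in self.results],
            "sensitivity": None if self.sensitivity is None else self.sensitivity.to_dict(),
            "error": self.error,
        }


def screen_panel(
    exposures: Sequence[SummaryDataset],
    outcome: SummaryDataset,
    ld: LDMatrix,
    direction: str = "forward",
    p_threshold: float | None = None,
    suggestive_alpha: float = 0.05,
    family_alpha: float = 0.05,
    n_tests: int | None = None,
    presso_n_sim: int = 1000,
    seed: int = 0,
) -> list[ScreenRecord]:
    """Screen a panel of exposures against one outcome.

    Per-pair failures are recorded on the ScreenRecord and the run continues;
    pairs whose instrument set is empty (or vanishes in harmonization) are
    tiered ``skipped``.
    """
    if p_threshold is None:
        p_threshold = FORWARD_P if direction == "forward" else REVERSE_P
    n_tests = n_tests if n_tests is not None else len(exposures)
    bonf = bonferroni_threshold(n_tests, family_alpha)
    records: list[ScreenRecord] = []
    for exp in exposures:
        thresholds = (suggestive_alpha, bonf, n_tests)
        try:
            inst = select_instruments(exp, ld, p_threshold=p_threshold)
            if len(inst) == 0:
                records.append(ScreenRecord(exp.trait_name, outcome.trait_name, direction,
                                            [], None, "skipped", thresholds, 0))
                continue
            harm = harmonize(inst, outcome)
            if harm.n_snp == 0:
                records.append(ScreenRecord(exp.trait_name, outcome.trait_name, direction,
                                            [], None, "skipped", thresholds, 0))
                continue
            results = run_all(harm, seed=seed)
            sens = sensitivity_report(harm, results, n_sim=presso_n_sim, seed=seed)
            ivw_p = results[0].pval
            tier = assign_tier(ivw_p, bonf, suggestive_alpha)
            records.append(ScreenRecord(exp.trait_name, outcome.trait_name, direction,
                                        results, sens, tier, thresholds, harm.n_snp))
        except Exception as err:  # per-pair isolation: the screen must finish
            logger.exception("screen %s vs %s failed", exp.trait_name, outcome.trait_name)
            records.append(ScreenRecord(exp.trait_name, outcome.trait_name, direction,
                                        [], None, "skipped", thresholds, 0, error=str(err)))
    return records


def bidirectional_report(
    forward: Sequence[ScreenRecord], reverse: Sequence[ScreenRecord]
) -> pd.DataFrame:
    """Pair forward and reverse screens per trait and flag unidirectionality.

    ``unidirectional`` is True when the forward tier is significant or
    suggestive and the reverse tier is null — the pattern that licenses a
    mediation analysis. Traits present in only one screen are warned about
    and omitted.
    """
    fwd = {r.exposure: r for r in forward}
    rev = {r.outcome: r for r in reverse}
    rows = []
    for name in fwd:
        if name not in rev:
            logger.warning("bidirectional_report: %s missing from reverse screen; row omitted", name)
            continue
        f, r = fwd[name], rev[name]
        uni = f.tier in ("significant", "suggestive") and r.tier == "null"
        note = ""
        if f.tier == "null" and r.tier in ("significant", "suggestive"):
            note = "reverse-only"
        rows.append((name, f.tier, r.tier, uni, note))
    return pd.DataFrame(rows, columns=["trait", "forward_tier", "reverse_tier",
                                       "unidirectional", "direction_note"])


def forest_table(records: Sequence[ScreenRecord]) -> pd.DataFrame:
    """Forest-plot-shaped table: one row per (exposure, method)."""
    rows = []
    for rec in records:
        for r in rec.results:
            rows.append((rec.exposure, r.n_snp, r.method, r.or_, r.ci_low,
                         r.ci_high, r.pval, rec.tier))
    return pd.DataFrame(rows, columns=["exposure", "nsnp", "method", "or",
                                       "ci_low", "ci_high", "p", "tier"])


def write_manifest(records: Sequence[ScreenRecord], path, config: dict | None = None) -> Path:
    """Machine-readable run manifest: config plus every screen record."""
    path = Path(path)
    payload = {
        "config": config or {},
        "records": [r.to_dict() for r in records],
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
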