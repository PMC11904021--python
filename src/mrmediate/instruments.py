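"""Instrument selection and effect-allele harmonization.

Selection applies, in order: an association p-value filter (lenient 5×10⁻⁶
forward, genome-wide 5×10⁻⁸ reverse), exclusion of strand-ambiguous
palindromic variants (A/T or C/G with MAF ≥ 0.42), greedy LD clumping
(10,000-kb window, r² > 0.001), and a per-variant instrument-strength filter
F > 10 with F = R²(N−2)/(1−R²) and R² = 2·MAF·(1−MAF)·β².

Harmonization aligns outcome effects to the exposure's effect allele:
matching labels are copied, swapped labels flip the outcome effect sign,
strand complements are resolved by label, and non-ambiguous palindromes are
oriented by comparing effect-allele frequencies across the two datasets.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .summary_io import (
    COMPLEMENT,
    LDMatrix,
    SummaryDataset,
    VariantAssociation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "InstrumentSet", "HarmonizedSet", "variance_explained", "f_statistic",
    "clump", "is_ambiguous_palindrome", "select_instruments", "harmonize",
    "write_harmonized", "read_harmonized",
]

HARMONIZED_COLUMNS = ["snp_id", "beta_exp", "se_exp", "beta_out", "se_out",
                      "eaf_exp", "eaf_out", "flipped"]


def variance_explained(maf: float, beta: float) -> float:
    """Variance in the exposure explained by one variant: 2·MAF·(1−MAF)·β².

    Assumes ``beta`` is on a standardized (per-SD) scale; if the formula
    exceeds 1 — a sign of non-standardized input — the value is capped just
    below 1 with a warning.
    """
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"maf must be the minor-allele frequency in (0, 0.5], got {maf}")
    r2 = 2.0 * (1.0 - maf) * maf * beta * beta
    if r2 >= 1.0:
        warnings.warn(
            f"variance_explained = {r2:.3g} >= 1; beta looks non-standardized — capping",
            RuntimeWarning,
        )
        r2 = np.nextafter(1.0, 0.0)
    return r2


def f_statistic(r2: float, n: int) -> float:
    """Single-instrument F-statistic, R²·(N−2)/(1−R²)."""
    if not 0.0 <= r2 < 1.0:
        raise ValueError(f"r2 must lie in [0, 1), got {r2}")
    if n <= 2:
        raise ValueError(f"sample size must exceed 2, got {n}")
    return r2 * (n - 2) / (1.0 - r2)


def is_ambiguous_palindrome(
    effect_allele: str, other_allele: str, eaf: float, maf_threshold: float = 0.42
) -> bool:
    """True iff the allele pair is palindromic (A/T or C/G) and MAF ≥ 0.42.

    Such variants cannot be reliably oriented across datasets by allele
    frequency and are excluded from instrument sets.
    """
    ea, oa = effect_allele.upper(), other_allele.upper()
    if COMPLEMENT.get(ea) != oa:
        return False
    return min(eaf, 1.0 - eaf) >= maf_threshold


@dataclasses.dataclass
class InstrumentSet:
    """Selected instruments for one exposure, with per-variant strength.

    ``table`` holds the retained variants in selection order plus ``R2``
    (variance explained) and ``F`` columns; ``selection_log`` records every
    exclusion as ``(snp_id, reason)`` with reason in
    {pvalue, palindrome, clumped, weak}.
    """

    exposure_name: str
    table: pd.DataFrame
    selection_log: list[tuple[str, str]]
    p_threshold: float

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> list[str]:
        return self.table["SNP"].tolist()

    @property
    def variants(self) -> list[VariantAssociation]:
        from .summary_io import _variant_from_row
        return [_variant_from_row(r) for r in self.table.itertuples()]


@dataclasses.dataclass
class HarmonizedSet:
    """Exposure and outcome effects aligned to a common effect allele.

    The unit of all causal estimation. ``table`` columns: snp_id, beta_exp,
    se_exp, beta_out, se_out, eaf_exp, eaf_out, flipped. ``dropped`` lists
    ``(snp_id, reason)`` with reason in
    {missing_in_outcome, allele_mismatch, ambiguous_palindrome}.
    """

    exposure_name: str
    outcome_name: str
    table: pd.DataFrame
    dropped: list[tuple[str, str]] = dataclasses.field(default_factory=list)

    @property
    def n_snp(self) -> int:
        return len(self.table)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        t = self.table
        return (t["beta_exp"].to_numpy(float), t["se_exp"].to_numpy(float),
                t["beta_out"].to_numpy(float), t["se_out"].to_numpy(float))


def clump(
    candidates: Sequence[VariantAssociation],
    ld: LDMatrix,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> list[VariantAssociation]:
    """Greedy LD clumping: keep the most significant variant, drop its LD
    partners, repeat.

    Variants are taken by ascending p-value (ties broken by snp_id); each
    index variant removes all remaining variants on the same chromosome
    within ``window_kb`` kilobases whose r² with it exceeds ``r2_threshold``.
    Pairs absent from ``ld`` count as r² = 0; cross-chromosome pairs are
    never clumped. Output order is selection order.
    """
    pool = sorted(candidates, key=lambda v: (v.pval, v.snp_id))
    retained: list[VariantAssociation] = []
    window_bp = window_kb * 1_000
    while pool:
        index = pool.pop(0)
        retained.append(index)
        survivors = []
        for v in pool:
            same_chrom = v.chrom == index.chrom
            in_window = abs(v.pos - index.pos) <= window_bp
            if same_chrom and in_window and ld.r2_between(index.snp_id, v.snp_id) > r2_threshold:
                logger.info("clump: %s removed (r2 with index %s above %g)",
                            v.snp_id, index.snp_id, r2_threshold)
            else:
                survivors.append(v)
        pool = survivors
    return retained


def select_instruments(
    exposure: SummaryDataset,
    ld: LDMatrix,
    p_threshold: float = 5e-6,
    clump_r2: float = 0.001,
    clump_kb: float = 10_000,
    f_min: float = 10.0,
    maf_ambiguous: float = 0.42,
) -> InstrumentSet:
    """Select instrumental variables for one exposure.

    Filters are applied in order: p-value, ambiguous-palindrome exclusion,
    LD clumping, then the per-variant F > ``f_min`` strength filter (R² from
    the variant's minor-allele frequency and beta). Every exclusion is logged
    in the returned set. For binary exposures (reverse direction) the R²
    formula is applied to the log-odds beta as printed, with a warning that
    the scale is not an SD unit.
    """
    if exposure.trait_type == "binary":
        warnings.warn(
            f"{exposure.trait_name}: R2/F computed from log-odds betas; "
            "variance-explained scale is approximate for binary traits",
            RuntimeWarning,
        )
    log: list[tuple[str, str]] = []
    survivors: list[VariantAssociation] = []
    all_variants = exposure.variants
    for v in (all_variants[s] for s in exposure.table["SNP"]):
        if not v.pval < p_threshold:
            log.append((v.snp_id, "pvalue"))
        elif is_ambiguous_palindrome(v.effect_allele, v.other_allele, v.eaf, maf_ambiguous):
            log.append((v.snp_id, "palindrome"))
        else:
            survivors.append(v)

    kept = clump(survivors, ld, r2_threshold=clump_r2, window_kb=clump_kb)
    clumped_away = {v.snp_id for v in survivors} - {v.snp_id for v in kept}
    log.extend((s, "clumped") for s in sorted(clumped_away))

    rows = []
    for v in kept:
        r2 = variance_explained(v.maf, v.beta)
        f = f_statistic(r2, v.n)
        if f_min is not None and not f > f_min:
            log.append((v.snp_id, "weak"))
            continue
        rows.append((v.snp_id, v.chrom, v.pos, v.effect_allele, v.other_allele,
                     v.eaf, v.beta, v.se, v.pval, v.n, r2, f))
    table = pd.DataFrame(rows, columns=["SNP", "CHR", "POS", "EA", "OA", "EAF",
                                        "BETA", "SE", "P", "N", "R2", "F"])
    if table.empty:
        warnings.warn(f"{exposure.trait_name}: no variants survived instrument selection",
                      RuntimeWarning)
    return InstrumentSet(exposure.trait_name, table, log, p_threshold)


def _orient_outcome(inst: VariantAssociation, out: VariantAssociation):
    """Align one outcome row to the instrument's effect allele.

    Returns (beta_out, se_out, eaf_out, flipped) or a drop-reason string.
    """
    ea, oa = inst.effect_allele, inst.other_allele
    o_ea, o_oa = out.effect_allele, out.other_allele
    palindromic = COMPLEMENT[ea] == oa

    beta, eaf, flipped = out.beta, out.eaf, False
    if (o_ea, o_oa) == (ea, oa):
        pass
    elif (o_ea, o_oa) == (oa, ea):
        beta, eaf, flipped = -beta, 1.0 - eaf, True
    elif not palindromic and (COMPLEMENT[o_ea], COMPLEMENT[o_oa]) == (ea, oa):
        pass  # opposite strand, same orientation
    elif not palindromic and (COMPLEMENT[o_ea], COMPLEMENT[o_oa]) == (oa, ea):
        beta, eaf, flipped = -beta, 1.0 - eaf, True
    else:
        return "allele_mismatch"

    if palindromic:
        # labels cannot distinguish strand flip from allele swap: orient by
        # whether the effect allele is minor on both sides
        if (inst.eaf < 0.5) != (eaf < 0.5):
            beta, eaf, flipped = -beta, 1.0 - eaf, True
    return beta, out.se, eaf, flipped


def harmonize(instruments: InstrumentSet, outcome: SummaryDataset) -> HarmonizedSet:
    """Align outcome effects to each instrument's effect allele.

    Instruments absent from the outcome dataset are dropped with reason
    ``missing_in_outcome``; irreconcilable allele pairs with
    ``allele_mismatch``. Non-ambiguous palindromic variants are oriented by
    allele-frequency comparison rather than dropped.
    """
    out_variants = outcome.variants
    rows, dropped = [], []
    for inst in instruments.variants:
        out = out_variants.get(inst.snp_id)
        if out is None:
            dropped.append((inst.snp_id, "missing_in_outcome"))
            continue
        oriented = _orient_outcome(inst, out)
        if isinstance(oriented, str):
            dropped.append((inst.snp_id, oriented))
            continue
        beta_out, se_out, eaf_out, flipped = oriented
        rows.append((inst.snp_id, inst.beta, inst.se, beta_out, se_out,
                     inst.eaf, eaf_out, flipped))
    table = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    if table.empty:
        warnings.warn(
            f"{instruments.exposure_name} vs {outcome.trait_name}: "
            "no instruments could be harmonized", RuntimeWarning)
    for snp, reason in dropped:
        logger.info("harmonize %s→%s: dropped %s (%s)",
                    instruments.exposure_name, outcome.trait_name, snp, reason)
    return HarmonizedSet(instruments.exposure_name, outcome.trait_name, table, dropped)


def write_harmonized(data: HarmonizedSet, path) -> None:
    """Serialize a harmonized set as TSV with a drop-log sidecar (``.drops``)."""
    data.table.to_csv(path, sep="\t", index=False)
    sidecar = str(path) + ".drops"
    pd.DataFrame(data.dropped, columns=["snp_id", "reason"]).to_csv(sidecar, sep="\t", index=False)


def read_harmonized(path, exposure_name: str = "exposure", outcome_name: str = "outcome") -> HarmonizedSet:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in HARMONIZED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"harmonized table missing columns {missing}")
    return HarmonizedSet(exposure_name, outcome_name, table[HARMONIZED_COLUMNS])
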