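"""Synthetic GWAS summary statistics under a known exposure→mediator→outcome model.

The generator emulates the structure of the real study inputs — a continuous
exposure panel (Olink-style cytokine GWAS), a continuous mediator panel
(metabolite GWAS) and a binary outcome reported on the log-odds scale — so
every downstream stage (instrument selection, harmonization, estimation,
diagnostics, mediation) can be exercised against ground truth.

Causal model on the per-variant true effects:

* exposure instruments carry effects ``γ_j`` on the exposure;
* the mediator inherits ``β1·γ_j`` from the exposure and additionally has its
  own instruments with direct effects ``δ_j`` (distinct loci, as metabolite
  and cytokine instruments are in practice);
* the outcome receives ``(direct + β1·β2)·γ_j`` through the causal chain,
  ``β2·δ_j`` through the mediator, optional horizontally-pleiotropic direct
  effects on exposure instruments, and its own disease loci ``ω_j`` (which
  serve as reverse-direction instruments).

Observed effects add Normal(0, se) noise with the standard GWAS approximation
``se_j = 1 / sqrt(2·MAF_j·(1−MAF_j)·n)``; p-values are two-sided normal Wald
tail probabilities.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats

from .summary_io import CANONICAL_COLUMNS, LDMatrix, SummaryDataset

import pandas as pd

__all__ = ["SimulationConfig", "SimulatedPanel", "simulate_panel", "inject_outliers",
           "simulate_screen_panel"]

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_NONPALINDROMIC_PAIRS = [("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
                         ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T")]

_TINY_P = np.finfo(float).tiny


@dataclasses.dataclass
class SimulationConfig:
    """Generative settings; defaults mirror the real study's scale.

    Sample sizes default to the source GWAS: exposure panel n = 14,824,
    mediator panel n = 8,299, outcome meta-analysis n = 1,339,769
    (6,015 cases + 1,333,754 controls). The default causal chain reproduces
    the study's headline arithmetic: exposure→mediator β1 = 0.115,
    mediator→outcome β2 = 0.168, total exposure→outcome effect 0.225
    (direct = 0.225 − β1·β2).
    """

    n_variants: int = 30                 # exposure-instrument loci
    n_mediator_variants: int = 30        # mediator-specific loci
    n_outcome_variants: int = 10         # disease-specific loci (reverse MR)
    n_exposure: int = 14_824
    n_mediator: int = 8_299
    n_outcome: int = 1_339_769
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_sd: float = 0.05               # SD of per-variant instrument effects
    gamma_min: float = 0.02              # truncation: |effect| >= gamma_min
    true_beta_exp_med: float = 0.115     # β1
    true_beta_med_out: float = 0.168     # β2
    true_direct_exp_out: float = 0.225 - 0.115 * 0.168   # total 0.225
    prop_pleiotropic: float = 0.0
    pleiotropy_scale: float = 0.05
    pleiotropy_mean: float = 0.0         # nonzero => directional pleiotropy
    pleiotropy_correlated: bool = False  # True violates the InSIDE assumption
    ld_block_size: int = 1
    ld_r2: float = 0.0
    palindrome_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if min(self.n_exposure, self.n_mediator, self.n_outcome) < 2:
            raise ValueError("sample sizes must be >= 2")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("prop_pleiotropic", "palindrome_fraction", "ld_r2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def true_total_exp_out(self) -> float:
        """Total exposure→outcome effect: direct + β1·β2."""
        return self.true_direct_exp_out + self.true_beta_exp_med * self.true_beta_med_out


@dataclasses.dataclass
class SimulatedPanel:
    exposure: SummaryDataset
    mediator: SummaryDataset
    outcome: SummaryDataset
    ld: LDMatrix
    truth: dict


def _truncated_normal(rng: np.random.Generator, n: int, sd: float, lo: float) -> np.ndarray:
    """Normal(0, sd²) effects with |x| >= lo (rejection sampling on magnitude)."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(0.0, sd, size=2 * (n - filled) + 8)
        keep = draw[np.abs(draw) >= lo]
        take = min(len(keep), n - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


def _wald_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, _TINY_P, 1.0)


def _observed_table(rng, snp, chrom, pos, ea, oa, eaf, true_beta, n) -> pd.DataFrame:
    maf = np.minimum(eaf, 1.0 - eaf)
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
    beta = true_beta + rng.normal(0.0, se)
    return pd.DataFrame({
        "SNP": snp, "CHR": chrom, "POS": pos, "EA": ea, "OA": oa,
        "EAF": eaf, "BETA": beta, "SE": se, "P": _wald_p(beta, se),
        "N": np.full(len(snp), n, dtype=np.int64),
    }, columns=CANONICAL_COLUMNS)


def simulate_panel(config: SimulationConfig | None = None, **overrides) -> SimulatedPanel:
    """Generate exposure, mediator and outcome summary statistics plus LD.

    One shared RNG seeded from ``config.seed``; per-trait noise streams are
    spawned deterministically, so identical configs give byte-identical
    datasets. The returned ``truth`` record carries every generative effect
    (per-variant instrument effects, pleiotropic ids, β0/β1/β2 and the true
    mediated proportion) for parameter-recovery tests.
    """
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)

    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_exp, rng_med, rng_out = (np.random.default_rng(s) for s in ss.spawn(4))

    n_e, n_m, n_o = config.n_variants, config.n_mediator_variants, config.n_outcome_variants
    m = n_e + n_m + n_o
    role = np.array(["exposure"] * n_e + ["mediator"] * n_m + ["outcome"] * n_o)
    snp = np.array([f"rs{config.seed % 1000:03d}{i:05d}" for i in range(m)])

    # genomic layout: LD blocks of consecutive variants, blocks far apart
    block = np.arange(m) // max(1, config.ld_block_size)
    chrom = (block % 22 + 1).astype(str)
    pos = (block // 22) * 50_000_000 + (np.arange(m) % max(1, config.ld_block_size)) * 1_000 + 1

    maf = rng_struct.uniform(config.maf_range[0], config.maf_range[1], size=m)
    flip = rng_struct.random(m) < 0.5
    eaf = np.where(flip, 1.0 - maf, maf)
    pal = rng_struct.random(m) < config.palindrome_fraction
    pair_idx_p = rng_struct.integers(0, len(_PALINDROMIC_PAIRS), size=m)
    pair_idx_n = rng_struct.integers(0, len(_NONPALINDROMIC_PAIRS), size=m)
    ea = np.where(pal, [ _PALINDROMIC_PAIRS[i][0] for i in pair_idx_p ],
                       [ _NONPALINDROMIC_PAIRS[i][0] for i in pair_idx_n ])
    oa = np.where(pal, [ _PALINDROMIC_PAIRS[i][1] for i in pair_idx_p ],
                       [ _NONPALINDROMIC_PAIRS[i][1] for i in pair_idx_n ])

    gamma = np.zeros(m)   # effect on exposure
    delta = np.zeros(m)   # direct effect on mediator
    omega = np.zeros(m)   # direct (disease-locus) effect on outcome
    gamma[:n_e] = _truncated_normal(rng_struct, n_e, config.gamma_sd, config.gamma_min)
    if n_m:
        delta[n_e:n_e + n_m] = _truncated_normal(rng_struct, n_m, config.gamma_sd, config.gamma_min)
    if n_o:
        omega[n_e + n_m:] = _truncated_normal(rng_struct, n_o, config.gamma_sd, config.gamma_min)

    # horizontal pleiotropy: direct variant→outcome effects on exposure instruments
    pleio = np.zeros(m)
    is_pleio = np.zeros(m, dtype=bool)
    if config.prop_pleiotropic > 0 and n_e:
        is_pleio[:n_e] = rng_struct.random(n_e) < config.prop_pleiotropic
        z = rng_struct.normal(0.0, 1.0, size=m)
        if config.pleiotropy_correlated:
            # couple pleiotropic effects to instrument strength (InSIDE violated)
            base = 0.5 * z + 0.8 * gamma / config.gamma_sd
        else:
            base = z
        pleio = np.where(is_pleio, config.pleiotropy_mean + config.pleiotropy_scale * base, 0.0)

    b1 = config.true_beta_exp_med
    b2 = config.true_beta_med_out
    total = config.true_total_exp_out
    true_exp = gamma
    true_med = b1 * gamma + delta
    true_out = total * gamma + b2 * delta + omega + pleio

    exposure = SummaryDataset("exposure", "continuous",
                              _observed_table(rng_exp, snp, chrom, pos, ea, oa, eaf, true_exp, config.n_exposure))
    mediator = SummaryDataset("mediator", "continuous",
                              _observed_table(rng_med, snp, chrom, pos, ea, oa, eaf, true_med, config.n_mediator))
    outcome = SummaryDataset("outcome", "binary",
                             _observed_table(rng_out, snp, chrom, pos, ea, oa, eaf, true_out, config.n_outcome))

    r2 = np.eye(m)
    if config.ld_block_size > 1 and config.ld_r2 > 0:
        same_block = block[:, None] == block[None, :]
        r2 = np.where(same_block, config.ld_r2, 0.0)
        np.fill_diagonal(r2, 1.0)
    ld = LDMatrix(list(snp), r2)

    truth = {
        "beta1_exp_med": b1,
        "beta2_med_out": b2,
        "direct_exp_out": config.true_direct_exp_out,
        "total_exp_out": total,
        "prop_mediated": (b1 * b2 / total) if total != 0 else 0.0,
        "gamma": dict(zip(snp, gamma)),
        "delta": dict(zip(snp, delta)),
        "omega": dict(zip(snp, omega)),
        "pleiotropic_snps": list(snp[is_pleio]),
        "exposure_instrument_snps": list(snp[role == "exposure"]),
        "mediator_instrument_snps": list(snp[role == "mediator"]),
        "outcome_instrument_snps": list(snp[role == "outcome"]),
        "seed": config.seed,
    }
    return SimulatedPanel(exposure, mediator, outcome, ld, truth)


def inject_outliers(dataset: SummaryDataset, snp_ids: Sequence[str], shift: float) -> SummaryDataset:
    """Return a copy with the named variants' betas shifted by ``shift``.

    P-values of the shifted rows are recomputed from the new Wald statistic
    so the dataset stays internally consistent; all other rows are untouched.
    """
    unknown = [s for s in snp_ids if s not in dataset]
    if unknown:
        raise ValueError(f"inject_outliers: unknown snp ids {unknown}")
    table = dataset.table.copy()
    mask = table["SNP"].isin(set(snp_ids)).to_numpy()
    if shift != 0.0 and mask.any():
        table.loc[mask, "BETA"] = table.loc[mask, "BETA"] + shift
        table.loc[mask, "P"] = _wald_p(table.loc[mask, "BETA"].to_numpy(),
                                       table.loc[mask, "SE"].to_numpy())
    return SummaryDataset(dataset.trait_name, dataset.trait_type, table)


def simulate_screen_panel(
    n_traits: int,
    causal_index: int = 0,
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> tuple[list[SummaryDataset], SummaryDataset, LDMatrix, list[dict]]:
    """A multi-exposure panel sharing one outcome, for screening-workflow runs.

    Each exposure gets its own (disjoint) variant set; only the exposure at
    ``causal_index`` keeps the configured causal chain — all others have zero
    exposure→outcome and exposure→mediator effects. The per-trait outcome and
    LD pieces are concatenated into a single outcome dataset and a
    block-diagonal LD matrix.
    """
    base = config or SimulationConfig()
    exposures: list[SummaryDataset] = []
    outcome_parts: list[pd.DataFrame] = []
    ld_ids: list[str] = []
    ld_blocks: list[np.ndarray] = []
    truths: list[dict] = []
    for t in range(n_traits):
        causal = t == causal_index
        cfg = dataclasses.replace(
            base,
            seed=seed + 7919 * t + 13,
            true_beta_exp_med=base.true_beta_exp_med if causal else 0.0,
            true_beta_med_out=base.true_beta_med_out if causal else 0.0,
            true_direct_exp_out=base.true_direct_exp_out if causal else 0.0,
        )
        panel = simulate_panel(cfg)
        exp_table = panel.exposure.table.copy()
        # disjoint ids per trait
        rename = {s: f"t{t:02d}_{s}" for s in exp_table["SNP"]}
        exp_table["SNP"] = exp_table["SNP"].map(rename)
        out_table = panel.outcome.table.copy()
        out_table["SNP"] = out_table["SNP"].map(rename)
        exp_table["CHR"] = exp_table["CHR"].astype(str)
        exposures.append(SummaryDataset(f"trait{t:02d}", "continuous", exp_table))
        outcome_parts.append(out_table)
        ld_ids.extend(exp_table["SNP"].tolist())
        ld_blocks.append(panel.ld.r2)
        truths.append({**{k: v for k, v in panel.truth.items()
                          if not isinstance(v, dict)}, "trait": f"trait{t:02d}", "causal": causal})
    from scipy.linalg import block_diag
    outcome = SummaryDataset("outcome", "binary", pd.concat(outcome_parts, ignore_index=True))
    ld = LDMatrix(ld_ids, block_diag(*ld_blocks))
    return exposures, outcome, ld, truths
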