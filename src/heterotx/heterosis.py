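"""Mid-parent and high-parent heterosis indices from phenotype tables.

MPH (%) = 100 * (F1 - MP) / MP with MP = (P1 + P2) / 2 (parental mean);
HPH (%) = 100 * (F1 - HP) / HP with HP = max(P1, P2) (better parent).
For all-positive means HP >= MP, hence MPH >= HPH always; both indices are
invariant under rescaling all replicate values by a common positive factor.

Significance uses Welch t-tests: the hybrid replicates against the
per-replicate parent-pair means (for MP) and against the higher parent's
replicates (for HP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["HeterosisResult", "heterosis_indices", "condition_effect"]


@dataclass(frozen=True)
class HeterosisResult:
    trait: str
    trio_id: str
    condition: str
    F1_mean: float
    P1_mean: float
    P2_mean: float
    MP: float
    HP: float
    MPH_pct: float
    HPH_pct: float
    p_vs_MP: float
    p_vs_HP: float

    def __post_init__(self):
        # provable for positive means: HP >= MP implies (F1-HP)/HP <= (F1-MP)/MP
        if self.MPH_pct < self.HPH_pct - 1e-9:
            raise AssertionError("MPH < HPH with all-positive means")


def _replicates(pheno: pd.DataFrame, trait: str, genotype: str,
                condition: str) -> np.ndarray:
    sub = pheno[(pheno["trait"] == trait)
                & (pheno["genotype_id"] == genotype)
                & (pheno["condition"] == condition)]
    if len(sub) == 0:
        raise ValueError(f"no phenotype rows for {genotype}/{trait}/{condition}")
    if len(sub) < 2:
        raise ValueError(f"{genotype}/{trait}/{condition}: need >= 2 replicates")
    values = sub.sort_values("replicate")["value"].to_numpy(dtype=float)
    if np.any(values <= 0):
        raise ValueError("phenotype values must be > 0")
    return values


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 and np.std(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def heterosis_indices(pheno: pd.DataFrame, trait: str, trio_id: str,
                      hybrid: str, parent1: str, parent2: str,
                      condition: str) -> HeterosisResult:
    """MPH/HPH (in percent) and Welch tests for one trait x trio x condition.

    The mid-parent comparison group is built by pairing the parents'
    replicates by sorted replicate index and averaging each pair.
    """
    f1 = _replicates(pheno, trait, hybrid, condition)
    p1 = _replicates(pheno, trait, parent1, condition)
    p2 = _replicates(pheno, trait, parent2, condition)
    f1_mean, p1_mean, p2_mean = f1.mean(), p1.mean(), p2.mean()
    mp = (p1_mean + p2_mean) / 2.0
    hp = max(p1_mean, p2_mean)
    n_pair = min(len(p1), len(p2))
    mp_group = (p1[:n_pair] + p2[:n_pair]) / 2.0
    hp_group = p1 if p1_mean >= p2_mean else p2
    return HeterosisResult(
        trait=trait, trio_id=trio_id, condition=condition,
        F1_mean=float(f1_mean), P1_mean=float(p1_mean),
        P2_mean=float(p2_mean), MP=float(mp), HP=float(hp),
        MPH_pct=float(100.0 * (f1_mean - mp) / mp),
        HPH_pct=float(100.0 * (f1_mean - hp) / hp),
        p_vs_MP=_welch_p(f1, mp_group),
        p_vs_HP=_welch_p(f1, hp_group),
    )


def condition_effect(pheno: pd.DataFrame, genotype: str, trait: str,
                     condition: str = "WD", baseline: str = "WW") -> tuple:
    """Percent change of a trait under one condition relative to baseline.

    Returns (percent_change, Welch p-value); e.g. a WD mean of 51.4 against
    a WW mean of 100 gives -48.6%.
    """
    treated = _replicates(pheno, trait, genotype, condition)
    control = _replicates(pheno, trait, genotype, baseline)
    pct = 100.0 * (treated.mean() - control.mean()) / control.mean()
    return float(pct), _welch_p(treated, control)
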