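"""Per-gene inheritance classification for hybrid/parent trios.

Two layers, per trio and condition:

1. **Presence/absence variation (PAV)** over the (hybrid, parent1, parent2)
   expressed/silent triple:
   type I — both parents expressed, hybrid silent;
   type II — exactly one parent expressed, hybrid silent;
   type III — hybrid expressed, both parents silent;
   type IV — hybrid plus exactly one parent expressed;
   type V — all three expressed.
   Genes silent in all three cells are excluded (``not_detected``).

2. **Expression mode** within type V, from hybrid-vs-parent and
   hybrid-vs-midparent tests: additive (F1 = mid-parent value
   MPV = (P1+P2)/2), high/low dominance (F1 equal to the higher/lower
   parent while the parents differ), overdominant (F1 above both parents),
   underdominant (below both), or ``other``.

"Expressed" is operationalized as value >= tau in >= k replicates
(defaults tau = 1, k = 2), and "equal" as not significantly different
under the same |FC| > 2, FDR < 5% rule used for DE throughout; BH is
applied within each test family (per comparison, per trio x condition).
Type III genes behave as overdominant, so ``merged_overdominant`` unions
them with the type-V overdominant class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_io import TrioExpressionSet
from .diffexpr import bh_adjust, nb_wald, size_factors

__all__ = [
    "PAV_TYPES",
    "MODE_LABELS",
    "expressed_flag",
    "classify_pav",
    "classify_mode",
    "midparent_test",
    "classify_all",
    "merged_overdominant",
]

PAV_TYPES = ("I", "II", "III", "IV", "V")
MODE_LABELS = ("additive", "high_dominance", "low_dominance", "overdominant",
               "underdominant", "other")


def expressed_flag(replicate_values, tau: float = 1.0,
                   min_reps: int = 2) -> bool:
    """True iff at least ``min_reps`` replicates reach ``tau``."""
    values = np.asarray(replicate_values, dtype=float)
    return int(np.sum(values >= tau)) >= min_reps


def classify_pav(f1: bool, p1: bool, p2: bool) -> str:
    """PAV type from the three expressed flags; raises on the all-silent case."""
    if not (f1 or p1 or p2):
        raise ValueError("gene not detected in any of the three cells")
    if f1:
        if p1 and p2:
            return "V"
        return "IV" if (p1 or p2) else "III"
    if p1 and p2:
        return "I"
    return "II"


def classify_mode(f1_vs_p1: str, f1_vs_p2: str, f1_vs_mpv: str,
                  p1_vs_p2: str) -> str:
    """Expression mode from four tri-state test outcomes.

    Each argument is ``"higher"`` / ``"equal"`` / ``"lower"`` for the first
    member of the comparison.  Precedence: the additive (mid-parent) test is
    evaluated first, then overdominant, underdominant, high dominance, low
    dominance; anything left is ``other``.
    """
    for state in (f1_vs_p1, f1_vs_p2, f1_vs_mpv, p1_vs_p2):
        if state not in ("higher", "equal", "lower"):
            raise ValueError(f"invalid tri-state {state!r}")
    if f1_vs_mpv == "equal":
        return "additive"
    if f1_vs_p1 == "higher" and f1_vs_p2 == "higher":
        return "overdominant"
    if f1_vs_p1 == "lower" and f1_vs_p2 == "lower":
        return "underdominant"
    if (f1_vs_p1 == "equal" and p1_vs_p2 == "higher") or \
       (f1_vs_p2 == "equal" and p1_vs_p2 == "lower"):
        return "high_dominance"
    if (f1_vs_p1 == "equal" and p1_vs_p2 == "lower") or \
       (f1_vs_p2 == "equal" and p1_vs_p2 == "higher"):
        return "low_dominance"
    return "other"


def _tri_state(log2fc, fdr, fc_threshold, fdr_threshold):
    gate = np.log2(fc_threshold)
    sig = fdr < fdr_threshold
    out = np.full(len(log2fc), "equal", dtype=object)
    out[sig & (log2fc > gate)] = "higher"
    out[sig & (log2fc < -gate)] = "lower"
    return out


def _cell_matrix(frame: pd.DataFrame, sheet, trio_id, role, condition):
    return frame[sheet.samples(trio_id, role, condition)].to_numpy(dtype=float)


def midparent_test(eset: TrioExpressionSet, trio_id: str, condition: str,
                   genes=None, alpha_mode="shared_mom",
                   fc_threshold: float = 2.0, fdr_threshold: float = 0.05
                   ) -> pd.DataFrame:
    """Hybrid vs mid-parent pseudo-group test for (a subset of) genes.

    The mid-parent pseudo-group pairs the parents' normalized replicate
    values by replicate index and takes (P1 + P2) / 2 per pairing, then
    applies the NB Wald machinery hybrid vs pseudo-group.  BH is applied
    across the tested genes.
    """
    sf = pd.Series(size_factors(eset.counts), index=eset.counts.columns)
    norm = eset.counts / sf
    if genes is not None:
        norm = norm.loc[genes]
    f1 = _cell_matrix(norm, eset.sheet, trio_id, "hybrid", condition)
    p1 = _cell_matrix(norm, eset.sheet, trio_id, "parent1", condition)
    p2 = _cell_matrix(norm, eset.sheet, trio_id, "parent2", condition)
    n_pair = min(p1.shape[1], p2.shape[1])
    mp = (p1[:, :n_pair] + p2[:, :n_pair]) / 2.0
    res = nb_wald(f1, mp, alpha_mode=alpha_mode)
    res.insert(0, "gene_id", norm.index.to_numpy())
    res["fdr"] = bh_adjust(res["p_value"].to_numpy())
    res["state"] = _tri_state(res["log2fc"].to_numpy(), res["fdr"].to_numpy(),
                              fc_threshold, fdr_threshold)
    return res


def classify_all(eset: TrioExpressionSet, tau: float = 1.0, min_reps: int = 2,
                 fc_threshold: float = 2.0, fdr_threshold: float = 0.05,
                 alpha_mode="shared_mom") -> pd.DataFrame:
    """Classify every gene per trio x condition: PAV type, then mode.

    Expression flags use FPKM when available, otherwise size-factor-
    normalized counts.  For type-V genes, four NB Wald comparisons are run
    (F1 vs P1, F1 vs P2, F1 vs mid-parent pseudo-group, P1 vs P2), each
    BH-corrected across the type-V genes of that trio x condition, and the
    resulting tri-states feed :func:`classify_mode`.

    Returns one row per (gene, trio, condition) with columns ``pav_type``
    (``not_detected`` for all-silent genes), ``mode`` (``not_applicable``
    outside type V), ``merged_overdominant`` and the four tri-state
    evidence columns.
    """
    sf = pd.Series(size_factors(eset.counts), index=eset.counts.columns)
    norm = eset.counts / sf
    flag_expr = eset.fpkm if eset.fpkm is not None else norm
    sheet = eset.sheet
    records = []
    for trio_id in sheet.trios():
        for condition in sheet.conditions():
            mats = {role: _cell_matrix(flag_expr, sheet, trio_id, role,
                                       condition)
                    for role in ("hybrid", "parent1", "parent2")}
            flags = {role: (np.sum(m >= tau, axis=1) >= min_reps)
                     for role, m in mats.items()}
            f1, p1, p2 = flags["hybrid"], flags["parent1"], flags["parent2"]
            detected = f1 | p1 | p2
            pav = np.full(eset.n_genes, "not_detected", dtype=object)
            idx = np.where(detected)[0]
            for i in idx:
                pav[i] = classify_pav(bool(f1[i]), bool(p1[i]), bool(p2[i]))

            mode = np.full(eset.n_genes, "not_applicable", dtype=object)
            states = {key: np.full(eset.n_genes, "", dtype=object)
                      for key in ("f1_vs_p1", "f1_vs_p2", "f1_vs_mpv",
                                  "p1_vs_p2")}
            v_mask = pav == "V"
            if v_mask.any():
                nf1 = _cell_matrix(norm, sheet, trio_id, "hybrid",
                                   condition)[v_mask]
                np1 = _cell_matrix(norm, sheet, trio_id, "parent1",
                                   condition)[v_mask]
                np2 = _cell_matrix(norm, sheet, trio_id, "parent2",
                                   condition)[v_mask]
                n_pair = min(np1.shape[1], np2.shape[1])
                nmp = (np1[:, :n_pair] + np2[:, :n_pair]) / 2.0
                comparisons = {"f1_vs_p1": (nf1, np1), "f1_vs_p2": (nf1, np2),
                               "f1_vs_mpv": (nf1, nmp),
                               "p1_vs_p2": (np1, np2)}
                tri = {}
                for key, (a, b) in comparisons.items():
                    res = nb_wald(a, b, alpha_mode=alpha_mode)
                    fdr = bh_adjust(res["p_value"].to_numpy())
                    tri[key] = _tri_state(res["log2fc"].to_numpy(), fdr,
                                          fc_threshold, fdr_threshold)
                    states[key][v_mask] = tri[key]
                v_idx = np.where(v_mask)[0]
                for j, i in enumerate(v_idx):
                    mode[i] = classify_mode(tri["f1_vs_p1"][j],
                                            tri["f1_vs_p2"][j],
                                            tri["f1_vs_mpv"][j],
                                            tri["p1_vs_p2"][j])
            merged = (pav == "III") | (mode == "overdominant")
            frame = pd.DataFrame({
                "gene_id": eset.gene_ids,
                "trio_id": trio_id,
                "condition": condition,
                "pav_type": pav,
                "mode": mode,
                "merged_overdominant": merged,
                **states,
            })
            records.append(frame)
    calls = pd.concat(records, ignore_index=True)
    _assert_partition(calls)
    return calls


def _assert_partition(calls: pd.DataFrame) -> None:
    """PAV labels partition detected genes; modes partition type V."""
    detected = calls[calls["pav_type"] != "not_detected"]
    if not detected["pav_type"].isin(PAV_TYPES).all():
        raise AssertionError("invalid PAV label")
    type_v = calls[calls["pav_type"] == "V"]
    if not type_v["mode"].isin(MODE_LABELS).all():
        raise AssertionError("type-V gene without a mode label")
    non_v = detected[detected["pav_type"] != "V"]
    if not (non_v["mode"] == "not_applicable").all():
        raise AssertionError("mode assigned outside type V")


def merged_overdominant(calls: pd.DataFrame, trio_id: str,
                        condition: str) -> frozenset:
    """Union of type-III genes and type-V overdominant genes (disjoint by
    construction, so the union size is the exact sum)."""
    sub = calls[(calls["trio_id"] == trio_id)
                & (calls["condition"] == condition)]
    return frozenset(sub.loc[sub["merged_overdominant"], "gene_id"])


def mode_gene_set(calls: pd.DataFrame, trio_id: str, condition: str,
                  mode: str) -> frozenset:
    """Type-V genes of one mode for a trio x condition."""
    sub = calls[(calls["trio_id"] == trio_id)
                & (calls["condition"] == condition) & (calls["mode"] == mode)]
    return frozenset(sub["gene_id"])


def summarize_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Count table of PAV types and modes per trio x condition."""
    pav_counts = (calls[calls["pav_type"] != "not_detected"]
                  .groupby(["trio_id", "condition", "pav_type"])
                  .size().rename("count").reset_index())
    pav_counts["layer"] = "pav"
    pav_counts = pav_counts.rename(columns={"pav_type": "label"})
    mode_counts = (calls[calls["pav_type"] == "V"]
                   .groupby(["trio_id", "condition", "mode"])
                   .size().rename("count").reset_index())
    mode_counts["layer"] = "mode"
    mode_counts = mode_counts.rename(columns={"mode": "label"})
    return pd.concat([pav_counts, mode_counts], ignore_index=True)[
        ["trio_id", "condition", "layer", "label", "count"]]
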