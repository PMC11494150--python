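"""Synthetic trio RNA-seq experiments with known inheritance ground truth.

Emulates the study design this package targets: two maize hybrid/parent
trios (AB = AA x BB, CD = CC x DD), three watering conditions (WW, WD, RW),
three replicate libraries per genotype x condition — 54 libraries.  Each
gene carries a ground-truth inheritance mode and drought-response
direction, so every downstream stage (DE, PAV and mode classification,
conserved-set algebra, enrichment) can be scored against truth.

Counts are negative binomial with variance mu + alpha * mu^2, sampled via
the gamma–Poisson mixture; one shared seed drives a counter-based
substream per gene, so the matrix is reproducible independently of gene
order or chunking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import AnnotationMap, SampleSheet, TrioExpressionSet

__all__ = [
    "MODES",
    "RESPONSES",
    "TrioSpec",
    "SimConfig",
    "SimTruth",
    "PhenotypeSpec",
    "simulate",
    "simulate_phenotypes",
    "simulate_annotation",
]

MODES = ("additive", "high_dom", "low_dom", "overdominant", "underdominant",
         "pav_I", "pav_II", "pav_III", "pav_IV")
RESPONSES = ("up_WD", "down_WD", "null")
_ROLES = ("hybrid", "parent1", "parent2")


@dataclass(frozen=True)
class TrioSpec:
    trio_id: str
    hybrid: str
    parent1: str
    parent2: str


def _default_trios():
    return (TrioSpec("AB", "AB", "AA", "BB"), TrioSpec("CD", "CD", "CC", "DD"))


def _default_mode_proportions():
    return {
        "additive": 0.45, "high_dom": 0.12, "low_dom": 0.12,
        "overdominant": 0.08, "underdominant": 0.08,
        "pav_I": 0.03, "pav_II": 0.04, "pav_III": 0.04, "pav_IV": 0.04,
    }


def _default_response_proportions():
    return {"up_WD": 0.15, "down_WD": 0.15, "null": 0.70}


@dataclass
class SimConfig:
    """Generating parameters for a synthetic trio experiment.

    ``effect_log2fc`` is both the parental split (high vs low parent) and
    the over/underdominance and condition-response magnitude, in log2
    units.  ``baseline_logmean_range`` is the log2 range of the baseline
    expected normalized count per gene.  ``mode_shared_across_trios``
    (default True) assigns the same inheritance mode to a gene in every
    trio, reflecting the conserved dominance classes the analysis looks
    for; set False for independent per-trio modes.
    """

    n_genes: int = 2000
    trios: tuple = field(default_factory=_default_trios)
    conditions: tuple = ("WW", "WD", "RW")
    n_replicates: int = 3
    lib_size_mean: float = 2e7
    lib_size_cv: float = 0.1
    dispersion: float = 0.05
    mode_proportions: dict = field(default_factory=_default_mode_proportions)
    response_proportions: dict = field(
        default_factory=_default_response_proportions)
    effect_log2fc: float = 2.0
    baseline_logmean_range: tuple = (6.0, 11.0)
    reset_probability: float = 0.6
    mode_shared_across_trios: bool = True
    low_expression_pav: bool = False  # PAV "silent" cells at 0.1x baseline instead of 0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for name, props in (("mode_proportions", self.mode_proportions),
                            ("response_proportions", self.response_proportions)):
            vals = np.array(list(props.values()), dtype=float)
            if np.any(vals < 0) or not np.isclose(vals.sum(), 1.0):
                raise ValueError(f"{name} must be a simplex (sum to 1)")
        unknown = set(self.mode_proportions) - set(MODES)
        if unknown:
            raise ValueError(f"unknown modes: {sorted(unknown)}")
        unknown = set(self.response_proportions) - set(RESPONSES)
        if unknown:
            raise ValueError(f"unknown responses: {sorted(unknown)}")


@dataclass
class SimTruth:
    """Ground truth: per-gene mode per trio, response, and true means.

    ``genes`` has columns ``gene_id``, ``mode_<trio>`` for each trio,
    ``response`` (up/down/null) and ``rewatering_reset``; ``mu`` holds the
    true normalized-scale mean per gene with MultiIndex columns
    (trio_id, role, condition).
    """

    genes: pd.DataFrame
    mu: pd.DataFrame
    config: SimConfig

    def modes(self, trio_id: str) -> pd.Series:
        return self.genes.set_index("gene_id")[f"mode_{trio_id}"]


def _draw_categories(rng, labels, probs, n):
    return rng.choice(np.asarray(labels, dtype=object), size=n, p=probs)


def _ww_means(mode: str, baseline: float, e: float, p1_high: bool,
              silent: float):
    """(hybrid, parent1, parent2) WW means from the mode-construction rules.

    Parents are split by ``e`` (log2) only for the dominance modes, where
    unequal parents are definitional; additive and over/underdominant genes
    have equal parents, so most genes are not parent-DE and median-of-ratios
    normalization stays valid.  ``silent`` is the mean used for PAV-absent
    cells (0 by default)."""
    half = 2.0 ** (e / 2.0)
    hi, lo = baseline * half, baseline / half
    p1, p2 = (hi, lo) if p1_high else (lo, hi)
    if mode == "additive":
        return (baseline, baseline, baseline)
    if mode == "high_dom":
        return (max(p1, p2), p1, p2)
    if mode == "low_dom":
        return (min(p1, p2), p1, p2)
    if mode == "overdominant":
        return (baseline * 2.0 ** e, baseline, baseline)
    if mode == "underdominant":
        return (baseline / 2.0 ** e, baseline, baseline)
    if mode == "pav_I":
        return (silent, baseline, baseline)
    if mode == "pav_II":
        return (silent, baseline, silent) if p1_high else (silent, silent, baseline)
    if mode == "pav_III":
        return (baseline, silent, silent)
    if mode == "pav_IV":
        return (baseline, baseline, silent) if p1_high \
            else (baseline, silent, baseline)
    raise ValueError(f"unknown mode {mode!r}")


def simulate(config: SimConfig) -> tuple:
    """Draw a synthetic trio experiment; returns (TrioExpressionSet, SimTruth).

    Deterministic given ``config.seed``.  The condition response scales all
    roles of a gene equally under WD (up: x 2^e, down: / 2^e); RW means
    revert to the WW value for genes with ``rewatering_reset`` and stay at
    the WD level otherwise.
    """
    cfg = config
    design_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0,)))
    n = cfg.n_genes
    gene_ids = [f"G{i:06d}" for i in range(1, n + 1)]

    mode_labels = list(cfg.mode_proportions)
    mode_probs = np.array([cfg.mode_proportions[m] for m in mode_labels])
    resp_labels = list(cfg.response_proportions)
    resp_probs = np.array([cfg.response_proportions[r] for r in resp_labels])

    baseline = 2.0 ** design_rng.uniform(*cfg.baseline_logmean_range, size=n)
    response = _draw_categories(design_rng, resp_labels, resp_probs, n)
    reset = design_rng.random(n) < cfg.reset_probability

    modes = {}
    p1_high = {}
    shared_mode = _draw_categories(design_rng, mode_labels, mode_probs, n)
    shared_hi = design_rng.random(n) < 0.5
    for trio in cfg.trios:
        if cfg.mode_shared_across_trios:
            modes[trio.trio_id] = shared_mode
            p1_high[trio.trio_id] = shared_hi
        else:
            modes[trio.trio_id] = _draw_categories(
                design_rng, mode_labels, mode_probs, n)
            p1_high[trio.trio_id] = design_rng.random(n) < 0.5

    # true normalized-scale means, (trio, role, condition) columns
    cols = pd.MultiIndex.from_tuples(
        [(t.trio_id, role, cond) for t in cfg.trios for role in _ROLES
         for cond in cfg.conditions],
        names=["trio_id", "role", "condition"])
    mu = np.zeros((n, len(cols)))
    col_pos = {key: i for i, key in enumerate(cols)}
    e = cfg.effect_log2fc
    for g in range(n):
        silent_frac = 0.1 if cfg.low_expression_pav else 0.0
        resp_factor = {"up_WD": 2.0 ** e, "down_WD": 2.0 ** -e,
                       "null": 1.0}[response[g]]
        for trio in cfg.trios:
            ww = _ww_means(modes[trio.trio_id][g], baseline[g], e,
                           bool(p1_high[trio.trio_id][g]),
                           silent_frac * baseline[g])
            for role, m_ww in zip(_ROLES, ww):
                for cond in cfg.conditions:
                    if cond == "WW":
                        m = m_ww
                    elif cond == "WD":
                        m = m_ww * resp_factor
                    else:  # RW
                        m = m_ww if (reset[g] or response[g] == "null") \
                            else m_ww * resp_factor
                    mu[g, col_pos[(trio.trio_id, role, cond)]] = m

    # sample sheet and library-size factors
    rows = []
    for trio in cfg.trios:
        for role, geno in zip(_ROLES, (trio.hybrid, trio.parent1, trio.parent2)):
            for cond in cfg.conditions:
                for rep in range(1, cfg.n_replicates + 1):
                    rows.append({
                        "sample_id": f"{geno}_{cond}_{rep}",
                        "trio_id": trio.trio_id, "role": role,
                        "condition": cond, "replicate": rep,
                        "genotype_id": geno,
                    })
    sheet_df = pd.DataFrame(rows)
    n_samples = len(sheet_df)
    sigma = np.sqrt(np.log1p(cfg.lib_size_cv ** 2))
    lib = cfg.lib_size_mean * np.exp(
        design_rng.normal(-sigma ** 2 / 2.0, sigma, size=n_samples))
    s = lib / cfg.lib_size_mean  # relative library-size factors

    # per-sample true mean for each gene: mu of that sample's design cell
    cell_idx = np.array([col_pos[(r.trio_id, r.role, r.condition)]
                         for r in sheet_df.itertuples()])
    counts = np.empty((n, n_samples), dtype=np.int64)
    shape = 1.0 / cfg.dispersion
    for g in range(n):
        rng_g = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1, g)))
        m = s * mu[g, cell_idx]
        lam = rng_g.gamma(shape, m * cfg.dispersion)
        counts[g] = rng_g.poisson(lam)

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=sheet_df["sample_id"])
    eset = TrioExpressionSet(counts=counts_df, sheet=SampleSheet(sheet_df))
    genes = pd.DataFrame({"gene_id": gene_ids})
    for trio in cfg.trios:
        genes[f"mode_{trio.trio_id}"] = modes[trio.trio_id]
    genes["response"] = response
    genes["rewatering_reset"] = reset
    truth = SimTruth(genes=genes,
                     mu=pd.DataFrame(mu, index=genes["gene_id"], columns=cols),
                     config=cfg)
    return eset, truth


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeSpec:
    """Generating means for one trait of one trio.

    ``means`` maps condition -> (hybrid, parent1, parent2) trait means.
    """

    trait: str
    hybrid: str
    parent1: str
    parent2: str
    means: dict  # condition -> (f1, p1, p2)
    sd: float = 0.5
    n_rep: int = 5

    def __post_init__(self):
        if self.n_rep < 2:
            raise ValueError("n_rep must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        for cond, triple in self.means.items():
            if any(m <= 0 for m in triple):
                raise ValueError(
                    f"non-positive mean for {self.trait}/{cond}")


def simulate_phenotypes(trait_specs, seed: int) -> pd.DataFrame:
    """Replicate trait values: normal draws truncated at zero (by redraw).

    Returns the long phenotype table (trait, genotype_id, condition,
    replicate, value); deterministic given ``seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(2,)))
    rows = []
    for spec in trait_specs:
        for cond, (f1, p1, p2) in spec.means.items():
            for geno, mean in ((spec.hybrid, f1), (spec.parent1, p1),
                               (spec.parent2, p2)):
                for rep in range(1, spec.n_rep + 1):
                    value = rng.normal(mean, spec.sd) if spec.sd > 0 else mean
                    while value <= 0:
                        value = rng.normal(mean, spec.sd)
                    rows.append({"trait": spec.trait, "genotype_id": geno,
                                 "condition": cond, "replicate": rep,
                                 "value": value})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# annotation maps with known enrichment
# ---------------------------------------------------------------------------

def simulate_annotation(truth: SimTruth, n_terms: int,
                        enriched_fraction: float, seed: int,
                        term_size_range: tuple = (20, 80),
                        packing: float = 0.9) -> AnnotationMap:
    """Gene→term map with a known fraction of deliberately enriched terms.

    An enriched term draws ``packing`` of its members from one
    mode/response class (the class is recorded in the term name as
    ``enriched:<class>``); the rest, and all null terms, are uniform draws
    from the gene universe.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(3,)))
    amap = AnnotationMap()
    if n_terms == 0:
        return amap
    universe = truth.genes["gene_id"].to_numpy()
    first_trio = truth.config.trios[0].trio_id
    class_pools = {}
    for resp in ("up_WD", "down_WD"):
        pool = universe[truth.genes["response"].to_numpy() == resp]
        if len(pool):
            class_pools[f"response:{resp}"] = pool
    for mode in ("overdominant", "underdominant"):
        pool = universe[truth.genes[f"mode_{first_trio}"].to_numpy() == mode]
        if len(pool):
            class_pools[f"mode:{mode}"] = pool
    n_enriched = int(round(enriched_fraction * n_terms))
    class_names = list(class_pools)
    for i in range(n_terms):
        size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        size = min(size, len(universe))
        if i < n_enriched and class_names:
            cls = class_names[i % len(class_names)]
            pool = class_pools[cls]
            n_packed = min(int(round(packing * size)), len(pool))
            packed = rng.choice(pool, size=n_packed, replace=False)
            rest = rng.choice(universe, size=size - n_packed, replace=False)
            genes = set(packed) | set(rest)
            name = f"enriched:{cls}"
        else:
            genes = set(rng.choice(universe, size=size, replace=False))
            name = "null"
        amap.add(f"T{i:04d}", name, genes)
    return amap
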