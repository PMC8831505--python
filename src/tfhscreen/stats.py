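"""Hit-calling statistics for pooled screens.

The analysis chain: per-guide log2 fold changes of CPM-normalized
counts between two populations (paired within mouse when sorts are
individual), averaged hierarchically — mean over mice within an
experiment, then mean over experiments — then summarized per gene as
mean +/- SEM over its guides.  Gene significance comes from two
complementary routes: a Z-score standardized against non-targeting
control pseudo-genes, and an alpha-restricted robust rank aggregation
(alpha-RRA) score with a control-guide permutation null and
Benjamini-Hochberg FDR.  Genes are finally classified by the quadrant
they occupy in the (Tfh/culture, Th1/culture) plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .library import GuideLibrary
from .quant import cpm_normalize
from .simulate import CountTable

__all__ = [
    "COMPARISONS",
    "Comparison",
    "guide_l2fc",
    "hierarchical_average",
    "compute_comparison",
    "guide_overall_means",
    "gene_summary",
    "gene_table",
    "control_pseudogenes",
    "control_zscore",
    "rra_score",
    "rra_gene_test",
    "classify_hits",
    "analyze_screen",
]


@dataclass(frozen=True)
class Comparison:
    """A named numerator/denominator population contrast."""

    name: str
    numerator: str          # "Tfh" means preTfh+GCTfh combined
    denominator: str
    paired_by: str          # "mouse" or "pooled"


COMPARISONS: dict[str, Comparison] = {
    c.name: c
    for c in [
        Comparison("Tfh_vs_Th1", "Tfh", "Th1", "mouse"),
        Comparison("Tfh_vs_culture", "Tfh", "culture", "mouse"),
        Comparison("Th1_vs_culture", "Th1", "culture", "mouse"),
        Comparison("culture_vs_plasmid", "culture", "plasmid", "pooled"),
        Comparison("preTfh_vs_Th1", "preTfh", "Th1", "mouse"),
        Comparison("GCTfh_vs_Th1", "GCTfh", "Th1", "mouse"),
    ]
}


def guide_l2fc(cpm_num: float, cpm_den: float, pseudocount: float = 0.5) -> float:
    """log2((num + pc) / (den + pc)); pc must be > 0 if either side can be 0."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (cpm_num == 0 or cpm_den == 0):
        raise ValueError("zero CPM requires a positive pseudocount")
    return float(np.log2((cpm_num + pseudocount) / (cpm_den + pseudocount)))


def hierarchical_average(
    values: pd.Series | pd.DataFrame,
) -> tuple[float, pd.Series]:
    """Replicate hierarchy: mean over mice within experiment, then
    unweighted mean over experiments.

    ``values``: Series indexed by (experiment_id, mouse_id) — or a
    DataFrame with columns experiment_id, mouse_id, value.  Experiments
    with unequal mouse counts weight equally at the top level.  Returns
    (overall_mean, per-experiment means).
    """
    if isinstance(values, pd.DataFrame):
        values = values.set_index(["experiment_id", "mouse_id"])["value"]
    values = values.dropna()
    if values.empty:
        raise ValueError("no replicate values to average")
    mouse_means = values.groupby(level=[0, 1]).mean()
    exp_means = mouse_means.groupby(level=0).mean()
    return float(exp_means.mean()), exp_means


def _population_columns(
    table: CountTable, population: str, experiment_id: str | None = None
) -> tuple[pd.DataFrame, dict[str, tuple[str, str]]]:
    """Raw counts for one population plus a column -> (experiment,
    mouse) map.  The combined "Tfh" population sums the preTfh and
    GCTfh gates per mouse (or per pooled sample)."""
    meta = table.samples
    if population != "Tfh":
        cols = table.columns_for(population, experiment_id)
        info = {c: (meta.loc[c, "experiment_id"], meta.loc[c, "mouse_id"])
                for c in cols}
        return table.counts[cols], info
    out = {}
    info = {}
    tfh_meta = meta[meta["population"].isin(["preTfh", "GCTfh"])]
    for (exp, mouse), grp in tfh_meta.groupby(["experiment_id", "mouse_id"]):
        if experiment_id is not None and exp != experiment_id:
            continue
        cols = [s for s in grp.index if s in table.counts.columns]
        if not cols:
            continue
        name = f"{mouse or exp + '_pooled'}_Tfh"
        out[name] = table.counts[cols].sum(axis=1)
        info[name] = (exp, mouse)
    return pd.DataFrame(out, index=table.counts.index), info


def compute_comparison(
    table: CountTable,
    comparison: str | Comparison,
    pseudocount: float = 0.5,
    drop_double_zero: bool = True,
) -> pd.DataFrame:
    """Per-guide per-replicate L2FC table for a named contrast.

    Returns a long DataFrame (guide_id, experiment_id, mouse_id, value).
    Ratios are computed within mouse for mouse-paired contrasts (the
    denominator for culture/plasmid is the experiment-level sample);
    pooled contrasts yield one value per pooled replicate.  Guides with
    zero counts in both members of a replicate pair are set to NaN
    (excluded downstream) when ``drop_double_zero``.
    """
    comp = COMPARISONS[comparison] if isinstance(comparison, str) else comparison
    meta = table.samples
    rows: list[pd.DataFrame] = []

    def pair_l2fc(num_raw: pd.Series, den_raw: pd.Series,
                  exp_id: str, mouse_id: str) -> pd.DataFrame:
        num_cpm = num_raw * 1e6 / num_raw.sum()
        den_cpm = den_raw * 1e6 / den_raw.sum()
        val = np.log2((num_cpm + pseudocount) / (den_cpm + pseudocount))
        if drop_double_zero:
            val = val.where(~((num_raw == 0) & (den_raw == 0)))
        return pd.DataFrame({
            "guide_id": num_raw.index,
            "experiment_id": exp_id,
            "mouse_id": mouse_id,
            "value": val.to_numpy(),
        })

    experiments = sorted(
        {e for e in meta["experiment_id"] if e != ""}
    ) or [""]
    for exp in experiments:
        num, num_info = _population_columns(
            table, comp.numerator,
            None if comp.numerator == "plasmid" else exp)
        den, den_info = _population_columns(
            table, comp.denominator,
            None if comp.denominator == "plasmid" else exp)
        if num.shape[1] == 0 or den.shape[1] == 0:
            warnings.warn(
                f"{comp.name}: no samples for experiment {exp!r}; skipped"
            )
            continue
        if comp.paired_by == "mouse" and comp.denominator == "Th1":
            # pair numerator and denominator columns within mouse
            den_by_mouse = {m: c for c, (_, m) in den_info.items()}
            for ncol in num.columns:
                mouse = num_info[ncol][1]
                dcol = den_by_mouse.get(mouse)
                if dcol is None:
                    continue
                rows.append(pair_l2fc(num[ncol], den[dcol], exp,
                                      mouse or ncol))
        else:
            # experiment-level denominator (culture or plasmid); one ratio
            # per numerator replicate
            den_col = den.iloc[:, 0]
            for ncol in num.columns:
                mouse = num_info[ncol][1] or ncol
                rows.append(pair_l2fc(num[ncol], den_col, exp, mouse))
    if not rows:
        raise ValueError(f"comparison {comp.name}: no replicate pairs found")
    return pd.concat(rows, ignore_index=True)


def guide_overall_means(replicates: pd.DataFrame) -> pd.Series:
    """Hierarchical overall mean per guide from a long replicate table."""
    def agg(df: pd.DataFrame) -> float:
        vals = df.set_index(["experiment_id", "mouse_id"])["value"].dropna()
        if vals.empty:
            return np.nan
        return hierarchical_average(vals)[0]

    out = replicates.groupby("guide_id", sort=False).apply(agg,
                                                           include_groups=False)
    out.name = "l2fc"
    return out


def gene_summary(guide_means: np.ndarray | pd.Series) -> tuple[float, float]:
    """Gene mean and SEM over its guides' overall means.

    SEM uses the n-1 sample standard deviation; it is NaN for a
    single-guide gene.
    """
    x = np.asarray(pd.Series(guide_means).dropna(), dtype=float)
    if len(x) == 0:
        return np.nan, np.nan
    mean = float(x.mean())
    if len(x) == 1:
        return mean, np.nan
    sem = float(x.std(ddof=1) / np.sqrt(len(x)))
    return mean, sem


def control_pseudogenes(library: GuideLibrary) -> dict[str, list[str]]:
    """Group control guides into pseudo-genes of ``guides_per_gene``
    consecutive guides (library order); a final smaller remainder group
    is kept if it has >= 2 guides."""
    ctrl = library.control_ids
    k = library.guides_per_gene
    groups: dict[str, list[str]] = {}
    for i in range(0, len(ctrl), k):
        chunk = ctrl[i:i + k]
        if len(chunk) == k or len(chunk) >= 2:
            groups[f"CTRL_pg{i // k + 1}"] = chunk
    return groups


def gene_table(guide_means: pd.Series, library: GuideLibrary) -> pd.DataFrame:
    """Per-gene mean and SEM over targeting guides."""
    gene_of = library.gene_of()
    rows = []
    for gene in library.genes:
        ids = [g.guide_id for g in library.guides if g.gene_symbol == gene]
        vals = guide_means.reindex(ids)
        mean, sem = gene_summary(vals)
        rows.append({"gene_symbol": gene, "n_guides": int(vals.notna().sum()),
                     "mean_l2fc": mean, "sem_l2fc": sem})
    return pd.DataFrame(rows).set_index("gene_symbol")


def control_zscore(
    gene_means: pd.Series, control_gene_means: pd.Series | np.ndarray
) -> pd.Series:
    """Standardize gene means against the control pseudo-gene
    distribution: z = (mean - mean(ctrl)) / sd(ctrl), sd with n-1.

    Applied to the control pseudo-genes themselves this yields sample
    mean 0 and sample sd 1 exactly (no leave-one-out correction).
    """
    ctrl = np.asarray(pd.Series(control_gene_means).dropna(), dtype=float)
    if len(ctrl) < 2:
        raise ValueError("need >= 2 control pseudo-genes for a Z-score")
    sd = ctrl.std(ddof=1)
    if sd == 0:
        raise ValueError("control pseudo-gene means have zero spread")
    return (gene_means - ctrl.mean()) / sd


def _beta_min_score(sorted_norm_ranks: np.ndarray, alpha: float) -> float:
    """alpha-RRA score for one gene: min over order statistics j with
    normalized rank < alpha of the Beta(j, k-j+1) lower tail at that
    rank; 1.0 when no guide ranks inside alpha."""
    r = np.sort(np.asarray(sorted_norm_ranks, dtype=float))
    k = len(r)
    j = np.arange(1, k + 1)
    inside = r < alpha
    if not inside.any():
        return 1.0
    tails = sps.beta.cdf(r[inside], j[inside], k - j[inside] + 1)
    return float(tails.min())


def rra_score(norm_ranks: np.ndarray, alpha: float = 0.25) -> float:
    """Public alpha-RRA score of one gene's normalized guide ranks."""
    return _beta_min_score(norm_ranks, alpha)


def _null_scores(
    pool_ranks: np.ndarray, k: int, alpha: float, n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Permutation null: n_perm size-k pseudo-genes drawn (without
    replacement within a draw) from the pool of normalized ranks."""
    n = len(pool_ranks)
    # vectorized sampling without replacement per row
    draws = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k]
    r = np.sort(pool_ranks[draws], axis=1)
    j = np.arange(1, k + 1)
    tails = sps.beta.cdf(r, j, k - j + 1)
    tails[r >= alpha] = np.inf
    scores = tails.min(axis=1)
    scores[~np.isfinite(scores)] = 1.0
    return scores


def rra_gene_test(
    guide_means: pd.Series,
    library: GuideLibrary,
    direction: str = "depleted",
    alpha: float = 0.25,
    n_perm: int = 10_000,
    seed: int = 0,
    null_pool: str = "auto",
) -> pd.DataFrame:
    """alpha-RRA gene test with a permutation null.

    Guides are ranked by L2FC (ascending for ``depleted``, descending
    for ``enriched``; missing values take the worst rank); normalized
    rank = rank / N.  Per gene the score is the minimum Beta order-
    statistic tail over its guides inside the top-alpha fraction;
    p = (1 + #{null <= observed}) / (1 + n_perm); FDR is
    Benjamini-Hochberg over targeting genes.

    The null draws size-matched pseudo-genes from a pool of guide
    ranks.  ``null_pool='controls'`` uses the non-targeting controls;
    ``'all'`` uses every guide (exact under exchangeability); ``'auto'``
    uses controls only when there are at least 10 pseudo-genes worth of
    them — conditioning the null on a handful of control ranks makes
    every gene's p-value rise and fall with that one draw, which a
    small pool cannot estimate stably.
    """
    if direction not in ("depleted", "enriched"):
        raise ValueError("direction must be 'depleted' or 'enriched'")
    if null_pool not in ("auto", "controls", "all"):
        raise ValueError("null_pool must be 'auto', 'controls' or 'all'")
    vals = guide_means.reindex(library.guide_ids)
    x = vals.to_numpy(dtype=float)
    if direction == "enriched":
        x = -x
    # missing values get the worst rank
    worst = np.nanmax(x) if np.isfinite(x).any() else 0.0
    x = np.where(np.isnan(x), worst + 1.0, x)
    ranks = sps.rankdata(x, method="average")
    norm_ranks = ranks / len(x)
    rank_of = pd.Series(norm_ranks, index=library.guide_ids)

    ctrl_ids = library.control_ids
    k = library.guides_per_gene
    min_ctrl = 10 * k if null_pool == "auto" else k
    if null_pool != "all" and len(ctrl_ids) >= min_ctrl:
        pool = rank_of[ctrl_ids].to_numpy()
    else:
        if null_pool == "controls":
            warnings.warn(
                "fewer control guides than guides_per_gene; permutation "
                "null drawn from all guides"
            )
        pool = norm_ranks
    rng = np.random.default_rng(seed)
    null = _null_scores(pool, k, alpha, n_perm, rng)

    rows = []
    for gene in library.genes:
        ids = [g.guide_id for g in library.guides if g.gene_symbol == gene]
        score = _beta_min_score(rank_of[ids].to_numpy(), alpha)
        p = (1 + int((null <= score).sum())) / (1 + n_perm)
        rows.append({"gene_symbol": gene, "rra_score": score, "p_value": p})
    out = pd.DataFrame(rows).set_index("gene_symbol")
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


CATEGORIES = ("required_for_Tfh", "required_for_Th1", "inhibits_expansion",
              "required_for_expansion", "neutral")


def classify_hits(
    tfh_vs_culture: pd.Series,
    th1_vs_culture: pd.Series,
    depletion_threshold: float = -1.0,
    enrichment_threshold: float = 1.0,
) -> pd.Series:
    """Quadrant classification of gene means in the
    (Tfh/culture, Th1/culture) plane.

    Both depleted -> required_for_expansion; both enriched ->
    inhibits_expansion; only Tfh depleted -> required_for_Tfh; only Th1
    depleted -> required_for_Th1; otherwise neutral.
    """
    if depletion_threshold >= 0 or enrichment_threshold <= 0:
        raise ValueError("thresholds must straddle zero")
    genes = tfh_vs_culture.index
    th1 = th1_vs_culture.reindex(genes)
    out = pd.Series("neutral", index=genes, name="category")
    both_down = (tfh_vs_culture < depletion_threshold) & (th1 < depletion_threshold)
    both_up = (tfh_vs_culture > enrichment_threshold) & (th1 > enrichment_threshold)
    tfh_down = (tfh_vs_culture < depletion_threshold) & ~both_down
    th1_down = (th1 < depletion_threshold) & ~both_down
    out[tfh_down] = "required_for_Tfh"
    out[th1_down] = "required_for_Th1"
    out[both_down] = "required_for_expansion"
    out[both_up] = "inhibits_expansion"
    return out


def analyze_screen(
    table: CountTable,
    library: GuideLibrary,
    comparison: str = "Tfh_vs_Th1",
    pseudocount: float = 0.5,
    zscore_reference: str = "controls",
    rra_direction: str = "both",
    alpha: float = 0.25,
    n_perm: int = 10_000,
    seed: int = 0,
    null_pool: str = "auto",
    classify: bool = True,
) -> pd.DataFrame:
    """End-to-end gene results for one contrast.

    Computes per-guide hierarchical L2FCs, gene mean +/- SEM, control-
    anchored Z-scores, alpha-RRA p/FDR (two-sided when
    ``rra_direction='both'``: per gene the smaller of the depleted and
    enriched p-values, doubled and capped at 1), and — when the table
    contains culture samples — the quadrant category.
    """
    reps = compute_comparison(table, comparison, pseudocount)
    gmeans = guide_overall_means(reps)
    genes = gene_table(gmeans, library)

    pg = control_pseudogenes(library)
    if zscore_reference == "controls" and len(pg) >= 2:
        ctrl_means = pd.Series(
            {name: gene_summary(gmeans.reindex(ids))[0]
             for name, ids in pg.items()}
        )
        genes["zscore"] = control_zscore(genes["mean_l2fc"], ctrl_means)
    else:
        if zscore_reference == "controls":
            warnings.warn("too few control pseudo-genes; using all genes "
                          "as the Z-score reference")
        mu, sd = genes["mean_l2fc"].mean(), genes["mean_l2fc"].std(ddof=1)
        genes["zscore"] = (genes["mean_l2fc"] - mu) / sd

    if rra_direction == "both":
        dep = rra_gene_test(gmeans, library, "depleted", alpha, n_perm, seed,
                            null_pool)
        enr = rra_gene_test(gmeans, library, "enriched", alpha, n_perm,
                            seed + 1, null_pool)
        p = np.minimum(1.0, 2.0 * np.minimum(dep["p_value"], enr["p_value"]))
        genes["rra_score"] = np.minimum(dep["rra_score"], enr["rra_score"])
        genes["p_value"] = p
        genes["fdr"] = multipletests(p, method="fdr_bh")[1]
    else:
        rra = rra_gene_test(gmeans, library, rra_direction, alpha, n_perm,
                            seed, null_pool)
        genes = genes.join(rra)

    if classify and table.columns_for("culture"):
        try:
            tfh_c = gene_table(
                guide_overall_means(
                    compute_comparison(table, "Tfh_vs_culture", pseudocount)
                ), library)["mean_l2fc"]
            th1_c = gene_table(
                guide_overall_means(
                    compute_comparison(table, "Th1_vs_culture", pseudocount)
                ), library)["mean_l2fc"]
            genes["category"] = classify_hits(tfh_c, th1_c)
        except ValueError:
            genes["category"] = "neutral"
    return genes
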