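"""Detection-limit analysis: spike-in titration power surfaces.

The experimental sensitivity question: how rare can effect-carrying
cells be in the transferred pool and still be detected?  The titration
spikes a known fraction of cells carrying a Tfh-differentiation effect
into a neutral background, runs the full bottleneck chain, and asks
whether the spiked gene's Tfh-vs-Th1 statistic stands out from the
background guides.  Monte-Carlo detection rates over a grid of
frequency x effect x coverage map the screen's power surface and its
minimum detectable frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .library import GuideLibrary
from .simulate import ScreenConfig, spike_in_cohort
from .stats import compute_comparison, gene_table, guide_overall_means

__all__ = [
    "PowerGrid",
    "titration_power",
    "minimum_detectable_frequency",
    "spiked_gene_zscore",
]

DEFAULT_FREQUENCIES = (1 / 100, 1 / 300, 1 / 1000, 1 / 3000)


@dataclass
class PowerGrid:
    """Monte-Carlo grid for the titration power surface."""

    spike_frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    effect_sizes: tuple[float, ...] = (-3.0,)
    coverages: tuple[int, ...] = (750,)
    n_reps: int = 20
    z_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        for f in self.spike_frequencies:
            if not 0 < f <= 1:
                raise ValueError("spike frequencies must be in (0, 1]")


def spiked_gene_zscore(
    library: GuideLibrary,
    target_gene: str,
    spike_frequency: float,
    effect: float,
    config: ScreenConfig,
) -> float:
    """Z of the spiked gene's Tfh-vs-Th1 L2FC against the background
    guides' L2FC distribution (one simulated cohort)."""
    table = spike_in_cohort(library, target_gene, spike_frequency, effect,
                            config)
    reps = compute_comparison(table, "Tfh_vs_Th1")
    gmeans = guide_overall_means(reps)
    genes = gene_table(gmeans, library)["mean_l2fc"]
    target_mean = genes.get(target_gene, np.nan)
    bg = genes.drop(target_gene).dropna()
    if len(bg) < 2 or bg.std(ddof=1) == 0 or np.isnan(target_mean):
        return np.nan
    # gene-level standardization: target and background gene means share
    # the same guides-per-gene averaging, so the null z is ~N(0, 1)
    return float((target_mean - bg.mean()) / bg.std(ddof=1))


def titration_power(
    library: GuideLibrary,
    grid: PowerGrid,
    config: ScreenConfig,
    target_gene: str | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo detection rate per (frequency, effect, coverage) cell.

    Detection: |z| >= grid.z_threshold for the spiked gene's Tfh-vs-Th1
    statistic.  Returns a long DataFrame with columns frequency, effect,
    coverage, detection_rate, mean_l2fc_z, se (binomial Monte-Carlo SE).
    """
    target_gene = target_gene or library.genes[0]
    rows = []
    ss = np.random.SeedSequence(seed)
    for cov in grid.coverages:
        for eff in grid.effect_sizes:
            for freq in grid.spike_frequencies:
                hits = 0
                used = 0
                zs = []
                for child in ss.spawn(grid.n_reps):
                    rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
                    cfg = replace(config, sort_coverage=cov, seed=rep_seed)
                    z = spiked_gene_zscore(library, target_gene, freq, eff,
                                           cfg)
                    if np.isnan(z):
                        continue
                    used += 1
                    zs.append(z)
                    if abs(z) >= grid.z_threshold:
                        hits += 1
                p = hits / used if used else np.nan
                se = np.sqrt(p * (1 - p) / used) if used else np.nan
                rows.append({
                    "frequency": freq, "effect": eff, "coverage": cov,
                    "detection_rate": p, "mean_z": float(np.mean(zs)) if zs
                    else np.nan, "se": se, "n_reps": used,
                })
    return pd.DataFrame(rows)


def minimum_detectable_frequency(
    power_result: pd.DataFrame, target_power: float = 0.8
) -> pd.DataFrame:
    """Smallest tested frequency reaching ``target_power`` per
    (effect, coverage) cell; NaN when no tested frequency reaches it."""
    rows = []
    for (eff, cov), grp in power_result.groupby(["effect", "coverage"]):
        ok = grp[grp["detection_rate"] >= target_power]
        rows.append({
            "effect": eff, "coverage": cov,
            "min_detectable_frequency":
                float(ok["frequency"].min()) if len(ok) else np.nan,
        })
    return pd.DataFrame(rows)
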