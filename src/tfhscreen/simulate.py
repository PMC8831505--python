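"""Forward model of the in vivo pooled screen.

The generative chain mirrors the experimental design: a skewed plasmid
pool is transduced into cultured CD4 T cells that expand with
guide-dependent fitness; a fixed number of cells is adoptively
transferred into each recipient mouse, of which only ~10% engraft; the
engrafted cells expand in vivo and each cell commits to the Tfh or Th1
fate with a guide-dependent probability; sorted populations are sampled
at a per-guide cell coverage with imperfect gate purity; finally guide
cassettes are PCR-amplified and sequenced to a per-guide read depth.

Every stage is a standard sampling distribution (multinomial, binomial,
Poisson, gamma-weighted multinomial), so the whole screen is cheap to
simulate at realistic scale and fully reproducible from a seed, with the
per-gene ground truth (`ScreenTruth`) available for power and
calibration studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .library import GuideLibrary, assemble_array_oligo

__all__ = [
    "POPULATIONS",
    "ScreenConfig",
    "ScreenTruth",
    "CountTable",
    "sample_plasmid_pool",
    "simulate_culture",
    "simulate_mouse",
    "simulate_sequencing",
    "simulate_screen",
    "emit_fastq",
    "spike_in_cohort",
]

#: Fixed vocabulary of sample populations.
POPULATIONS = ("plasmid", "culture", "Th1", "preTfh", "GCTfh")

#: Populations produced by sorting one mouse.
SORT_GATES = ("Th1", "preTfh", "GCTfh")


@dataclass
class ScreenConfig:
    """Tunable parameters of the simulated screen.

    Defaults follow the screen design: 1e6 cells transferred per mouse,
    ~90% loss on adoptive transfer (engraftment_rate 0.10), >=750x
    sorted-cell coverage and >=300x read depth per guide, >95% sort
    purity, 2 experiments of 5 mice sorted individually.
    """

    plasmid_sigma: float = 0.5
    culture_doublings: float = 6.0
    transfer_pool_size: int = 1_000_000
    engraftment_rate: float = 0.10
    invivo_doublings: float = 6.0
    baseline_tfh_logit: float = 0.0
    gc_tfh_fraction: float = 0.4
    sort_coverage: int = 750
    seq_depth: int = 300
    sort_purity: float = 0.95
    pcr_shape: float = 10.0
    n_mice: int = 5
    n_experiments: int = 2
    pooled_sort: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("engraftment_rate", "sort_purity", "gc_tfh_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("plasmid_sigma", "culture_doublings", "invivo_doublings",
                     "pcr_shape"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("transfer_pool_size", "sort_coverage", "seq_depth",
                     "n_mice", "n_experiments"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class ScreenTruth:
    """Per-gene ground-truth effects driving the simulator.

    invitro_fitness / invivo_fitness: per-doubling log2 growth advantage
    (0 = neutral, -1 = no net growth).  tfh_logit_shift: additive shift
    on the baseline Tfh log-odds for cells carrying a guide against the
    gene; negative means knockout impairs Tfh differentiation (the
    intact gene promotes Tfh).  Control guides always carry zero effects.
    """

    invitro_fitness: dict[str, float] = field(default_factory=dict)
    invivo_fitness: dict[str, float] = field(default_factory=dict)
    tfh_logit_shift: dict[str, float] = field(default_factory=dict)

    @classmethod
    def neutral(cls, library: GuideLibrary) -> "ScreenTruth":
        return cls(
            invitro_fitness={g: 0.0 for g in library.genes},
            invivo_fitness={g: 0.0 for g in library.genes},
            tfh_logit_shift={g: 0.0 for g in library.genes},
        )

    def per_guide(self, library: GuideLibrary, which: str) -> np.ndarray:
        """Effect vector aligned with the library's guide order."""
        table = getattr(self, which)
        return np.array(
            [0.0 if g.is_control else table.get(g.gene_symbol, 0.0)
             for g in library.guides]
        )

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(
            set(self.invitro_fitness) | set(self.invivo_fitness)
            | set(self.tfh_logit_shift)
        )
        return pd.DataFrame(
            {
                "gene_symbol": genes,
                "invitro_fitness": [self.invitro_fitness.get(g, 0.0) for g in genes],
                "invivo_fitness": [self.invivo_fitness.get(g, 0.0) for g in genes],
                "tfh_logit_shift": [self.tfh_logit_shift.get(g, 0.0) for g in genes],
            }
        )


@dataclass
class CountTable:
    """Guides x samples integer counts plus per-sample metadata.

    ``counts``: DataFrame indexed by guide_id (library order), one column
    per sample.  ``samples``: DataFrame indexed by sample_id with columns
    population, mouse_id, experiment_id, day.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        extra = set(self.counts.columns) - set(self.samples.index)
        if extra:
            raise ValueError(f"count columns without sample metadata: {extra}")
        bad = set(self.samples["population"]) - set(POPULATIONS)
        if bad:
            raise ValueError(f"unknown populations: {bad}")

    def columns_for(self, population: str, experiment_id=None) -> list[str]:
        mask = self.samples["population"] == population
        if experiment_id is not None:
            mask &= self.samples["experiment_id"] == experiment_id
        return [s for s in self.counts.columns if s in self.samples.index[mask]]

    def write(self, counts_path, samples_path) -> None:
        self.counts.to_csv(counts_path, sep="\t")
        self.samples.to_csv(samples_path)

    @classmethod
    def read(cls, counts_path, samples_path) -> "CountTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        # keep empty mouse/experiment ids as "" rather than NaN
        samples = pd.read_csv(samples_path, index_col=0,
                              keep_default_na=False)
        return cls(counts=counts, samples=samples)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def sample_plasmid_pool(
    library: GuideLibrary, config: ScreenConfig, rng: np.random.Generator
) -> np.ndarray:
    """Relative guide abundance in the plasmid pool: log-normal with
    log-sd ``plasmid_sigma``, normalized to sum 1.  sigma=0 is exactly
    uniform."""
    n = len(library)
    if config.plasmid_sigma == 0:
        return np.full(n, 1.0 / n)
    w = np.exp(rng.normal(0.0, config.plasmid_sigma, size=n))
    return w / w.sum()


def simulate_culture(
    abundance: np.ndarray,
    truth: ScreenTruth,
    library: GuideLibrary,
    config: ScreenConfig,
    rng: np.random.Generator,
    total_cells: float = 3e7,
) -> np.ndarray:
    """Cell counts per guide at the end of in vitro expansion.

    Expected cells per guide are proportional to
    ``abundance * 2**(culture_doublings * (1 + invitro_fitness))`` with
    Poisson realization; ``total_cells`` scales the neutral-guide yield.
    """
    fit = truth.per_guide(library, "invitro_fitness")
    growth = 2.0 ** (config.culture_doublings * (1.0 + fit))
    expected = abundance * growth
    # scale so that a fully-neutral pool of this composition yields total_cells
    neutral_mass = (abundance * 2.0**config.culture_doublings).sum()
    expected *= total_cells / neutral_mass
    return rng.poisson(expected).astype(np.int64)


def _sort_population(
    gate_counts: np.ndarray,
    other_counts: np.ndarray,
    n_guides: int,
    config: ScreenConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample sorted cells for one gate with symmetric cross-contamination.

    Draws min(available, sort_coverage * n_guides) cells; each sorted
    cell is from the gate with probability sort_purity, otherwise from
    the complementary population.  Proportional (with-replacement)
    sampling — indistinguishable from without-replacement at screen scale.
    """
    avail = int(gate_counts.sum())
    if avail == 0:
        return np.zeros_like(gate_counts)
    n_sort = min(avail, config.sort_coverage * n_guides)
    n_true = rng.binomial(n_sort, config.sort_purity)
    sorted_cells = rng.multinomial(n_true, gate_counts / gate_counts.sum())
    n_contam = n_sort - n_true
    if n_contam > 0 and other_counts.sum() > 0:
        sorted_cells = sorted_cells + rng.multinomial(
            n_contam, other_counts / other_counts.sum()
        )
    return sorted_cells


def simulate_mouse(
    culture_counts: np.ndarray,
    truth: ScreenTruth,
    library: GuideLibrary,
    config: ScreenConfig,
    rng: np.random.Generator,
    sort: bool = True,
) -> dict[str, np.ndarray]:
    """One recipient mouse: transfer, engraftment, expansion,
    differentiation, and (optionally) sorting.

    Returns per-guide cell counts for each sort gate (Th1, preTfh,
    GCTfh), or the unsorted gate populations when ``sort=False`` (used
    for pooled sorting across mice).
    """
    total = int(culture_counts.sum())
    if total < config.transfer_pool_size:
        raise ValueError(
            f"culture pool ({total}) smaller than transfer_pool_size "
            f"({config.transfer_pool_size})"
        )
    # (1) transfer: multinomial draw by culture abundance
    transferred = rng.multinomial(
        config.transfer_pool_size, culture_counts / total
    )
    # (2) engraftment bottleneck: ~90% of transferred cells are lost
    engrafted = rng.binomial(transferred, config.engraftment_rate)
    if engrafted.sum() == 0:
        warnings.warn("no cells engrafted; returning empty mouse sample")
        z = np.zeros(len(library), dtype=np.int64)
        return {gate: z.copy() for gate in SORT_GATES}
    # (3) in vivo expansion: exponential expectation, Poisson realization
    fit = truth.per_guide(library, "invivo_fitness")
    expanded = rng.poisson(
        engrafted * 2.0 ** (config.invivo_doublings * (1.0 + fit))
    )
    # (4) differentiation: per-cell Bernoulli on the gene-shifted logit
    p_tfh = _sigmoid(
        config.baseline_tfh_logit + truth.per_guide(library, "tfh_logit_shift")
    )
    tfh = rng.binomial(expanded, p_tfh)
    th1 = expanded - tfh
    gc_tfh = rng.binomial(tfh, config.gc_tfh_fraction)
    pre_tfh = tfh - gc_tfh
    gates = {"Th1": th1, "preTfh": pre_tfh, "GCTfh": gc_tfh}
    if not sort:
        return gates
    return sort_gates(gates, library, config, rng)


def sort_gates(
    gates: dict[str, np.ndarray],
    library: GuideLibrary,
    config: ScreenConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Sort the three gate populations with coverage and purity limits.

    The complementary (contaminating) population for Th1 is all Tfh
    cells; for the two Tfh gates it is Th1.
    """
    n = len(library)
    all_tfh = gates["preTfh"] + gates["GCTfh"]
    complements = {"Th1": all_tfh, "preTfh": gates["Th1"], "GCTfh": gates["Th1"]}
    return {
        gate: _sort_population(gates[gate], complements[gate], n, config, rng)
        for gate in SORT_GATES
    }


def simulate_sequencing(
    sorted_cells: np.ndarray, config: ScreenConfig, rng: np.random.Generator
) -> np.ndarray:
    """Reads per guide for one sample.

    Multinomial draw of ``seq_depth * n_guides`` reads on gamma-weighted
    cell counts; the gamma weights (shape ``pcr_shape``, mean 1) model
    per-guide PCR amplification jitter.  As pcr_shape -> inf the read
    fractions converge to the cell fractions.
    """
    cells = np.asarray(sorted_cells, dtype=float)
    if (cells < 0).any():
        raise ValueError("cell counts must be non-negative")
    n_reads = config.seq_depth * len(cells)
    if cells.sum() == 0:
        warnings.warn("all-zero cell counts; emitting all-zero read column")
        return np.zeros(len(cells), dtype=np.int64)
    if np.isfinite(config.pcr_shape):
        weights = cells * rng.gamma(config.pcr_shape, 1.0 / config.pcr_shape,
                                    size=len(cells))
    else:
        weights = cells
    if weights.sum() == 0:  # all mass lost to zero gamma draws (pathological)
        weights = cells
    return rng.multinomial(n_reads, weights / weights.sum())


def simulate_screen(
    library: GuideLibrary,
    truth: ScreenTruth,
    config: ScreenConfig,
) -> CountTable:
    """Full screen: plasmid + per-experiment culture + sorted populations.

    Individual sorting yields one Th1/preTfh/GCTfh sample triple per
    mouse; pooled sorting pools the gate populations across an
    experiment's mice before sorting (one triple per experiment).
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = len(library)
    columns: dict[str, np.ndarray] = {}
    meta: list[dict] = []

    abundance = sample_plasmid_pool(library, config, rng)
    # plasmid sequencing sees the pool composition directly
    plasmid_cells = abundance * 1e7
    columns["plasmid"] = simulate_sequencing(plasmid_cells, config, rng)
    meta.append({"sample_id": "plasmid", "population": "plasmid",
                 "mouse_id": "", "experiment_id": "", "day": 0})

    for e in range(1, config.n_experiments + 1):
        exp_id = f"exp{e}"
        culture = simulate_culture(abundance, truth, library, config, rng)
        cid = f"{exp_id}_culture"
        columns[cid] = simulate_sequencing(culture, config, rng)
        meta.append({"sample_id": cid, "population": "culture",
                     "mouse_id": "", "experiment_id": exp_id, "day": 0})

        if config.pooled_sort:
            pooled = {gate: np.zeros(n, dtype=np.int64) for gate in SORT_GATES}
            for _ in range(config.n_mice):
                gates = simulate_mouse(culture, truth, library, config, rng,
                                       sort=False)
                for gate in SORT_GATES:
                    pooled[gate] += gates[gate]
            sorted_gates = sort_gates(pooled, library, config, rng)
            for gate in SORT_GATES:
                sid = f"{exp_id}_pooled_{gate}"
                columns[sid] = simulate_sequencing(sorted_gates[gate], config, rng)
                meta.append({"sample_id": sid, "population": gate,
                             "mouse_id": "", "experiment_id": exp_id, "day": 6})
        else:
            for m in range(1, config.n_mice + 1):
                mouse_id = f"{exp_id}_m{m}"
                sorted_gates = simulate_mouse(culture, truth, library, config, rng)
                for gate in SORT_GATES:
                    sid = f"{mouse_id}_{gate}"
                    columns[sid] = simulate_sequencing(
                        sorted_gates[gate], config, rng
                    )
                    meta.append({"sample_id": sid, "population": gate,
                                 "mouse_id": mouse_id, "experiment_id": exp_id,
                                 "day": 6})

    counts = pd.DataFrame(columns, index=pd.Index(library.guide_ids,
                                                  name="guide_id"))
    samples = pd.DataFrame(meta).set_index("sample_id")
    return CountTable(counts=counts, samples=samples)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def emit_fastq(
    count_column: pd.Series | np.ndarray,
    library: GuideLibrary,
    path,
    read_length: int = 100,
    error_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> int:
    """Write one amplicon FASTQ: one read per count.

    Each read embeds the guide's uppercased flank-spacer-flank cassette
    at a random offset, padded with random bases, with per-base
    substitution errors at ``error_rate`` and constant Phred+33
    qualities.  Returns the number of reads written.
    """
    rng = np.random.default_rng() if rng is None else rng
    counts = np.asarray(count_column, dtype=np.int64)
    cassettes = [assemble_array_oligo(g.spacer).upper() for g in library.guides]
    cass_len = len(cassettes[0])
    if read_length < 75:
        raise ValueError(
            f"read_length must be >= 75 to contain the {cass_len}-nt cassette "
            f"with margin, got {read_length}"
        )
    n_total = int(counts.sum())
    # build all reads as one uint8 matrix for speed
    reads = _BASES[rng.integers(0, 4, size=(n_total, read_length))]
    guide_idx = np.repeat(np.arange(len(counts)), counts)
    order = rng.permutation(n_total)
    guide_idx = guide_idx[order]
    offsets = rng.integers(0, read_length - cass_len + 1, size=n_total)
    cass_bytes = np.array(
        [np.frombuffer(c.encode(), dtype=np.uint8) for c in cassettes]
    )
    for i in range(n_total):
        o = offsets[i]
        reads[i, o:o + cass_len] = cass_bytes[guide_idx[i]]
    if error_rate > 0:
        err = rng.random(size=reads.shape) < error_rate
        # substitute with a uniformly random *different* base
        shift = rng.integers(1, 4, size=int(err.sum()))
        flat = reads[err]
        base_idx = np.searchsorted(_BASES, flat)
        reads[err] = _BASES[(base_idx + shift) % 4]
    qual = "I" * read_length  # Q40, Phred+33
    names = [g.guide_id for g in library.guides]
    with open(path, "w") as fh:
        for i in range(n_total):
            seq = reads[i].tobytes().decode()
            fh.write(f"@read{i}_{names[guide_idx[i]]}\n{seq}\n+\n{qual}\n")
    return n_total


def spike_in_cohort(
    library: GuideLibrary,
    target_gene: str,
    spike_frequency: float,
    effect: float,
    config: ScreenConfig,
) -> CountTable:
    """Spike-in titration: the target gene's guides make up
    ``spike_frequency`` of the transferred pool and carry a Tfh logit
    shift of ``effect``; all other guides are a neutral background.

    Returns sorted-population counts for ``config.n_mice`` mice (one
    experiment), suitable for the spiked-vs-background detection readout.
    """
    if not 0.0 < spike_frequency <= 1.0:
        raise ValueError("spike_frequency must be in (0, 1]")
    rng = np.random.default_rng(config.seed)
    n = len(library)
    target_mask = np.array(
        [g.gene_symbol == target_gene for g in library.guides]
    )
    n_target = int(target_mask.sum())
    if n_target == 0:
        raise ValueError(f"gene {target_gene!r} not in library")
    abundance = np.empty(n)
    abundance[target_mask] = spike_frequency / n_target
    if n_target < n:
        abundance[~target_mask] = (1.0 - spike_frequency) / (n - n_target)
    else:
        abundance /= abundance.sum()
    truth = ScreenTruth.neutral(library)
    truth.tfh_logit_shift[target_gene] = effect

    # the transferred pool is the mixture itself (no culture fitness stage)
    culture_counts = rng.multinomial(
        max(config.transfer_pool_size * 10, 10 * n), abundance
    )
    columns: dict[str, np.ndarray] = {}
    meta: list[dict] = []
    for m in range(1, config.n_mice + 1):
        mouse_id = f"exp1_m{m}"
        gates = simulate_mouse(culture_counts, truth, library, config, rng)
        for gate in SORT_GATES:
            sid = f"{mouse_id}_{gate}"
            columns[sid] = simulate_sequencing(gates[gate], config, rng)
            meta.append({"sample_id": sid, "population": gate,
                         "mouse_id": mouse_id, "experiment_id": "exp1",
                         "day": 6})
    counts = pd.DataFrame(columns, index=pd.Index(library.guide_ids,
                                                  name="guide_id"))
    samples = pd.DataFrame(meta).set_index("sample_id")
    return CountTable(counts=counts, samples=samples)
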