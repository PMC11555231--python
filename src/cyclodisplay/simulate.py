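"""Generative model of affinity-selection rounds.

Synthetic stand-in for selection NGS data, with the statistical structure
the deconvolution and scanning analyses assume and full ground truth.

Each library member i carries a latent binding weight w_i in [0, 1]; a
selection round retains it with probability

    p_i = beta * w_i + gamma

where beta is the capture efficiency of a true binder and gamma the
background (non-specific) retention that carries non-binders between rounds.
Post-selection relative abundances are x_i * p_i renormalised; optional
log-normal per-member amplification noise models PCR; sequencing draws
``reads_per_round`` reads multinomially. Next-round abundances are the
post-amplification proportions, so with equal weights and no noise the
expected composition is invariant round to round.

The linear capture partition has closed-form expectations; an equilibrium
binding-isotherm weight map w = L / (L + K_D) can be layered on top by the
caller when constructing weights.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .deconvolution import RoundCounts, assign_cyclization, translate
from .library_design import (
    ConfigurationError,
    LibraryDesign,
    NNK_CODONS,
    build_library_read,
    length_weights,
    make_codon_table,
    theoretical_diversity,
)


class ExtinctionError(RuntimeError):
    """Every member has zero retention probability; the selection dies out."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated selection campaign.

    Defaults model a naive-library selection at desk scale: a sparse binder
    fraction with Beta(5, 1) weights (concentrated near 1), 50% capture of a
    perfect binder, 1% background carry-over, eight rounds, and 1e5 reads
    per round with noise-free PCR.
    """

    n_variants: int = 5000
    design: LibraryDesign = field(default_factory=LibraryDesign)
    f_binder: float = 0.01
    beta_a: float = 5.0
    beta_b: float = 1.0
    capture_efficiency: float = 0.5     # beta
    background_retention: float = 0.01  # gamma
    rounds: int = 8
    reads_per_round: int = 100_000
    amplification_noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.f_binder <= 1:
            raise ConfigurationError("f_binder must be in [0, 1]")
        if not 0 < self.capture_efficiency <= 1:
            raise ConfigurationError("capture_efficiency must be in (0, 1]")
        if not 0 <= self.background_retention < 1:
            raise ConfigurationError("background_retention must be in [0, 1)")
        if self.capture_efficiency + self.background_retention > 1:
            raise ConfigurationError("beta + gamma must not exceed 1 "
                                     "(retention is a probability)")
        if self.rounds < 0 or self.reads_per_round <= 0 or self.n_variants <= 0:
            raise ConfigurationError("rounds/reads/n_variants out of range")
        if self.amplification_noise_sigma < 0:
            raise ConfigurationError("amplification_noise_sigma must be >= 0")
        if self.n_variants > theoretical_diversity(self.design):
            raise ConfigurationError("n_variants exceeds design diversity")


#: NNK codons that do not encode the amber stop (the displayed library)
_CODING_NNK = tuple(c for c in NNK_CODONS if c != "TAG")


@dataclass
class SimulatedPopulation:
    """Ground-truth library state: member identities, weights, abundances."""

    peptides: list          # synthesis-form keys
    dna: list               # random-region inserts
    w: np.ndarray           # latent binding weights, [0, 1]
    x: np.ndarray           # relative abundances, sum 1

    def __post_init__(self):
        self.w = np.asarray(self.w, float)
        self.x = np.asarray(self.x, float)
        if not np.isclose(self.x.sum(), 1.0, atol=1e-12):
            raise ValueError("abundances must sum to 1")
        if ((self.w < 0) | (self.w > 1)).any():
            raise ValueError("weights must lie in [0, 1]")

    def __len__(self):
        return len(self.peptides)


def init_library(config: SimulationConfig,
                 rng: np.random.Generator | None = None) -> SimulatedPopulation:
    """Draw an initial library: lengths from the design's length ratios,
    random stop-free NNK inserts, binder weights from the affinity mixture."""
    rng = rng or np.random.default_rng(config.seed)
    weights_by_n = length_weights(config.design)
    lengths = np.array(sorted(weights_by_n))
    probs = np.array([weights_by_n[n] for n in lengths])
    table = make_codon_table(config.design.mode)
    ns = rng.choice(lengths, size=config.n_variants, p=probs)
    codon_idx = rng.integers(0, len(_CODING_NNK), size=int(ns.sum()))
    dna, peptides = [], []
    off = 0
    for n in ns:
        insert = "".join(_CODING_NNK[i] for i in codon_idx[off:off + n])
        off += n
        dna.append(insert)
        peptides.append(assign_cyclization(translate(insert, table)).key)
    is_binder = rng.random(config.n_variants) < config.f_binder
    w = np.zeros(config.n_variants)
    if is_binder.any():
        w[is_binder] = rng.beta(config.beta_a, config.beta_b,
                                size=int(is_binder.sum()))
    x = np.full(config.n_variants, 1.0 / config.n_variants)
    return SimulatedPopulation(peptides=peptides, dna=dna, w=w, x=x)


def retention_probabilities(pop: SimulatedPopulation,
                            config: SimulationConfig) -> np.ndarray:
    return config.capture_efficiency * pop.w + config.background_retention


def run_round(pop: SimulatedPopulation, config: SimulationConfig,
              rng: np.random.Generator, round_index: int = 1,
              emit_reads: bool = False):
    """One selection round: capture, amplify, sequence.

    Returns ``(next_pop, RoundCounts, reads)`` where *reads* is a list of
    (read_id, dna, quality) FASTQ triples (empty unless ``emit_reads``).
    """
    p = retention_probabilities(pop, config)
    mass = pop.x * p
    total = mass.sum()
    if total <= 0:
        raise ExtinctionError(f"round {round_index}: all retention probabilities are 0")
    post = mass / total
    if config.amplification_noise_sigma > 0:
        amp = rng.lognormal(0.0, config.amplification_noise_sigma, size=len(pop))
        post = post * amp
        post = post / post.sum()
    read_counts = rng.multinomial(config.reads_per_round, post)
    counts = Counter()
    for pep, c in zip(pop.peptides, read_counts):
        if c:
            counts[pep] += int(c)
    rc = RoundCounts(round_id=f"round{round_index}", counts=counts)
    reads = []
    if emit_reads:
        qual = None
        for m, (insert, c) in enumerate(zip(pop.dna, read_counts)):
            if not c:
                continue
            seq = build_library_read(insert, config.design)
            if qual is None or len(qual) != len(seq):
                qual = "I" * len(seq)
            for k in range(c):
                reads.append((f"r{round_index}_m{m}_{k}", seq, "I" * len(seq)))
    next_pop = SimulatedPopulation(peptides=pop.peptides, dna=pop.dna,
                                   w=pop.w, x=post)
    return next_pop, rc, reads


def simulate_selection(config: SimulationConfig, emit_reads: bool = False):
    """Run a full selection campaign.

    Returns ``(final_pop, results)``; *results* is a list of per-round
    ``(RoundCounts, reads)`` beginning with the naive input library
    (round 0, sequenced at the same depth). ``rounds = 0`` yields the input
    counts only. Identical seeds give byte-identical reads and counts.
    """
    rng = np.random.default_rng(config.seed)
    pop = init_library(config, rng)
    results = []
    # round 0: sequence the naive input pool
    in_counts = rng.multinomial(config.reads_per_round, pop.x)
    counts = Counter()
    for pep, c in zip(pop.peptides, in_counts):
        if c:
            counts[pep] += int(c)
    reads0 = []
    if emit_reads:
        for m, (insert, c) in enumerate(zip(pop.dna, in_counts)):
            if not c:
                continue
            seq = build_library_read(insert, config.design)
            for k in range(c):
                reads0.append((f"r0_m{m}_{k}", seq, "I" * len(seq)))
    results.append((RoundCounts(round_id="round0", counts=counts), reads0))
    for r in range(1, config.rounds + 1):
        pop, rc, reads = run_round(pop, config, rng, round_index=r,
                                   emit_reads=emit_reads)
        results.append((rc, reads))
    return pop, results


def simulate_scanning_experiment(parent: str, universe, true_e: dict,
                                 reads_per_round: int = 100_000,
                                 seed: int = 0,
                                 input_distribution: dict | None = None):
    """Single-round scanning selection with known per-variant retention.

    *universe* is an iterable of variant peptide strings (the parent must
    appear in *true_e* with a positive relative retention). Input counts are
    multinomial over *input_distribution* (default uniform); output
    proportions are input_i * true_e_i renormalised, sampled multinomially.

    Returns ``(input RoundCounts, output RoundCounts, truth DataFrame)`` with
    the truth table holding true E_i = true_e_i / true_e_parent and its log2.
    """
    import pandas as pd

    universe = list(universe)
    if parent not in universe:
        universe = [parent] + universe
    if true_e.get(parent, 0) <= 0:
        raise ValueError("true_e must be positive for the parent")
    rng = np.random.default_rng(seed)
    if input_distribution is None:
        p_in = np.full(len(universe), 1.0 / len(universe))
    else:
        p_in = np.array([input_distribution[k] for k in universe], float)
        p_in = p_in / p_in.sum()
    e = np.array([true_e[k] for k in universe], float)
    if (e < 0).any():
        raise ValueError("true_e values must be non-negative")
    counts_in = rng.multinomial(reads_per_round, p_in)
    mass = counts_in * e
    if mass.sum() <= 0:
        raise ExtinctionError("no variant survives the scanning selection")
    counts_out = rng.multinomial(reads_per_round, mass / mass.sum())
    rc_in = RoundCounts("input", Counter(
        {k: int(c) for k, c in zip(universe, counts_in) if c}))
    rc_out = RoundCounts("output", Counter(
        {k: int(c) for k, c in zip(universe, counts_out) if c}))
    true_E = e / true_e[parent]
    with np.errstate(divide="ignore"):
        truth = pd.DataFrame({"peptide": universe, "true_e": e,
                              "true_E": true_E,
                              "true_log2E": np.log2(true_E)})
    return rc_in, rc_out, truth
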