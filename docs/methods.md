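# Methods

`cyclodisplay` analyses mRNA-display selections of thioether-cyclised
peptides: it models the NNK-encoded library, deconvolutes selection-round
reads into ranked peptide identities, scores single-round mutational-scanning
enrichment, simulates selection campaigns with known ground truth, and fits
dose-response curves for the downstream activity assays. This note documents
the models, the parameters that matter, and the numerical choices.

## Library model

The library template is

```
5'-TAATACGACTCACTATAGGGTTAACTTTAAGAAGGAGATATACATATG (NNK)n TGCGGCAGCGGCAGCGGCAGCTAG GACGGGGGGCGGAAA-3'
```

a T7 transcription/translation cassette whose initiator ATG is reprogrammed
(via a pre-charged initiator tRNA) to N-chloroacetyl-D- or L-tyrosine, with a
random region of n = 6–12 NNK codons at molar ratios
0.001 : 0.032 : 1 : 32 : 33 : 33 : 11, and a constant
Cys-Gly-Ser-Gly-Ser-Gly-Ser linker ending in the amber stop. NNK degenerate
codons (N = A/C/G/T, K = G/T) comprise 32 codons encoding all 20 amino acids
with TAG the only stop. Length weights are the ratios normalised to 1 (so
weight(n = 10) = 33/110.033 ≈ 0.2999); encodable stop-free diversity is
Σ 20ⁿ ≈ 4.3 × 10¹⁵, comfortably above the ~10¹² members physically displayed.

Three genetic codes are supported: `main_D`/`main_L` (naive selections;
elongation follows the standard code; initiator → ClAc-D/L-Tyr) and
`scanning` (mutational scanning; elongation ATG → N-methyl-alanine, since
the translation system omits methionine). Non-canonical residues are
registered multi-character symbols with one-letter display fallbacks
(ClAc-D/L-Tyr → `Y`, N-Me-Ala → `a`), so the N-Me-Ala row of a scanning
heatmap stays distinct from alanine. Internal ATG in the main modes is
translated as `M` but flagged `contains_unassigned`, because a Met-minus
translation system makes such reads chemically ambiguous; they are retained
in rankings but carry the flag.

`reverse_translate` maps each residue to its lexicographically smallest NNK
codon, giving deterministic fixtures whose translation round-trips exactly.

## Deconvolution

Per read: (1) locate the 5′ and 3′ constant flanks, allowing up to
`max_mismatch` substitutions per anchor (default 0 — amplicon constant
regions are high-fidelity, and tolerance is configurable); (2) keep the
between-anchor insert if it is codon-aligned with a codon count in the
design; (3) translate under the selected code, terminating at the first
stop; (4) assign the thioether bridge from the N-terminal chloroacetyl group
to the *first* cysteine thiol. The synthesis form — the key peptides are
counted and ranked under — is:

- **constant-Cys rule**: when the first Cys is the constant-region one
  (index n+1), the form runs through the glycine immediately after it
  (n + 3 residues; a 10-codon region gives a 13-mer);
- **internal-Cys rule**: when a random-region Cys closes the macrocycle
  first, the form runs through the end of the random region (so an 11-mer
  region with Cys at position 4 gives a 12-mer).

Stop-truncated and cysteine-less records are tallied in QC but excluded
from binder ranking; QC reason counts always reconcile exactly with the
input read count. Ranking is by descending read count with lexicographic
tie-break (a deterministic total order, stable under input permutation).
`collapse_families` optionally merges near-identical sequences by
single-linkage clustering under Levenshtein distance (edlib), reporting each
family by its highest-count representative.

## Scanning enrichment

For one input/bound pool pair and variant i,

F_i = (reads_i + c) / Σ(reads + c),  e_i = F_i,out / F_i,in,
E_i = e_i / e_parent,

reported as log₂E; the parent scores log₂E = 0 by construction (the
statistic is a ratio of ratios, and is invariant to rescaling either pool's
counts when c = 0). Frequencies are computed over the declared scanning
universe only; reads outside it are ignored. The pseudocount c defaults to
0.5 whenever any universe member has zero reads in either pool, and 0
otherwise — zero-read variants then get finite (strongly negative) scores
without perturbing fully-observed pools. Replicates are aggregated as the
mean and sample SD (ddof = 1) of log₂E per variant — averaging on the log
scale, which is the scale scores are compared and plotted on — with
per-cell support counts for variants missing from some replicates; fewer
than two replicates yields NaN SDs.

The default scanning universe substitutes positions 2–11 of the parent with
the 18 other canonical residues (no Met) plus N-Me-Ala: 10 × 19 + 1 = 191
peptides.

## Selection simulator

The generator emulates the structure of iterated affinity panning, not its
chemistry. Member i has a latent weight w_i ∈ [0, 1] and abundance x_i; one
round retains it with probability p_i = β·w_i + γ (β = capture efficiency,
γ = background/non-specific retention, β + γ ≤ 1), so post-selection
proportions are x_i p_i / Σ x_j p_j, optionally perturbed by log-normal
amplification noise (σ, default 0 — PCR modelled as unbiased), then
sequenced as a multinomial draw of `reads_per_round` reads. Next-round
abundances are the post-amplification *proportions* (the molecular
population is far deeper than the sequenced sample), so with equal weights
the expected composition is exactly invariant and round counts are plain
multinomial draws — the property the neutrality tests exploit. The linear
partition was chosen over an explicit binding isotherm because downstream
analyses only consume rank/enrichment structure and the linear model has
closed-form expectations; an isotherm is recovered by setting
w = L/(L + K_D) when building weights.

Defaults (chosen once as a realistic desk-scale campaign): 5 000 variants,
binder fraction 1% with w ~ Beta(5, 1), β = 0.5, γ = 0.01, 8 rounds, 10⁵
reads/round, σ = 0. Random-region codons are drawn from the 31 non-stop NNK
codons: stop-truncated members do not display a cyclic peptide, so the
modelled pool is the displayable library (the deconvoluter still handles
stop-containing reads when given them). All randomness flows through one
`numpy` Generator seeded from the config; identical seeds give
byte-identical FASTQ and counts. Reads are emitted with uniform quality 'I'
and no sequencing-error model by default, matching the exact-anchor
deconvolution default.

What the simulator does **not** emulate: PCR bias families, sequencing
errors and chimeras, mRNA/cDNA-tag-mediated background (which in real
selections can enrich non-binders — subsumed into γ), round-to-round input
losses, and negative-selection steps. Passing recovery tests therefore shows
the statistics are implemented correctly and identifiable at the stated
depths, not that real selections are free of those artefacts.

The single-round scanning simulator draws input counts multinomially from a
uniform (or supplied) distribution over the universe, sets output
proportions ∝ input_i × true_e_i, and records the ground truth
E_i = true_e_i / true_e_parent.

## Dose-response models

The citrulline standard curve is an ordinary least-squares line
(absorbance vs concentration); inverse prediction is defined on the fitted
range and extrapolation is flagged. Dose-response data are fitted with the
four-parameter logistic

y(x) = bottom + (top − bottom) / (1 + (x/c50)^h),

with bottom ≤ top after canonicalisation and the Hill sign h encoding
direction (h > 0 decreasing/inhibition, h < 0 increasing/activation);
y(c50) = (bottom + top)/2 exactly. IC50, AC50, K50(Ca²⁺), CP50 and EC50 are
role-labelled read-outs of the same c50. Free bottom/top (4PL rather than
3PL) because normalised plateaus still vary between assays. A helper
normalises responses to the mean vehicle (DMSO) control. Fold-changes are
unit-aware point-estimate ratios (nM/µM/mM carried explicitly and converted
at boundaries), with optional nearest-integer rounding to reproduce printed
fold values; no error propagation, matching how printed ratio columns are
formed.

Numerics: fitting uses `scipy.optimize.curve_fit` with c50 parametrised as
log₁₀(c50) (the identifiable scale across nM–mM windows), initialised from
the response extremes, the dose nearest half-range, and h = ±1 by direction
(inferred from a log-dose slope when not given); tolerances 1e-14 so
noiseless data recovers generating parameters to better than 1e-6 relative.
Flat data is returned flagged unidentifiable rather than fitted. Degenerate
inputs (x ≤ 0, < 5 points, < 3 standards, constant x) raise typed errors.

## Pipeline and determinism

`run_pipeline` chains simulate → deconvolute → rank → scan-score from a
validated configuration (pydantic; unknown keys rejected, the seed is
mandatory) and writes a manifest with the package version, the run seed and
a SHA-256 digest per artifact; stage seeds derive from the run seed by fixed
offsets, and reruns are byte-identical. Tables are TSV (peptide strings
never need quoting); positions in reports are 1-based (position 1 is the
initiator), 0-based internally.

## Test problem sizes

The suite exercises recovery at the depths where the statistics are
identifiable while staying desk-scale: scanning recovery at 10⁵ reads/pool
over the 191-variant universe (Spearman ≥ 0.9 between true and estimated
log₂E); an 8-round default campaign whose top-ranked final peptide must be a
true binder; neutral-selection goodness-of-fit over 100 seeded runs of
24 × 2 400-read pools, where the number of χ² rejections at α = 0.01 must
stay within the 99% binomial bound (≤ 4/100 — demanding zero rejections
across 100 independent tests would itself be rejected under the null);
noiseless 4PL recovery over 50 random parameter draws; and 10 000
translate/reverse-translate round trips.

## Known limitations

- The truncation rule for internal-Cys peptides that also retain the
  constant Cys-Gly is only constrained by the observed synthesised forms;
  sequences where both rules could apply follow the internal-Cys rule.
- Enrichment scores are single-round frequency ratios; no multi-round
  fitness regression or epistasis modelling.
- No UMI handling, paired-end merging, quality trimming or error
  correction; reads are processed as given (an optional reverse-complement
  rescue and anchor-mismatch tolerance are the only relaxations).
- Real printed assay values (IC50s, K_D, K50 measurements) depend on raw
  plate data that is not reconstructible; the assay module reproduces the
  functional forms and the arithmetic on printed values, not the wet-lab
  numbers themselves.
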