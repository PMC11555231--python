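"""Mutational-scanning enrichment scoring.

A single-position saturation-scanning library (parent peptide with each
scanned position substituted to every other coded residue) is panned for one
round against the target; input and bound pools are sequenced. Each
variant i gets a frequency F_i = reads_i / sum(reads) per pool, an
output/input frequency ratio e_i = F_i,out / F_i,in, and an enrichment score

    E_i = e_i / e_parent

so the parent scores E = 1 (log2 E = 0) by construction. Scores are reported
on the log2 scale; replicate selections are aggregated as the mean and
standard deviation of log2 E per position x substitution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deconvolution import RoundCounts
from .residues import CANONICAL, N_ME_ALA, display

#: residues offered at each scanned position: the 19 canonical amino acids
#: other than Met, plus N-methyl-alanine (which replaces Met in the
#: reprogrammed scanning code).
SCANNING_ALPHABET = tuple(aa for aa in CANONICAL if aa != "M") + (N_ME_ALA,)


def scanning_library_universe(parent: str, positions=range(2, 12)) -> pd.DataFrame:
    """Enumerate the single-substitution scanning universe of *parent*.

    *parent* is a synthesis-form peptide string; *positions* are 1-based
    residue positions to scan (default 2-11, i.e. the ten random-region
    positions after the initiator). Each position contributes 19 variants
    (18 other canonicals excluding Met, plus N-Me-Ala); with the parent the
    default universe has 10 x 19 + 1 = 191 members.

    Returns a DataFrame with columns peptide, position, substitution; the
    parent row has position 0 and substitution ''.
    """
    positions = list(positions)
    for pos in positions:
        if not 1 <= pos <= len(parent):
            raise ValueError(f"position {pos} outside parent of length {len(parent)}")
    rows = [{"peptide": parent, "position": 0, "substitution": ""}]
    seen = {parent}
    for pos in positions:
        for sub in SCANNING_ALPHABET:
            ch = display(sub)
            variant = parent[:pos - 1] + ch + parent[pos:]
            if variant in seen:
                continue
            seen.add(variant)
            rows.append({"peptide": variant, "position": pos, "substitution": ch})
    return pd.DataFrame(rows)


def score_enrichment(input_counts: RoundCounts, output_counts: RoundCounts,
                     parent_key: str, pseudocount: float | None = None,
                     universe=None) -> pd.DataFrame:
    """Per-variant enrichment table for one input/bound pool pair.

    Frequencies are computed over *universe* (default: keys present in the
    input pool); reads mapping outside it are ignored. ``pseudocount`` is
    added to every variant's count in both pools before normalising; the
    default (``None``) applies 0.5 when any universe member has zero output
    reads and 0 otherwise, so zero-read variants get finite scores without
    perturbing fully-observed pools.

    Returns a DataFrame with columns peptide, reads_in, reads_out, F_in,
    F_out, e, E, log2E.
    """
    if universe is None:
        universe = sorted(input_counts.counts)
    else:
        universe = list(universe)
    if parent_key not in universe:
        universe = [parent_key] + universe
    if input_counts.counts.get(parent_key, 0) <= 0:
        raise ValueError("parent peptide absent from the input pool")
    reads_in = np.array([input_counts.counts.get(k, 0) for k in universe], float)
    reads_out = np.array([output_counts.counts.get(k, 0) for k in universe], float)
    if pseudocount is None:
        pseudocount = 0.5 if (reads_out == 0).any() or (reads_in == 0).any() else 0.0
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and output_counts.counts.get(parent_key, 0) <= 0:
        raise ValueError("parent absent from the output pool with pseudocount 0; "
                         "e_parent is undefined")
    f_in = (reads_in + pseudocount) / (reads_in + pseudocount).sum()
    f_out = (reads_out + pseudocount) / (reads_out + pseudocount).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        e = f_out / f_in
    e_parent = e[universe.index(parent_key)]
    E = e / e_parent
    with np.errstate(divide="ignore"):
        log2E = np.log2(E)
    return pd.DataFrame({
        "peptide": universe,
        "reads_in": reads_in.astype(int),
        "reads_out": reads_out.astype(int),
        "F_in": f_in,
        "F_out": f_out,
        "e": e,
        "E": E,
        "log2E": log2E,
    })


@dataclass
class ScanMatrix:
    """Replicate-aggregated position x substitution score grid."""

    mean: pd.DataFrame       # positions x substitutions, mean log2E
    sd: pd.DataFrame         # same shape; sample SD (ddof=1), NaN if support < 2
    support: pd.DataFrame    # number of replicates contributing per cell
    n_replicates: int
    parent_mask: pd.DataFrame | None = None


def aggregate_replicates(tables, universe: pd.DataFrame | None = None):
    """Aggregate per-replicate enrichment tables into mean/SD of log2E.

    *tables* is a sequence of ``score_enrichment`` outputs (>=1; fewer than
    two replicates yields undefined SDs and a warning-level support flag).
    Returns a long-format DataFrame (peptide, mean_log2E, sd_log2E, support);
    pass *universe* (from :func:`scanning_library_universe`) to also receive
    a :class:`ScanMatrix` pivoted on position x substitution.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no replicate tables given")
    long = pd.concat(
        [t[["peptide", "log2E"]].assign(replicate=i) for i, t in enumerate(tables)],
        ignore_index=True,
    )
    long = long[np.isfinite(long["log2E"])]
    agg = long.groupby("peptide")["log2E"].agg(
        mean_log2E="mean",
        sd_log2E=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan,
        support="size",
    ).reset_index()
    agg["support"] = agg["support"].astype(int)
    if universe is None:
        return agg
    merged = universe.merge(agg, on="peptide", how="left")
    var = merged[merged["position"] > 0]
    mean = var.pivot_table(index="substitution", columns="position",
                           values="mean_log2E", aggfunc="mean")
    sd = var.pivot_table(index="substitution", columns="position",
                         values="sd_log2E", aggfunc="mean")
    support = var.pivot_table(index="substitution", columns="position",
                              values="support", aggfunc="max").fillna(0).astype(int)
    parent_mask = pd.DataFrame(False, index=mean.index, columns=mean.columns)
    parent = universe.loc[universe["position"] == 0, "peptide"].iloc[0]
    for pos in mean.columns:
        ch = parent[pos - 1]
        if ch in parent_mask.index:
            parent_mask.loc[ch, pos] = True
    matrix = ScanMatrix(mean=mean, sd=sd, support=support,
                        n_replicates=len(tables), parent_mask=parent_mask)
    return agg, matrix


def plot_scan_heatmap(matrix: ScanMatrix, ax=None, cmap: str = "coolwarm_r"):
    """Render the position x substitution mean-log2E grid as a heatmap.

    Red marks substitutions enriched over the parent, blue depleted; parent
    cells are outlined in black.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(0.5 * matrix.mean.shape[1] + 2,
                                      0.35 * matrix.mean.shape[0] + 1))
    data = matrix.mean
    vmax = np.nanmax(np.abs(data.values)) or 1.0
    im = ax.imshow(data.values, cmap=cmap, vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(data.shape[1]), data.columns)
    ax.set_yticks(range(data.shape[0]), data.index)
    ax.set_xlabel("parent position")
    ax.set_ylabel("substitution")
    if matrix.parent_mask is not None:
        for yi, sub in enumerate(data.index):
            for xi, pos in enumerate(data.columns):
                if matrix.parent_mask.loc[sub, pos]:
                    ax.add_patch(plt.Rectangle((xi - 0.5, yi - 0.5), 1, 1,
                                               fill=False, edgecolor="black",
                                               linewidth=1.5))
    ax.figure.colorbar(im, ax=ax, label="mean log2 enrichment")
    return ax
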