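"""Selection-round read deconvolution.

Turns raw amplicon reads from an affinity-selection round into counted,
ranked cyclic-peptide identities: locate the constant flanks, extract the
random-region insert, translate it under the reprogrammed genetic code,
assign the thioether cyclisation bridge (N-terminus to first cysteine), and
tally reads per synthesis-form peptide.

Peptides are keyed by their *synthesis form* — the sub-sequence that would be
made by solid-phase synthesis: through the glycine following the constant
cysteine when the macrocycle closes on the constant Cys, or through the end
of the random region when an internal cysteine closes it first.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib
import pandas as pd

from .library_design import CONSTANT_RESIDUES, CodonTable, LibraryDesign
from .residues import STOP, to_string

# reason codes for skipped reads
SKIP_BAD_CHARS = "bad_characters"
SKIP_NO_ANCHOR = "anchor_not_found"
SKIP_BAD_FRAME = "insert_not_codon_aligned"
SKIP_BAD_LENGTH = "length_not_in_design"
SKIP_STOP = "truncated_by_stop"
SKIP_NO_CYS = "no_cysteine"
SKIP_BAD_CODON = "non_nnk_codon"


class EmptyPoolError(ValueError):
    """No valid records in a selection round."""


@dataclass
class PeptideRecord:
    """A translated library member.

    ``linear`` is the full residue-symbol sequence (initiator + random region
    + constant linker, up to the first stop); ``bridge`` is the
    (N-terminus, first-Cys) thioether pair; ``synthesis_form`` is the
    truncated sequence a synthesiser would make.
    """

    linear: tuple
    n: int
    flags: set = field(default_factory=set)
    bridge: tuple | None = None
    synthesis_form: tuple = ()

    @property
    def key(self) -> str:
        return to_string(self.synthesis_form)

    @property
    def linear_str(self) -> str:
        return to_string(self.linear)

    @property
    def valid_for_ranking(self) -> bool:
        return self.bridge is not None and "truncated_by_stop" not in self.flags \
            and "non_nnk_codon" not in self.flags


@dataclass
class RoundCounts:
    """Read counts per peptide key for one selection round or pool."""

    round_id: str
    counts: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def frequency(self, key: str) -> float:
        return self.counts[key] / self.total


def _hamming_find(read: str, anchor: str, max_mismatch: int) -> int:
    """Leftmost start of *anchor* in *read* with <= max_mismatch substitutions,
    or -1."""
    if max_mismatch == 0:
        return read.find(anchor)
    la, lr = len(anchor), len(read)
    for start in range(lr - la + 1):
        mism = 0
        for a, b in zip(anchor, read[start:start + la]):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            return start
    return -1


def extract_random_region(read: str, design: LibraryDesign,
                          max_mismatch: int = 0) -> str | None:
    """Extract the NNK random-region insert between the constant flanks.

    Returns the insert DNA if both anchors are found (allowing up to
    ``max_mismatch`` substitutions per anchor), the insert is codon-aligned
    and its codon count is one of the design's lengths; otherwise ``None``.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    read = read.upper()
    if set(read) - set("ACGTN"):
        raise ValueError("read contains characters outside A/C/G/T/N")
    i5 = _hamming_find(read, design.five_prime_const, max_mismatch)
    if i5 < 0:
        return None
    insert_start = i5 + len(design.five_prime_const)
    i3 = _hamming_find(read[insert_start:], design.three_prime_const, max_mismatch)
    if i3 < 0:
        return None
    insert = read[insert_start:insert_start + i3]
    if len(insert) % 3 != 0:
        return None
    if len(insert) // 3 not in design.lengths:
        return None
    return insert


def translate(insert: str, table: CodonTable) -> PeptideRecord:
    """Translate a codon-aligned random-region insert into a PeptideRecord.

    The linear sequence is initiator + elongation translation of the insert +
    the constant Cys-(Gly-Ser)x3 residues, terminating at the first stop. A
    stop inside the random region sets ``truncated_by_stop``; a non-NNK codon
    sets ``non_nnk_codon`` (the record is excluded from ranking, not fatal).
    """
    if len(insert) % 3 != 0:
        raise ValueError("insert length must be divisible by 3")
    insert = insert.upper()
    n = len(insert) // 3
    seq = [table.initiator_symbol]
    flags: set = set()
    for i in range(n):
        codon = insert[3 * i:3 * i + 3]
        if not table.is_nnk(codon):
            flags.add("non_nnk_codon")
            try:
                aa = table.translate_codon(codon)
            except KeyError:
                return PeptideRecord(linear=tuple(seq), n=n, flags=flags)
        else:
            aa = table.translate_codon(codon)
        if aa == STOP:
            flags.add("truncated_by_stop")
            return PeptideRecord(linear=tuple(seq), n=n, flags=flags)
        if codon == "ATG" and aa == "M":
            # Met(-) translation system: internal AUG reads are chemically
            # ambiguous in the main library modes
            flags.add("contains_unassigned")
        seq.append(aa)
    seq.extend(CONSTANT_RESIDUES)
    return PeptideRecord(linear=tuple(seq), n=n, flags=flags)


def assign_cyclization(record: PeptideRecord) -> PeptideRecord:
    """Assign the thioether bridge (N-terminus to first Cys) and derive the
    synthesis form.

    Rule (a): first Cys is the constant-region Cys (index n+1) -> synthesis
    form runs through the glycine immediately following it (n+3 residues).
    Rule (b): first Cys is inside the random region -> synthesis form runs
    through the end of the random region.
    """
    cys_idx = next((i for i, s in enumerate(record.linear) if s == "C"), None)
    if cys_idx is None:
        record.flags.add("no_cysteine")
        record.bridge = None
        record.synthesis_form = ()
        return record
    record.bridge = (0, cys_idx)
    constant_cys = 1 + record.n
    if cys_idx == constant_cys and "truncated_by_stop" not in record.flags:
        record.synthesis_form = record.linear[:constant_cys + 2]   # ...Cys-Gly
    else:
        record.synthesis_form = record.linear[:record.n + 1]       # end of random region
    return record


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def deconvolute_reads(reads, design: LibraryDesign, table: CodonTable,
                      max_mismatch: int = 0, round_id: str = "round",
                      rescue_reverse_complement: bool = False):
    """Run the full per-read pipeline over an iterable of DNA reads.

    Returns ``(RoundCounts, qc)`` where ``qc`` maps skip-reason codes to read
    counts; valid + skipped always reconciles to the input read count.
    ``rescue_reverse_complement`` retries anchor-less reads on the opposite
    strand (off by default; reads are processed as given).
    """
    counts: Counter = Counter()
    qc: Counter = Counter()
    n_reads = 0
    for read in reads:
        n_reads += 1
        try:
            insert = extract_random_region(read, design, max_mismatch)
            if insert is None and rescue_reverse_complement:
                insert = extract_random_region(reverse_complement(read.upper()),
                                               design, max_mismatch)
        except ValueError:
            qc[SKIP_BAD_CHARS] += 1
            continue
        if insert is None:
            qc[SKIP_NO_ANCHOR] += 1
            continue
        rec = assign_cyclization(translate(insert, table))
        if "non_nnk_codon" in rec.flags:
            qc[SKIP_BAD_CODON] += 1
        elif "truncated_by_stop" in rec.flags:
            qc[SKIP_STOP] += 1
        elif rec.bridge is None:
            qc[SKIP_NO_CYS] += 1
        else:
            counts[rec.key] += 1
    qc["valid"] = sum(counts.values())
    qc["input_reads"] = n_reads
    return RoundCounts(round_id=round_id, counts=counts), dict(qc)


def tally_and_rank(records, round_id: str = "round"):
    """Tally PeptideRecords into RoundCounts and a ranked table.

    Ranking is by descending count with lexicographic tie-break on the
    synthesis-form string; stop-truncated and cysteine-less records are
    excluded from the ranking (kept in QC tallies by callers).
    """
    counts: Counter = Counter()
    meta: dict = {}
    for rec in records:
        if not rec.valid_for_ranking:
            continue
        counts[rec.key] += 1
        meta[rec.key] = rec
    if not counts:
        raise EmptyPoolError("no valid records in pool")
    rc = RoundCounts(round_id=round_id, counts=counts)
    return rc, rank_counts(rc, meta)


def rank_counts(rc: RoundCounts, meta: dict | None = None) -> pd.DataFrame:
    """Ranked table (rank, peptide, count, frequency, n, flags) from counts."""
    if rc.total == 0:
        raise EmptyPoolError(f"round {rc.round_id!r} has no reads")
    items = sorted(rc.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    total = rc.total
    rows = []
    for rank, (key, count) in enumerate(items, start=1):
        rec = meta.get(key) if meta else None
        rows.append({
            "rank": rank,
            "peptide": key,
            "count": count,
            "frequency": count / total,
            "n": rec.n if rec else pd.NA,
            "flags": ";".join(sorted(rec.flags)) if rec else "",
        })
    return pd.DataFrame(rows)


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def collapse_families(ranked: pd.DataFrame, max_edit_distance: int) -> pd.DataFrame:
    """Single-linkage clustering of ranked peptides under Levenshtein distance.

    Peptides within ``max_edit_distance`` edits (transitively) form one
    family, reported by its highest-count representative with summed counts.
    Distance 0 is the identity clustering.
    """
    if max_edit_distance < 0:
        raise ValueError("max_edit_distance must be >= 0")
    if max_edit_distance == 0 or len(ranked) <= 1:
        return ranked.copy()
    peps = list(ranked["peptide"])
    parent = list(range(len(peps)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(peps)):
        for j in range(i + 1, len(peps)):
            if _edit_distance(peps[i], peps[j]) <= max_edit_distance:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    df = ranked.copy()
    df["_family"] = [find(i) for i in range(len(peps))]
    out = []
    for _, grp in df.groupby("_family"):
        rep = grp.sort_values(["count", "peptide"],
                              ascending=[False, True]).iloc[0]
        row = rep.drop(labels="_family").to_dict()
        row["count"] = int(grp["count"].sum())
        row["family_size"] = len(grp)
        out.append(row)
    out_df = pd.DataFrame(out).sort_values(
        ["count", "peptide"], ascending=[False, True]).reset_index(drop=True)
    total = out_df["count"].sum()
    out_df["frequency"] = out_df["count"] / total
    out_df["rank"] = range(1, len(out_df) + 1)
    return out_df
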