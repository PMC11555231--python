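"""Encoded cyclic-peptide library model.

An mRNA-display library is encoded by a DNA template of the form

    5'const ... ATG (NNK)n  TGCGGCAGCGGCAGCGGCAGC TAG ... 3'const

where the initiator ATG is reprogrammed to carry an N-chloroacetyl-D- or
L-tyrosine, the NNK degenerate codons (N = A/C/G/T, K = G/T; 32 codons
covering all 20 amino acids with TAG as the only stop) encode a random
region of mixed length, and the constant Cys-Gly-Ser-Gly-Ser-Gly-Ser linker
provides the cysteine that closes the thioether macrocycle.

This module models the library design (template, length/ratio composition,
initiator chemistry), the reprogrammed genetic codes, and deterministic
reverse translation for building test fixtures.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import yaml
from Bio.Seq import Seq

from . import residues
from .residues import CLAC_D_TYR, CLAC_L_TYR, N_ME_ALA, STOP

#: T7 promoter + ribosome binding region, ending in the initiator ATG.
PADI4_FIVE_PRIME = "TAATACGACTCACTATAGGGTTAACTTTAAGAAGGAGATATACATATG"
#: constant Cys-(Gly-Ser)x3 linker, amber stop, and 3' tail.
PADI4_THREE_PRIME = "TGCGGCAGCGGCAGCGGCAGCTAGGACGGGGGGCGGAAA"
#: residues encoded by the constant region up to (not including) the stop.
CONSTANT_RESIDUES = ("C", "G", "S", "G", "S", "G", "S")

#: mixed-length NNK composition of the naive selection library: n random
#: codons at relative molar ratio.
PADI4_LENGTH_RATIOS = [
    (6, 0.001),
    (7, 0.032),
    (8, 1.0),
    (9, 32.0),
    (10, 33.0),
    (11, 33.0),
    (12, 11.0),
]

NNK_CODONS = tuple(
    "".join(c) for c in itertools.product("ACGT", "ACGT", "GT")
)

MODES = ("main_D", "main_L", "scanning")


class ConfigurationError(ValueError):
    """Invalid library/codon-table/simulation configuration."""


@dataclass(frozen=True)
class LibraryDesign:
    """Template and composition of an encoded peptide library."""

    five_prime_const: str = PADI4_FIVE_PRIME
    three_prime_const: str = PADI4_THREE_PRIME
    length_components: tuple = tuple(PADI4_LENGTH_RATIOS)
    initiator_stereo: str = "D"

    def __post_init__(self):
        object.__setattr__(self, "length_components",
                           tuple((int(n), float(r)) for n, r in self.length_components))
        if not self.five_prime_const.endswith("ATG"):
            raise ConfigurationError("5' constant region must end in the initiator ATG")
        if not self.three_prime_const.startswith("TGCGGCAGC"):
            raise ConfigurationError("3' constant region must begin with the Cys-Gly-Ser linker")
        for region in (self.five_prime_const, self.three_prime_const):
            if set(region) - set("ACGT"):
                raise ConfigurationError("constant regions may contain only A/C/G/T")
        ns = [n for n, _ in self.length_components]
        if len(set(ns)) != len(ns):
            raise ConfigurationError("length components must have distinct n")
        for n, r in self.length_components:
            if r <= 0:
                raise ConfigurationError(f"ratio for n={n} must be positive")
            if not 1 <= n <= 40:
                raise ConfigurationError(f"random-region length n={n} out of range")
        if self.initiator_stereo not in ("D", "L"):
            raise ConfigurationError("initiator_stereo must be 'D' or 'L'")

    @property
    def lengths(self) -> tuple:
        return tuple(n for n, _ in self.length_components)

    @property
    def mode(self) -> str:
        return "main_D" if self.initiator_stereo == "D" else "main_L"

    def to_config(self) -> dict:
        return {
            "five_prime_const": self.five_prime_const,
            "three_prime_const": self.three_prime_const,
            "length_components": [[n, r] for n, r in self.length_components],
            "initiator_stereo": self.initiator_stereo,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "LibraryDesign":
        known = {"five_prime_const", "three_prime_const", "length_components",
                 "initiator_stereo"}
        unknown = set(cfg) - known
        if unknown:
            raise ConfigurationError(f"unknown design keys: {sorted(unknown)}")
        return cls(**{k: (tuple(map(tuple, v)) if k == "length_components" else v)
                      for k, v in cfg.items()})

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_config(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "LibraryDesign":
        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh))


@dataclass(frozen=True)
class CodonTable:
    """Reprogrammed genetic code restricted to the NNK codon set.

    ``mode`` selects the reprogramming: ``main_D``/``main_L`` are the naive
    selections (initiator ATG -> chloroacetyl-D/L-Tyr, elongation follows the
    standard code); ``scanning`` is the mutational-scanning code in which
    elongation ATG is reprogrammed to N-methyl-alanine.
    """

    mode: str
    mapping: dict = field(repr=False)
    stop_codons: frozenset
    initiator_symbol: str

    def translate_codon(self, codon: str, initiator: bool = False) -> str:
        """Residue symbol (or ``'*'``) for one codon; initiator position uses
        the reprogrammed initiator symbol."""
        codon = codon.upper()
        if initiator:
            if codon != "ATG":
                raise ValueError(f"initiator codon must be ATG, got {codon}")
            return self.initiator_symbol
        if codon in self.stop_codons:
            return STOP
        try:
            return self.mapping[codon]
        except KeyError:
            raise KeyError(f"codon {codon} is not resolvable (not NNK)") from None

    def is_nnk(self, codon: str) -> bool:
        return codon.upper() in NNK_CODONS


def make_codon_table(mode: str) -> CodonTable:
    """Build the reprogrammed NNK genetic code for *mode*."""
    if mode not in MODES:
        raise ConfigurationError(f"unsupported codon-table mode: {mode!r}")
    mapping = {}
    stops = set()
    for codon in NNK_CODONS:
        aa = str(Seq(codon).translate())
        if aa == "*":
            stops.add(codon)
        else:
            mapping[codon] = aa
    if mode == "scanning":
        mapping["ATG"] = N_ME_ALA
    initiator = {"main_D": CLAC_D_TYR, "main_L": CLAC_L_TYR,
                 "scanning": CLAC_D_TYR}[mode]
    return CodonTable(mode=mode, mapping=mapping,
                      stop_codons=frozenset(stops), initiator_symbol=initiator)


def length_weights(design: LibraryDesign) -> dict:
    """Normalised length distribution of the random region, n -> probability."""
    if not design.length_components:
        raise ConfigurationError("design has no length components")
    total = sum(r for _, r in design.length_components)
    return {n: r / total for n, r in design.length_components}


def theoretical_diversity(design: LibraryDesign) -> int:
    """Number of distinct stop-free random-region peptide sequences encodable
    by the design: sum of 20**n over length components."""
    return sum(20 ** n for n, _ in design.length_components)


# smallest NNK codon per canonical residue under the standard elongation code
_MIN_NNK_CODON = {}
for _codon in NNK_CODONS:
    _aa = str(Seq(_codon).translate())
    if _aa != "*" and (_aa not in _MIN_NNK_CODON or _codon < _MIN_NNK_CODON[_aa]):
        _MIN_NNK_CODON[_aa] = _codon


def reverse_translate(random_region: str, policy: str = "lexicographic") -> str:
    """Deterministically reverse-translate a canonical random-region peptide
    into NNK-valid DNA (smallest NNK codon per residue).

    Used to construct library-format fixture reads; the round trip
    ``translate(reverse_translate(p)) == p`` holds for any canonical peptide.
    """
    if policy != "lexicographic":
        raise ConfigurationError(f"unknown reverse-translation policy: {policy!r}")
    codons = []
    for aa in random_region:
        if aa not in _MIN_NNK_CODON:
            raise ValueError(f"residue {aa!r} is not a canonical amino acid")
        codons.append(_MIN_NNK_CODON[aa])
    return "".join(codons)


def build_library_read(random_region_dna: str,
                       design: LibraryDesign | None = None) -> str:
    """Assemble a full library-format read around a random-region insert."""
    design = design or LibraryDesign()
    return design.five_prime_const + random_region_dna + design.three_prime_const
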