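"""Residue symbol registry.

Peptides produced by reprogrammed in vitro translation contain residues
outside the 20 canonical amino acids: the N-terminal chloroacetyl-D/L-tyrosine
initiator that drives thioether macrocyclisation, and N-methyl-alanine, which
replaces methionine in the scanning genetic code.  Canonical residues are
their usual one-letter codes; non-canonical residues are registered
multi-character symbols with a defined one-letter display fallback so that
peptide strings remain printable and hashable.
"""

from __future__ import annotations

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"

# registered extended symbols
CLAC_D_TYR = "ClAc-dY"   # N-chloroacetyl-D-tyrosine initiator
CLAC_L_TYR = "ClAc-lY"   # N-chloroacetyl-L-tyrosine initiator
N_ME_ALA = "NMeA"        # N-methyl-alanine (replaces Met in scanning mode)
STOP = "*"

EXTENDED = {CLAC_D_TYR, CLAC_L_TYR, N_ME_ALA}

#: one-letter display fallback; N-Me-Ala uses lowercase 'a' so the scanning
#: heatmap keeps a row distinct from alanine.
DISPLAY = {CLAC_D_TYR: "Y", CLAC_L_TYR: "Y", N_ME_ALA: "a"}

STEREO = {CLAC_D_TYR: "D", CLAC_L_TYR: "L"}


def is_valid(symbol: str) -> bool:
    """True if *symbol* is a canonical one-letter code or a registered extended symbol."""
    return (len(symbol) == 1 and symbol in CANONICAL) or symbol in EXTENDED


def require_valid(symbol: str) -> str:
    if not is_valid(symbol):
        raise ValueError(f"unknown residue symbol: {symbol!r}")
    return symbol


def display(symbol: str) -> str:
    """One-letter display character for a residue symbol."""
    if len(symbol) == 1 and symbol in CANONICAL:
        return symbol
    try:
        return DISPLAY[symbol]
    except KeyError:
        raise ValueError(f"unknown residue symbol: {symbol!r}") from None


def to_string(symbols) -> str:
    """Join a residue-symbol sequence into its one-letter display string."""
    return "".join(display(s) for s in symbols)


def stereo(symbol: str) -> str:
    """Stereo annotation for a residue symbol ('L' unless registered D)."""
    require_valid(symbol)
    return STEREO.get(symbol, "L")
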