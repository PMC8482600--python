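"""Small DNA helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC degenerate alphabet, base set -> code.
IUPAC_CODE = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
    frozenset("ACG"): "V",
    frozenset("ACT"): "H",
    frozenset("AGT"): "D",
    frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}

#: Inverse map, IUPAC code -> set of bases it covers.
IUPAC_SET = {code: set(bases) for bases, code in IUPAC_CODE.items()}

# one-letter ambiguity codes that are collapsed to N on input
AMBIGUITY_CODES = set("RYSWKMBDHV")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G+C among ACGT characters (N excluded); 0.0 for empty."""
    acgt = sum(seq.count(b) for b in BASES)
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


def normalize_sequence(seq: str) -> tuple[str, bool]:
    """Upcase and map non-N ambiguity codes to N.

    Returns the normalized sequence and whether any ambiguity code was
    replaced.  Raises ValueError on characters outside the IUPAC alphabet.
    """
    seq = seq.strip().upper().replace("U", "T")
    replaced = False
    out = []
    for ch in seq:
        if ch in "ACGTN":
            out.append(ch)
        elif ch in AMBIGUITY_CODES:
            out.append("N")
            replaced = True
        else:
            raise ValueError(f"invalid sequence character {ch!r}")
    return "".join(out), replaced
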