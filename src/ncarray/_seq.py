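"""Small shared sequence helpers (DNA/RNA alphabets, complements)."""

from __future__ import annotations

_DNA_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: DNA base complementary to a given RNA base (U/T treated alike).
DNA_COMPLEMENT_OF_RNA = {"A": "T", "C": "G", "G": "C", "U": "A", "T": "A"}


def to_dna(seq: str) -> str:
    """Uppercase and transliterate U->T."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Uppercase and transliterate T->U."""
    return seq.upper().replace("T", "U")


def revcomp_dna(seq: str) -> str:
    """Reverse complement in the DNA alphabet (input may contain U)."""
    return to_dna(seq).translate(_DNA_COMPLEMENT)[::-1]


def validate_alphabet(seq: str, *, allow_u: bool = True, context: str = "sequence") -> None:
    allowed = set("ACGT") | ({"U"} if allow_u else set())
    bad = set(seq.upper()) - allowed
    if bad:
        raise ValueError(f"{context} contains non-ACGT/U characters: {sorted(bad)!r}")
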