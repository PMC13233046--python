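"""Canonical 96-channel single-base-substitution categories and trinucleotide order.

Conventions used throughout the package:

* Substitutions are expressed on the pyrimidine strand, giving six classes
  ``C>A, C>G, C>T, T>A, T>C, T>G``.
* The 96 categories are ordered substitution-major, then by 5' flank, then by
  3' flank, both alphabetical (``A[C>A]A, A[C>A]C, ..., T[T>G]T``) — the order
  COSMIC uses for its SBS matrices.
* The 32 strand-collapsed trinucleotides are pyrimidine-centered and ordered
  by (5' flank, center in {C, T}, 3' flank): ``ACA ... TCT, ATA ... TTT``.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: the 96 category labels, e.g. "A[C>A]A", in canonical order
CATEGORIES: tuple[str, ...] = tuple(
    f"{f5}[{sub}]{f3}" for sub in SUBSTITUTIONS for f5 in BASES for f3 in BASES
)

CATEGORY_INDEX = {label: i for i, label in enumerate(CATEGORIES)}

#: the 32 pyrimidine-centered trinucleotides, center-C block then center-T block
PYRIMIDINE_TRINUCS: tuple[str, ...] = tuple(
    f"{f5}{center}{f3}" for center in "CT" for f5 in BASES for f3 in BASES
)

TRINUC_INDEX = {t: i for i, t in enumerate(PYRIMIDINE_TRINUCS)}

#: trinucleotide index (0..31) of each of the 96 categories
CATEGORY_TRINUC = np.array(
    [TRINUC_INDEX[lab[0] + lab[2] + lab[6]] for lab in CATEGORIES], dtype=np.intp
)

#: True for the 16 T>A categories (the classes ENU enriches)
TA_CATEGORY_MASK = np.array([lab[2:5] == "T>A" for lab in CATEGORIES], dtype=bool)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def category_label(ref: str, alt: str, flank5: str, flank3: str) -> str:
    """Pyrimidine-strand category label for a substitution in its context.

    Purine-reference substitutions are reverse-complemented: ref/alt are
    complemented and the flanks swap and complement.
    """
    ref, alt = ref.upper(), alt.upper()
    flank5, flank3 = flank5.upper(), flank3.upper()
    if ref in PURINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        flank5, flank3 = COMPLEMENT[flank3], COMPLEMENT[flank5]
    return f"{flank5}[{ref}>{alt}]{flank3}"


def category_index(ref: str, alt: str, flank5: str, flank3: str) -> int:
    """Index in [0, 96) of the pyrimidine-strand category; see category_label."""
    return CATEGORY_INDEX[category_label(ref, alt, flank5, flank3)]


def collapse_trinuc(trinuc: str) -> str:
    """Strand-collapse a trinucleotide to its pyrimidine-centered representative."""
    t = trinuc.upper()
    return t if t[1] in PYRIMIDINES else revcomp(t)


# integer base codes for vectorized sequence work: A=0 C=1 G=2 T=3, invalid=255
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0 C=1 G=2 T=3, other=255)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


# map each of the 64 raw trinucleotide codes (16*b0 + 4*b1 + b2) onto the
# 32-entry pyrimidine-collapsed index
_TRINUC64_TO_32 = np.empty(64, dtype=np.intp)
for _c0 in range(4):
    for _c1 in range(4):
        for _c2 in range(4):
            _tri = BASES[_c0] + BASES[_c1] + BASES[_c2]
            _TRINUC64_TO_32[16 * _c0 + 4 * _c1 + _c2] = TRINUC_INDEX[collapse_trinuc(_tri)]


def trinuc32_codes(codes: np.ndarray) -> np.ndarray:
    """Per-window collapsed trinucleotide indices for an encoded sequence.

    Returns an array of length ``len(codes) - 2`` with values in [0, 32) for
    valid windows and -1 where any base in the window is not A/C/G/T.
    """
    if codes.size < 3:
        return np.empty(0, dtype=np.intp)
    c0, c1, c2 = codes[:-2], codes[1:-1], codes[2:]
    valid = (c0 != 255) & (c1 != 255) & (c2 != 255)
    out = np.full(codes.size - 2, -1, dtype=np.intp)
    idx64 = (
        16 * c0[valid].astype(np.intp)
        + 4 * c1[valid].astype(np.intp)
        + c2[valid].astype(np.intp)
    )
    out[valid] = _TRINUC64_TO_32[idx64]
    return out
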