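"""The 96-channel single-base-substitution alphabet.

Single nucleotide variants are summarized pyrimidine-centered: a substitution
with a purine reference base is mapped to its reverse complement, so every
mutation falls into one of 6 substitution types (C>A, C>G, C>T, T>A, T>C, T>G)
times 16 flanking-base contexts. Channel order follows the COSMIC convention:
substitution types in the order above, flanks alphabetical (5' major,
3' minor), e.g. ``A[C>A]A, A[C>A]C, ..., T[T>G]T``.
"""

from __future__ import annotations

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"

#: the 96 channel labels, COSMIC order
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
)

CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def fold(ref: str, alt: str, context: str) -> str:
    """Map an SNV (with its 3-mer reference context) to its 96-channel label.

    Purine-reference changes are folded to the reverse-complement strand so
    the central base is a pyrimidine. Raises ``ValueError`` if the middle base
    of ``context`` is not ``ref``, or the change is not a valid SNV.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not an SNV: {ref}>{alt}")
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not match ref {ref!r}")
    if any(b not in COMPLEMENT for b in context + alt):
        raise ValueError(f"non-ACGT base in {context!r}>{alt!r}")
    if ref in "AG":
        context = revcomp(context)
        ref = COMPLEMENT[ref]
        alt = COMPLEMENT[alt]
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    return label


def unfold(channel: str) -> tuple[str, str, str]:
    """Inverse of :func:`fold` on the pyrimidine strand: (ref, alt, context)."""
    five, mid, three = channel[0], channel[2:5], channel[6]
    ref, alt = mid.split(">")
    return ref, alt, five + ref + three
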