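"""Low-level sequence generators for synthetic genomes, strains and marker proteins.

Genomes are represented internally as ``uint8`` arrays of base codes
(A=0, C=1, G=2, T=3); helpers convert to/from strings at the boundary.
Each genome carries its own dinucleotide usage signature so that
composition-based binning (tetranucleotide frequencies) can tell genomes
apart, as it does for real microbial genomes.
"""

from __future__ import annotations



import numpy as np

BASES = "ACGT"
_BASE_CODES = {b: i for i, b in enumerate(BASES)}
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _base, _code in _BASE_CODES.items():
    _ENCODE_LUT[ord(_base)] = _code


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 code array; reject other letters."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_LUT[arr]
    if (codes == 255).any():
        bad = chr(arr[codes == 255][0])
        raise ValueError(f"non-ACGT character in sequence: {bad!r}")
    return codes


def decode_sequence(codes: np.ndarray) -> str:
    lut = np.frombuffer("ACGT".encode("ascii"), dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def random_genome(length: int, gc: float, rng: np.random.Generator,
                  signature_scale: float = 0.45) -> np.ndarray:
    """Generate a random genome with a genome-specific composition signature.

    The sequence is a concatenation of i.i.d. dinucleotide blocks drawn from
    a genome-specific distribution: a product of single-base frequencies set
    by the GC content, perturbed by log-normal noise of scale
    ``signature_scale``. The perturbation gives every genome a distinct
    tetranucleotide profile while keeping GC near the target, mimicking the
    oligonucleotide signatures that make composition-based binning work.
    """
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must be in (0,1), got {gc}")
    if length < 2:
        raise ValueError("genome length must be >= 2")
    p1 = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    dinuc = np.outer(p1, p1).ravel()
    dinuc = dinuc * np.exp(signature_scale * rng.normal(size=16))
    dinuc /= dinuc.sum()
    n_blocks = (length + 1) // 2
    blocks = rng.choice(16, size=n_blocks, p=dinuc)
    codes = np.empty(2 * n_blocks, dtype=np.uint8)
    codes[0::2] = blocks // 4
    codes[1::2] = blocks % 4
    return codes[:length]


def mutate_strain(reference, rate: float, seed=None):
    """Mutate a reference sequence with i.i.d. per-site substitutions.

    Parameters
    ----------
    reference : str or uint8 code array
        Reference nucleotide sequence (ACGT only).
    rate : float
        Per-site substitution probability in [0, 1).  ``rate=1`` is accepted
        as the degenerate force-change case (every site substituted).
    seed : int, numpy Generator, or None
        Source of randomness.

    Returns
    -------
    (sequence, substitutions)
        Sequence of the same type as the input and a list of
        ``(position, ref_base, alt_base)`` tuples (bases as letters).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0,1], got {rate}")
    as_str = isinstance(reference, str)
    codes = encode_sequence(reference) if as_str else np.asarray(reference, dtype=np.uint8).copy()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    hit = np.nonzero(rng.random(codes.size) < rate)[0]
    out = codes.copy()
    if hit.size:
        # offset 1..3 guarantees the new base differs from the old one
        out[hit] = (codes[hit] + rng.integers(1, 4, size=hit.size)) % 4
    subs = [(int(i), BASES[codes[i]], BASES[out[i]]) for i in hit]
    return (decode_sequence(out) if as_str else out), subs


def random_protein(length: int, rng: np.random.Generator) -> str:
    """Uniform random amino-acid sequence over the 20-letter alphabet."""
    idx = rng.integers(0, 20, size=length)
    return "".join(AMINO_ACIDS[i] for i in idx)


def mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute amino acids i.i.d. at ``rate``; substitutions always change the residue."""
    residues = list(seq)
    hit = np.nonzero(rng.random(len(residues)) < rate)[0]
    for i in hit:
        choices = [a for a in AMINO_ACIDS if a != residues[i]]
        residues[i] = choices[rng.integers(0, len(choices))]
    return "".join(residues)


def contig_lengths(total: int, rng: np.random.Generator,
                   median: int = 5000, sigma: float = 0.45,
                   min_length: int = 500) -> list[int]:
    """Split ``total`` bp into contiguous contig lengths.

    Lengths are drawn from a lognormal with the given median and shape
    ``sigma``; the final fragment is merged backwards when shorter than
    ``min_length`` so no contig falls below the assembler-style cutoff.
    """
    if total < min_length:
        return [total]
    lengths: list[int] = []
    remaining = total
    while remaining > 0:
        ln = int(rng.lognormal(np.log(median), sigma))
        ln = max(min_length, ln)
        if remaining - ln < min_length:
            ln = remaining
        lengths.append(min(ln, remaining))
        remaining -= lengths[-1]
    return lengths
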