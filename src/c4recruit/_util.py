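"""Shared small helpers: alphabet encoding, IUPAC codes, seeded substreams."""

from __future__ import annotations

import zlib

import numpy as np

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# IUPAC code keyed by the sorted tuple of allowed bases
IUPAC_BY_SET = {
    ("A",): "A", ("C",): "C", ("G",): "G", ("T",): "T",
    ("A", "C"): "M", ("A", "G"): "R", ("A", "T"): "W",
    ("C", "G"): "S", ("C", "T"): "Y", ("G", "T"): "K",
    ("A", "C", "G"): "V", ("A", "C", "T"): "H",
    ("A", "G", "T"): "D", ("C", "G", "T"): "B",
    ("A", "C", "G", "T"): "N",
}
IUPAC_SETS = {code: set(bases) for bases, code in IUPAC_BY_SET.items()}
IUPAC_COMPLEMENT = {
    code: IUPAC_BY_SET[tuple(sorted(COMPLEMENT[b] for b in bases))]
    for bases, code in IUPAC_BY_SET.items()
}


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def revcomp_iupac(code_string: str) -> str:
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(code_string))


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3 and anything else (N) as 4."""
    table = np.full(256, 4, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].astype(np.int64)


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def _tag_int(tag) -> int:
    if isinstance(tag, str):
        # process-independent string hash (hash() is salted per interpreter run)
        return zlib.crc32(tag.encode("utf-8"))
    return int(tag) & 0xFFFFFFFF


def substream(seed: int, *tags) -> np.random.Generator:
    """Deterministic named child RNG.

    Every source of randomness in the package derives from one root seed via
    stable string/int tags, so runs are reproducible stage by stage.
    """
    key = [int(seed)] + [_tag_int(t) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(key))


def substream_seed(seed: int, *tags) -> int:
    """A plain integer seed (< 2**31) derived from a named substream."""
    return int(substream(seed, *tags).integers(0, 2**31 - 1))
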