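"""Position weight matrices and MEME-minimal motif I/O.

A :class:`PWM` stores per-position base frequencies (shape ``(width, 4)``,
columns ordered A, C, G, T).  The *consensus* is the per-position argmax
string; information content is computed against a uniform background.
Provenance (engine, k-run, gene, segment) travels with the matrix so that
consensus-building stages can report where a motif came from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import motifs as bio_motifs

from ._util import ALPHABET, substream


@dataclass
class PWM:
    """Per-position base-frequency model of a DNA motif."""

    matrix: np.ndarray  # (width, 4) row-stochastic, columns A,C,G,T
    name: str = ""
    pseudocount: float = 0.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (width, 4)")
        if self.matrix.shape[0] < 1:
            raise ValueError("PWM width must be >= 1")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PWM rows (positions) must each sum to 1")
        if (self.matrix < 0).any():
            raise ValueError("PWM frequencies must be nonnegative")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def information_content(self) -> np.ndarray:
        """Per-position IC in bits relative to a uniform background."""
        p = np.clip(self.matrix, 1e-12, 1.0)
        return 2.0 + (p * np.log2(p)).sum(axis=1)

    def reverse_complement(self) -> "PWM":
        return PWM(self.matrix[::-1, ::-1].copy(), name=self.name,
                   pseudocount=self.pseudocount, provenance=dict(self.provenance))

    def log_odds(self, background: np.ndarray | None = None,
                 pseudocount: float | None = None) -> np.ndarray:
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        pc = self.pseudocount if pseudocount is None else pseudocount
        p = (self.matrix + pc) / (1.0 + 4 * pc)
        return np.log(p) - np.log(bg)

    def sample_site(self, rng: np.random.Generator,
                    allowed: list[set] | None = None) -> str:
        """Draw one site, optionally restricted to per-position allowed bases."""
        out = []
        for i in range(self.width):
            p = self.matrix[i].copy()
            if allowed is not None:
                mask = np.array([b in allowed[i] for b in ALPHABET])
                p = p * mask
                p = p / p.sum()
            out.append(ALPHABET[rng.choice(4, p=p)])
        return "".join(out)

    @classmethod
    def from_sites(cls, sites: list[str], pseudocount: float = 0.01,
                   name: str = "", **prov) -> "PWM":
        width = len(sites[0])
        if any(len(s) != width for s in sites):
            raise ValueError("all sites must have equal length")
        counts = np.zeros((width, 4))
        for s in sites:
            for i, b in enumerate(s.upper()):
                counts[i, ALPHABET.index(b)] += 1
        counts += pseudocount
        return cls(counts / counts.sum(axis=1, keepdims=True), name=name,
                   pseudocount=pseudocount, provenance=prov)

    @classmethod
    def from_word(cls, word: str, pseudocount: float = 0.01, name: str = "",
                  **prov) -> "PWM":
        """Lift a literal word to a one-hot-with-pseudocount PWM."""
        return cls.from_sites([word], pseudocount=pseudocount,
                              name=name or word, **prov)

    @classmethod
    def random(cls, width: int, rng: np.random.Generator,
               sharpness: float = 0.85, name: str = "") -> "PWM":
        """A random sharp PWM: one dominant base per position."""
        m = np.full((width, 4), (1 - sharpness) / 3)
        m[np.arange(width), rng.integers(0, 4, size=width)] = sharpness
        return cls(m, name=name)


def write_meme(pwms: list[PWM], path, background: np.ndarray | None = None) -> None:
    """Write motifs in MEME minimal format."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A %.5f C %.5f G %.5f T %.5f\n\n" % tuple(bg))
        for i, pwm in enumerate(pwms):
            name = pwm.name or f"motif_{i + 1}"
            fh.write(f"MOTIF {name}\n")
            # large nsites so parsers that reconstruct integer counts keep
            # the frequencies to ~1e-4
            fh.write(f"letter-probability matrix: alphabet= ACGT w= {pwm.width} "
                     f"nsites= 10000 E= 0\n")
            for row in pwm.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def _parse_meme_handle(fh) -> list[PWM]:
    records = bio_motifs.parse(fh, "minimal")
    out = []
    for rec in records:
        mat = np.array([[rec.pwm[b][i] for b in ALPHABET]
                        for i in range(rec.length)], dtype=float)
        mat = mat / mat.sum(axis=1, keepdims=True)
        out.append(PWM(mat, name=rec.name))
    return out


def read_meme(path) -> list[PWM]:
    """Read motifs from MEME minimal format (via Bio.motifs)."""
    with open(path) as fh:
        return _parse_meme_handle(fh)


def toy_library() -> list[PWM]:
    """The small generic plant-element PWM library shipped with the
    package (synthetic stand-in for a curated motif catalog)."""
    import io
    from importlib.resources import files
    text = files("c4recruit").joinpath("data/toy_library.meme").read_text()
    return _parse_meme_handle(io.StringIO(text))


def trim_low_ic_edges(pwm: PWM, min_bits: float = 0.5,
                      min_width: int = 5) -> PWM:
    """Trim uninformative terminal positions (IC below ``min_bits``).

    EM finders often lock onto a site shifted by one position, picking up
    a near-random flanking column; trimming it restores the informative
    core.  Returns the input unchanged if trimming would go below
    ``min_width``.
    """
    ic = pwm.information_content()
    lo, hi = 0, pwm.width
    while lo < hi and ic[lo] < min_bits:
        lo += 1
    while hi > lo and ic[hi - 1] < min_bits:
        hi -= 1
    if hi - lo < min_width or (lo == 0 and hi == pwm.width):
        return pwm
    return PWM(pwm.matrix[lo:hi].copy(), name=pwm.name,
               pseudocount=pwm.pseudocount,
               provenance={**pwm.provenance, "trimmed": (lo, pwm.width - hi)})


def shuffled_columns(pwm: PWM, rng: np.random.Generator) -> PWM:
    """Column-shuffled copy (used for alignment null distributions)."""
    perm = rng.permutation(pwm.width)
    return PWM(pwm.matrix[perm], name=pwm.name + "_shuf")


__all__ = ["PWM", "write_meme", "read_meme", "shuffled_columns", "substream"]
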