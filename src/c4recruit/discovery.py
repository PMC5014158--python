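"""Motif discovery engines and the enrichment test.

Three independent engines, mirroring the common practice of combining a
PWM expectation-maximization finder, an exhaustive word enumerator, and
a biophysical PWM-library scorer:

``em_discover``
    ZOOPS (zero-or-one occurrence per sequence) expectation-maximization:
    each sequence either contains one motif site (uniform prior over
    offsets, both strands) or is pure background.  The E-step computes the
    posterior over site placements under the current PWM versus a
    zero-order background; the M-step re-estimates the PWM from expected
    site counts with a pseudocount.  Best of several random restarts by
    log-likelihood; the log-likelihood is non-decreasing by construction
    and the full trace is kept for auditing.

``word_enumerate``
    Exhaustive enumeration of all words of the configured widths; a
    foreground sequence supports a word if it contains an occurrence
    within ``max_word_mm`` mismatches on either strand.  The per-sequence
    background hit probability is computed analytically from a
    first-order Markov background model, and enrichment is a one-sided
    binomial test over sequences.

``trap_affinity`` / ``library_enrichment``
    Biophysical binding-affinity scoring: each window contributes
    ``1/(1 + exp(E - ln R0))`` where the mismatch energy ``E`` is the
    lambda-scaled log-ratio of the best to the observed base frequency,
    summed over positions.  Library motifs are called enriched when
    foreground affinities exceed background affinities by a one-sided
    rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import IUPAC_SETS, encode, revcomp, revcomp_iupac
from .pwm import PWM

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# background model
# ---------------------------------------------------------------------------

@dataclass
class BackgroundModel:
    """First-order Markov model of a segment class's sequence composition."""

    segment_class: str
    transition: np.ndarray          # (4,4), rows sum to 1
    initial: np.ndarray             # (4,)
    base_freqs: np.ndarray          # zero-order base frequencies

    @classmethod
    def fit(cls, seqs: list[str], segment_class: str = "",
            pseudocount: float = 1.0) -> "BackgroundModel":
        trans = np.full((4, 4), pseudocount)
        init = np.full(4, pseudocount)
        freqs = np.full(4, pseudocount)
        for s in seqs:
            codes = encode(s)
            valid = codes < 4
            freqs += np.bincount(codes[valid], minlength=5)[:4]
            pair_ok = valid[:-1] & valid[1:]
            if pair_ok.any():
                np.add.at(trans, (codes[:-1][pair_ok], codes[1:][pair_ok]), 1)
            if len(codes) and valid[0]:
                init[codes[0]] += 1
        return cls(segment_class=segment_class,
                   transition=trans / trans.sum(axis=1, keepdims=True),
                   initial=init / init.sum(),
                   base_freqs=freqs / freqs.sum())

    def word_prob(self, word: str) -> float:
        codes = encode(word)
        p = self.initial[codes[0]]
        for a, b in zip(codes[:-1], codes[1:]):
            p *= self.transition[a, b]
        return float(p)

    def all_word_probs(self, width: int) -> np.ndarray:
        """Markov probability of every width-mer, indexed base-4
        (first base most significant)."""
        p = self.initial.copy()
        for _ in range(width - 1):
            # p[..., b_k] -> p[..., b_k, b_{k+1}] via one Markov step
            p = p[..., None] * self.transition
        return p.reshape(-1)

    def scan_match_prob(self, consensus: str, degenerate: str,
                        max_mm: int = 2) -> float:
        """Probability that one window matches the two-rule scan on either
        strand (<= max_mm literal mismatches AND degenerate-compatible)."""
        def one_strand(cons, degen):
            codes = encode(cons)
            total = 0.0
            stack = [(0, 0, 1.0, -1)]  # (pos, mm, prob, prev_base)
            while stack:
                pos, mm, prob, prev = stack.pop()
                if pos == len(cons):
                    total += prob
                    continue
                for b in IUPAC_SETS[degen[pos]]:
                    bi = "ACGT".index(b)
                    nmm = mm + (bi != codes[pos])
                    if nmm > max_mm:
                        continue
                    step = self.initial[bi] if prev < 0 else self.transition[prev, bi]
                    stack.append((pos + 1, nmm, prob * step, bi))
            return total

        q = one_strand(consensus, degenerate)
        q += one_strand(revcomp(consensus), revcomp_iupac(degenerate))
        return float(min(q, 1.0))

    def sample(self, length: int, rng: np.random.Generator) -> str:
        out = np.empty(length, dtype=np.int64)
        out[0] = rng.choice(4, p=self.initial)
        for i in range(1, length):
            out[i] = rng.choice(4, p=self.transition[out[i - 1]])
        return "".join("ACGT"[c] for c in out)


# ---------------------------------------------------------------------------
# enrichment test
# ---------------------------------------------------------------------------

def enrichment_test(fg_hits: int, fg_trials: int, bg_rate: float) -> float:
    """One-sided binomial upper-tail p-value P(X >= fg_hits),
    X ~ Binomial(fg_trials, bg_rate)."""
    if not 0 < bg_rate < 1:
        raise ValueError("bg_rate must lie strictly between 0 and 1")
    if fg_hits > fg_trials:
        raise ValueError("fg_hits cannot exceed fg_trials")
    if fg_hits <= 0:
        return 1.0
    return float(stats.binom.sf(fg_hits - 1, fg_trials, bg_rate))


# ---------------------------------------------------------------------------
# hits
# ---------------------------------------------------------------------------

@dataclass
class MotifHit:
    motif: PWM
    engine: str                     # em | word | library
    pvalue: float
    segment: str = ""
    gene_list_id: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 <= self.pvalue <= 1:
            raise ValueError("p-value out of [0, 1]")


# ---------------------------------------------------------------------------
# ZOOPS EM
# ---------------------------------------------------------------------------

def _stack_windows(seqs: list[str], width: int, both_strands: bool):
    """All N-free windows of all sequences, with per-sequence offsets."""
    windows, seq_of = [], []
    kept = 0
    for s in seqs:
        codes = encode(s)
        if len(codes) < width:
            continue
        win = np.lib.stride_tricks.sliding_window_view(codes, width)
        win = win[(win < 4).all(axis=1)]
        if win.size == 0:
            continue
        if both_strands:
            win = np.vstack([win, (3 - win)[:, ::-1]])
        windows.append(win)
        seq_of.append(np.full(len(win), kept))
        kept += 1
    if not windows:
        raise ValueError("no sequence provides a window of the requested width")
    X = np.vstack(windows)
    seq_of = np.concatenate(seq_of)
    order = np.argsort(seq_of, kind="stable")
    return X[order], seq_of[order]


def em_discover(seqs: list[str], width: int, seed: int = 0, n_seeds: int = 5,
                max_iter: int = 200, tol: float = 1e-6,
                pseudocount: float = 0.01,
                both_strands: bool = True,
                bg_model: "BackgroundModel | None" = None) -> PWM:
    """ZOOPS EM motif discovery; returns the best-restart PWM.

    Background windows are scored under ``bg_model`` (first-order Markov)
    when given — without it, genomes with dinucleotide structure pull the
    EM toward homopolymer runs — or a zero-order model fit from the input
    otherwise.  The returned PWM's provenance records the per-iteration
    log-likelihood trace (``loglik_history``), the site prior ``gamma``
    and the seed.
    """
    usable = [s for s in seqs if len(s) >= width]
    if not usable:
        raise ValueError("all sequences shorter than the motif width")
    X, seq_of = _stack_windows(usable, width, both_strands)
    n_seq = seq_of.max() + 1
    starts = np.searchsorted(seq_of, np.arange(n_seq))
    m_s = np.diff(np.append(starts, len(seq_of)))  # windows per sequence

    if bg_model is not None:
        log_init = np.log(np.clip(bg_model.initial, 1e-12, None))
        log_T = np.log(np.clip(bg_model.transition, 1e-12, None))
        log_bg_win = log_init[X[:, 0]] + log_T[X[:, :-1], X[:, 1:]].sum(axis=1)
    else:
        counts = np.bincount(X.reshape(-1), minlength=5)[:4] + 1.0
        bg = counts / counts.sum()
        log_bg_win = np.log(bg)[X].sum(axis=1)

    rng = np.random.default_rng(seed)
    pos_idx = np.arange(width)

    def run(start_window: np.ndarray):
        theta = np.full((width, 4), 0.15 / 3)
        theta[pos_idx, start_window] = 0.85
        gamma = 0.5
        history = []
        for _ in range(max_iter):
            log_theta = np.log(theta)
            site_ll = log_theta[pos_idx, X].sum(axis=1)
            t = np.log(gamma) - np.log(m_s)[seq_of] + site_ll - log_bg_win
            # per-sequence logsumexp over window terms
            mx = np.maximum.reduceat(t, starts)
            sums = np.add.reduceat(np.exp(t - mx[seq_of]), starts)
            lse = mx + np.log(sums)
            L = np.logaddexp(np.log1p(-gamma), lse)  # per-seq marginal (vs bg)
            obj = float(L.sum())
            history.append(obj)
            if len(history) > 1 and obj - history[-2] < tol:
                break
            z = np.exp(t - L[seq_of])
            new = np.full((width, 4), pseudocount)
            for i in range(width):
                new[i] += np.bincount(X[:, i], weights=z, minlength=4)
            theta = new / new.sum(axis=1, keepdims=True)
            gamma = float(np.clip(np.add.reduceat(z, starts).mean(), 1e-4, 1 - 1e-4))
        return theta, gamma, history

    best = None
    for trial in range(n_seeds):
        start = X[rng.integers(0, len(X))]
        theta, gamma, history = run(start)
        if best is None or history[-1] > best[2][-1]:
            best = (theta, gamma, history)
    theta, gamma, history = best
    return PWM(theta, name=f"em_w{width}", pseudocount=pseudocount,
               provenance={"engine": "em", "width": width, "gamma": gamma,
                           "loglik": history[-1], "loglik_history": history,
                           "seed": seed})


# ---------------------------------------------------------------------------
# word enumeration
# ---------------------------------------------------------------------------

def _word_ids(seq: str, width: int, max_mm: int) -> np.ndarray:
    """Unique base-4 ids of all words occurring in ``seq`` (both strands)
    within ``max_mm`` mismatches (supported: 0 or 1)."""
    if max_mm not in (0, 1):
        raise ValueError("word enumeration supports at most 1 mismatch")
    mult = 4 ** np.arange(width - 1, -1, -1)
    collected = []
    for s in (seq, revcomp(seq)):
        codes = encode(s)
        if len(codes) < width:
            continue
        win = np.lib.stride_tricks.sliding_window_view(codes, width)
        win = win[(win < 4).all(axis=1)]
        if win.size == 0:
            continue
        ids = win @ mult
        collected.append(ids)
        if max_mm == 1:
            # neighbor id = id + (b - base_i) * 4^(width-1-i)
            delta = (np.arange(4)[None, None, :] - win[:, :, None]) * mult[None, :, None]
            collected.append((ids[:, None, None] + delta).reshape(-1))
    if not collected:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(collected))


def _revcomp_ids(width: int) -> np.ndarray:
    """Permutation mapping word id -> id of its reverse complement."""
    ids = np.arange(4 ** width)
    mult = 4 ** np.arange(width - 1, -1, -1)
    digits = (ids[:, None] // mult[None, :]) % 4
    return (3 - digits[:, ::-1]) @ mult


def _neighborhood_probs(p_all: np.ndarray, width: int, max_mm: int) -> np.ndarray:
    """q[word] = P(random width-mer is within max_mm of word), from per-word
    background probabilities."""
    if max_mm == 0:
        return p_all
    cube = p_all.reshape((4,) * width)
    S = np.zeros_like(cube)
    for axis in range(width):
        S = S + cube.sum(axis=axis, keepdims=True)
    return (S - (width - 1) * cube).reshape(-1)


def word_enumerate(fg: list[str], bg_model: BackgroundModel,
                   widths=(6, 8), max_word_mm: int = 1,
                   alpha: float = 0.05, top_n: int | None = None) -> pd.DataFrame:
    """Rank words by binomial enrichment of supporting sequences.

    Support = number of foreground sequences containing the word within
    ``max_word_mm`` mismatches on either strand; the background rate is
    the analytic per-sequence hit probability under the Markov model.
    Returns words with p <= alpha ranked by (p, -support, word).
    """
    if not fg:
        raise ValueError("empty foreground")
    frames = []
    n_seq = len(fg)
    for width in widths:
        per_seq = [_word_ids(s, width, max_word_mm) for s in fg]
        support = np.zeros(4 ** width, dtype=np.int64)
        for ids in per_seq:
            support[ids] += 1
        n_win = np.mean([max(len(s) - width + 1, 0) for s in fg])
        if n_win == 0:
            continue
        q = _neighborhood_probs(bg_model.all_word_probs(width), width, max_word_mm)
        q2 = np.clip(q + q[_revcomp_ids(width)], 1e-15, 1 - 1e-15)
        bg_rate = np.clip(1.0 - (1.0 - q2) ** n_win, 1e-15, 1 - 1e-15)
        cand = np.nonzero(support)[0]
        pvals = stats.binom.sf(support[cand] - 1, n_seq, bg_rate[cand])
        keep = pvals <= alpha
        cand, pvals = cand[keep], pvals[keep]
        mult = 4 ** np.arange(width - 1, -1, -1)
        words = ["".join("ACGT"[(i // m) % 4] for m in mult) for i in cand]
        frames.append(pd.DataFrame({
            "word": words, "width": width, "support": support[cand],
            "n_seqs": n_seq, "bg_rate": bg_rate[cand], "pvalue": pvals,
            # multiplicity-corrected significance over the candidate-word
            # space (MEME-E-value-style); raw p stays for calibration
            "evalue": np.minimum(pvals * float(4 ** width), 1e6)}))
    if not frames:
        return pd.DataFrame(columns=["word", "width", "support", "n_seqs",
                                     "bg_rate", "pvalue", "evalue"])
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["pvalue", "support", "word"],
                          ascending=[True, False, True], ignore_index=True)
    if top_n is not None:
        out = out.head(top_n)
    return out


# ---------------------------------------------------------------------------
# TRAP-style affinity and library enrichment
# ---------------------------------------------------------------------------

def default_ln_r0(width: int) -> float:
    """Published width-scaling of the TRAP threshold parameter."""
    return 0.584 * width - 5.66


def trap_affinity(seq: str, pwm: PWM, lam: float = 0.7,
                  ln_r0: float | None = None, pseudocount: float = 0.01,
                  both_strands: bool = True) -> float:
    """Total biophysical binding affinity of a sequence for a PWM.

    Each N-free window contributes ``1 / (1 + exp(E - ln R0))`` with
    mismatch energy ``E = (1/lambda) * sum_i ln(p_max_i / p_i(base))``.
    """
    w = pwm.width
    if len(seq) < w:
        return 0.0
    if ln_r0 is None:
        ln_r0 = default_ln_r0(w)
    p = (pwm.matrix + pseudocount) / (1 + 4 * pseudocount)
    logp = np.log(p)
    penalty = logp.max(axis=1)[:, None] - logp  # (w, 4) >= 0
    codes = encode(seq)
    win = np.lib.stride_tricks.sliding_window_view(codes, w)
    win = win[(win < 4).all(axis=1)]
    if win.size == 0:
        return 0.0
    if both_strands:
        win = np.vstack([win, (3 - win)[:, ::-1]])
    E = penalty[np.arange(w), win].sum(axis=1) / lam
    return float((1.0 / (1.0 + np.exp(E - ln_r0))).sum())


def library_enrichment(fg: list[str], bg: list[str], library: list[PWM],
                       alpha: float = 0.05, lam: float = 0.7,
                       pseudocount: float = 0.01) -> list[MotifHit]:
    """Library PWMs whose foreground affinities beat background by a
    one-sided Wilcoxon rank-sum test at level alpha."""
    if not fg or not bg:
        raise ValueError("foreground and background must be nonempty")
    hits = []
    for pwm in library:
        a_fg = [trap_affinity(s, pwm, lam=lam, pseudocount=pseudocount) for s in fg]
        a_bg = [trap_affinity(s, pwm, lam=lam, pseudocount=pseudocount) for s in bg]
        if np.ptp(a_fg + a_bg) < 1e-15:
            continue  # no signal at all
        p = float(stats.mannwhitneyu(a_fg, a_bg, alternative="greater").pvalue)
        if p <= alpha:
            hits.append(MotifHit(motif=pwm, engine="library", pvalue=p,
                                 extras={"median_fg": float(np.median(a_fg)),
                                         "median_bg": float(np.median(a_bg))}))
    hits.sort(key=lambda h: h.pvalue)
    return hits


__all__ = ["BackgroundModel", "MotifHit", "enrichment_test", "em_discover",
           "word_enumerate", "trap_affinity", "library_enrichment",
           "default_ln_r0"]
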