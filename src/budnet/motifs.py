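"""Promoter oligo-analysis: exhaustive k-mer overrepresentation and assembly.

All overlapping 6–8-nt windows are counted on both strands and collapsed
onto canonical oligos (the lexicographically smaller of a k-mer and its
reverse complement); palindromic words are counted once per window so
nothing is double-counted.  Expected counts come from an order-0
background model — by default the base composition of the input promoter
set itself, symmetrized over strands — and significance is the binomial
upper tail with a Bonferroni-style E-value over the number of possible
canonical oligos at that word length.  (The binomial is the standard
oligo-counting approximation; it is only approximate for self-overlapping
words.)  Significant oligos are then greedily assembled into position
frequency matrices whose mixed-case consensus renders a base uppercase
when its column frequency is ≥ 0.5.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import binom

from .core_io import BASES, MotifMatrix, PromoterRecord

logger = logging.getLogger("budnet")

__all__ = [
    "OligoStat",
    "revcomp",
    "canonical_oligo",
    "is_palindrome",
    "n_canonical_oligos",
    "count_oligos",
    "forward_window_count",
    "base_frequencies",
    "oligo_significance",
    "assemble_patterns",
    "discover_motifs",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: floor probability used when a background base frequency is zero
PSEUDO_PROB = 1e-6


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_oligo(oligo: str) -> str:
    rc = revcomp(oligo)
    return oligo if oligo <= rc else rc


def is_palindrome(oligo: str) -> bool:
    return oligo == revcomp(oligo)


def n_canonical_oligos(k: int) -> int:
    """Number of distinct canonical k-mers (palindromes counted once)."""
    total = 4**k
    palindromes = 4 ** (k // 2) if k % 2 == 0 else 0
    return (total + palindromes) // 2


@dataclass(frozen=True)
class OligoStat:
    """Overrepresentation statistics for one canonical oligo.

    ``log10_pval`` stays meaningful where the linear p-value underflows;
    ``sig`` is −log10 E-value, positive when overrepresented beyond the
    multiple-testing burden.
    """

    oligo: str
    k: int
    observed: int
    expected: float
    pval: float
    evalue: float
    log10_pval: float
    palindrome: bool

    @property
    def log10_evalue(self) -> float:
        return self.log10_pval + math.log10(n_canonical_oligos(self.k))

    @property
    def sig(self) -> float:
        return -self.log10_evalue


def _log_binom_sf(k: int, n: int, p: float) -> float:
    """Natural-log binomial upper tail ln P(X ≥ k), stable at extreme tails."""
    if k <= 0:
        return 0.0
    sf = float(binom.sf(k - 1, n, p))
    if sf > 1e-280:
        return math.log(sf)
    # direct log-space summation of pmf terms past the underflow point
    logp, logq = math.log(p), math.log1p(-p)

    def logpmf(j: int) -> float:
        return float(
            gammaln(n + 1) - gammaln(j + 1) - gammaln(n - j + 1) + j * logp + (n - j) * logq
        )

    total = logpmf(k)
    j = k
    while j < n:
        j += 1
        term = logpmf(j)
        total = float(np.logaddexp(total, term))
        if term < total - 40:
            break
    return total


def _check_k(k: int, allow_any_k: bool) -> None:
    if not allow_any_k and not (6 <= k <= 8):
        raise ValueError(f"k={k} outside the 6-8 oligo range (pass allow_any_k=True to override)")


def count_oligos(
    promoters: Sequence[PromoterRecord], k: int, allow_any_k: bool = False
) -> Counter:
    """Two-strand canonical k-mer counts; windows containing N are skipped.

    Each window position contributes two counts (one per strand) for
    non-palindromic words and one for palindromes.
    """
    _check_k(k, allow_any_k)
    counts: Counter = Counter()
    for rec in promoters:
        seq = rec.sequence
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if "N" in window:
                continue
            rc = revcomp(window)
            if window == rc:
                counts[window] += 1
            else:
                counts[min(window, rc)] += 2
    return counts


def forward_window_count(promoters: Sequence[PromoterRecord], k: int) -> int:
    """Number of valid (N-free) window positions on the forward strand."""
    total = 0
    for rec in promoters:
        seq = rec.sequence
        total += sum(1 for i in range(len(seq) - k + 1) if "N" not in seq[i : i + k])
    return total


def base_frequencies(promoters: Sequence[PromoterRecord]) -> np.ndarray:
    """Order-0 background from the input, symmetrized over strands.

    Symmetrization (A with T, C with G) makes every word equiprobable with
    its reverse complement, which keeps two-strand expectations coherent.
    """
    counts = Counter()
    for rec in promoters:
        counts.update(c for c in rec.sequence if c in BASES)
    total = sum(counts.values())
    if total == 0:
        return np.full(4, 0.25)
    a, c, g, t = (counts[b] for b in BASES)
    at = (a + t) / (2 * total)
    cg = (c + g) / (2 * total)
    return np.array([at, cg, cg, at])


def _word_prob(word: str, freqs: np.ndarray) -> float:
    p = 1.0
    floored = False
    for ch in word:
        f = freqs["ACGT".index(ch)]
        if f <= 0:
            f = PSEUDO_PROB
            floored = True
        p *= f
    if floored:
        logger.warning("oligo background: zero base frequency floored at %g for %s",
                       PSEUDO_PROB, word)
    return p


def oligo_significance(
    counts: Counter,
    k: int,
    n_forward_windows: int,
    background: np.ndarray | None = None,
    promoters: Sequence[PromoterRecord] | None = None,
    allow_any_k: bool = False,
) -> list[OligoStat]:
    """Binomial overrepresentation statistics, sorted by significance.

    ``background`` is the order-0 base frequency vector (A, C, G, T); when
    omitted it is estimated from ``promoters``.  For a non-palindromic
    canonical pair the trial count is the two-strand window total with the
    strand-averaged word probability; palindromes use one-strand windows.
    The E-value multiplies the p-value by the number of possible canonical
    oligos at this k.
    """
    _check_k(k, allow_any_k)
    if background is None:
        if promoters is None:
            raise ValueError("need either background frequencies or the promoter set")
        background = base_frequencies(promoters)
    background = np.asarray(background, dtype=float)
    if not math.isclose(background.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("background frequencies must sum to 1")
    n_tested = n_canonical_oligos(k)
    stats: list[OligoStat] = []
    for oligo, observed in counts.items():
        pal = is_palindrome(oligo)
        if pal:
            n_trials = n_forward_windows
            q = _word_prob(oligo, background)
            events = observed
        else:
            n_trials = 2 * n_forward_windows
            q = 0.5 * (_word_prob(oligo, background) + _word_prob(revcomp(oligo), background))
            # a non-palindromic word and its complement occur as a strand
            # pair at one window position; testing the doubled count would
            # halve the variance, so the binomial runs on window events
            events = (observed + 1) // 2
        expected = n_trials * q
        log_pval = _log_binom_sf(events, n_trials, q)
        pval = math.exp(log_pval)
        log10_pval = log_pval / math.log(10.0)
        evalue = min(pval * n_tested, float(n_tested))
        stats.append(
            OligoStat(oligo=oligo, k=k, observed=observed, expected=expected,
                      pval=pval, evalue=evalue, log10_pval=log10_pval, palindrome=pal)
        )
    stats.sort(key=lambda s: (s.log10_evalue, s.oligo))
    return stats


# ---------------------------------------------------------------------------
# pattern assembly


class _Assembly:
    """A growing alignment of oligos, stored as weighted base counts.

    The alignment never grows wider than the seed oligo plus
    ``max_offset`` flanking positions on each side, so one matrix stays a
    motif-sized object rather than absorbing the whole oligo list.
    """

    def __init__(self, oligo: str, weight: float, max_offset: int):
        self.max_width = len(oligo) + 2 * max_offset
        self.counts = np.zeros((len(oligo), 4))
        self._add(oligo, 0, weight)

    def _add(self, oligo: str, offset: int, weight: float) -> None:
        if offset < 0:
            pad = np.zeros((-offset, 4))
            self.counts = np.vstack([pad, self.counts])
            offset = 0
        end = offset + len(oligo)
        if end > len(self.counts):
            pad = np.zeros((end - len(self.counts), 4))
            self.counts = np.vstack([self.counts, pad])
        for i, ch in enumerate(oligo):
            self.counts[offset + i, "ACGT".index(ch)] += weight

    @property
    def consensus(self) -> str:
        return "".join(BASES[int(np.argmax(row))] for row in self.counts)

    def try_merge(self, oligo: str, weight: float, max_offset: int, max_mismatch: int) -> bool:
        """Merge the oligo if an ungapped alignment fits; returns success.

        Both orientations are tried; among admissible alignments the one
        with the fewest mismatches wins (ties: smallest |shift|, forward
        orientation first).
        """
        cons = self.consensus
        k = len(oligo)
        # rank admissible alignments by (mismatches, |shift|, orientation, shift sign)
        best: tuple[int, int, int, int, int, str] | None = None
        for order, oriented in enumerate((oligo, revcomp(oligo))):
            for shift in range(-max_offset, len(cons) - k + max_offset + 1):
                lo = max(shift, 0)
                hi = min(shift + k, len(cons))
                if hi - lo < k - max_offset:
                    continue
                if max(shift + k, len(cons)) - min(shift, 0) > self.max_width:
                    continue
                mm = sum(1 for pos in range(lo, hi) if cons[pos] != oriented[pos - shift])
                if mm <= max_mismatch:
                    cand = (mm, abs(shift), order, 0 if shift >= 0 else 1, shift, oriented)
                    if best is None or cand[:4] < best[:4]:
                        best = cand
        if best is None:
            return False
        _, _, _, _, shift, oriented = best
        self._add(oriented, shift, weight)
        return True

    def to_matrix(self) -> MotifMatrix:
        support = self.counts.sum(axis=1)
        freq = self.counts / support[:, None]
        return MotifMatrix(freq, support)


def assemble_patterns(
    significant: Sequence[OligoStat],
    max_offset: int = 2,
    max_mismatch: int = 1,
    max_matrices: int = 20,
) -> list[MotifMatrix]:
    """Greedy assembly of significant oligos into frequency matrices.

    Oligos are visited from most to least significant; each one joins the
    first existing assembly it aligns to (within ``max_offset`` shift and
    ``max_mismatch`` mismatches, either orientation, weighted by its
    observed count) or seeds a new assembly while fewer than
    ``max_matrices`` exist.
    """
    assemblies: list[_Assembly] = []
    ordered = sorted(significant, key=lambda s: (s.log10_evalue, s.oligo))
    for stat in ordered:
        merged = False
        for asm in assemblies:
            if asm.try_merge(stat.oligo, float(stat.observed), max_offset, max_mismatch):
                merged = True
                break
        if not merged and len(assemblies) < max_matrices:
            assemblies.append(_Assembly(stat.oligo, float(stat.observed), max_offset))
    return [asm.to_matrix() for asm in assemblies]


def discover_motifs(
    promoters: Sequence[PromoterRecord],
    ks: Sequence[int] = (6, 7, 8),
    evalue_threshold: float = 1.0,
    background: np.ndarray | None = None,
    max_offset: int = 2,
    max_mismatch: int = 1,
    max_matrices: int = 20,
) -> tuple[list[OligoStat], list[MotifMatrix]]:
    """Full oligo-analysis: count, test and assemble across word lengths."""
    all_stats: list[OligoStat] = []
    for k in ks:
        counts = count_oligos(promoters, k)
        n_fwd = forward_window_count(promoters, k)
        if n_fwd == 0:
            continue
        all_stats.extend(
            oligo_significance(counts, k, n_fwd, background=background, promoters=promoters)
        )
    significant = [s for s in all_stats if s.evalue < evalue_threshold]
    logger.info("discover_motifs: %d significant oligo(s) below E=%g",
                len(significant), evalue_threshold)
    matrices = assemble_patterns(significant, max_offset, max_mismatch, max_matrices)
    all_stats.sort(key=lambda s: (s.log10_evalue, s.oligo))
    return all_stats, matrices
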