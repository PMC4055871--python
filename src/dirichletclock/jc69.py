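"""JC69 substitution model for a two-sequence alignment.

For two sequences separated by molecular distance ``d`` (expected
substitutions per site summed over both lineages) the probability that a site
differs is ``p(d) = (3/4) (1 - exp(-4d/3))``.  The alignment enters the
likelihood only through the number of sites compared ``N`` and the number of
differing sites ``x``, so alignments are reduced to counts on ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PairCountData",
    "jc69_mismatch_prob",
    "jc69_distance_mle",
    "pair_log_likelihood",
    "pair_counts_from_seqs",
    "pair_counts_from_fasta",
]

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class PairCountData:
    """Mismatch summary of a two-sequence alignment: N sites, x differing."""

    n_sites: int
    n_diff: int

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not 0 <= self.n_diff <= self.n_sites:
            raise ValueError("n_diff must be in [0, n_sites]")


def jc69_mismatch_prob(d):
    """Probability that a site differs between two sequences at distance d.

    Strictly increasing in d with asymptote 3/4.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    p = 0.75 * (-np.expm1(-4.0 * d / 3.0))
    return p if p.ndim else float(p)


def jc69_distance_mle(data: PairCountData) -> float:
    """Maximum-likelihood distance ``-(3/4) log(1 - 4x/(3N))``.

    Undefined at saturation (x/N >= 3/4).
    """
    frac = data.n_diff / data.n_sites
    if frac >= 0.75:
        raise ValueError(
            f"observed mismatch fraction {frac:.3f} >= 3/4: distance undefined (saturation)"
        )
    return float(-0.75 * np.log1p(-4.0 * frac / 3.0))


def pair_log_likelihood(data: PairCountData, d) -> float:
    """Log-likelihood ``x log(p/3) + (N - x) log(1 - p)`` at distance d.

    This is the probability of one sequence given the other; the ``3^-x``
    factor from the three possible mismatch bases is retained.  Returns -inf
    when d = 0 but mismatches were observed.
    """
    p = jc69_mismatch_prob(d)
    x, N = data.n_diff, data.n_sites
    with np.errstate(divide="ignore"):
        lp = np.where(p > 0, np.log(np.maximum(p, 1e-300) / 3.0), -np.inf)
    term1 = x * lp if x > 0 else 0.0
    term2 = (N - x) * np.log1p(-p)
    out = term1 + term2
    return out if np.ndim(out) else float(out)


def mismatch_loglik(x, n_sites, d):
    """Vectorized mismatch-count log-likelihood (arrays of x and d).

    Distances are clipped away from 0 only through the probability floor, so
    d = 0 with x > 0 yields -inf as it should.
    """
    p = 0.75 * (-np.expm1(-4.0 * np.asarray(d, dtype=float) / 3.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(
            p > 0,
            x * np.log(np.maximum(p, 1e-300) / 3.0),
            np.where(x > 0, -np.inf, 0.0),
        )
    return ll + (n_sites - x) * np.log1p(-p)


def pair_counts_from_seqs(seq1: str, seq2: str) -> PairCountData:
    """Reduce two aligned sequences to (N, x), skipping ambiguous sites.

    Sites where either sequence carries anything other than A/C/G/T
    (alignment gaps, N's, lower-case soft-masking is upper-cased first) are
    excluded from N.
    """
    s1, s2 = seq1.upper(), seq2.upper()
    if len(s1) != len(s2):
        raise ValueError("aligned sequences must have equal length")
    n = x = 0
    for a, b in zip(s1, s2):
        if a in _VALID and b in _VALID:
            n += 1
            if a != b:
                x += 1
    if n == 0:
        raise ValueError("no comparable A/C/G/T sites in the alignment")
    return PairCountData(n, x)


def pair_counts_from_fasta(path) -> PairCountData:
    """Read a FASTA alignment of exactly two equal-length sequences."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"expected exactly 2 sequences in {path}, got {len(records)}")
    return pair_counts_from_seqs(str(records[0].seq), str(records[1].seq))
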