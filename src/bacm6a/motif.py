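"""Hexamer motif enrichment in peak sequences against scrambled backgrounds.

Peak sequences are taken in the sense orientation of their assigned
gene (the IP library is strand-specific and m6A is a transcript mark).
Enrichment of each k-mer is scored empirically: each background set is
a per-sequence letter permutation (mononucleotide composition preserved
exactly), and the observed number of peaks containing the k-mer is
compared with the per-shuffle MAXIMUM count over all k-mers
(Westfall-Young max-statistic null). Because only k-mers that already
recur in the real peaks are examined, a per-k-mer null would be
anti-conservative under that selection; the max-count null is valid for
the top-ranked k-mer and conservative for the rest. The upper-tail
p-value uses the standard +1 correction so it can never be zero, and
Benjamini-Hochberg adjustment is applied across k-mers seen in at least
two peaks.

A degenerate IUPAC consensus is assembled from the top k-mers within
Hamming distance 1 of the best one, weighting each column's base
frequencies by peak counts; bases reaching a 0.25 column frequency
enter the code (e.g. GGTCAG + GGCCAG at equal weight -> GGYCAG).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .gene_context import GeneModel
from .synthetic_data import reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "PeakSequence",
    "KmerEnrichment",
    "ConsensusMotif",
    "extract_sequences",
    "shuffle_background",
    "kmer_enrichment",
    "build_consensus",
    "motif_fraction",
    "iupac_regex",
]

# base sets -> IUPAC code
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}
_IUPAC_BASES = {code: bases for bases, code in _IUPAC.items()}


@dataclass
class PeakSequence:
    """A peak's DNA sequence in the sense orientation of its gene."""

    peak_id: str
    sequence: str


@dataclass
class KmerEnrichment:
    """Enrichment statistics of one k-mer over the shuffle null."""

    kmer: str
    obs_count: int
    bg_mean: float
    p_value: float
    q_value: float
    fraction_of_peaks: float


@dataclass
class ConsensusMotif:
    """Degenerate IUPAC summary of closely related enriched k-mers."""

    iupac: str
    member_kmers: dict[str, int]

    def __post_init__(self) -> None:
        pat = iupac_regex(self.iupac)
        for kmer in self.member_kmers:
            if not pat.fullmatch(kmer):
                raise ValueError(f"member {kmer} does not match consensus {self.iupac}")


def iupac_regex(iupac: str) -> re.Pattern:
    """Compile an IUPAC string to a regex over {A,C,G,T}."""
    parts = []
    for code in iupac:
        bases = _IUPAC_BASES.get(code)
        if bases is None:
            raise ValueError(f"unknown IUPAC code {code!r}")
        parts.append(f"[{''.join(sorted(bases))}]")
    return re.compile("".join(parts))


def extract_sequences(
    peaks: Sequence,
    genome_sequence: str,
    genes: Sequence[GeneModel],
) -> list[PeakSequence]:
    """Genome subsequences of gene-assigned peaks, sense-oriented.

    Peaks on - strand genes are reverse-complemented; unassigned peaks
    are skipped with a warning.
    """
    by_id = {g.gene_id: g for g in genes}
    out = []
    for i, p in enumerate(peaks):
        if p.gene_id is None:
            logger.warning("peak %d unassigned; skipped from sequence extraction", i)
            continue
        if p.start < 0 or p.end > len(genome_sequence):
            raise ValueError("peak interval outside genome bounds")
        seq = genome_sequence[p.start : p.end]
        if by_id[p.gene_id].strand == "-":
            seq = reverse_complement(seq)
        out.append(PeakSequence(peak_id=f"peak{i + 1}", sequence=seq))
    return out


def shuffle_background(
    seqs: Sequence[PeakSequence], n_shuffles: int = 30_000, seed: int = 0
) -> list[list[str]]:
    """Scrambled null sequences: per-sequence letter permutations.

    Returns ``n_shuffles`` background sets, each a list parallel to
    ``seqs`` whose entries conserve the original mononucleotide
    composition exactly. Deterministic per seed.
    """
    if not seqs:
        raise ValueError("no sequences to shuffle")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    arrays = [np.frombuffer(s.sequence.encode("ascii"), dtype="S1") for s in seqs]
    sets = []
    for _ in range(n_shuffles):
        sets.append(
            [rng.permutation(a).tobytes().decode("ascii") for a in arrays]
        )
    return sets


def _peaks_containing(seqs: Sequence[str], kmer: str) -> int:
    return sum(1 for s in seqs if kmer in s)


def _kmer_presence_counts(seqs: Sequence[str], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for s in seqs:
        seen = {s[i : i + k] for i in range(len(s) - k + 1)}
        for kmer in seen:
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def kmer_enrichment(
    seqs: Sequence[PeakSequence],
    backgrounds: Sequence[Sequence[str]],
    k: int = 6,
) -> list[KmerEnrichment]:
    """Rank k-mers by empirical enrichment over the shuffled background.

    ``obs_count`` is the number of peaks containing the k-mer at least
    once; the empirical upper-tail p-value is
    ``(1 + #{shuffles whose max per-k-mer count >= obs}) / (1 + n_shuffles)``
    (max-statistic null, robust to the obs >= 2 selection). BH q-values
    are computed over k-mers observed in >= 2 peaks; ranking is by
    (p, obs_count descending, lexicographic).
    """
    usable = [s.sequence for s in seqs if len(s.sequence) >= k]
    for s in seqs:
        if len(s.sequence) < k:
            logger.warning("sequence %s shorter than k=%d; skipped", s.peak_id, k)
    if not usable:
        raise ValueError("no sequence of length >= k")
    n_peaks = len(usable)
    obs = _kmer_presence_counts(usable, k)
    tested = {km: c for km, c in obs.items() if c >= 2} or obs

    n_sh = len(backgrounds)
    bg_sum = {km: 0 for km in tested}
    max_counts = np.zeros(n_sh, dtype=np.int64)
    for j, bg_set in enumerate(backgrounds):
        bg_counts = _kmer_presence_counts([s for s in bg_set if len(s) >= k], k)
        max_counts[j] = max(bg_counts.values(), default=0)
        for km in tested:
            bg_sum[km] += bg_counts.get(km, 0)

    kmers = sorted(tested)
    pvals = np.array(
        [(1 + int((max_counts >= tested[km]).sum())) / (1 + n_sh) for km in kmers]
    )
    qvals = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else pvals
    qvals = np.maximum(qvals, pvals)  # BH never below the raw p

    rows = [
        KmerEnrichment(
            kmer=km,
            obs_count=tested[km],
            bg_mean=bg_sum[km] / n_sh,
            p_value=float(p),
            q_value=float(q),
            fraction_of_peaks=tested[km] / n_peaks,
        )
        for km, p, q in zip(kmers, pvals, qvals)
    ]
    rows.sort(key=lambda r: (r.p_value, -r.obs_count, r.kmer))
    return rows


def build_consensus(
    top: Sequence[KmerEnrichment], max_members: int = 5
) -> ConsensusMotif:
    """Degenerate IUPAC consensus of the top k-mers.

    Members are the highest-ranked k-mers within Hamming distance <= 1
    of the best k-mer (no shifts), at most ``max_members``. Column base
    frequencies are weighted by ``obs_count``; every base with column
    frequency >= 0.25 enters that column's IUPAC code.
    """
    if not top:
        raise ValueError("no enriched k-mers to summarize")
    best = top[0].kmer
    members: dict[str, int] = {}
    for row in top:
        if len(row.kmer) == len(best) and _hamming(row.kmer, best) <= 1:
            members[row.kmer] = row.obs_count
            if len(members) >= max_members:
                break
    total = sum(members.values())
    cols = []
    for i in range(len(best)):
        freq: dict[str, float] = {}
        for kmer, w in members.items():
            freq[kmer[i]] = freq.get(kmer[i], 0.0) + w / total
        included = frozenset(b for b, f in freq.items() if f >= 0.25)
        if not included:  # all bases rare: keep the plurality base
            included = frozenset(max(freq, key=freq.get))
        cols.append(_IUPAC[included])
    iupac = "".join(cols)
    # a low-weight Hamming-1 member whose base missed the 0.25 column cut
    # does not match the code; drop it rather than dilute the consensus
    pat = iupac_regex(iupac)
    members = {km: w for km, w in members.items() if pat.fullmatch(km)}
    return ConsensusMotif(iupac=iupac, member_kmers=members)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def motif_fraction(
    seqs: Sequence[PeakSequence], consensus: ConsensusMotif
) -> float:
    """Fraction of peaks whose sense sequence matches the consensus at
    least once."""
    pat = iupac_regex(consensus.iupac)
    if not seqs:
        return 0.0
    hits = sum(1 for s in seqs if pat.search(s.sequence))
    return hits / len(seqs)
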