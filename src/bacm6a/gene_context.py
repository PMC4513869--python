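"""Gene assignment, positional classification and metagene profiles.

Bacterial transcripts lack annotated UTRs, so instead of the eukaryotic
5'UTR/CDS/3'UTR metagene, peaks are classified into three mutually
exclusive positional categories relative to their gene: ``OverlapStart``
(within +/-100 nt of the start codon), ``OverlapEnd`` (within +/-100 nt
of the stop codon) and ``Inside`` (elsewhere in the coding region).
Classification uses the peak summit, the sharpest available point
estimate, so the trichotomy is exhaustive and non-overlapping.

Metagene profiles average read density across genes after mapping each
gene onto a common coordinate system: a fixed-width 5' flank, a
length-scaled gene body, and a fixed-width 3' flank, all oriented
5'->3'.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "ContextLabel",
    "MetageneProfile",
    "assign_gene",
    "classify_context",
    "context_fractions",
    "metagene_profile",
]


@dataclass
class GeneModel:
    """An intronless gene on a single linear chromosome.

    Coordinates are 0-based, half-open; ``strand`` is '+' or '-'.
    """

    gene_id: str
    start: int
    end: int
    strand: str
    name: str = ""
    categories: set[str] = field(default_factory=set)
    is_small_rna: bool = False

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def start_codon_pos(self) -> int:
        """Genomic position of the first base of the start codon."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def stop_codon_pos(self) -> int:
        """Genomic position of the last base of the stop codon."""
        return self.end - 1 if self.strand == "+" else self.start


class ContextLabel(enum.Enum):
    """Positional category of a peak within its gene."""

    OVERLAP_START = "OverlapStart"
    INSIDE = "Inside"
    OVERLAP_END = "OverlapEnd"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class MetageneProfile:
    """Mean read density over genes in flank/body/flank coordinates.

    Bin values are (reads per nt) / (total fragments in the track),
    averaged unweighted across genes.
    """

    start_flank: np.ndarray
    body: np.ndarray
    end_flank: np.ndarray
    n_bins: int
    n_genes: int

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.start_flank, self.body, self.end_flank])


def assign_gene(peak, genes: Sequence[GeneModel], flank: int = 100) -> str | None:
    """Assign a peak to the gene whose flank-extended interval contains its summit.

    If the summit falls in the extended intervals of two adjacent genes, the
    gene whose unextended body is nearer wins; an exact tie goes to the
    upstream (genomically earlier) gene. Returns ``None`` for intergenic
    summits beyond every extension.
    """
    summit = peak.summit
    hits = [
        g for g in genes if g.start - flank <= summit <= g.end + flank
    ]
    if not hits:
        return None
    if len(hits) == 1:
        return hits[0].gene_id

    def body_distance(g: GeneModel) -> int:
        return max(0, g.start - summit, summit - g.end)

    # stable min: ties resolved by genomic order (genes are sorted)
    hits.sort(key=lambda g: g.start)
    best = min(hits, key=body_distance)
    return best.gene_id


def classify_context(peak, gene: GeneModel, flank: int = 100) -> ContextLabel:
    """Classify a gene-assigned peak as OverlapStart / Inside / OverlapEnd.

    The windows are ``[s - flank, s + flank]`` around the start-codon
    position ``s`` and likewise around the stop-codon position, both in
    genomic coordinates honoring strand. For genes short enough that the
    two windows overlap, the nearer codon wins and an exact tie is
    OverlapStart.
    """
    if gene is None:
        raise ValueError("peak must be assigned to a gene before classification")
    summit = peak.summit
    s = gene.start_codon_pos
    t = gene.stop_codon_pos
    in_start = abs(summit - s) <= flank
    in_end = abs(summit - t) <= flank
    if in_start and in_end:
        return (
            ContextLabel.OVERLAP_START
            if abs(summit - s) <= abs(summit - t)
            else ContextLabel.OVERLAP_END
        )
    if in_start:
        return ContextLabel.OVERLAP_START
    if in_end:
        return ContextLabel.OVERLAP_END
    return ContextLabel.INSIDE


def context_fractions(
    labels: Iterable[ContextLabel],
) -> tuple[Fraction, Fraction, Fraction]:
    """Exact (start, inside, end) fractions of a label list.

    Computed in rational arithmetic so the three fractions sum to 1
    exactly; format on output as needed.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("context_fractions requires at least one label")
    n = len(labels)
    counts = {lab: 0 for lab in ContextLabel}
    for lab in labels:
        counts[lab] += 1
    return (
        Fraction(counts[ContextLabel.OVERLAP_START], n),
        Fraction(counts[ContextLabel.INSIDE], n),
        Fraction(counts[ContextLabel.OVERLAP_END], n),
    )


def _bin_means(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean of `values` over n_bins near-equal contiguous bins."""
    edges = np.linspace(0, len(values), n_bins + 1).round().astype(int)
    return np.array(
        [values[edges[i] : edges[i + 1]].mean() for i in range(n_bins)]
    )


def metagene_profile(
    coverage,
    genes: Sequence[GeneModel],
    n_bins: int = 20,
    flank: int = 100,
) -> MetageneProfile:
    """Average per-gene read density in flank / scaled-body / flank bins.

    Flanking windows use fixed-width bins (``flank / n_bins`` nt each);
    the gene body is divided into ``n_bins`` length-scaled bins. Each
    gene's densities are depth per nt divided by the track's total
    fragment count, oriented 5'->3', and genes contribute equally to the
    mean. Genes shorter than ``n_bins`` are skipped with a warning.
    """
    depth = np.asarray(coverage.depth, dtype=float)
    total = max(coverage.total_fragments, 1)
    L = len(depth)
    sf, bf, ef, used = [], [], [], 0
    for g in genes:
        if len(g) < n_bins:
            logger.warning("gene %s shorter than %d bins; skipped", g.gene_id, n_bins)
            continue
        lo, hi = g.start - flank, g.end + flank
        window = np.zeros(hi - lo)
        src_lo, src_hi = max(lo, 0), min(hi, L)
        window[src_lo - lo : src_hi - lo] = depth[src_lo:src_hi]
        if g.strand == "-":
            window = window[::-1]
        per_nt = window / total
        sf.append(_bin_means(per_nt[:flank], n_bins))
        bf.append(_bin_means(per_nt[flank : flank + len(g)], n_bins))
        ef.append(_bin_means(per_nt[flank + len(g) :], n_bins))
        used += 1
    if used == 0:
        raise ValueError("no gene long enough for the requested binning")
    return MetageneProfile(
        start_flank=np.mean(sf, axis=0),
        body=np.mean(bf, axis=0),
        end_flank=np.mean(ef, axis=0),
        n_bins=n_bins,
        n_genes=used,
    )
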