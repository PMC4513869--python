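"""Synthetic genomes, planted m6A sites, IP/input reads and nucleoside tables.

Every downstream stage of the pipeline is exercised offline against
data with a known ground truth: an intronless single-chromosome genome
with non-overlapping genes on alternating strands, methylation sites
planted as hexamer motifs preferentially inside ORFs, IP read sets
enriched over planted sites by rejection sampling at short
(photo-crosslinking-scale, ~23-30 nt) fragment lengths, and LC-MS/MS
nucleoside tables in which an rRNA residue contributes both m6A and a
matched m62A tracer.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .gene_context import ContextLabel, GeneModel
from .ms_quant import NucleosideMeasurement

__all__ = [
    "SyntheticGenome",
    "MethylationSite",
    "ReadSet",
    "CapacityError",
    "generate_genome",
    "plant_sites",
    "simulate_reads",
    "simulate_nucleoside_table",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: default functional categories cycled over synthetic genes
DEFAULT_CATEGORIES = (
    "aerobic respiration",
    "amino acid biosynthesis",
    "stress response",
    "cell wall biosynthesis",
    "anaerobic respiration",
    "transport",
    "gene regulation",
    "metabolism",
)

_MIN_GENE_LEN = 300


class CapacityError(ValueError):
    """Raised when the genome cannot hold the requested number of sites."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SyntheticGenome:
    """A single linear chromosome with non-overlapping annotated genes."""

    sequence: str
    genes: list[GeneModel]
    seed: int

    def __len__(self) -> int:
        return len(self.sequence)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class MethylationSite:
    """A planted methylated adenosine inside a gene.

    ``position`` is the 0-based genomic coordinate of the base that
    reads as A on the transcript (sense) strand; ``motif`` is the
    planted hexamer in sense orientation and ``window_start`` the
    genomic start of the 6-nt window holding it (the window carries the
    reverse complement of the motif on - strand genes).
    """

    position: int
    gene_id: str
    context_label: ContextLabel
    motif: str
    window_start: int
    strand: str


@dataclass
class ReadSet:
    """Aligned single-end fragments for one sample (IP or input)."""

    starts: np.ndarray
    lengths: np.ndarray
    strands: np.ndarray
    sample_tag: str
    genome_length: int

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.strands = np.asarray(self.strands, dtype="U1")
        if len(self.starts) and (
            self.starts.min() < 0
            or (self.starts + self.lengths).max() > self.genome_length
        ):
            raise ValueError("fragment outside genome bounds")
        if len(self.lengths) and self.lengths.min() < 20:
            raise ValueError("fragment shorter than 20 nt")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def total_bases(self) -> int:
        return int(self.lengths.sum())

    @property
    def records(self) -> list[tuple[int, int, str, str]]:
        return [
            (int(s), int(l), str(st), self.sample_tag)
            for s, l, st in zip(self.starts, self.lengths, self.strands)
        ]


def generate_genome(
    n_genes: int,
    gene_len_range: tuple[int, int] = (900, 1500),
    intergenic_range: tuple[int, int] = (100, 300),
    gc_fraction: float = 0.5,
    seed: int = 0,
) -> SyntheticGenome:
    """Generate a random genome with non-overlapping genes.

    Genes alternate strand (+, -, +, ...), lengths and intergenic gaps
    are drawn uniformly from the given inclusive ranges, and terminal
    flanks are drawn from the intergenic range. Each gene is assigned
    one functional category cycled deterministically from
    :data:`DEFAULT_CATEGORIES`.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    glo, ghi = gene_len_range
    ilo, ihi = intergenic_range
    if glo < _MIN_GENE_LEN or ghi < glo:
        raise ValueError(f"gene lengths must satisfy {_MIN_GENE_LEN} <= lo <= hi")
    if ilo < 0 or ihi < ilo:
        raise ValueError("intergenic range must satisfy 0 <= lo <= hi")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")

    rng = np.random.default_rng(seed)
    lengths = rng.integers(glo, ghi + 1, size=n_genes)
    gaps = rng.integers(ilo, ihi + 1, size=n_genes - 1) if n_genes > 1 else []
    flanks = rng.integers(ilo, ihi + 1, size=2)

    genes: list[GeneModel] = []
    pos = int(flanks[0])
    for i, length in enumerate(lengths):
        genes.append(
            GeneModel(
                gene_id=f"gene{i + 1:04d}",
                start=pos,
                end=pos + int(length),
                strand="+" if i % 2 == 0 else "-",
                name=f"syn{i + 1}",
                categories={DEFAULT_CATEGORIES[i % len(DEFAULT_CATEGORIES)]},
            )
        )
        pos += int(length)
        if i < n_genes - 1:
            pos += int(gaps[i])
    total_len = pos + int(flanks[1])

    p = np.array(
        [
            (1 - gc_fraction) / 2,
            gc_fraction / 2,
            gc_fraction / 2,
            (1 - gc_fraction) / 2,
        ]
    )
    bases = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=total_len, p=p)
    sequence = bases.tobytes().decode("ascii")
    return SyntheticGenome(sequence=sequence, genes=genes, seed=seed)


# sense-coordinate window-start ranges for each positional context; the
# planted A must respect the +/-100 nt codon windows used downstream
def _eligible_range(context: ContextLabel, gene_len: int) -> tuple[int, int]:
    if context is ContextLabel.OVERLAP_START:
        return 0, min(94, gene_len - 6)
    if context is ContextLabel.OVERLAP_END:
        return max(0, gene_len - 100), gene_len - 6
    return 101, gene_len - 107  # Inside: > 100 nt from both codons


def plant_sites(
    genome: SyntheticGenome,
    n_sites: int,
    context_mix: tuple[float, float, float] = (0.15, 0.72, 0.13),
    motif: str = "TGCCAG",
    seed: int = 0,
    min_spacing: int = 200,
) -> list[MethylationSite]:
    """Overwrite hexamer windows in gene bodies with a methylation motif.

    Context labels (start / inside / end) are drawn multinomially from
    ``context_mix``; sites within one gene are kept >= ``min_spacing``
    nt apart so that planted peaks are individually resolvable. The
    genome's sequence is modified in place (reverse complement planted
    on - strand genes so the transcript reads the motif).
    """
    if len(motif) != 6:
        raise ValueError("motif must be a hexamer")
    if "A" not in motif:
        raise ValueError("motif must contain at least one A to methylate")
    if abs(sum(context_mix) - 1.0) > 1e-9:
        raise ValueError("context_mix must sum to 1")

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_sites, context_mix)
    labels = (
        [ContextLabel.OVERLAP_START] * counts[0]
        + [ContextLabel.INSIDE] * counts[1]
        + [ContextLabel.OVERLAP_END] * counts[2]
    )
    rng.shuffle(labels)  # type: ignore[arg-type]

    a_index = motif.index("A")
    seq = bytearray(genome.sequence, "ascii")
    planted: dict[str, list[int]] = {g.gene_id: [] for g in genome.genes}
    sites: list[MethylationSite] = []

    for label in labels:
        placed = False
        gene_order = rng.permutation(len(genome.genes))
        for gi in gene_order:
            g = genome.genes[gi]
            lo, hi = _eligible_range(label, len(g))
            if hi < lo:
                continue
            for _ in range(60):
                o = int(rng.integers(lo, hi + 1))
                if g.strand == "+":
                    wstart = g.start + o
                    pos = wstart + a_index
                else:
                    wstart = g.end - o - 6
                    pos = g.end - o - 1 - a_index
                if all(abs(pos - q) >= min_spacing for q in planted[g.gene_id]):
                    ins = motif if g.strand == "+" else reverse_complement(motif)
                    seq[wstart : wstart + 6] = ins.encode("ascii")
                    planted[g.gene_id].append(pos)
                    sites.append(
                        MethylationSite(
                            position=pos,
                            gene_id=g.gene_id,
                            context_label=label,
                            motif=motif,
                            window_start=wstart,
                            strand=g.strand,
                        )
                    )
                    placed = True
                    break
            if placed:
                break
        if not placed:
            raise CapacityError(
                f"could not place {n_sites} sites with spacing {min_spacing}"
            )

    genome.sequence = seq.decode("ascii")
    sites.sort(key=lambda s: s.position)
    return sites


def _draw_fragments(
    rng: np.random.Generator,
    genes: Sequence[GeneModel],
    n: int,
    frag_len_mean: float,
    frag_len_sd: float,
    genome_length: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw fragment (start, length, gene_index) with starts uniform over
    gene bodies and lengths normal truncated at 20 nt."""
    gene_lens = np.array([len(g) for g in genes], dtype=float)
    gidx = rng.choice(len(genes), size=n, p=gene_lens / gene_lens.sum())
    lengths = np.maximum(
        20, np.rint(rng.normal(frag_len_mean, frag_len_sd, size=n))
    ).astype(np.int64)
    starts = np.empty(n, dtype=np.int64)
    g_start = np.array([g.start for g in genes])
    g_end = np.array([g.end for g in genes])
    span = np.maximum(g_end[gidx] - g_start[gidx] - lengths, 1)
    starts = g_start[gidx] + (rng.random(n) * span).astype(np.int64)
    # clip against the genome end for fragments running off short flanks
    lengths = np.minimum(lengths, genome_length - starts)
    lengths = np.maximum(lengths, 20)
    starts = np.minimum(starts, genome_length - lengths)
    return starts, lengths, gidx


def simulate_reads(
    genome: SyntheticGenome,
    sites: Sequence[MethylationSite],
    n_input_reads: int,
    enrichment_factor: float = 10.0,
    frag_len_mean: float = 30.0,
    frag_len_sd: float = 5.0,
    seed: int = 0,
) -> tuple[ReadSet, ReadSet]:
    """Simulate one IP and one input read set over gene bodies.

    Input fragments are uniform over gene bodies and unstranded. IP
    fragments come from the same proposal, but a fragment covering a
    planted site is accepted with probability 1 while background
    fragments are accepted with probability 1/enrichment_factor
    (rejection sampling), and IP strand follows the owning gene. Both
    sets contain ``n_input_reads`` fragments.
    """
    if enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")
    rng = np.random.default_rng(seed)
    L = len(genome)
    empty = lambda tag: ReadSet(  # noqa: E731
        starts=np.empty(0, dtype=np.int64),
        lengths=np.empty(0, dtype=np.int64),
        strands=np.empty(0, dtype="U1"),
        sample_tag=tag,
        genome_length=L,
    )
    if n_input_reads == 0:
        return empty("IP"), empty("input")

    in_starts, in_lengths, _ = _draw_fragments(
        rng, genome.genes, n_input_reads, frag_len_mean, frag_len_sd, L
    )
    input_set = ReadSet(
        starts=in_starts,
        lengths=in_lengths,
        strands=np.full(n_input_reads, ".", dtype="U1"),
        sample_tag="input",
        genome_length=L,
    )

    site_pos = np.sort(np.array([s.position for s in sites], dtype=np.int64))
    gene_strands = np.array([g.strand for g in genome.genes], dtype="U1")
    acc_s: list[np.ndarray] = []
    acc_l: list[np.ndarray] = []
    acc_g: list[np.ndarray] = []
    n_have = 0
    while n_have < n_input_reads:
        m = max(2 * (n_input_reads - n_have), 1000)
        s, l, g = _draw_fragments(
            rng, genome.genes, m, frag_len_mean, frag_len_sd, L
        )
        if len(site_pos):
            hit = np.searchsorted(site_pos, s) < np.searchsorted(
                site_pos, s + l
            )
        else:
            hit = np.zeros(m, dtype=bool)
        keep = hit | (rng.random(m) < 1.0 / enrichment_factor)
        s, l, g = s[keep], l[keep], g[keep]
        acc_s.append(s)
        acc_l.append(l)
        acc_g.append(g)
        n_have += len(s)
    starts = np.concatenate(acc_s)[:n_input_reads]
    lengths = np.concatenate(acc_l)[:n_input_reads]
    gidx = np.concatenate(acc_g)[:n_input_reads]
    ip_set = ReadSet(
        starts=starts,
        lengths=lengths,
        strands=gene_strands[gidx],
        sample_tag="IP",
        genome_length=L,
    )
    return ip_set, input_set


def simulate_nucleoside_table(
    true_m6a_ratio: float,
    rrna_contam_frac: float = 0.05,
    rrna_m6a_per_A: float = 0.01,
    R: float = 1.30,
    cv: float = 0.0,
    n_reps: int = 3,
    seed: int = 0,
    sample_id: str = "synthetic",
    condition: str = "",
    total_A: float = 1000.0,
) -> list[NucleosideMeasurement]:
    """Per-replicate nucleoside quantities with an rRNA residue.

    The sample's adenosine pool of size ``total_A`` (arbitrary units) is
    split into an mRNA fraction and an rRNA residue of fraction
    ``rrna_contam_frac``. The mRNA methylation contributes
    ``true_m6a_ratio * total_A`` of m6A — the ratio is defined on the
    same denominator the assay reports — while the rRNA residue
    contributes ``rrna_m6a_per_A`` m6A per rRNA adenosine plus a matched
    m62A tracer of ``R`` times its m6A. Each quantity carries
    independent multiplicative noise with coefficient of variation
    ``cv``.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    if not 0 <= rrna_contam_frac < 1:
        raise ValueError("rrna_contam_frac must be in [0, 1)")
    if not 0 <= cv < 1:
        raise ValueError("cv must be in [0, 1)")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")

    rng = np.random.default_rng(seed)
    a_rrna = rrna_contam_frac * total_A
    m6a_rrna = rrna_m6a_per_A * a_rrna
    m6a = true_m6a_ratio * total_A + m6a_rrna
    m62a = R * m6a_rrna

    out = []
    for rep in range(1, n_reps + 1):
        f = 1.0 + cv * rng.standard_normal(3) if cv > 0 else np.ones(3)
        f = np.maximum(f, 1e-6)
        out.append(
            NucleosideMeasurement(
                sample_id=sample_id,
                replicate=rep,
                quantity_A=total_A * f[0],
                quantity_m6A=m6a * f[1],
                quantity_m62A=m62a * f[2],
                condition=condition,
            )
        )
    return out
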