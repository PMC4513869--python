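"""Readers and writers for the pipeline's on-disk formats.

Internal coordinates are 0-based half-open throughout the package;
conversion to 1-based inclusive happens only at the GFF3 boundary (BED
is natively 0-based half-open). Gene annotations are written as GFF3
``gene`` features with ``ID`` and ``category`` attributes; aligned
fragments travel as BED6 (name = sample tag, score = 0) or a minimal
SAM subset; nucleoside quantities and results are plain TSV.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import gffutils
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .gene_context import GeneModel, MetageneProfile
from .ms_quant import NucleosideMeasurement
from .peaks import Peak
from .synthetic_data import MethylationSite, ReadSet, SyntheticGenome

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_gff3",
    "read_gff3",
    "write_bed",
    "read_bed",
    "read_sam",
    "write_sites_tsv",
    "write_peaks",
    "read_nucleoside_tsv",
    "write_nucleoside_tsv",
    "write_metagene_tsv",
    "read_category_map_tsv",
]


def write_fasta(genome: SyntheticGenome, path: str | Path, seqid: str = "chr") -> None:
    rec = SeqRecord(Seq(genome.sequence), id=seqid, description="synthetic chromosome")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path: str | Path) -> str:
    """Sequence of the first (single-chromosome) FASTA record."""
    rec = next(SeqIO.parse(str(path), "fasta"))
    return str(rec.seq).upper()


def write_gff3(genes: Sequence[GeneModel], path: str | Path, seqid: str = "chr") -> None:
    """Write genes as GFF3 ``gene`` features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = [f"ID={g.gene_id}"]
            if g.name:
                attrs.append(f"Name={g.name}")
            if g.categories:
                attrs.append("category=" + ",".join(sorted(g.categories)))
            if g.is_small_rna:
                attrs.append("small_rna=true")
            fh.write(
                "\t".join(
                    [
                        seqid,
                        "bacm6a",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load ``gene`` features from a GFF3 file, sorted by start."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        cats = set()
        for v in feat.attributes.get("category", []):
            cats.update(c for c in v.split(",") if c)
        genes.append(
            GeneModel(
                gene_id=feat.id,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                name=(feat.attributes.get("Name") or [""])[0],
                categories=cats,
                is_small_rna=(feat.attributes.get("small_rna") or ["false"])[0]
                == "true",
            )
        )
    genes.sort(key=lambda g: g.start)
    return genes


def write_bed(reads: ReadSet, path: str | Path, seqid: str = "chr") -> None:
    """Write fragments as BED6 (name = sample tag, score = 0)."""
    with open(path, "w") as fh:
        for start, length, strand in zip(reads.starts, reads.lengths, reads.strands):
            fh.write(
                f"{seqid}\t{start}\t{start + length}\t{reads.sample_tag}\t0\t{strand}\n"
            )


def read_bed(path: str | Path, genome_length: int, sample_tag: str | None = None) -> ReadSet:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    tag = sample_tag or (str(df["name"].iloc[0]) if len(df) else "reads")
    return ReadSet(
        starts=df["start"].to_numpy(np.int64),
        lengths=(df["end"] - df["start"]).to_numpy(np.int64),
        strands=df["strand"].fillna(".").to_numpy(dtype="U1"),
        sample_tag=tag,
        genome_length=genome_length,
    )


def read_sam(path: str | Path, genome_length: int, sample_tag: str = "reads") -> ReadSet:
    """Load mapped records from a minimal SAM file (columns 1-6 honored)."""
    starts, lengths, strands = [], [], []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            starts.append(rec.reference_start)
            lengths.append(rec.query_length or rec.infer_read_length() or 0)
            strands.append("-" if rec.is_reverse else "+")
    return ReadSet(
        starts=np.array(starts, dtype=np.int64),
        lengths=np.array(lengths, dtype=np.int64),
        strands=np.array(strands, dtype="U1"),
        sample_tag=sample_tag,
        genome_length=genome_length,
    )


def write_sites_tsv(sites: Sequence[MethylationSite], path: str | Path) -> None:
    pd.DataFrame(
        {
            "position": [s.position for s in sites],
            "gene_id": [s.gene_id for s in sites],
            "context": [s.context_label.value for s in sites],
            "motif": [s.motif for s in sites],
        }
    ).to_csv(path, sep="\t", index=False)


def write_peaks(peaks: Sequence[Peak], path: str | Path, seqid: str = "chr") -> None:
    """Write peaks as BED6+3 (summit, fold_enrichment, p_value extras).

    Score is -log10(p) capped at 1000.
    """
    with open(path, "w") as fh:
        for i, p in enumerate(peaks, 1):
            score = min(1000, int(round(-math.log10(max(p.p_value, 1e-300)))))
            ctx = p.context.value if p.context is not None else "."
            fh.write(
                "\t".join(
                    [
                        seqid, str(p.start), str(p.end), f"peak{i}", str(score), ".",
                        str(p.summit), f"{p.fold_enrichment:.3f}", f"{p.p_value:.3e}",
                        p.gene_id or ".", ctx,
                    ]
                )
                + "\n"
            )


def read_nucleoside_tsv(path: str | Path) -> list[NucleosideMeasurement]:
    """One row per (sample, replicate): sample_id, replicate, condition, A, m6A, m62A."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "replicate", "A", "m6A", "m62A"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"nucleoside table missing columns: {sorted(missing)}")
    return [
        NucleosideMeasurement(
            sample_id=str(row.sample_id),
            replicate=int(row.replicate),
            quantity_A=float(row.A),
            quantity_m6A=float(row.m6A),
            quantity_m62A=float(row.m62A),
            condition=str(getattr(row, "condition", "")),
        )
        for row in df.itertuples()
    ]


def write_nucleoside_tsv(
    measurements: Sequence[NucleosideMeasurement], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in measurements],
            "replicate": [m.replicate for m in measurements],
            "condition": [m.condition for m in measurements],
            "A": [m.quantity_A for m in measurements],
            "m6A": [m.quantity_m6A for m in measurements],
            "m62A": [m.quantity_m62A for m in measurements],
        }
    ).to_csv(path, sep="\t", index=False)


def write_metagene_tsv(
    ip_profile: MetageneProfile, input_profile: MetageneProfile, path: str | Path
) -> None:
    rows = []
    for segment, ipv, inv in [
        ("start_flank", ip_profile.start_flank, input_profile.start_flank),
        ("body", ip_profile.body, input_profile.body),
        ("end_flank", ip_profile.end_flank, input_profile.end_flank),
    ]:
        for i, (a, b) in enumerate(zip(ipv, inv)):
            rows.append(
                {"segment": segment, "bin": i, "ip_density": a, "input_density": b}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_category_map_tsv(path: str | Path):
    """TSV (gene_id, category) -> CategoryMap."""
    from .enrichment import CategoryMap

    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "category"} <= set(df.columns):
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "category"])
    assignments: dict[str, set[str]] = {}
    for row in df.itertuples():
        assignments.setdefault(str(row.gene_id), set()).add(str(row.category))
    return CategoryMap(assignments=assignments)
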