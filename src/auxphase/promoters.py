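"""Promoter-window extraction anchored on annotated transcription start sites.

The promoter interval used throughout the package runs from a fixed distance
upstream of the TSS to either the translation start site or a downstream cap
(1 kb by default), whichever is closer to the TSS.  Windows are represented in
0-based half-open genomic coordinates and their sequences are stored in
transcript orientation (reverse-complemented for minus-strand genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Union

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """One gene reduced to the coordinates the promoter rule needs.

    ``tss`` is the 0-based genomic position of the first transcribed base;
    ``translation_start`` the 0-based genomic position of the first coding
    base (5'-most CDS base in transcript orientation), or None when the
    annotation provides no CDS.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    translation_start: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be non-negative")
        if self.translation_start is not None:
            if self.strand == "+" and self.translation_start < self.tss:
                raise ValueError(
                    f"{self.gene_id}: translation start upstream of TSS on + strand"
                )
            if self.strand == "-" and self.translation_start > self.tss:
                raise ValueError(
                    f"{self.gene_id}: translation start upstream of TSS on - strand"
                )


@dataclass(frozen=True)
class PromoterWindow:
    """A TSS-anchored genomic interval with its transcript-oriented sequence."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: invalid interval [{self.start},{self.end})")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(f"{self.gene_id}: sequence length != interval length")


def parse_gene_models(source: Union[str, Path, IO[str], Iterable[str]]) -> list[GeneModel]:
    """Parse a GFF3 annotation into one :class:`GeneModel` per gene.

    GFF3 is 1-based inclusive; coordinates are converted to the internal
    0-based convention here.  For multi-transcript genes the transcript with
    the lexicographically smallest ID is used.  Genes whose CDS lies upstream
    of the TSS in transcript orientation are skipped with a warning.

    Parameters
    ----------
    source
        Path to a GFF3 file, an open text handle, or an iterable of lines.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return parse_gene_models(fh)

    # transcript_id -> (gene_id, chrom, strand, start, end)
    transcripts: dict[str, tuple[str, str, str, int, int]] = {}
    # transcript_id -> list of (cds_start, cds_end) in 1-based inclusive coords
    cds_by_tx: dict[str, list[tuple[int, int]]] = {}
    standalone_genes: dict[str, tuple[str, str, int, int]] = {}

    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"malformed GFF3 line {lineno}: expected 9 columns, got {len(fields)}")
        chrom, _, ftype, start_s, end_s, _, strand, _, attrs_s = fields
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ValueError(f"malformed GFF3 line {lineno}: non-integer coordinates") from exc
        if start > end:
            raise ValueError(f"malformed GFF3 line {lineno}: start > end")
        attrs = _parse_attributes(attrs_s)
        if ftype == "gene":
            gid = attrs.get("ID")
            if gid:
                standalone_genes[gid] = (chrom, strand, start, end)
        elif ftype in {"mRNA", "transcript"}:
            tid = attrs.get("ID")
            parent = attrs.get("Parent", tid)
            if tid is None:
                raise ValueError(f"malformed GFF3 line {lineno}: {ftype} without ID")
            transcripts[tid] = (parent, chrom, strand, start, end)
        elif ftype == "CDS":
            parent = attrs.get("Parent")
            if parent is None:
                raise ValueError(f"malformed GFF3 line {lineno}: CDS without Parent")
            for pid in parent.split(","):
                cds_by_tx.setdefault(pid, []).append((start, end))

    # Primary transcript per gene: lexicographically smallest transcript ID.
    primary: dict[str, str] = {}
    for tid, (gid, *_rest) in transcripts.items():
        if gid not in primary or tid < primary[gid]:
            primary[gid] = tid

    models: list[GeneModel] = []
    for gid, tid in sorted(primary.items()):
        _, chrom, strand, start, end = transcripts[tid]
        tss = start - 1 if strand == "+" else end - 1
        tstart: int | None = None
        if tid in cds_by_tx:
            spans = cds_by_tx[tid]
            if strand == "+":
                tstart = min(s for s, _ in spans) - 1
            else:
                tstart = max(e for _, e in spans) - 1
        else:
            log.warning("%s: no CDS child; no 5' boundary, downstream cap will apply", gid)
        try:
            models.append(
                GeneModel(gene_id=gid, chrom=chrom, strand=strand, tss=tss, translation_start=tstart)
            )
        except ValueError as exc:
            log.warning("skipping gene with invalid model: %s", exc)

    # Genes annotated without any transcript child are not analyzable.
    for gid in standalone_genes:
        if gid not in primary:
            log.warning("%s: gene feature without mRNA/transcript child; skipped", gid)
    return models


def _parse_attributes(attrs: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attrs.split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        key, value = part.split("=", 1)
        out[key] = value
    return out


def _chrom_seq(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end] from a dict of strings or a pyfaidx.Fasta."""
    record = genome[chrom]
    piece = record[start:end]
    seq = getattr(piece, "seq", piece)
    return str(seq)


def _chrom_len(genome, chrom: str) -> int:
    return len(genome[chrom])


def extract_promoter_windows(
    genome,
    models: Iterable[GeneModel],
    upstream: int = 600,
    downstream_cap: int = 1000,
) -> list[PromoterWindow]:
    """Extract per-gene promoter windows from a genome.

    For each gene, let ``d`` be the transcript-orientation distance from the
    TSS to the translation start, capped at ``downstream_cap`` (genes without
    a translation start use the cap).  The window covers transcript
    coordinates ``[-upstream, d)``, mapped to genomic coordinates and clipped
    to the chromosome; minus-strand sequences are reverse-complemented so
    every emitted sequence reads 5'->3' on the transcript.

    Parameters
    ----------
    genome
        Mapping of chromosome name to sequence: a plain ``dict[str, str]`` or
        an indexed ``pyfaidx.Fasta``.
    models
        Gene models, e.g. from :func:`parse_gene_models`.
    """
    if upstream <= 0 or downstream_cap <= 0:
        raise ValueError("upstream and downstream_cap must be positive")
    models = list(models)
    missing = sorted({m.gene_id for m in models if not _has_chrom(genome, m.chrom)})
    if missing:
        raise KeyError(f"chromosome missing from genome for genes: {', '.join(missing)}")

    windows: list[PromoterWindow] = []
    for m in models:
        if m.translation_start is None:
            d = downstream_cap
        else:
            d = min(abs(m.translation_start - m.tss), downstream_cap)
        if m.strand == "+":
            g_start, g_end = m.tss - upstream, m.tss + d
        else:
            # transcript coordinate t maps to genomic g = tss - t
            g_start, g_end = m.tss - d + 1, m.tss + upstream + 1
        clen = _chrom_len(genome, m.chrom)
        g_start, g_end = max(0, g_start), min(clen, g_end)
        if g_start >= g_end:
            log.warning("%s: empty promoter window after clipping; skipped", m.gene_id)
            continue
        seq = _chrom_seq(genome, m.chrom, g_start, g_end).upper()
        if m.strand == "-":
            seq = reverse_complement(seq)
        windows.append(
            PromoterWindow(
                gene_id=m.gene_id,
                chrom=m.chrom,
                start=g_start,
                end=g_end,
                strand=m.strand,
                sequence=seq,
            )
        )
    return windows


def _has_chrom(genome, chrom: str) -> bool:
    try:
        genome[chrom]
    except KeyError:
        return False
    return True


def write_promoter_fasta(windows: Iterable[PromoterWindow], path: Union[str, Path]) -> None:
    """Write windows as FASTA, record id = gene id, deterministic order."""
    with open(path, "w") as fh:
        for w in sorted(windows, key=lambda w: w.gene_id):
            fh.write(f">{w.gene_id}\n")
            for i in range(0, len(w.sequence), 60):
                fh.write(w.sequence[i : i + 60] + "\n")


def write_promoter_bed(windows: Iterable[PromoterWindow], path: Union[str, Path]) -> None:
    """Write windows as BED6 (0-based half-open; name = gene id)."""
    with open(path, "w") as fh:
        for w in sorted(windows, key=lambda w: (w.chrom, w.start, w.gene_id)):
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.gene_id}\t0\t{w.strand}\n")


def read_promoter_fasta(path: Union[str, Path]) -> dict[str, str]:
    """Read a promoters FASTA into an ordered ``{gene_id: sequence}`` dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
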