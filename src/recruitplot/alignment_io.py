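"""Alignment and sequence I/O plus a minimal built-in aligner.

Provides the :class:`AlignmentHit` record used throughout the pipeline, a
reference-genome collection (:class:`ReferenceDB`), readers/writers for the
BLAST tabular (outfmt 6) and PAF dialects, FASTA/FASTQ helpers, and
:func:`toy_align`, an ungapped seed-and-extend aligner that stands in for an
external aligner so the whole pipeline is testable end to end.

Coordinate conventions
----------------------
All coordinates are 1-based inclusive on both query and subject.  Hits on
the reverse strand of the subject are stored with ``subject_start >
subject_end``.  PAF input (0-based, half-open) is converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError, ParseError

logger = logging.getLogger(__name__)

_COMPLEMENT = bytes.maketrans(b"ACGTacgtNn", b"TGCAtgcaNn")

BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgtNn", "TGCAtgcaNn"))[::-1]


class Read(NamedTuple):
    """A sequencing read: identifier plus nucleotide sequence."""

    id: str
    sequence: str


@dataclass
class AlignmentHit:
    """One read-vs-reference alignment record.

    ``mismatches`` and ``gap_opens`` exist for blast6 round-tripping;
    the pipeline's decisions use identity, overlap, and bitscore only.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    bitscore: float
    evalue: float = 0.0
    query_length: int | None = None
    mismatches: int = 0
    gap_opens: int = 0

    def __post_init__(self) -> None:
        if self.alignment_length < 1:
            raise DataError(f"alignment_length must be >= 1, got {self.alignment_length}")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise DataError(f"percent_identity out of [0, 100]: {self.percent_identity}")
        if not 1 <= self.query_start <= self.query_end:
            raise DataError(
                f"require 1 <= query_start <= query_end, got "
                f"{self.query_start}..{self.query_end}"
            )
        if self.query_length is not None and self.query_end > self.query_length:
            raise DataError(
                f"query_end {self.query_end} exceeds query_length {self.query_length}"
            )
        if self.bitscore < 0:
            raise DataError(f"bitscore must be non-negative, got {self.bitscore}")

    @property
    def query_coverage(self) -> float:
        """Alignment length as a percentage of the full read length."""
        if self.query_length is None:
            raise DataError(f"hit for {self.query_id!r} lacks query_length")
        return 100.0 * self.alignment_length / self.query_length

    @property
    def subject_span(self) -> tuple[int, int]:
        """(low, high) subject coordinates regardless of strand."""
        lo, hi = self.subject_start, self.subject_end
        return (lo, hi) if lo <= hi else (hi, lo)

    @property
    def is_reverse(self) -> bool:
        return self.subject_start > self.subject_end


@dataclass
class Genome:
    genome_id: str
    species: str
    subspecies: str | None = None
    length: int = 0
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.sequence is not None:
            if self.length and self.length != len(self.sequence):
                raise DataError(
                    f"{self.genome_id}: declared length {self.length} != "
                    f"sequence length {len(self.sequence)}"
                )
            self.length = len(self.sequence)


class ReferenceDB:
    """Ordered collection of reference genomes with a species index."""

    def __init__(self, genomes: Iterable[Genome]):
        self.genomes: list[Genome] = list(genomes)
        self._by_id: dict[str, Genome] = {}
        self.species_index: dict[str, list[str]] = {}
        for g in self.genomes:
            if g.genome_id in self._by_id:
                raise DataError(f"duplicate genome id {g.genome_id!r}")
            self._by_id[g.genome_id] = g
            self.species_index.setdefault(g.species, []).append(g.genome_id)

    def __len__(self) -> int:
        return len(self.genomes)

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self._by_id

    def __iter__(self) -> Iterator[Genome]:
        return iter(self.genomes)

    def get(self, genome_id: str) -> Genome:
        try:
            return self._by_id[genome_id]
        except KeyError:
            raise DataError(f"unknown genome id {genome_id!r}") from None

    def species_of(self, genome_id: str) -> str:
        return self.get(genome_id).species

    @property
    def has_sequences(self) -> bool:
        return all(g.sequence is not None for g in self.genomes)

    @classmethod
    def from_fasta(cls, fasta_path: str | Path, metadata_tsv: str | Path | None = None) -> "ReferenceDB":
        """Load genomes from FASTA, optionally joining a metadata table.

        The metadata TSV must have a header with columns ``genome_id`` and
        ``species`` (``subspecies`` optional).  Without metadata each genome
        becomes its own species.
        """
        meta: dict[str, tuple[str, str | None]] = {}
        if metadata_tsv is not None:
            meta = _read_metadata(metadata_tsv)
        genomes = []
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            species, subsp = meta.get(rec.id, (rec.id, None))
            genomes.append(
                Genome(rec.id, species, subsp, sequence=str(rec.seq).upper())
            )
        return cls(genomes)

    @classmethod
    def from_metadata(cls, metadata_tsv: str | Path) -> "ReferenceDB":
        """Load sequence-less genome metadata (id, species, subspecies, length)."""
        genomes = []
        with open(metadata_tsv) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {name: i for i, name in enumerate(header)}
            for name in ("genome_id", "species"):
                if name not in idx:
                    raise ParseError(f"metadata missing column {name!r}")
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                subsp = parts[idx["subspecies"]] if "subspecies" in idx else ""
                length = int(parts[idx["length"]]) if "length" in idx else 0
                genomes.append(
                    Genome(
                        parts[idx["genome_id"]],
                        parts[idx["species"]],
                        subsp or None,
                        length=length,
                    )
                )
        return cls(genomes)

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(g.sequence), id=g.genome_id, description="")
            for g in self.genomes
            if g.sequence is not None
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_metadata(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("genome_id\tspecies\tsubspecies\tlength\n")
            for g in self.genomes:
                fh.write(f"{g.genome_id}\t{g.species}\t{g.subspecies or ''}\t{g.length}\n")


def _read_metadata(path: str | Path) -> dict[str, tuple[str, str | None]]:
    out: dict[str, tuple[str, str | None]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            subsp = parts[idx["subspecies"]] if "subspecies" in idx else ""
            out[parts[idx["genome_id"]]] = (parts[idx["species"]], subsp or None)
    return out


# ---------------------------------------------------------------------------
# Tabular alignment formats


def read_alignment_table(
    path: str | Path,
    dialect: str = "blast6",
    ref: ReferenceDB | None = None,
) -> list[AlignmentHit]:
    """Parse a tabular alignment file into :class:`AlignmentHit` records.

    ``dialect`` is ``"blast6"`` (12 canonical columns, optional 13th qlen
    column) or ``"paf"``.  An empty file yields an empty list.  Subject ids
    not present in ``ref`` are allowed but counted and logged.
    """
    if dialect not in ("blast6", "paf"):
        raise DataError(f"unknown dialect {dialect!r}")
    hits: list[AlignmentHit] = []
    unknown = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            try:
                if dialect == "blast6":
                    hit = _parse_blast6_row(line)
                else:
                    hit = _parse_paf_row(line)
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed {dialect} row: {exc}") from exc
            if ref is not None and hit.subject_id not in ref:
                unknown += 1
            hits.append(hit)
    if unknown:
        logger.warning("%s: %d hits reference subjects absent from the database", path, unknown)
    return hits


def _parse_blast6_row(line: str) -> AlignmentHit:
    f = line.split("\t")
    if len(f) < 12:
        raise ValueError(f"expected >= 12 columns, got {len(f)}")
    qlen = int(f[12]) if len(f) >= 13 and f[12] != "" else None
    return AlignmentHit(
        query_id=f[0],
        subject_id=f[1],
        percent_identity=float(f[2]),
        alignment_length=int(f[3]),
        mismatches=int(f[4]),
        gap_opens=int(f[5]),
        query_start=int(f[6]),
        query_end=int(f[7]),
        subject_start=int(f[8]),
        subject_end=int(f[9]),
        evalue=float(f[10]),
        bitscore=float(f[11]),
        query_length=qlen,
    )


def _parse_paf_row(line: str) -> AlignmentHit:
    f = line.split("\t")
    if len(f) < 12:
        raise ValueError(f"expected >= 12 columns, got {len(f)}")
    qlen = int(f[1])
    qstart0, qend0 = int(f[2]), int(f[3])
    strand = f[4]
    if strand not in "+-":
        raise ValueError(f"bad strand {strand!r}")
    tstart0, tend0 = int(f[7]), int(f[8])
    nmatch, blocklen = int(f[9]), int(f[10])
    if blocklen <= 0:
        raise ValueError("alignment block length must be positive")
    if strand == "+":
        sstart, send = tstart0 + 1, tend0
    else:
        sstart, send = tend0, tstart0 + 1
    return AlignmentHit(
        query_id=f[0],
        subject_id=f[5],
        percent_identity=100.0 * nmatch / blocklen,
        alignment_length=qend0 - qstart0,
        query_start=qstart0 + 1,
        query_end=qend0,
        subject_start=sstart,
        subject_end=send,
        # PAF carries no bitscore; residue matches are a monotone surrogate.
        bitscore=float(nmatch),
        evalue=0.0,
        query_length=qlen,
    )


def write_blast6(hits: Iterable[AlignmentHit], path: str | Path, include_qlen: bool = True) -> None:
    """Write hits as 12-column blast6 TSV plus an optional 13th qlen column.

    pident is written with 3 decimals (the blastn convention); evalue and
    bitscore use the shortest exact float repr so a write/read cycle is
    stable.
    """
    with open(path, "w") as fh:
        for h in hits:
            cols = [
                h.query_id,
                h.subject_id,
                f"{h.percent_identity:.3f}",
                str(h.alignment_length),
                str(h.mismatches),
                str(h.gap_opens),
                str(h.query_start),
                str(h.query_end),
                str(h.subject_start),
                str(h.subject_end),
                repr(h.evalue),
                repr(h.bitscore),
            ]
            if include_qlen:
                cols.append("" if h.query_length is None else str(h.query_length))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# FASTA / FASTQ reads


def read_reads(path: str | Path, fmt: str | None = None) -> list[Read]:
    """Load reads from FASTA or FASTQ (format inferred from the suffix)."""
    if fmt is None:
        suffix = Path(path).suffix.lower()
        fmt = "fastq" if suffix in (".fastq", ".fq") else "fasta"
    return [Read(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    """Write reads as FASTQ with uniform placeholder qualities."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_fasta_reads(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n{r.sequence}\n")


# ---------------------------------------------------------------------------
# Toy aligner


class ToyAligner:
    """Ungapped seed-and-extend aligner over an in-memory reference.

    Seeds are exact k-mer matches; candidate placements are diagonals with
    at least ``min_seed_hits`` seeds.  Each candidate is scored by placing
    the full read on the diagonal (clipped at genome edges) and counting
    matching bases.  Bitscore is ``max(0, 2*matches - 3*mismatches)`` — any
    strictly monotone score works for best-hit selection; this fixed one
    keeps ties reproducible.  Both strands are searched and all candidate
    placements are reported, not only the best.
    """

    def __init__(self, ref: ReferenceDB, k: int = 15):
        if k < 8:
            raise DataError(f"seed length k must be >= 8, got {k}")
        if not ref.has_sequences:
            missing = [g.genome_id for g in ref if g.sequence is None]
            raise DataError(f"reference genomes lack sequences: {missing}")
        self.ref = ref
        self.k = k
        self._seqs = [g.sequence for g in ref.genomes]
        self._arrs = [np.frombuffer(s.encode(), dtype=np.uint8) for s in self._seqs]
        self._index: dict[str, list[tuple[int, int]]] = {}
        for gi, seq in enumerate(self._seqs):
            add = self._index.setdefault
            for pos in range(len(seq) - k + 1):
                add(seq[pos : pos + k], []).append((gi, pos))

    def align_read(
        self, read: Read, min_seed_hits: int = 2, stride: int = 1
    ) -> list[AlignmentHit]:
        hits: list[AlignmentHit] = []
        for strand, seq in ((1, read.sequence), (-1, reverse_complement(read.sequence))):
            hits.extend(self._align_oriented(read.id, seq, strand, min_seed_hits, stride))
        return hits

    def _align_oriented(
        self, read_id: str, seq: str, strand: int, min_seed_hits: int, stride: int
    ) -> list[AlignmentHit]:
        k = self.k
        n = len(seq)
        if n < k:
            return []
        diag_counts: dict[tuple[int, int], int] = {}
        index_get = self._index.get
        for qpos in range(0, n - k + 1, stride):
            for gi, gpos in index_get(seq[qpos : qpos + k], ()):
                key = (gi, gpos - qpos)
                diag_counts[key] = diag_counts.get(key, 0) + 1
        read_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        out = []
        for (gi, diag), count in diag_counts.items():
            if count < min_seed_hits:
                continue
            glen = len(self._seqs[gi])
            q0 = max(0, -diag)  # 0-based clip on the oriented read
            q1 = min(n, glen - diag)
            if q1 - q0 < k:
                continue
            g0, g1 = q0 + diag, q1 + diag
            matches = int((self._arrs[gi][g0:g1] == read_arr[q0:q1]).sum())
            aln_len = q1 - q0
            mism = aln_len - matches
            bitscore = max(0, 2 * matches - 3 * mism)
            # oriented-read 1-based coordinates
            oq_start, oq_end = q0 + 1, q1
            if strand == 1:
                q_start, q_end = oq_start, oq_end
                s_start, s_end = g0 + 1, g1
            else:
                q_start, q_end = n - oq_end + 1, n - oq_start + 1
                s_start, s_end = g1, g0 + 1  # reverse strand: start > end
            out.append(
                AlignmentHit(
                    query_id=read_id,
                    subject_id=self.ref.genomes[gi].genome_id,
                    percent_identity=100.0 * matches / aln_len,
                    alignment_length=aln_len,
                    query_start=q_start,
                    query_end=q_end,
                    subject_start=s_start,
                    subject_end=s_end,
                    bitscore=float(bitscore),
                    evalue=0.0,
                    query_length=n,
                    mismatches=mism,
                    gap_opens=0,
                )
            )
        return out


def toy_align(
    reads: Sequence[Read],
    ref: ReferenceDB,
    k: int = 15,
    min_seed_hits: int = 2,
    stride: int = 1,
) -> list[AlignmentHit]:
    """Align reads to the reference with the built-in toy aligner.

    See :class:`ToyAligner` for the model.  For repeated calls against the
    same reference, build a :class:`ToyAligner` once instead.
    """
    aligner = ToyAligner(ref, k=k)
    hits: list[AlignmentHit] = []
    for read in reads:
        hits.extend(aligner.align_read(read, min_seed_hits=min_seed_hits, stride=stride))
    return hits
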