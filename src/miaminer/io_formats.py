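"""Readers and writers for the external formats the pipeline touches.

All downstream modules operate on the in-memory domain types defined here:
gene models parsed from StringTie-style GTF or GFF3, BLAST tabular hits
(outfmt 6, optionally with a subject-coverage column), simplified
hmmscan-like domain tables, and labelled TSV matrices.  Coordinates are
1-based inclusive throughout, following GFF convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from gffutils.feature import feature_from_line


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """A parsed record violates a domain invariant."""


_PFAM_RE = re.compile(r"^PF\d{5}$")


def strip_pfam_version(accession: str) -> str:
    """Drop a trailing Pfam version suffix: ``PF00107.26`` -> ``PF00107``."""
    acc = accession.split(".", 1)[0]
    if not _PFAM_RE.match(acc):
        raise ValidationError(f"not a Pfam accession: {accession!r}")
    return acc


def locus_id(transcript_id: str) -> str:
    """Collapse a transcript id to its locus: ``MSTRG.5283.1`` -> ``MSTRG.5283``.

    Ids with fewer than three dot-separated parts (already locus-level, or
    metabolite ids) are returned unchanged.  Only a trailing all-digit
    isoform suffix is stripped.
    """
    head, _, tail = transcript_id.rpartition(".")
    if head and tail.isdigit() and "." in head:
        return head
    return transcript_id


@dataclass(frozen=True)
class GeneModel:
    """A gene locus with its transcript ids and genomic span (1-based, inclusive)."""

    gene_id: str
    transcript_ids: tuple[str, ...]
    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"{self.gene_id}: start {self.start} < 1")
        if self.end < self.start:
            raise ValidationError(
                f"{self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class BlastHit:
    """One BLAST tabular hit of a predicted protein against a known MIA protein.

    ``coverage`` is subject coverage (fraction of the known protein aligned,
    in percent); it may be missing (None) when the input table carries no
    coverage column and no subject lengths are supplied.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    coverage: float | None
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValidationError(
                f"{self.query_id}: identity {self.percent_identity} outside [0, 100]"
            )
        if self.coverage is not None and not 0.0 <= self.coverage <= 100.0:
            raise ValidationError(
                f"{self.query_id}: coverage {self.coverage} outside [0, 100]"
            )
        if self.evalue < 0:
            raise ValidationError(f"{self.query_id}: negative e-value {self.evalue}")


@dataclass(frozen=True)
class DomainAnnotation:
    """A Pfam domain call on a gene; accession stored version-stripped."""

    gene_id: str
    pfam_accession: str
    domain_name: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        if not _PFAM_RE.match(self.pfam_accession):
            raise ValidationError(
                f"{self.gene_id}: bad Pfam accession {self.pfam_accession!r}"
            )


# ---------------------------------------------------------------------------
# gene models (GTF / GFF3)
# ---------------------------------------------------------------------------

_GENE_FEATURES = {"gene", "transcript", "mRNA", "exon", "CDS"}


def _feature_ids(feat) -> tuple[str | None, str | None]:
    """Extract (gene_id, transcript_id) from either attribute dialect."""
    attrs = feat.attributes
    gene = attrs["gene_id"][0] if "gene_id" in attrs else None
    tx = attrs["transcript_id"][0] if "transcript_id" in attrs else None
    if gene is None and tx is None:  # GFF3 ID/Parent style
        if feat.featuretype == "gene" and "ID" in attrs:
            gene = attrs["ID"][0]
        elif feat.featuretype in {"transcript", "mRNA"}:
            tx = attrs["ID"][0] if "ID" in attrs else None
            gene = attrs["Parent"][0] if "Parent" in attrs else None
        elif "Parent" in attrs:
            tx = attrs["Parent"][0]
    if gene is None and tx is not None:
        gene = locus_id(tx)
    return gene, tx


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse a GTF or GFF3 file into gene-level models.

    The span of a gene is the min start / max end over all records assigned
    to it, so StringTie files without explicit ``gene`` features work.
    Unknown feature types are ignored.  Raises :class:`ParseError` naming the
    line number on malformed input and :class:`ValidationError` on
    ``end < start``.
    """
    spans: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise ValidationError(f"{path}:{lineno}: end {end} < start {start}")
            if cols[2] not in _GENE_FEATURES:
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            gene_id, tx_id = _feature_ids(feat)
            if gene_id is None:
                raise ParseError(
                    f"{path}:{lineno}: record carries no gene or transcript id"
                )
            rec = spans.get(gene_id)
            if rec is None:
                rec = spans[gene_id] = {
                    "contig": feat.seqid,
                    "start": start,
                    "end": end,
                    "strand": feat.strand or ".",
                    "tx": [],
                }
                order.append(gene_id)
            else:
                if rec["contig"] != feat.seqid:
                    raise ValidationError(
                        f"{path}:{lineno}: gene {gene_id} spans contigs "
                        f"{rec['contig']} and {feat.seqid}"
                    )
                rec["start"] = min(rec["start"], start)
                rec["end"] = max(rec["end"], end)
            if tx_id is not None and tx_id not in rec["tx"]:
                rec["tx"].append(tx_id)
    return [
        GeneModel(
            gene_id=g,
            transcript_ids=tuple(spans[g]["tx"]),
            contig=spans[g]["contig"],
            start=spans[g]["start"],
            end=spans[g]["end"],
            strand=spans[g]["strand"],
        )
        for g in order
    ]


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene + transcript features, deterministic order)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig}\tminer\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for tx in g.transcript_ids:
                fh.write(
                    f"{g.contig}\tminer\ttranscript\t{g.start}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={tx};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6, optionally + subject coverage)
# ---------------------------------------------------------------------------

BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend "
    "sstart send evalue bitscore"
).split()


def read_blast_tab(
    path: str | Path, subject_lengths: dict[str, int] | None = None
) -> list[BlastHit]:
    """Parse BLAST outfmt-6 rows (12 columns, or 13 with appended subject coverage).

    Without an explicit coverage column, subject coverage is computed as
    ``100 * alignment_length / subject_length`` when ``subject_lengths`` is
    given, and left missing otherwise.
    """
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) not in (12, 13):
                raise ParseError(
                    f"{path}:{lineno}: expected 12 or 13 columns, got {len(cols)}"
                )
            try:
                pident = float(cols[2])
                length = int(cols[3])
                evalue = float(cols[10])
                bitscore = float(cols[11])
                coverage = float(cols[12]) if len(cols) == 13 else None
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field") from exc
            if coverage is None and subject_lengths is not None:
                slen = subject_lengths.get(cols[1])
                if slen:
                    coverage = 100.0 * length / slen
            hits.append(
                BlastHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    percent_identity=pident,
                    coverage=coverage,
                    evalue=evalue,
                    bitscore=bitscore,
                )
            )
    return hits


def write_blast_tab(hits: Iterable[BlastHit], path: str | Path) -> None:
    """Write hits in 13-column outfmt-6 + coverage form (placeholder alignment fields)."""
    with open(path, "w") as fh:
        for h in hits:
            cov = "" if h.coverage is None else f"\t{h.coverage:.2f}"
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.2f}\t0\t0\t0"
                f"\t0\t0\t0\t0\t{h.evalue:.3g}\t{h.bitscore:.1f}{cov}\n"
            )


# ---------------------------------------------------------------------------
# domain tables (simplified hmmscan)
# ---------------------------------------------------------------------------


def read_domain_table(path: str | Path) -> list[DomainAnnotation]:
    """Read a TSV of (gene_id, pfam_accession, domain_name, score); versions stripped."""
    out: list[DomainAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ParseError(f"{path}:{lineno}: expected >=2 columns")
            try:
                acc = strip_pfam_version(cols[1])
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            name = cols[2] if len(cols) > 2 else ""
            try:
                score = float(cols[3]) if len(cols) > 3 and cols[3] else 0.0
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            out.append(DomainAnnotation(cols[0], acc, name, score))
    return out


def write_domain_table(domains: Iterable[DomainAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for d in domains:
            fh.write(f"{d.gene_id}\t{d.pfam_accession}\t{d.domain_name}\t{d.score:g}\n")


# ---------------------------------------------------------------------------
# labelled matrices
# ---------------------------------------------------------------------------


def read_matrix(
    path: str | Path, kind: Literal["expression", "metabolite"] = "expression"
) -> pd.DataFrame:
    """Read a features x samples TSV into a labelled float DataFrame.

    Duplicate feature ids are rejected.  Missing values are rejected for
    expression matrices and zero-filled for metabolite matrices.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate feature ids {dups[:5]}")
    if df.isna().any().any():
        if kind == "expression":
            raise ValidationError(f"{path}: missing values in expression matrix")
        df = df.fillna(0.0)
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ParseError(f"{path}: non-numeric columns {non_numeric[:5]}")
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Write with fixed-width float formatting so round-trips are bit-stable."""
    df.to_csv(path, sep="\t", float_format="%.6g")
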