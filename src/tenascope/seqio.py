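"""Readers and writers: protein FASTA, domain/locus TSV tables, Newick trees
and the JSON results report.

All readers follow the same contract: structurally invalid rows are rejected
with a logged message and the run continues; whole-file problems (empty file,
duplicate ids) abort.  TSV tables are tab-delimited with a header row and "."
for null values.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .config import domain_synonyms
from .records import (
    ALLOWED_RESIDUES,
    AnnotationMethod,
    DomainAnnotation,
    DomainKind,
    GeneLocus,
    ProteinRecord,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- FASTA

def _clean_seq(pid: str, raw: str) -> str:
    seq = raw.upper()
    bad = set(seq) - ALLOWED_RESIDUES
    if bad:
        log.warning("%s: replacing non-standard residues %s with X", pid, sorted(bad))
        seq = "".join(c if c in ALLOWED_RESIDUES else "X" for c in seq)
    return seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA.  Sequences are uppercased; residues outside the
    20-letter alphabet (plus X) become X with a warning.  The record id is the
    first whitespace-delimited header token; a ``species=...`` key in the
    description is honoured."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA id: {entry.id}")
        seen.add(entry.id)
        species = ""
        for token in entry.description.split():
            if token.startswith("species="):
                species = token[len("species="):]
        records.append(
            ProteinRecord(id=entry.id, seq=_clean_seq(entry.id, str(entry.seq)),
                          species=species)
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.species:
                header += f" species={rec.species}"
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def read_labeled_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a reference FReD set whose headers are ``>LABEL|name``.
    Returns (label, name, sequence) triples."""
    out = []
    for rec in read_fasta(path):
        if "|" not in rec.id:
            raise ValueError(f"reference id {rec.id!r} lacks a LABEL| prefix")
        label, name = rec.id.split("|", 1)
        out.append((label, name, rec.seq))
    return out


# ---------------------------------------------------------------- TSV tables

def read_domain_table(path: str | Path, synonyms_path: str | None = None
                      ) -> list[DomainAnnotation]:
    """Ingest an externally produced domain table (protein_id, kind, start,
    end, score).  Unknown kind strings map to OTHER with a warning; rows with
    non-integer or inverted coordinates are rejected (logged), the run
    continues."""
    table = domain_synonyms(synonyms_path)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    required = {"protein_id", "kind", "start", "end", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"domain table missing columns: {sorted(missing)}")
    annotations: list[DomainAnnotation] = []
    n_rejected = 0
    for row in df.itertuples(index=False):
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError):
            log.error("domain row %s: non-integer coordinates, rejected", tuple(row))
            n_rejected += 1
            continue
        if start > end or start < 1:
            log.error("domain row %s: invalid interval, rejected", tuple(row))
            n_rejected += 1
            continue
        kind = table.get(str(row.kind).upper())
        if kind is None:
            log.warning("domain row %s: unknown kind %r mapped to OTHER",
                        row.protein_id, row.kind)
            kind = DomainKind.OTHER
        score = None if pd.isna(row.score) or row.score == "" else float(row.score)
        annotations.append(DomainAnnotation(
            protein_id=str(row.protein_id), kind=kind, start=start, end=end,
            score=score, method=AnnotationMethod.EXTERNAL))
    log.info("domain table %s: %d accepted, %d rejected", path, len(annotations), n_rejected)
    return annotations


def read_locus_table(path: str | Path) -> list[GeneLocus]:
    """Read a gene-order table (species, chrom, start, end, strand, symbol)."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    required = {"species", "chrom", "start", "end", "strand", "symbol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"locus table missing columns: {sorted(missing)}")
    loci: list[GeneLocus] = []
    seen: set[tuple] = set()
    n_rejected = 0
    for row in df.itertuples(index=False):
        try:
            locus = GeneLocus(species=row.species, chrom=row.chrom,
                              start=int(row.start), end=int(row.end),
                              strand=row.strand if row.strand else ".",
                              symbol=row.symbol)
        except (TypeError, ValueError) as exc:
            log.error("locus row %s rejected: %s", tuple(row), exc)
            n_rejected += 1
            continue
        key = (locus.species, locus.chrom, locus.start, locus.end, locus.symbol)
        if key in seen:
            log.error("locus row %s rejected: duplicate", key)
            n_rejected += 1
            continue
        seen.add(key)
        loci.append(locus)
    log.info("locus table %s: %d accepted, %d rejected", path, len(loci), n_rejected)
    return loci


def write_locus_table(loci: Iterable[GeneLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tchrom\tstart\tend\tstrand\tsymbol\n")
        for g in loci:
            fh.write(f"{g.species}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\t{g.symbol}\n")


# ---------------------------------------------------------------- Newick

def read_newick(path_or_string: str | Path):
    """Parse a Newick tree (branch lengths; optional support values after the
    closing parentheses).  Malformed input raises ValueError naming the
    approximate character offset."""
    from .phylo import PhyloTree
    text = None
    p = Path(str(path_or_string))
    if p.exists():
        text = p.read_text()
    else:
        text = str(path_or_string)
    return PhyloTree.from_newick(text)


def write_newick(tree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------- report

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "value") and not isinstance(obj, (int, float, str, bool)):
        return obj.value  # enums
    return obj


def write_report(report: dict | Sequence, path: str | Path) -> None:
    """Serialize the pipeline report (or a bare list of calls) as JSON."""
    payload = _jsonable(report)
    if isinstance(payload, list):
        payload = {"calls": payload}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
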