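"""Taxa x domain copy-count matrices (the character data for ancestry).

Columns are the sorted non-redundant union of domain names across all
repertoires, rows are taxa; entry (t, d) is the copy count of domain d in
taxon t. Counts, not presence/absence, are the character states handed to
the parsimony reconstruction; a presence/absence view is available.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import numpy as np
import pandas as pd

from .domain_annotation import DomainRepertoire, nonredundant_domains

__all__ = [
    "DomainCountMatrix",
    "build_matrix",
    "presence_absence",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "extract_character",
    "write_nexus",
]


@dataclass
class DomainCountMatrix:
    taxa: list[str]
    domains: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.taxa), len(self.domains)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.domains)} domains"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa")
        if len(set(self.domains)) != len(self.domains):
            raise ValueError("duplicate domains")
        if self.counts.size and (
            not np.issubdtype(self.counts.dtype, np.integer) or (self.counts < 0).any()
        ):
            raise ValueError("counts must be non-negative integers")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxa, columns=self.domains)


def build_matrix(
    repertoires: Iterable[DomainRepertoire], drop_empty_columns: bool = True
) -> DomainCountMatrix:
    """Assemble repertoires into a count matrix with sorted domain columns.

    All-zero columns are dropped by default (they cannot arise directly from
    repertoires, but can after subsetting; zero-variance characters produce
    no events).
    """
    repertoires = list(repertoires)
    taxa = [r.taxon for r in repertoires]
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon among repertoires")
    domains = nonredundant_domains(repertoires)
    counts = np.zeros((len(taxa), len(domains)), dtype=np.int64)
    col = {d: j for j, d in enumerate(domains)}
    for i, r in enumerate(repertoires):
        for d, c in r.counts.items():
            counts[i, col[d]] = c
    m = DomainCountMatrix(taxa=taxa, domains=domains, counts=counts)
    if drop_empty_columns and m.counts.size:
        keep = m.counts.sum(axis=0) > 0
        m = DomainCountMatrix(
            taxa=taxa,
            domains=[d for d, k in zip(domains, keep) if k],
            counts=m.counts[:, keep],
        )
    return m


def presence_absence(m: DomainCountMatrix) -> DomainCountMatrix:
    """Clamp counts to 0/1 (domain present or absent per genome)."""
    return DomainCountMatrix(
        taxa=list(m.taxa), domains=list(m.domains), counts=np.minimum(m.counts, 1)
    )


def write_matrix_tsv(m: DomainCountMatrix, stream: TextIO) -> None:
    """TSV with a header row of domain names; first column is the taxon."""
    df = m.to_frame()
    df.index.name = "taxon"
    df.to_csv(stream, sep="\t")


def read_matrix_tsv(stream: TextIO | str) -> DomainCountMatrix:
    """Inverse of :func:`write_matrix_tsv`; validates integer, non-negative cells."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = [ln.rstrip("\n") for ln in stream if ln.strip()]
    if not lines:
        raise ValueError("empty matrix file")
    header = lines[0].split("\t")
    domains = header[1:]
    width = len(header)
    taxa: list[str] = []
    rows: list[list[int]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != width:
            raise ValueError(f"line {lineno}: ragged row ({len(parts)} fields, expected {width})")
        taxa.append(parts[0])
        row = []
        for d, cell in zip(domains, parts[1:]):
            try:
                value = int(cell)
            except ValueError:
                raise ValueError(f"line {lineno}: non-integer count {cell!r} for {d}") from None
            if value < 0:
                raise ValueError(f"line {lineno}: negative count for {d}")
            row.append(value)
        rows.append(row)
    counts = (
        np.array(rows, dtype=np.int64)
        if rows
        else np.zeros((0, len(domains)), dtype=np.int64)
    )
    return DomainCountMatrix(taxa=taxa, domains=domains, counts=counts)


def extract_character(m: DomainCountMatrix, domain: str) -> dict[str, int]:
    """One domain column as leaf character states (taxon -> copy count)."""
    if domain not in m.domains:
        raise KeyError(f"domain {domain!r} not in matrix")
    j = m.domains.index(domain)
    return {t: int(m.counts[i, j]) for i, t in enumerate(m.taxa)}


def write_nexus(m: DomainCountMatrix, stream: TextIO) -> None:
    """NEXUS characters block for legacy parsimony software.

    State symbols are digits 0-9; counts above 9 are rejected.
    """
    if m.counts.size and m.counts.max() > 9:
        offenders = [
            m.domains[j] for j in np.unique(np.nonzero(m.counts > 9)[1])
        ]
        raise ValueError(
            f"NEXUS symbols support counts 0-9 only; over-limit domains: {offenders}"
        )
    stream.write("#NEXUS\n\nBEGIN DATA;\n")
    stream.write(f"  DIMENSIONS NTAX={len(m.taxa)} NCHAR={len(m.domains)};\n")
    stream.write('  FORMAT DATATYPE=STANDARD SYMBOLS="0123456789" MISSING=? GAP=-;\n')
    stream.write("  MATRIX\n")
    pad = max((len(t) for t in m.taxa), default=0) + 2
    for i, t in enumerate(m.taxa):
        row = "".join(str(int(c)) for c in m.counts[i])
        stream.write(f"    {t.replace(' ', '_'):<{pad}}{row}\n")
    stream.write("  ;\nEND;\n")
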