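"""HMMER3 domtblout parsing, E-value filtering, and domain repertoires.

A domtblout table (``hmmscan --domtblout``) holds one line per domain hit,
with 22 whitespace-separated columns followed by a free-text description.
Reliable hits are those whose full-sequence E-value AND per-domain
conditional E-value (c-Evalue) are both at or below 1e-3; the per-organism
domain repertoire is then the multiset of family names among the kept hits,
every hit counting as one domain copy.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence, TextIO

__all__ = [
    "DomainHit",
    "FilterCriteria",
    "DomainRepertoire",
    "parse_domtblout",
    "write_domtblout",
    "filter_hits",
    "deduplicate_overlaps",
    "build_repertoire",
    "nonredundant_domains",
]


@dataclass(frozen=True)
class DomainHit:
    """One profile-HMM domain match (one domtblout data line)."""

    target_name: str
    target_accession: str
    tlen: int
    query_name: str
    query_accession: str
    qlen: int
    seq_evalue: float
    seq_score: float
    seq_bias: float
    domain_index: int
    domain_total: int
    c_evalue: float
    i_evalue: float
    dom_score: float
    dom_bias: float
    hmm_from: int
    hmm_to: int
    ali_from: int
    ali_to: int
    env_from: int
    env_to: int
    acc: float
    description: str = "-"

    def __post_init__(self) -> None:
        for name in ("seq_evalue", "c_evalue", "i_evalue"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.ali_from > self.ali_to:
            raise ValueError("ali_from must be <= ali_to")
        if not (self.env_from <= self.ali_from and self.ali_to <= self.env_to):
            raise ValueError("alignment must lie within its envelope")
        if self.domain_index > self.domain_total:
            raise ValueError("domain_index must be <= domain_total")


@dataclass(frozen=True)
class FilterCriteria:
    """Inclusion thresholds for reliable hits (both inclusive)."""

    seq_evalue_max: float = 1e-3
    dom_evalue_max: float = 1e-3

    def __post_init__(self) -> None:
        if self.seq_evalue_max <= 0 or self.dom_evalue_max <= 0:
            raise ValueError("E-value thresholds must be positive")


@dataclass
class DomainRepertoire:
    """Per-taxon domain copy counts; absent domains are omitted."""

    taxon: str
    counts: dict[str, int] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.counts.values())


# domtblout field order; description is the free-text remainder.
_FIELDS = [f.name for f in fields(DomainHit) if f.name != "description"]
_TYPES = {f.name: f.type for f in fields(DomainHit)}


def parse_domtblout(stream: TextIO | str) -> list[DomainHit]:
    """Parse HMMER3 per-domain tabular output.

    Lines starting with ``#`` are comments; each data line must have at
    least 22 columns, the 23rd onward forming the description. Raises
    ``ValueError`` with the line number on short or unparseable lines.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    hits = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split(None, 22)
        if len(parts) < 22:
            raise ValueError(f"line {lineno}: expected >= 22 columns, got {len(parts)}")
        kwargs = {}
        for name, raw in zip(_FIELDS, parts):
            kind = _TYPES[name]
            try:
                if kind == "int":
                    kwargs[name] = int(raw)
                elif kind == "float":
                    kwargs[name] = float(raw)
                else:
                    kwargs[name] = raw
            except ValueError:
                raise ValueError(
                    f"line {lineno}: cannot parse field {name!r} from {raw!r}"
                ) from None
        kwargs["description"] = parts[22].strip() if len(parts) == 23 and parts[22].strip() else "-"
        hits.append(DomainHit(**kwargs))
    return hits


def _fmt(value: object) -> str:
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_domtblout(hits: Iterable[DomainHit], stream: TextIO) -> None:
    """Write hits in the domtblout dialect accepted by :func:`parse_domtblout`."""
    stream.write("#                                                               --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord\n")
    stream.write("# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target\n")
    stream.write("#------------------- ---------- ----- -------------------- ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- ---------------------\n")
    for h in hits:
        cols = [_fmt(getattr(h, name)) for name in _FIELDS]
        cols.append(h.description)
        stream.write(" ".join(cols) + "\n")


def filter_hits(
    hits: Sequence[DomainHit], criteria: FilterCriteria = FilterCriteria()
) -> list[DomainHit]:
    """Keep hits passing both E-value thresholds (inclusive); order preserved."""
    return [
        h
        for h in hits
        if h.seq_evalue <= criteria.seq_evalue_max and h.c_evalue <= criteria.dom_evalue_max
    ]


def deduplicate_overlaps(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Optional per-query envelope-overlap de-duplication (keep best dom_score).

    Off by default in the pipeline: every filtered hit normally contributes
    one domain copy. Within each query, hits whose envelopes overlap an
    already-kept, higher-scoring hit are dropped.
    """
    by_query: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_name, []).append(h)
    kept: list[DomainHit] = []
    for query_hits in by_query.values():
        chosen: list[DomainHit] = []
        for h in sorted(query_hits, key=lambda x: -x.dom_score):
            if all(h.env_to < k.env_from or h.env_from > k.env_to for k in chosen):
                chosen.append(h)
        kept.extend(chosen)
    order = {id(h): i for i, h in enumerate(hits)}
    kept.sort(key=lambda h: order[id(h)])
    return kept


def build_repertoire(hits: Sequence[DomainHit], taxon: str) -> DomainRepertoire:
    """Count kept hits per domain family name for one taxon."""
    return DomainRepertoire(taxon=taxon, counts=dict(Counter(h.target_name for h in hits)))


def nonredundant_domains(repertoires: Iterable[DomainRepertoire]) -> list[str]:
    """Lexicographically sorted union of domain names across repertoires."""
    names: set[str] = set()
    for r in repertoires:
        names.update(r.counts)
    return sorted(names)
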