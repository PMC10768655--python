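"""Branch-wise gain, loss, and duplication calls from ancestral counts.

A change in reconstructed copy count along a branch is decomposed into unit
events: appearance from zero is one gain (plus duplications for any extra
copies), an increment of an existing count is that many duplications, and
each unit decrement is one loss. Events attach to branches, identified by
the child node; the root itself never carries events. The calls can be
summarized and exported as an iTOL DATASET_SYMBOL annotation for display as
colored boxes along the tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

from .phylo_parsimony import AncestralAssignment, Phylogeny

__all__ = [
    "BranchEventRecord",
    "EventSummary",
    "classify_branch",
    "call_events",
    "summarize_events",
    "export_itol",
    "write_events_tsv",
    "read_events_tsv",
]

GAIN_COLOR = "#00A550"
LOSS_COLOR = "#FFFFFF"
DUPLICATION_COLOR = "#6A0DAD"


@dataclass(frozen=True)
class BranchEventRecord:
    """Events for one (branch, domain); all-zero records are never emitted."""

    parent_label: str
    child_label: str
    domain: str
    gains: int = 0
    duplications: int = 0
    losses: int = 0

    def __post_init__(self) -> None:
        if min(self.gains, self.duplications, self.losses) < 0:
            raise ValueError("event counts must be non-negative")
        if self.gains > 1:
            raise ValueError("at most one gain per branch and domain")
        if (self.gains + self.duplications) > 0 and self.losses > 0:
            raise ValueError("a branch cannot both add and remove copies of one domain")
        if self.gains + self.duplications + self.losses == 0:
            raise ValueError("all-zero event record; omit it instead")

    @property
    def total(self) -> int:
        return self.gains + self.duplications + self.losses


@dataclass
class EventSummary:
    """Per-domain and grand totals of gains/duplications/losses."""

    gains: int = 0
    duplications: int = 0
    losses: int = 0
    per_domain: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.gains + self.duplications + self.losses


def classify_branch(parent_count: int, child_count: int) -> tuple[int, int, int]:
    """Decompose a count change into (gains, duplications, losses).

    - parent 0, child k>0: one gain plus k-1 duplications;
    - parent p>0, child c>p: c-p duplications;
    - child c<p: p-c losses (each unit decrement is one loss event);
    - no change: (0, 0, 0).
    """
    if parent_count < 0 or child_count < 0:
        raise ValueError("counts must be non-negative")
    if parent_count == 0 and child_count > 0:
        return (1, child_count - 1, 0)
    if child_count > parent_count:
        return (0, child_count - parent_count, 0)
    if child_count < parent_count:
        return (0, 0, parent_count - child_count)
    return (0, 0, 0)


def call_events(
    t: Phylogeny, assignments: Iterable[AncestralAssignment]
) -> list[BranchEventRecord]:
    """Classify every (branch, domain) change; drop zero-event records.

    Output order is deterministic: branches in preorder of the child node,
    then domain name.
    """
    assignments = sorted(assignments, key=lambda a: a.domain)
    node_labels = {n.label for n in t.preorder()}
    for a in assignments:
        missing = node_labels - set(a.state)
        if missing:
            raise ValueError(
                f"assignment for {a.domain!r} missing nodes: {sorted(missing)}"
            )
    records: list[BranchEventRecord] = []
    for parent, child in t.branches():
        for a in assignments:
            g, d, l = classify_branch(a.state[parent.label], a.state[child.label])
            if g + d + l:
                records.append(
                    BranchEventRecord(
                        parent_label=parent.label,
                        child_label=child.label,
                        domain=a.domain,
                        gains=g,
                        duplications=d,
                        losses=l,
                    )
                )
    return records


def summarize_events(records: Sequence[BranchEventRecord]) -> EventSummary:
    """Exact per-domain and grand event totals."""
    summary = EventSummary()
    for r in records:
        summary.gains += r.gains
        summary.duplications += r.duplications
        summary.losses += r.losses
        g, d, l = summary.per_domain.get(r.domain, (0, 0, 0))
        summary.per_domain[r.domain] = (g + r.gains, d + r.duplications, l + r.losses)
    return summary


_ITOL_HEADER = """\
DATASET_SYMBOL
SEPARATOR TAB
DATASET_LABEL\tDomain events
COLOR\t#444444
LEGEND_TITLE\tDomain events
LEGEND_SHAPES\t2\t2\t2
LEGEND_COLORS\t{gain}\t{loss}\t{dup}
LEGEND_LABELS\tGain\tLoss\tDuplication
MAXIMUM_SIZE\t20
DATA
"""


def export_itol(
    t: Phylogeny,
    records: Sequence[BranchEventRecord],
    domain_filter: str | None = None,
) -> str:
    """Render records as an iTOL DATASET_SYMBOL annotation.

    One data line per (branch, event type), anchored to the child node id,
    square symbols (shape 2), gain green / loss white / duplication purple,
    symbol size scaled by the event count.
    """
    lines = [
        _ITOL_HEADER.format(gain=GAIN_COLOR, loss=LOSS_COLOR, dup=DUPLICATION_COLOR)
    ]
    base_size = 10
    for r in records:
        if domain_filter is not None and r.domain != domain_filter:
            continue
        if r.child_label not in t:
            raise ValueError(f"record child label {r.child_label!r} not in tree")
        for count, color, kind in (
            (r.gains, GAIN_COLOR, "gain"),
            (r.duplications, DUPLICATION_COLOR, "duplication"),
            (r.losses, LOSS_COLOR, "loss"),
        ):
            if count:
                size = base_size + 2 * (count - 1)
                # node id, symbol, size, color, fill, position
                lines.append(
                    f"{r.child_label}\t2\t{size}\t{color}\t1\t0.5\t{r.domain} {kind} x{count}\n"
                )
    return "".join(lines)


def write_events_tsv(records: Sequence[BranchEventRecord], stream: TextIO) -> None:
    stream.write("parent\tchild\tdomain\tgains\tduplications\tlosses\n")
    for r in records:
        stream.write(
            f"{r.parent_label}\t{r.child_label}\t{r.domain}\t"
            f"{r.gains}\t{r.duplications}\t{r.losses}\n"
        )


def read_events_tsv(stream: TextIO) -> list[BranchEventRecord]:
    header = stream.readline().rstrip("\n").split("\t")
    expected = ["parent", "child", "domain", "gains", "duplications", "losses"]
    if header != expected:
        raise ValueError(f"unexpected events header {header}")
    records = []
    for line in stream:
        if not line.strip():
            continue
        p, c, d, g, dup, l = line.rstrip("\n").split("\t")
        records.append(
            BranchEventRecord(
                parent_label=p,
                child_label=c,
                domain=d,
                gains=int(g),
                duplications=int(dup),
                losses=int(l),
            )
        )
    return records
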