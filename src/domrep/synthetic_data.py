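"""Synthetic trees, repertoires, genomes, and hit tables with ground truth.

Every stage of the pipeline is testable without genome downloads, a Pfam
release, or an HMMER run: a Yule (pure-birth) process generates ultrametric
trees like the time-calibrated trees the pipeline consumes; a per-branch
birth-death process over domain copies generates leaf repertoires together
with a replayable log of every unit gain/duplication/loss event; genomes
with planted ORFs exercise the ORF caller; and domtblout fixtures with
E-values straddling the inclusion threshold exercise the annotation stage.

The repertoire process is an exact Gillespie walk along each branch: with
copy count C(t), gains arrive at ``gain_rate`` (per unit branch length,
drawing a fresh name from the domain pool), duplications at
``dup_rate * C(t)`` and losses at ``loss_rate * C(t)``, so the exposure is
re-evaluated after every event and a loss can never drive a count negative.
All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

import io

from .domain_annotation import DomainHit, DomainRepertoire, write_domtblout
from .genome_orf import GenomeSequence
from .phylo_parsimony import PhyloNode, Phylogeny, _autoname

__all__ = [
    "EvolutionParameters",
    "TruthEvent",
    "TruthLog",
    "PlantedGenome",
    "simulate_yule_tree",
    "simulate_repertoire_evolution",
    "plant_orfs",
    "make_domtblout_fixture",
    "default_parameters",
]


@dataclass
class EvolutionParameters:
    """Rates and initial state of the repertoire birth-death process.

    Rates are events per unit branch length: ``gain_rate`` per domain pool
    (one novel family appearing), ``dup_rate`` and ``loss_rate`` per existing
    copy. ``max_events_per_domain`` caps the number of unit events any one
    domain experiences across the whole tree (saturated domains drop out of
    the dup/loss exposure); None means uncapped.
    """

    gain_rate: float = 0.1
    dup_rate: float = 0.2
    loss_rate: float = 0.2
    root_repertoire: dict[str, int] = field(default_factory=dict)
    domain_pool: list[str] = field(default_factory=list)
    seed: int = 0
    max_events_per_domain: int | None = None

    def __post_init__(self) -> None:
        if min(self.gain_rate, self.dup_rate, self.loss_rate) < 0:
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class TruthEvent:
    """One unit event on the branch above ``child_label``."""

    child_label: str
    domain: str
    event_type: str  # gain | duplication | loss
    count: int = 1


@dataclass
class TruthLog:
    """Unit events in simulation order; replayable from the root repertoire."""

    events: list[TruthEvent] = field(default_factory=list)

    def replay(
        self, t: Phylogeny, root_repertoire: dict[str, int]
    ) -> dict[str, dict[str, int]]:
        """Re-derive every leaf repertoire by applying the log along the tree."""
        by_child: dict[str, list[TruthEvent]] = {}
        for ev in self.events:
            by_child.setdefault(ev.child_label, []).append(ev)
        out: dict[str, dict[str, int]] = {}

        def walk(node: PhyloNode, state: dict[str, int]) -> None:
            for ev in by_child.get(node.label, []):
                if ev.event_type in ("gain", "duplication"):
                    state[ev.domain] = state.get(ev.domain, 0) + ev.count
                elif ev.event_type == "loss":
                    state[ev.domain] = state.get(ev.domain, 0) - ev.count
                    if state[ev.domain] < 0:
                        raise ValueError(f"log drives {ev.domain} negative at {node.label}")
                    if state[ev.domain] == 0:
                        del state[ev.domain]
                else:
                    raise ValueError(f"unknown event type {ev.event_type!r}")
            if node.is_leaf:
                out[node.label] = dict(state)
            for child in node.children:
                walk(child, dict(state))

        walk(t.root, dict(root_repertoire))
        return out


def simulate_yule_tree(n_leaves: int, birth_rate: float, seed: int) -> Phylogeny:
    """Rooted binary ultrametric tree under a pure-birth (Yule) process.

    The root splits at time 0; while k lineages are extant the next split
    waits Exponential(birth_rate * k), and the tree is cut after the waiting
    time drawn with all n lineages. Leaves are labeled T1..Tn; expected root
    height is sum_{k=2..n} 1/(k * birth_rate).
    """
    if n_leaves < 2:
        raise ValueError("n_leaves must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    root = PhyloNode(label="")
    active: list[tuple[PhyloNode, float]] = []
    for _ in range(2):
        child = root.add_child(PhyloNode(label=""))
        active.append((child, 0.0))
    t = 0.0
    while True:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        if k == n_leaves:
            break
        idx = int(rng.integers(k))
        node, attach = active.pop(idx)
        node.branch_length = t - attach
        for _ in range(2):
            active.append((node.add_child(PhyloNode(label="")), t))
    for i, (node, attach) in enumerate(active, start=1):
        node.label = f"T{i}"
        node.branch_length = t - attach
    _autoname(root)
    return Phylogeny(root)


def simulate_repertoire_evolution(
    t: Phylogeny, p: EvolutionParameters
) -> tuple[dict[str, DomainRepertoire], TruthLog]:
    """Evolve the root repertoire down the tree; return leaves + event log."""
    for _, child in t.branches():
        if child.branch_length is None:
            raise ValueError(f"branch above {child.label!r} has no length")
    rng = np.random.default_rng(p.seed)
    pool = iter(p.domain_pool)
    event_counts: dict[str, int] = {}
    log = TruthLog()
    leaves: dict[str, DomainRepertoire] = {}
    cap = p.max_events_per_domain

    def eligible(state: dict[str, int]) -> dict[str, int]:
        if cap is None:
            return state
        return {d: c for d, c in state.items() if event_counts.get(d, 0) < cap}

    def record(child_label: str, domain: str, kind: str) -> None:
        event_counts[domain] = event_counts.get(domain, 0) + 1
        log.events.append(TruthEvent(child_label, domain, kind))

    def weighted_choice(counts: dict[str, int]) -> str:
        names = sorted(counts)
        weights = np.array([counts[n] for n in names], dtype=float)
        return names[int(rng.choice(len(names), p=weights / weights.sum()))]

    def walk(node: PhyloNode, state: dict[str, int]) -> None:
        if node.parent is not None:
            elapsed = 0.0
            length = node.branch_length
            while True:
                exposed = eligible(state)
                copies = sum(exposed.values())
                # A gained domain starts with one event on its tally, so gains
                # are allowed whenever the cap admits at least one event.
                r_gain = p.gain_rate if (cap is None or cap >= 1) else 0.0
                r_dup = p.dup_rate * copies
                r_loss = p.loss_rate * copies
                total = r_gain + r_dup + r_loss
                if total == 0:
                    break
                elapsed += rng.exponential(1.0 / total)
                if elapsed > length:
                    break
                u = rng.random() * total
                if u < r_gain:
                    name = next(pool, None)
                    if name is None:
                        raise ValueError("domain_pool exhausted")
                    state[name] = 1
                    record(node.label, name, "gain")
                elif u < r_gain + r_dup:
                    d = weighted_choice(exposed)
                    state[d] += 1
                    record(node.label, d, "duplication")
                else:
                    d = weighted_choice(exposed)
                    state[d] -= 1
                    if state[d] == 0:
                        del state[d]
                    record(node.label, d, "loss")
        if node.is_leaf:
            leaves[node.label] = DomainRepertoire(taxon=node.label, counts=dict(state))
        for child in node.children:
            walk(child, dict(state))

    walk(t.root, dict(p.root_repertoire))
    return leaves, log


# Deterministic reverse translation: lexicographically smallest codon per aa.
_AA_TO_CODON = {
    "A": "GCA", "C": "TGC", "D": "GAC", "E": "GAA", "F": "TTC", "G": "GGA",
    "H": "CAC", "I": "ATA", "K": "AAA", "L": "CTA", "M": "ATG", "N": "AAC",
    "P": "CCA", "Q": "CAA", "R": "AGA", "S": "AGC", "T": "ACA", "V": "GTA",
    "W": "TGG", "Y": "TAC",
}


@dataclass
class PlantedGenome:
    """A synthetic genome plus the forward-strand coordinates of planted ORFs."""

    genome: GenomeSequence
    planted: list[tuple[int, int, str]]  # (start, end incl. stop, protein)


def _spacer(length: int, rng: np.random.Generator) -> str:
    """Stop-rich spacer: random A/T with TAA stamped at offsets 0, 4, 8.

    The stamps put a stop codon in every reading frame; the absence of G
    means the spacer contains no ATG (and, being A/T only, none on the
    reverse strand either), so spacers can neither open nor shadow an ORF.
    """
    length = max(length, 11)
    chars = list(rng.choice(list("AT"), size=length))
    for off in (0, 4, 8):
        chars[off : off + 3] = "TAA"
    return "".join(chars)


def plant_orfs(
    proteins: Sequence[str], spacer_length: int = 30, seed: int = 0
) -> PlantedGenome:
    """Concatenate reverse-translated ORFs separated by stop-rich spacers.

    Each protein becomes ATG + codons + TAA; every planted ORF is exactly
    recoverable by the ORF caller in maximal mode, because spacers contain
    in-frame stops in all frames and no start codons.
    """
    if not proteins:
        raise ValueError("proteins must be non-empty")
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    planted: list[tuple[int, int, str]] = []
    pos = 0
    for aa in proteins:
        bad = set(aa) - set(_AA_TO_CODON)
        if bad:
            raise ValueError(f"cannot reverse-translate residues {sorted(bad)}")
        sp = _spacer(spacer_length, rng)
        parts.append(sp)
        pos += len(sp)
        orf = "ATG" + "".join(_AA_TO_CODON[a] for a in aa) + "TAA"
        parts.append(orf)
        planted.append((pos, pos + len(orf), "M" + aa))
        pos += len(orf)
    sp = _spacer(spacer_length, rng)
    parts.append(sp)
    genome = GenomeSequence(id="synthetic", organism="synthetic", seq="".join(parts))
    return PlantedGenome(genome=genome, planted=planted)


def make_domtblout_fixture(r: DomainRepertoire, decoys: int = 0, seed: int = 0) -> str:
    """domtblout text whose filtered repertoire is exactly ``r``.

    One passing hit (both E-values <= 1e-4) per repertoire copy, plus
    ``decoys`` failing hits: alternating between a bad conditional E-value
    with a good sequence E-value and vice versa, so the AND of the two
    inclusion criteria is exercised.
    """
    rng = np.random.default_rng(seed)

    def hit(name: str, query: str, seq_e: float, c_e: float) -> DomainHit:
        ali_from = int(rng.integers(5, 40))
        ali_len = int(rng.integers(20, 120))
        return DomainHit(
            target_name=name,
            target_accession=f"PF{rng.integers(0, 99999):05d}.1",
            tlen=int(rng.integers(50, 300)),
            query_name=query,
            query_accession="-",
            qlen=int(rng.integers(100, 900)),
            seq_evalue=seq_e,
            seq_score=float(np.round(rng.uniform(20, 300), 1)),
            seq_bias=float(np.round(rng.uniform(0, 5), 1)),
            domain_index=1,
            domain_total=1,
            c_evalue=c_e,
            i_evalue=c_e * 10,
            dom_score=float(np.round(rng.uniform(20, 300), 1)),
            dom_bias=float(np.round(rng.uniform(0, 5), 1)),
            hmm_from=1,
            hmm_to=ali_len,
            ali_from=ali_from,
            ali_to=ali_from + ali_len,
            env_from=max(1, ali_from - 3),
            env_to=ali_from + ali_len + 3,
            acc=float(np.round(rng.uniform(0.7, 1.0), 2)),
            description=f"{name} synthetic fixture hit",
        )

    hits: list[DomainHit] = []
    q = 0
    for name in sorted(r.counts):
        for _ in range(r.counts[name]):
            q += 1
            hits.append(
                hit(
                    name,
                    f"{r.taxon}|orf{q}",
                    float(10.0 ** -rng.uniform(5, 10)),
                    float(10.0 ** -rng.uniform(4, 10)),
                )
            )
    for k in range(decoys):
        q += 1
        if k % 2 == 0:
            seq_e, c_e = float(10.0 ** -rng.uniform(5, 10)), float(10.0 ** rng.uniform(-2, 0))
        else:
            seq_e, c_e = float(10.0 ** rng.uniform(-2, 1)), float(10.0 ** -rng.uniform(4, 10))
        hits.append(hit(f"DECOY_{k:03d}", f"{r.taxon}|orf{q}", seq_e, c_e))
    buf = io.StringIO()
    write_domtblout(hits, buf)
    return buf.getvalue()


def default_parameters(seed: int = 0, n_pool: int = 400) -> EvolutionParameters:
    """Study-scale defaults: a 12-family root repertoire (Ca_hom_mod plus
    eleven background families at 1-3 copies) and a pool of novel names."""
    root = {"Ca_hom_mod": 1}
    for i in range(1, 12):
        root[f"R{i:02d}"] = (i % 3) + 1
    pool = [f"N{i:03d}" for i in range(n_pool)]
    return EvolutionParameters(
        gain_rate=0.1,
        dup_rate=0.2,
        loss_rate=0.2,
        root_repertoire=root,
        domain_pool=pool,
        seed=seed,
    )
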