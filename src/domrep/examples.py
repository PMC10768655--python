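"""Worked example: CALHM6 Ca_hom_mod events on a 20-taxon tree.

The CALHM6 calcium channel carries a single Pfam domain, Ca_hom_mod. Its
published branch-event log across 20 eukaryote genomes — one gain, six
duplications, and fourteen losses — is a compact end-to-end check of the
event-calling machinery and the iTOL export, and is the worked example in
the README.

The tree below follows the published 20-organism topology (corals through
fishes, reptiles, birds, and mammals) with the internal-node numbering used
in the event log (n2 at the root).
"""

from __future__ import annotations

from .event_calling import BranchEventRecord
from .phylo_parsimony import Phylogeny, parse_newick

__all__ = [
    "CALHM6_TREE_NEWICK",
    "calhm6_tree",
    "calhm6_event_log",
    "CALHM6_BRANCH_COUNTS",
]

CALHM6_TREE_NEWICK = (
    "(Stylophora_pistillata,(Exaiptasia_diaphana,"
    "(((Austrofundulus_limnaeus,(Lates_calcarifer,Maylandia_zebra)n8)n6,"
    "(Salmo_salar,Danio_rerio)n11)n5,"
    "(((Pogona_vitticeps,Python_bivittatus)n36,"
    "(Gallus_gallus,(Ficedula_albicollis,(Falco_cherrug,Columba_livia)n31)n30)n29)n28,"
    "(((Camelus_dromedarius,Bos_mutus)n17,"
    "(Canis_lupus_familiaris,(Felis_catus,Homo_sapiens)n22)n20)n16,"
    "(Rattus_norvegicus,Microtus_ochrogaster)n25)n15)n14)n4)n3)n2;"
)


def calhm6_tree() -> Phylogeny:
    """The 20-taxon tree the Ca_hom_mod event log is drawn on."""
    return parse_newick(CALHM6_TREE_NEWICK)


def calhm6_event_log() -> list[BranchEventRecord]:
    """The seven published Ca_hom_mod branch events (1 gain, 6 dup, 14 loss)."""
    return [
        BranchEventRecord("n2", "n3", "Ca_hom_mod", gains=1),
        BranchEventRecord("n3", "n4", "Ca_hom_mod", duplications=3),
        BranchEventRecord("n14", "n15", "Ca_hom_mod", duplications=1),
        BranchEventRecord("n11", "Salmo_salar", "Ca_hom_mod", losses=4),
        BranchEventRecord("n28", "n36", "Ca_hom_mod", losses=5),
        BranchEventRecord("n20", "n22", "Ca_hom_mod", losses=5),
        BranchEventRecord("n29", "n30", "Ca_hom_mod", duplications=2),
    ]


# Reconstructed ancestral/descendant Ca_hom_mod copy counts for the branches
# whose counts are pinned down by the published reconstruction.
CALHM6_BRANCH_COUNTS: dict[tuple[str, str], tuple[int, int]] = {
    ("n3", "n4"): (1, 4),
    ("n11", "Salmo_salar"): (4, 0),
    ("n29", "n30"): (5, 7),
}
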