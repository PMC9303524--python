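"""Bundled worked-example fixtures.

Two kinds of objects live here:

* the published contingency tables and category counts of the lamprey
  linkage-group synteny analysis, entered verbatim from the printed study
  tables (cell counts only; all p-values are recomputed at run time); and
* **synthetic** reconstructions of alignment blocks.  The original
  supplementary alignment is not redistributed here; the blocks built by
  :func:`hmg_box_block` and :func:`exon3_block` are generated sequences
  that carry only the documented residue structure (which subfamily is
  distinguished by which residues at which columns) on an arbitrary
  background, so column-level conclusions - not sequence-level ones - are
  reproducible from them.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .ancestry import ABSENT, FeatureMatrix, UNKNOWN, extract_features
from .model import AlignmentBlock, GeneModel, ParalogTree
from .synteny import ContingencyTable2x2, NeighborhoodAssignment, OTHER, SHARED

__all__ = [
    "NEIGHBORHOODS",
    "TCF_CHROMOSOMES",
    "table2_tables",
    "table2_assignment",
    "lamprey_category_counts",
    "tcf_gene_models",
    "tcf_paralog_tree",
    "CYCLOSTOME_TAXA",
    "tcf_feature_matrix",
    "hmg_box_block",
    "exon3_block",
    "HMG_EXPECTED_DIAGNOSTICS",
]

NEIGHBORHOODS = ("TCF7", "LEF1", "TCF7L1", "TCF7L2")
#: lamprey chromosomes carrying a TCF gene (TCFa, TCFb, TCFc respectively)
TCF_CHROMOSOMES = ("chr8", "chr41", "chr68")

# (chromosome, neighborhood) -> (a, b, c, d): label-on-chromosome,
# label-elsewhere, other-on-chromosome, other-elsewhere.
_TABLE2_CELLS = {
    ("chr8", "TCF7"): (6, 13, 46, 91),
    ("chr8", "LEF1"): (15, 31, 37, 73),
    ("chr8", "TCF7L1"): (7, 3, 45, 101),
    ("chr8", "TCF7L2"): (21, 25, 31, 79),
    ("chr41", "TCF7"): (7, 12, 36, 101),
    ("chr41", "LEF1"): (20, 26, 23, 87),
    ("chr41", "TCF7L1"): (2, 8, 41, 105),
    ("chr41", "TCF7L2"): (10, 36, 33, 77),
    ("chr68", "TCF7"): (1, 18, 11, 126),
    ("chr68", "LEF1"): (1, 45, 11, 99),
    ("chr68", "TCF7L1"): (0, 10, 12, 134),
    ("chr68", "TCF7L2"): (6, 40, 6, 104),
}


def table2_tables() -> dict:
    """The published 2x2 tables: (chromosome, neighborhood) -> table."""
    return {k: ContingencyTable2x2(*v) for k, v in _TABLE2_CELLS.items()}


def lamprey_category_counts() -> dict:
    """Published split of the 156 lamprey linkage-group orthologs."""
    return {"TCF7": 19, "LEF1": 46, "TCF7L1": 10, "TCF7L2": 46, SHARED: 11, OTHER: 24}


def table2_assignment() -> NeighborhoodAssignment:
    """A synthetic per-family assignment consistent with every published cell.

    The study reports only the category totals and the 2x2 cells; this
    reconstruction distributes 156 pseudo-families over the neighborhood
    labels and the three TCF-containing chromosomes so that
    ``build_contingency`` reproduces each printed table exactly.
    """
    on_chrom = {
        "TCF7": {"chr8": 6, "chr41": 7, "chr68": 1},
        "LEF1": {"chr8": 15, "chr41": 20, "chr68": 1},
        "TCF7L1": {"chr8": 7, "chr41": 2, "chr68": 0},
        "TCF7L2": {"chr8": 21, "chr41": 10, "chr68": 6},
        SHARED: {"chr8": 2, "chr41": 2, "chr68": 2},
        OTHER: {"chr8": 1, "chr41": 2, "chr68": 2},
    }
    totals = lamprey_category_counts()
    label: dict[str, str] = {}
    chroms: dict[str, frozenset] = {}
    i = 0
    for category in list(NEIGHBORHOODS) + [SHARED, OTHER]:
        placed = 0
        for chrom, k in on_chrom[category].items():
            for _ in range(k):
                i += 1
                fam = f"clg{i:03d}"
                label[fam] = category
                chroms[fam] = frozenset({chrom})
                placed += 1
        for _ in range(totals[category] - placed):
            i += 1
            fam = f"clg{i:03d}"
            label[fam] = category
            chroms[fam] = frozenset({"chr_other"})
    return NeighborhoodAssignment(label, chroms, "P_marinus", NEIGHBORHOODS)


# ---------------------------------------------------------------------------
# Gene models, tree, feature matrix
# ---------------------------------------------------------------------------

CYCLOSTOME_TAXA = ("TCFa", "TCFb", "TCFc", "TCFd")


def _data_path(name: str):
    return resources.files("paralogon.data").joinpath(name)


def tcf_gene_models() -> list[GeneModel]:
    """Composite per-subfamily gene models bundled with the package."""
    from .io import read_gene_models

    with resources.as_file(_data_path("tcf_gene_models.yaml")) as path:
        return read_gene_models(path)


def tcf_paralog_tree() -> ParalogTree:
    """Rooted subfamily topology ((TCF7,LEF1),(TCF7L1,TCF7L2)) + outgroups."""
    return ParalogTree.from_newick(_data_path("tcf_paralog_tree.nwk").read_text())


def tcf_feature_matrix(include_cyclostomes: bool = True) -> FeatureMatrix:
    """Character matrix over the bundled gene models.

    The generic N-type isoform character is split into two lineage
    characters (LEF1-type vs TCF7L2-type N), since their homology is
    unresolved; each then records an independent origin.
    """
    models = tcf_gene_models()
    if not include_cyclostomes:
        models = [m for m in models if m.gene_id not in CYCLOSTOME_TAXA]
    matrix = extract_features(models)
    base = matrix.column("ISOFORM_N")
    col_lef1 = {
        t: (base[t] if t == "LEF1" else (UNKNOWN if base[t] == UNKNOWN else ABSENT))
        for t in matrix.taxa
    }
    col_l2 = {
        t: (base[t] if t == "TCF7L2" else (UNKNOWN if base[t] == UNKNOWN else ABSENT))
        for t in matrix.taxa
    }
    matrix = matrix.without_characters(["ISOFORM_N"])
    matrix = matrix.with_character("ISOFORM_N_LEF1", col_lef1)
    matrix = matrix.with_character("ISOFORM_N_TCF7L2", col_l2)
    return matrix


# ---------------------------------------------------------------------------
# Synthetic alignment blocks
# ---------------------------------------------------------------------------

_GNATHOSTOME_SPECIES = ("Hsap", "Mmus", "Ggal", "Xtro", "Locu", "Drer")
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: the documented subfamily-diagnostic columns of the HMG-box block
HMG_EXPECTED_DIAGNOSTICS = {
    ("TCF7", 2): frozenset({"T", "V"}),
    ("LEF1", 20): frozenset({"N"}),
    ("TCF7", 22): frozenset({"I"}),
    ("TCF7L1", 43): frozenset({"N", "S"}),
    ("TCF7L1", 64): frozenset({"S"}),
}

_HMG_WIDTH = 65
# consensus must avoid every diagnostic / divergent residue at its column
_HMG_FORBIDDEN = {2: {"T", "V"}, 3: {"V"}, 20: {"N"}, 22: {"I"}, 43: {"N", "S"}, 45: {"T"}, 64: {"S"}}
_TCFC_PRIVATE_COLUMNS = (10, 15, 30, 50, 55, 60)


def _consensus(width: int, forbidden: dict, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    cons = rng.choice(_AA, size=width)
    for col, bad in forbidden.items():
        allowed = [a for a in _AA if a not in bad]
        cons[col - 1] = allowed[int(rng.integers(len(allowed)))]
    return cons


def _variant(cons: np.ndarray, substitutions: dict) -> str:
    seq = cons.copy()
    for col, residue in substitutions.items():
        seq[col - 1] = residue
    return "".join(seq)


def hmg_box_block(include_cyclostomes: bool = False) -> AlignmentBlock:
    """Synthetic HMG-box alignment block (65 columns).

    Gnathostome sequences reproduce the documented structure: TCF7 carries
    T or V at column 2 and I at 22; LEF1 carries N at 20; TCF7L1 carries N
    or S at 43 and S at 64; TCF7L2 equals the consensus.  With
    ``include_cyclostomes`` the lamprey/hagfish genes are added with their
    described residue mixtures (TCFb: I@22 + S@64; TCFc: I@22 plus eight
    further substitutions; TCFa/TCFd: consensus, with one divergent TCFd
    sequence at column 47).  The background consensus itself is arbitrary.
    """
    cons = _consensus(_HMG_WIDTH, _HMG_FORBIDDEN, seed=650)
    sequences: dict[str, str] = {}
    labels: dict[str, str] = {}

    def add(subfamily: str, species: str, subs: dict) -> None:
        sid = f"{species}_{subfamily}"
        sequences[sid] = _variant(cons, subs)
        labels[sid] = subfamily

    for i, sp in enumerate(_GNATHOSTOME_SPECIES):
        add("TCF7", sp, {2: "T" if i % 2 == 0 else "V", 22: "I"})
        add("LEF1", sp, {20: "N"})
        add("TCF7L1", sp, {43: "N" if i % 2 == 0 else "S", 64: "S"})
        add("TCF7L2", sp, {})
    if include_cyclostomes:
        for sp in ("Pmar", "Etri", "Lrei", "Ebur"):
            add("TCFa", sp, {})
            add("TCFb", sp, {22: "I", 64: "S"})
        rng = np.random.default_rng(651)
        tcfc_subs = {3: "V", 45: "T", 22: "I"}
        for col in _TCFC_PRIVATE_COLUMNS:
            alt = [a for a in _AA if a != cons[col - 1]]
            tcfc_subs[col] = alt[int(rng.integers(len(alt)))]
        for sp in ("Pmar", "Lpla"):
            add("TCFc", sp, tcfc_subs)
        alt47 = [a for a in _AA if a != cons[46]]
        add("TCFd", "Lpla", {47: alt47[0]})
        add("TCFd", "Ebur", {})
    return AlignmentBlock("HMG-box", sequences, labels)


_EXON3_WIDTH = 40
_EXON3_MET_COLUMN = 33


def exon3_block() -> AlignmentBlock:
    """Synthetic exon III alignment block (40 columns).

    Column 33 carries the internal start methionine in every gnathostome
    subfamily and in cyclostome TCFa/TCFb/TCFc, but not in TCFd nor in the
    invertebrate sequences.
    """
    cons = _consensus(_EXON3_WIDTH, {_EXON3_MET_COLUMN: {"M"}}, seed=333)
    sequences: dict[str, str] = {}
    labels: dict[str, str] = {}

    def add(subfamily: str, species: str, has_met: bool) -> None:
        sid = f"{species}_{subfamily}"
        sequences[sid] = _variant(cons, {_EXON3_MET_COLUMN: "M"} if has_met else {})
        labels[sid] = subfamily

    for sp in _GNATHOSTOME_SPECIES:
        for subfamily in NEIGHBORHOODS:
            add(subfamily, sp, True)
    for sp in ("Pmar", "Ebur"):
        add("TCFa", sp, True)
        add("TCFb", sp, True)
    for sp in ("Pmar", "Lpla"):
        add("TCFc", sp, True)
    for sp in ("Lpla", "Ebur"):
        add("TCFd", sp, False)
    for sp, lineage in (("Cint", "Invertebrate"), ("Blan", "Invertebrate"), ("Spur", "Invertebrate")):
        add(lineage, sp, False)
    return AlignmentBlock("exonIII", sequences, labels)
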