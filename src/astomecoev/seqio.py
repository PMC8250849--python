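"""Alignment and tree I/O, p-distances, and divergence summaries.

Pairwise p-distances follow the pairwise-deletion convention: for each pair of
sequences, alignment columns where either member carries a gap, an ``N`` or an
IUPAC ambiguity code are excluded, and the distance is the proportion of
mismatches over the remaining compared sites.  Pairs with no comparable site
are reported as undefined (``NaN``), never silently zeroed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "MultipleAlignment",
    "DistanceMatrix",
    "DivergenceSummary",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "translate_invertebrate_mito",
    "p_distance_matrix",
    "divergence_summary",
    "read_newick",
    "cophenetic_distances",
    "write_distance_tsv",
    "write_distance_phylip",
    "read_distance_tsv",
]

_DNA_UNAMBIGUOUS = set("ACGT")
_DNA_ALLOWED = set("ACGTUNRYSWKMBDHV-")


@dataclass
class MultipleAlignment:
    """Equal-length sequences with ordered, unique identifiers.

    ``U`` is normalised to ``T`` and lowercase input is uppercased so that DNA
    and RNA alignments are directly comparable.
    """

    ids: list[str]
    rows: list[str]
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError("empty alignment")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence identifiers")
        self.rows = [r.upper().replace("U", "T") if self.alphabet == "dna" else r.upper()
                     for r in self.rows]
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with labelled rows/columns.

    Undefined entries (no comparable sites under pairwise deletion) are NaN.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("nonzero diagonal")
        finite = ~np.isnan(self.values)
        sym = finite & finite.T
        if not np.allclose(self.values[sym], self.values.T[sym], atol=1e-12):
            raise ValueError("matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if math.isnan(self.values[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out


@dataclass
class DivergenceSummary:
    """Within-group and between-group divergence ranges, in proportions."""

    intra: dict[str, tuple[float, float]] = field(default_factory=dict)
    inter: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    units: str = "proportion"

    def as_percent(self) -> "DivergenceSummary":
        if self.units == "percent":
            return self
        return DivergenceSummary(
            intra={g: (lo * 100.0, hi * 100.0) for g, (lo, hi) in self.intra.items()},
            inter={k: (lo * 100.0, hi * 100.0) for k, (lo, hi) in self.inter.items()},
            units="percent",
        )


def read_fasta_alignment(path: str | Path, alphabet: str = "dna") -> MultipleAlignment:
    """Read an aligned FASTA file; order preserved, duplicates and ragged rows rejected."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty or non-FASTA input: {path}")
    ids = [r.id for r in records]
    rows = [str(r.seq) for r in records]
    return MultipleAlignment(ids=ids, rows=rows, alphabet=alphabet)


def write_fasta_alignment(aln: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.ids, aln.rows):
            fh.write(f">{sid}\n{row}\n")


_TABLE5 = CodonTable.unambiguous_dna_by_id[5]


def translate_invertebrate_mito(nt: str, frame: int = 1) -> str:
    """Translate a DNA sequence under the invertebrate mitochondrial code.

    NCBI translation table 5: AGA/AGG -> Ser, ATA -> Met, TGA -> Trp.  The
    incomplete trailing codon is dropped.  A codon made entirely of gaps
    translates to ``-``; codons containing ``N``, ambiguity codes or partial
    gaps translate to ``X``; stop codons to ``*``.
    """
    if frame not in (1, 2, 3):
        raise ValueError("frame must be 1, 2 or 3")
    seq = nt.upper().replace("U", "T")
    bad = set(seq) - _DNA_ALLOWED
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    seq = seq[frame - 1:]
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i:i + 3]
        if codon == "---":
            out.append("-")
        elif set(codon) <= _DNA_UNAMBIGUOUS:
            if codon in _TABLE5.stop_codons:
                out.append("*")
            else:
                out.append(_TABLE5.forward_table[codon])
        else:
            out.append("X")
    return "".join(out)


def _encode(aln: MultipleAlignment) -> np.ndarray:
    """Encode sequences as integers; anything but unambiguous ACGT becomes -1."""
    mapping = np.full(256, -1, dtype=np.int8)
    for k, base in enumerate("ACGT"):
        mapping[ord(base)] = k
    arr = np.frombuffer("".join(aln.rows).encode("ascii"), dtype=np.uint8)
    return mapping[arr].reshape(aln.n_sequences, aln.n_sites)


def p_distance_matrix(aln: MultipleAlignment) -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion of gaps/N/ambiguities.

    Pairs sharing no comparable site are undefined and returned as NaN.
    """
    if aln.n_sequences < 2:
        raise ValueError("need at least two sequences")
    enc = _encode(aln)
    n = aln.n_sequences
    dm = np.zeros((n, n))
    valid = enc >= 0
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            compared = int(both.sum())
            if compared == 0:
                dm[i, j] = dm[j, i] = np.nan
            else:
                mism = int((enc[i][both] != enc[j][both]).sum())
                dm[i, j] = dm[j, i] = mism / compared
    return DistanceMatrix(labels=list(aln.ids), values=dm)


def divergence_summary(dm: DistanceMatrix,
                       grouping: Mapping[str, str]) -> DivergenceSummary:
    """Within-group and between-group-pair (min, max) divergence ranges.

    Singleton groups have no within-group comparison and are absent from the
    intraspecific ranges; undefined (NaN) pairs are excluded from all ranges.
    """
    missing = [lab for lab in dm.labels if lab not in grouping]
    if missing:
        raise ValueError(f"labels without group assignment: {missing}")
    intra: dict[str, list[float]] = {}
    inter: dict[tuple[str, str], list[float]] = {}
    for i in range(dm.n):
        for j in range(i + 1, dm.n):
            v = dm.values[i, j]
            if math.isnan(v):
                continue
            gi, gj = grouping[dm.labels[i]], grouping[dm.labels[j]]
            if gi == gj:
                intra.setdefault(gi, []).append(v)
            else:
                inter.setdefault(tuple(sorted((gi, gj))), []).append(v)
    return DivergenceSummary(
        intra={g: (min(v), max(v)) for g, v in intra.items()},
        inter={k: (min(v), max(v)) for k, v in inter.items()},
    )


def read_newick(path: str | Path, require_branch_lengths: bool = False) -> dendropy.Tree:
    """Read a Newick tree; duplicate tip labels rejected."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip labels in tree: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels in tree")
    if require_branch_lengths:
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node and edge.length is None:
                raise ValueError("tree is missing branch lengths")
    return tree


def cophenetic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Tip-to-tip path-length (cophenetic/patristic) distances from a tree."""
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            raise ValueError("tree is missing branch lengths")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            dm[i, j] = dm[j, i] = d
    return DistanceMatrix(labels=labels, values=dm)


def write_distance_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(dm.labels) + "\n")
        for lab, row in zip(dm.labels, dm.values):
            fh.write(lab + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_distance_tsv(path: str | Path) -> DistanceMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        rows = []
        labels = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if labels != header:
        raise ValueError("row and column labels disagree")
    return DistanceMatrix(labels=labels, values=np.array(rows))


def write_distance_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """Square PHYLIP distance format."""
    with open(path, "w") as fh:
        fh.write(f"{dm.n}\n")
        for lab, row in zip(dm.labels, dm.values):
            fh.write(f"{lab:<10s} " + " ".join(f"{v:.6f}" for v in row) + "\n")
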