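"""ITS2 sequence-structure characterisation and compensatory base changes.

The ITS2 molecule of astome ciliates folds into a central loop radiating
helices I-III (one taxon exhibits only two helices).  This module parses
sequence + dot-bracket pairs, tallies the per-domain features used to
characterise the molecules (lengths, GC content, paired/unpaired counts,
bulges, GU wobble pairs), counts compensatory (CBC) and hemi-compensatory
(hemi-CBC) base changes between aligned taxa under a shared pairing
annotation, and computes per-position nucleotide frequencies for structure
logos.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Its2Structure",
    "StructureFeatures",
    "CbcCount",
    "parse_structure",
    "structure_features",
    "count_cbc",
    "position_frequencies",
    "feature_summary",
]

_CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
_GU = {("G", "U"), ("U", "G")}


@dataclass
class Its2Structure:
    """RNA sequence with dot-bracket pairing and optional helix spans.

    ``helix_spans`` maps helix names (``I``, ``II``, ``III``) to 1-based
    inclusive (start, end) intervals; helix III may be absent for taxa with
    only two helices.
    """

    sequence: str
    pairing: str
    pairs: list[tuple[int, int]]  # 1-based, i < j
    helix_spans: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)


def parse_structure(seq: str, dotbracket: str,
                    helix_spans: Optional[Mapping[str, tuple[int, int]]] = None
                    ) -> Its2Structure:
    """Stack-match a dot-bracket string against its sequence.

    Raises on length mismatch, unbalanced brackets, or helix spans that
    overlap or fall outside the sequence.
    """
    seq = seq.upper().replace("T", "U")
    if len(seq) != len(dotbracket):
        raise ValueError("sequence and structure lengths differ")
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(dotbracket, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {pos}")
            pairs.append((stack.pop(), pos))
        elif ch not in ".-":
            raise ValueError(f"invalid structure character {ch!r}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    spans = dict(helix_spans or {})
    claimed: set[int] = set()
    for name, (lo, hi) in spans.items():
        if not (1 <= lo <= hi <= len(seq)):
            raise ValueError(f"helix {name} span out of bounds")
        span = set(range(lo, hi + 1))
        if span & claimed:
            raise ValueError(f"helix {name} overlaps another span")
        claimed |= span
    return Its2Structure(sequence=seq, pairing=dotbracket,
                         pairs=sorted(pairs), helix_spans=spans)


@dataclass
class StructureFeatures:
    total_length: int
    gc_content: float                       # percent
    helix_lengths: dict[str, int]           # base pairs per helix
    central_loop_unpaired: Optional[int]
    terminal_loop_unpaired: dict[str, int]  # per helix
    bulge_unpaired: dict[str, int]          # per helix
    n_bulges_helix_iii: Optional[int]
    n_gu_pairs: int
    n_paired: int
    n_unpaired: int


def structure_features(s: Its2Structure) -> StructureFeatures:
    """Per-domain base-pair and unpaired-nucleotide tallies plus GC content.

    Helix length is the number of base pairs with both partners inside the
    helix span; the terminal loop is the unpaired stretch enclosed by the
    innermost pair; other unpaired positions inside a span are bulge/internal
    loop nucleotides.  Without helix spans only the global metrics are
    produced.
    """
    n = s.length
    gc = 100.0 * sum(1 for c in s.sequence if c in "GC") / n
    paired_pos = {p for pr in s.pairs for p in pr}
    n_gu = sum(1 for i, j in s.pairs
               if (s.sequence[i - 1], s.sequence[j - 1]) in _GU)
    helix_lengths: dict[str, int] = {}
    terminal: dict[str, int] = {}
    bulges: dict[str, int] = {}
    n_bulges_iii: Optional[int] = None
    central: Optional[int] = None
    if s.helix_spans:
        in_any_span = set()
        for name, (lo, hi) in sorted(s.helix_spans.items()):
            span = range(lo, hi + 1)
            in_any_span.update(span)
            span_pairs = [(i, j) for i, j in s.pairs
                          if lo <= i <= hi and lo <= j <= hi]
            helix_lengths[name] = len(span_pairs)
            unpaired = [p for p in span if p not in paired_pos]
            if span_pairs:
                inner_i = max(i for i, _ in span_pairs)
                inner_j = min(j for _, j in span_pairs if j > inner_i)
                term = [p for p in unpaired if inner_i < p < inner_j]
            else:
                term = []
            terminal[name] = len(term)
            bulge_pos = sorted(set(unpaired) - set(term))
            bulges[name] = len(bulge_pos)
            if name.upper() in ("III", "3"):
                runs = 0
                prev = None
                for p in bulge_pos:
                    if prev is None or p != prev + 1:
                        runs += 1
                    prev = p
                n_bulges_iii = runs
        central = sum(1 for p in range(1, n + 1)
                      if p not in in_any_span and p not in paired_pos)
    return StructureFeatures(
        total_length=n,
        gc_content=gc,
        helix_lengths=helix_lengths,
        central_loop_unpaired=central,
        terminal_loop_unpaired=terminal,
        bulge_unpaired=bulges,
        n_bulges_helix_iii=n_bulges_iii,
        n_gu_pairs=n_gu,
        n_paired=len(paired_pos),
        n_unpaired=n - len(paired_pos),
    )


@dataclass
class CbcCount:
    n_cbc: int
    n_hemi_cbc: int
    compared_pairs: int

    def __post_init__(self) -> None:
        if self.n_cbc + self.n_hemi_cbc > self.compared_pairs:
            raise ValueError("more changes than compared pairs")


def count_cbc(seq_a: str, seq_b: str, pairing: str) -> CbcCount:
    """Compensatory and hemi-compensatory base changes under a shared pairing.

    Both taxa must form canonical pairs (AU, UA, GC, CG, GU, UG) at a shared
    pair for it to be compared: a CBC changes both partners, a hemi-CBC
    exactly one.  Pairs broken in either taxon (non-canonical, or containing
    a gap) are skipped and do not enter ``compared_pairs``.  The count is
    symmetric in its two inputs.
    """
    a = seq_a.upper().replace("T", "U")
    b = seq_b.upper().replace("T", "U")
    if len(a) != len(b) or len(a) != len(pairing):
        raise ValueError("sequences and pairing must have equal length")
    struct = parse_structure("N" * len(pairing), pairing)
    n_cbc = n_hemi = compared = 0
    for i, j in struct.pairs:
        pa = (a[i - 1], a[j - 1])
        pb = (b[i - 1], b[j - 1])
        if pa not in _CANONICAL or pb not in _CANONICAL:
            continue
        compared += 1
        diff = (pa[0] != pb[0]) + (pa[1] != pb[1])
        if diff == 2:
            n_cbc += 1
        elif diff == 1:
            n_hemi += 1
    return CbcCount(n_cbc=n_cbc, n_hemi_cbc=n_hemi, compared_pairs=compared)


def position_frequencies(rows: Sequence[str]) -> pd.DataFrame:
    """Per-column frequencies of A/C/G/U/gap (each column sums to 1)."""
    if not rows:
        raise ValueError("empty input")
    norm = [r.upper().replace("T", "U") for r in rows]
    lengths = {len(r) for r in norm}
    if len(lengths) != 1:
        raise ValueError("rows must be aligned to equal length")
    n_sites = lengths.pop()
    symbols = ["A", "C", "G", "U", "-"]
    counts = np.zeros((n_sites, len(symbols)))
    for r in norm:
        for col, ch in enumerate(r):
            if ch in symbols:
                counts[col, symbols.index(ch)] += 1
            else:  # ambiguity codes count toward the gap/other bucket
                counts[col, symbols.index("-")] += 1
    freqs = counts / len(norm)
    return pd.DataFrame(freqs, columns=symbols,
                        index=pd.RangeIndex(1, n_sites + 1, name="position"))


def feature_summary(table: pd.DataFrame,
                    columns: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Min / max / arithmetic mean / SD summary rows over feature columns,
    the arithmetic used at the foot of ITS2 characterisation tables.

    The standard deviation is the sample SD (ddof=1).
    """
    cols = list(columns) if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    data = table[cols].astype(float)
    return pd.DataFrame({
        "minimum": data.min(),
        "maximum": data.max(),
        "arithmetic_mean": data.mean(),
        "standard_deviation": data.std(ddof=1),
    }).T
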