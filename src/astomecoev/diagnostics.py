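"""Diagnostic molecular signatures, barcode-gap assessment and prevalence.

A diagnostic signature lists alignment positions at which every member of a
query group shares one state that occurs in no member of the reference group
— the barcoding rule used to diagnose new species from alignments.  Barcode
gaps are assessed against per-marker divergence thresholds (1% for the
mitochondrial 16S rRNA gene, 3% for COI by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .seqio import DivergenceSummary, MultipleAlignment

__all__ = [
    "DiagnosticSignature",
    "OccurrenceTable",
    "BarcodeThresholds",
    "PrevalenceStats",
    "diagnostic_signature",
    "format_signature",
    "barcode_gap_report",
    "prevalence_stats",
    "round_percent",
]

_IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}


@dataclass
class DiagnosticSignature:
    marker: str
    positions: list[tuple[int, str]]  # 1-based alignment column, state

    def __post_init__(self) -> None:
        pos = [p for p, _ in self.positions]
        if pos != sorted(set(pos)):
            raise ValueError("positions must be strictly increasing")


@dataclass
class OccurrenceTable:
    """Per host species: examined and infected counts, symbiont species set."""

    hosts: list[str]
    examined: dict[str, int]
    infected: dict[str, int]
    symbionts: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for h in self.hosts:
            e = self.examined[h]
            i = self.infected[h]
            if e < 0 or i < 0 or i > e:
                raise ValueError(f"invalid counts for {h}: {i} infected of {e}")


@dataclass
class BarcodeThresholds:
    """Per-marker percent-divergence thresholds above which two groups are
    suggestive of different taxa."""

    thresholds: dict[str, float] = field(
        default_factory=lambda: {"16S": 1.0, "COI": 3.0})

    def __post_init__(self) -> None:
        for marker, t in self.thresholds.items():
            if t <= 0:
                raise ValueError(f"threshold for {marker} must be > 0")


def diagnostic_signature(aln: MultipleAlignment, query_ids: Sequence[str],
                         reference_ids: Sequence[str], marker: str = "",
                         allow_gap_state: bool = True) -> DiagnosticSignature:
    """Positions where all query rows share a state absent from the reference.

    The shared query state must be an unambiguous nucleotide (or, with
    ``allow_gap_state``, a gap shared by every query row).  Ambiguity codes in
    the reference are expanded, so a reference ``R`` blocks both ``A`` and
    ``G`` — a conservative rule that only removes candidate diagnostics.
    """
    qset, rset = set(query_ids), set(reference_ids)
    if not qset or not rset:
        raise ValueError("query and reference must be nonempty")
    if qset & rset:
        raise ValueError(f"query and reference overlap: {sorted(qset & rset)}")
    missing = (qset | rset) - set(aln.ids)
    if missing:
        raise ValueError(f"ids not in alignment: {sorted(missing)}")
    q_rows = [aln.row(i) for i in query_ids]
    r_rows = [aln.row(i) for i in reference_ids]
    positions: list[tuple[int, str]] = []
    for col in range(aln.n_sites):
        states = {row[col] for row in q_rows}
        if len(states) != 1:
            continue
        state = states.pop()
        if state not in "ACGT" and not (allow_gap_state and state == "-"):
            continue
        blocked = False
        for row in r_rows:
            ref = row[col]
            if ref == state:
                blocked = True
            elif state != "-" and ref in _IUPAC and state in _IUPAC[ref]:
                blocked = True
            if blocked:
                break
        if not blocked:
            positions.append((col + 1, state))
    return DiagnosticSignature(marker=marker, positions=positions)


def format_signature(sig: DiagnosticSignature) -> str:
    """Render as the conventional \"position state\" list, e.g. ``252 G, 289 C``."""
    return ", ".join(f"{p} {s}" for p, s in sig.positions)


def barcode_gap_report(summary: DivergenceSummary, thresholds: BarcodeThresholds,
                       marker: str) -> dict[tuple[str, str], str]:
    """Classify group pairs against the marker's divergence threshold.

    ``distinct``: the smallest between-group divergence exceeds the threshold
    and no within-group divergence does.  ``conflict``: a within-group range
    itself exceeds the threshold (cryptic-lineage situation).  ``ambiguous``:
    anything else (no barcode gap).
    """
    if marker not in thresholds.thresholds:
        raise KeyError(f"no threshold for marker {marker!r}")
    thr = thresholds.thresholds[marker]
    pct = summary.as_percent()
    report: dict[tuple[str, str], str] = {}
    for pair, (inter_min, _inter_max) in pct.inter.items():
        intra_max = max((pct.intra.get(g, (0.0, 0.0))[1] for g in pair), default=0.0)
        if intra_max > thr:
            report[pair] = "conflict"
        elif inter_min > thr:
            report[pair] = "distinct"
        else:
            report[pair] = "ambiguous"
    return report


@dataclass
class PrevalenceStats:
    per_host: dict[str, float | None]     # percent; None where examined == 0
    pooled: float                          # percent over all hosts
    positive_pooled: float                 # percent over hosts with >= 1 infection


def round_percent(value: float, ndigits: int = 2) -> float:
    """Half-up rounding for presentation of percentages."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def prevalence_stats(table: OccurrenceTable) -> PrevalenceStats:
    """Per-host, pooled and positive-species-pooled prevalence, in percent."""
    per_host: dict[str, float | None] = {}
    tot_e = tot_i = pos_e = pos_i = 0
    for h in table.hosts:
        e, i = table.examined[h], table.infected[h]
        per_host[h] = (100.0 * i / e) if e > 0 else None
        tot_e += e
        tot_i += i
        if i > 0:
            pos_e += e
            pos_i += i
    if tot_e == 0:
        raise ValueError("no examined individuals")
    pooled = 100.0 * tot_i / tot_e
    positive_pooled = 100.0 * pos_i / pos_e if pos_e > 0 else 0.0
    return PrevalenceStats(per_host=per_host, pooled=pooled,
                           positive_pooled=positive_pooled)


def read_occurrence_tsv(path: str | Path) -> OccurrenceTable:
    """TSV columns: host, examined, infected, symbionts (comma-separated, may
    be empty)."""
    hosts: list[str] = []
    examined: dict[str, int] = {}
    infected: dict[str, int] = {}
    symbionts: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            h = parts[0]
            hosts.append(h)
            examined[h] = int(parts[1])
            infected[h] = int(parts[2])
            symbionts[h] = set(filter(None, parts[3].split(","))) if len(parts) > 3 else set()
    return OccurrenceTable(hosts=hosts, examined=examined, infected=infected,
                           symbionts=symbionts)


def write_occurrence_tsv(table: OccurrenceTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("host\texamined\tinfected\tsymbionts\n")
        for h in table.hosts:
            fh.write(f"{h}\t{table.examined[h]}\t{table.infected[h]}\t"
                     f"{','.join(sorted(table.symbionts.get(h, set())))}\n")
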