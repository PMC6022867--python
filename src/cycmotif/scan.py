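"""Exhaustive variable-gap motif scanning over protein sequences.

The scanner enumerates *every* distinct (start, end) span of a sequence that
admits at least one element-by-element assignment of the motif, including
overlapping spans and multiple spans at the same start arising from
different gap-length choices.  One witness assignment is stored per span.

Matching is exact class membership: ambiguity codes (B, J, O, U, X, Z) and
``*`` never satisfy a named residue class; wildcard gap positions accept
any letter except ``*``.  All reported coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .motif import Motif

logger = logging.getLogger(__name__)

__all__ = [
    "SequenceRecord",
    "Match",
    "ScanSummary",
    "load_fasta",
    "find_matches",
    "scan_records",
    "scan_fasta",
    "compare_variants",
    "locus_id",
    "hits_to_tsv",
    "hits_to_gff3",
]


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence: id (header token up to first whitespace),
    free-text description, and an uppercase residue string."""

    id: str
    description: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Match:
    """One motif occurrence.  ``element_spans`` holds one (start, end) pair
    per motif element, 1-based inclusive; a zero-width optional gap is
    recorded as (p, p - 1).  The spans tile [start, end] in element order."""

    record_id: str
    start: int
    end: int
    matched: str
    element_spans: tuple

    @property
    def gap_choices(self) -> tuple:
        return tuple(e - s + 1 for s, e in self.element_spans)


@dataclass
class ScanSummary:
    """Aggregate scan result for one motif over one set of records."""

    motif_name: str
    n_records_scanned: int
    n_records_hit: int
    n_matches: int
    hits: list = field(default_factory=list)
    n_loci_hit: int | None = None


def locus_id(record_id: str) -> str:
    """Collapse an isoform id to its locus (truncate at the first '.')."""
    return record_id.split(".", 1)[0]


# ---------------------------------------------------------------------------
# FASTA loading


def load_fasta(path) -> list:
    """Read protein FASTA into :class:`SequenceRecord` objects.

    Sequences are uppercased; one trailing ``*`` (stop) is removed; empty
    records are skipped with a warning; duplicate ids are kept but renamed
    with a ``.dupN`` suffix (with a warning).
    """
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            warnings.warn(f"skipping zero-length record {rec.id!r}")
            continue
        rid = rec.id
        if rid in seen:
            seen[rid] += 1
            new_id = f"{rid}.dup{seen[rid]}"
            warnings.warn(f"duplicate record id {rid!r}; renamed to {new_id!r}")
            rid = new_id
        else:
            seen[rid] = 0
        records.append(SequenceRecord(rid, rec.description, seq))
    return records


# ---------------------------------------------------------------------------
# core matcher


def find_matches(m: Motif, rec: SequenceRecord) -> list:
    """Enumerate all distinct motif spans in one record.

    Returns one :class:`Match` per distinct (start, end) span, ordered by
    (start, end), each carrying a witness element assignment.
    """
    seq = rec.residues
    n = len(seq)
    if n < m.min_span:
        return []

    elements = m.elements
    n_el = len(elements)
    # ok[i] == 1 iff seq[i] can sit inside a wildcard gap (any letter, not '*')
    ok_prefix = [0] * (n + 1)
    for i, c in enumerate(seq):
        ok_prefix[i + 1] = ok_prefix[i] + (1 if c.isalpha() else 0)

    def gap_clear(a: int, b: int) -> bool:  # [a, b) all gap-eligible
        return ok_prefix[b] - ok_prefix[a] == b - a

    first = elements[0]
    if first.is_gap:
        candidate_starts: Iterable[int] = range(n)
    else:
        allowed0 = first.residue_class.allowed
        candidate_starts = [i for i, c in enumerate(seq) if c in allowed0]

    matches: list[Match] = []
    for s in candidate_starts:
        if n - s < m.min_span:
            continue
        # frontier: position -> predecessor position at previous element
        frontier: dict[int, int | None] = {s: None}
        trace: list[dict] = []
        for el in elements:
            nxt: dict[int, int] = {}
            if el.is_gap:
                for pos in frontier:
                    hi = min(el.max_repeat, n - pos)
                    for k in range(el.min_repeat, hi + 1):
                        q = pos + k
                        if q not in nxt and gap_clear(pos, q):
                            nxt[q] = pos
            else:
                allowed = el.residue_class.allowed
                for pos in frontier:
                    if pos < n and seq[pos] in allowed and pos + 1 not in nxt:
                        nxt[pos + 1] = pos
            if not nxt:
                frontier = {}
                break
            trace.append(nxt)
            frontier = nxt
        for end_excl in sorted(frontier):
            # backtrack one witness assignment
            bounds = [0] * (n_el + 1)
            bounds[n_el] = end_excl
            pos = end_excl
            for i in range(n_el - 1, -1, -1):
                pos = trace[i][pos]
                bounds[i] = pos
            spans = tuple(
                (bounds[i] + 1, bounds[i + 1]) for i in range(n_el))
            matches.append(Match(
                record_id=rec.id,
                start=s + 1,
                end=end_excl,
                matched=seq[s:end_excl],
                element_spans=spans,
            ))
    matches.sort(key=lambda mt: (mt.start, mt.end))
    return matches


def scan_records(m: Motif, records: Sequence[SequenceRecord],
                 collapse_isoforms: bool = False) -> ScanSummary:
    """Scan a list of records and summarise hits."""
    hits: list[Match] = []
    for rec in records:
        hits.extend(find_matches(m, rec))
    hit_ids = {h.record_id for h in hits}
    summary = ScanSummary(
        motif_name=m.name,
        n_records_scanned=len(records),
        n_records_hit=len(hit_ids),
        n_matches=len(hits),
        hits=hits,
    )
    if collapse_isoforms:
        summary.n_loci_hit = len({locus_id(i) for i in hit_ids})
    return summary


def scan_fasta(m: Motif, fasta_path,
               collapse_isoforms: bool = False) -> ScanSummary:
    """Scan every record of a FASTA file with one motif."""
    records = load_fasta(fasta_path)
    return scan_records(m, records, collapse_isoforms=collapse_isoforms)


def compare_variants(motifs: Sequence[Motif], fasta_path,
                     collapse_isoforms: bool = False) -> pd.DataFrame:
    """Scan the same records with several motifs; one summary row each."""
    if not motifs:
        raise ValueError("at least one motif is required")
    records = load_fasta(fasta_path)
    rows = []
    for m in motifs:
        s = scan_records(m, records, collapse_isoforms=collapse_isoforms)
        row = {
            "motif_name": s.motif_name,
            "n_records_scanned": s.n_records_scanned,
            "n_records_hit": s.n_records_hit,
            "n_matches": s.n_matches,
        }
        if collapse_isoforms:
            row["n_loci_hit"] = s.n_loci_hit
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# writers


def hits_frame(summary: ScanSummary) -> pd.DataFrame:
    """One row per match: record, motif, span, sequence, gap choices."""
    rows = [{
        "record_id": h.record_id,
        "motif": summary.motif_name,
        "start": h.start,
        "end": h.end,
        "matched": h.matched,
        "gap_choices": ",".join(map(str, h.gap_choices)),
    } for h in summary.hits]
    return pd.DataFrame(
        rows, columns=["record_id", "motif", "start", "end", "matched",
                       "gap_choices"])


def hits_to_tsv(summary: ScanSummary, path) -> None:
    hits_frame(summary).to_csv(path, sep="\t", index=False)


def hits_to_gff3(summary: ScanSummary, path) -> None:
    """Write matches as GFF3 polypeptide_motif features (protein coords)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, h in enumerate(summary.hits, 1):
            attrs = (f"ID=motif{i};Name={summary.motif_name};"
                     f"pattern_match={h.matched}")
            fh.write("\t".join([
                h.record_id, "cycmotif", "polypeptide_motif",
                str(h.start), str(h.end), ".", ".", ".", attrs,
            ]) + "\n")
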