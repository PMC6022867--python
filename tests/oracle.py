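"""Independent reference implementations used only by the tests.

The span oracle translates a motif into a plain ``re`` pattern and
enumerates every candidate (start, length) pair with an anchored fullmatch.
It shares no code with the package's scanner: gap alternatives are resolved
by the regex engine's own backtracking, one candidate substring at a time.
"""

from __future__ import annotations

import re

from cycmotif.motif import Motif


def motif_regex(m: Motif) -> str:
    parts = []
    for el in m.elements:
        if el.residue_class.is_wildcard:
            if el.min_repeat == el.max_repeat:
                parts.append("[A-Z]{%d}" % el.min_repeat)
            else:
                parts.append("[A-Z]{%d,%d}" % (el.min_repeat, el.max_repeat))
        else:
            parts.append("[" + "".join(sorted(el.residue_class.allowed)) + "]")
    return "".join(parts)


def oracle_spans(m: Motif, seq: str) -> list:
    """All distinct (start, end) spans, 1-based inclusive, by brute force."""
    pat = re.compile(motif_regex(m))
    lo, hi = m.min_span, m.max_span
    n = len(seq)
    first = m.elements[0]
    if first.residue_class.is_wildcard:
        starts = range(n)
    else:
        allowed = first.residue_class.allowed
        starts = [i for i in range(n) if seq[i] in allowed]
    spans = []
    for s in starts:
        for length in range(lo, min(hi, n - s) + 1):
            if pat.fullmatch(seq, s, s + length):
                spans.append((s + 1, s + length))
    return spans
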