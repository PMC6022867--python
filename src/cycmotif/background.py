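"""Expected chance-hit counts for a motif under an i.i.d. background.

The screening statistic is a union bound: the probability that a match
*starts* at a fixed position is taken as the sum over all gap-length
combinations of the product of per-position class probabilities (wildcard
positions contribute 1).  Because class probabilities do not depend on the
gap lengths chosen, this equals (number of gap combinations) x (product of
class probabilities).  It is an upper bound — spans sharing a start are
counted once each — but at the probabilities involved here the slack is
negligible.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import yaml

from .motif import Motif, STANDARD_RESIDUES
from .scan import load_fasta

__all__ = ["BackgroundModel", "ExpectedHits", "start_probability",
           "expected_hits"]


@dataclass(frozen=True)
class BackgroundModel:
    """Residue composition of a background proteome."""

    composition: dict = field(default_factory=dict)

    def __post_init__(self):
        comp = dict(self.composition)
        if any(f < 0 for f in comp.values()):
            raise ValueError("composition frequencies must be non-negative")
        total = sum(comp.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"composition must sum to 1 (got {total})")
        bad = set(comp) - STANDARD_RESIDUES
        if bad:
            raise ValueError(f"non-standard residues in composition: {bad}")
        object.__setattr__(self, "composition", comp)

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls({r: 1 / 20 for r in sorted(STANDARD_RESIDUES)})

    @classmethod
    def from_frequencies(cls, freqs: dict) -> "BackgroundModel":
        total = sum(freqs.values())
        if total <= 0:
            raise ValueError("frequencies must have a positive sum")
        return cls({r: f / total for r, f in freqs.items()})

    @classmethod
    def from_fasta(cls, path) -> "BackgroundModel":
        """Empirical composition over the standard residues of a FASTA file."""
        counts: Counter = Counter()
        for rec in load_fasta(path):
            counts.update(c for c in rec.residues if c in STANDARD_RESIDUES)
        if not counts:
            raise ValueError(f"no standard residues found in {path}")
        return cls.from_frequencies(dict(counts))

    @classmethod
    def from_yaml(cls, path) -> "BackgroundModel":
        with open(path) as fh:
            freqs = yaml.safe_load(fh)
        return cls.from_frequencies({str(k): float(v) for k, v in freqs.items()})

    def class_probability(self, allowed) -> float:
        return sum(self.composition.get(r, 0.0) for r in allowed)


@dataclass(frozen=True)
class ExpectedHits:
    sites: float
    records: float


def start_probability(m: Motif, bg: BackgroundModel) -> float:
    """Union-bound probability that a match begins at a fixed position."""
    p = 1.0
    combos = 1
    for el in m.elements:
        if el.is_gap:
            combos *= el.max_repeat - el.min_repeat + 1
        else:
            p *= bg.class_probability(el.residue_class.allowed)
    return min(p * combos, 1.0)


def expected_hits(m: Motif, bg: BackgroundModel, total_residues: int,
                  n_records: int, mean_length: float) -> ExpectedHits:
    """Expected numbers of match sites and of records with >= 1 match.

    Edge effects are handled by discounting max_span - 1 positions per
    record; record expectations use independence across the effective
    start positions of each record.
    """
    if total_residues <= 0 or n_records <= 0 or mean_length <= 0:
        raise ValueError("sizes must be positive")
    p = start_probability(m, bg)
    edge = m.max_span - 1
    eff_total = max(total_residues - n_records * edge, 0)
    eff_per_record = max(mean_length - edge, 0.0)
    sites = p * eff_total
    records = n_records * (1.0 - (1.0 - p) ** eff_per_record)
    return ExpectedHits(sites=sites, records=records)
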