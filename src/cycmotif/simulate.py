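"""Synthetic proteomes and expression matrices with known ground truth.

Proteomes are i.i.d. residues drawn from a background composition, with
record lengths following a shifted geometric distribution (minimum 50).
Motif instances are planted by substitution — the instantiation overwrites
a stretch of background residues — so record lengths and downstream
coordinates are unaffected and the truth table is exact.

Expression matrices embed a latent query-gene signal; correlated genes mix
the standardized signal with independent noise at the designed Pearson r,
and condition inductions multiply the affected samples by a fold factor.
All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .background import BackgroundModel
from .coexpression import ExpressionMatrix
from .motif import Motif, STANDARD_RESIDUES
from .scan import SequenceRecord

__all__ = ["PlantedTruth", "generate_proteome", "sample_instantiation",
           "plant_motifs", "generate_expression", "write_fasta",
           "truth_to_tsv"]

_STANDARD = sorted(STANDARD_RESIDUES)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth location of one planted motif instance (1-based)."""

    record_id: str
    start: int
    end: int
    motif_name: str
    instantiation: str


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def generate_proteome(n_records: int, mean_length: int,
                      composition: BackgroundModel, seed) -> list:
    """Simulate a proteome of i.i.d. background residues.

    Lengths are ``49 + Geometric(p)`` with ``p = 1/(mean_length - 49)``
    (minimum 50, mean ``mean_length``); any positive-support model would do.
    """
    if n_records < 0:
        raise ValueError("n_records must be non-negative")
    if mean_length < 50:
        raise ValueError("mean_length must be >= 50")
    rng = _as_rng(seed)
    residues = sorted(composition.composition)
    probs = np.array([composition.composition[r] for r in residues])
    p_geom = 1.0 / (mean_length - 49)
    records = []
    width = max(5, len(str(max(n_records, 1))))
    for i in range(n_records):
        length = 49 + int(rng.geometric(p_geom))
        seq = "".join(rng.choice(residues, size=length, p=probs))
        rid = f"syn{i + 1:0{width}d}"
        records.append(SequenceRecord(rid, f"{rid} simulated background", seq))
    return records


def sample_instantiation(m: Motif, seed) -> str:
    """Draw one string satisfying the motif element by element.

    Class elements choose uniformly from their allowed residues; gaps choose
    a length uniformly in range and fill with uniform standard residues.
    """
    rng = _as_rng(seed)
    parts = []
    for el in m.elements:
        if el.is_gap:
            k = int(rng.integers(el.min_repeat, el.max_repeat + 1))
            parts.append("".join(rng.choice(_STANDARD, size=k)))
        else:
            parts.append(str(rng.choice(sorted(el.residue_class.allowed))))
    return "".join(parts)


def plant_motifs(records, m: Motif, n_insertions: int, seed):
    """Overwrite random non-overlapping stretches with motif instantiations.

    Returns ``(new_records, truths)``.  Raises if the requested number of
    non-overlapping placements cannot be found.
    """
    if n_insertions < 0:
        raise ValueError("n_insertions must be non-negative")
    rng = _as_rng(seed)
    if n_insertions == 0:
        return list(records), []
    seqs = {r.id: list(r.residues) for r in records}
    occupied: dict[str, list] = {r.id: [] for r in records}
    order = list(records)
    truths: list[PlantedTruth] = []
    max_attempts = 200 * n_insertions
    attempts = 0
    while len(truths) < n_insertions:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n_insertions} non-overlapping instances "
                f"(placed {len(truths)})")
        inst = sample_instantiation(m, rng)
        rec = order[int(rng.integers(len(order)))]
        if len(rec.residues) < len(inst):
            continue
        start0 = int(rng.integers(0, len(rec.residues) - len(inst) + 1))
        end0 = start0 + len(inst)  # exclusive
        if any(start0 < e and s < end0 for s, e in occupied[rec.id]):
            continue
        seqs[rec.id][start0:end0] = inst
        occupied[rec.id].append((start0, end0))
        truths.append(PlantedTruth(
            record_id=rec.id, start=start0 + 1, end=end0,
            motif_name=m.name, instantiation=inst))
    new_records = [
        SequenceRecord(r.id, r.description, "".join(seqs[r.id]))
        for r in records]
    truths.sort(key=lambda t: (t.record_id, t.start))
    return new_records, truths


def generate_expression(n_genes: int, n_samples: int,
                        query_r_targets: dict | None = None,
                        inductions: dict | None = None,
                        noise_sd: float = 0.0,
                        seed=0,
                        conditions=("control",),
                        query_gene: str = "gene_query"):
    """Build an expression matrix around a latent query-gene signal.

    Parameters
    ----------
    query_r_targets:
        gene id -> designed Pearson correlation with the query gene
        (must lie strictly inside (-1, 1)).
    inductions:
        (gene id, condition) -> fold factor (> 0) applied multiplicatively
        to that gene's values in samples of that condition.
    conditions:
        Condition labels; samples are assigned in contiguous equal blocks.

    Returns ``(ExpressionMatrix, truth_dict)``.
    """
    query_r_targets = dict(query_r_targets or {})
    inductions = dict(inductions or {})
    for g, r in query_r_targets.items():
        if not -1.0 < r < 1.0:
            raise ValueError(f"target r for {g!r} must be in (-1, 1), got {r}")
    for (g, cond), fold in inductions.items():
        if fold <= 0:
            raise ValueError(f"fold for {(g, cond)!r} must be positive")
    rng = _as_rng(seed)

    sample_ids = [f"sample{j + 1:03d}" for j in range(n_samples)]
    block = int(np.ceil(n_samples / len(conditions)))
    group_labels = {
        s: conditions[min(j // block, len(conditions) - 1)]
        for j, s in enumerate(sample_ids)}

    signal = rng.standard_normal(n_samples)
    z = (signal - signal.mean()) / signal.std()

    gene_ids = [query_gene] + [
        g for g in query_r_targets if g != query_gene]
    extra = n_genes - len(gene_ids)
    gene_ids += [f"gene{j + 1:04d}" for j in range(max(extra, 0))]

    latent = {query_gene: z}
    for g in gene_ids[1:]:
        eps = rng.standard_normal(n_samples)
        # project out the signal so the in-sample correlation hits the
        # designed r exactly (up to later induction/noise perturbations)
        eps = eps - (eps @ z) / (z @ z) * z
        eps = (eps - eps.mean()) / eps.std()
        r = query_r_targets.get(g, 0.0)
        latent[g] = r * z + np.sqrt(1.0 - r * r) * eps

    # affine map to strictly positive microarray-style intensities;
    # affine transforms preserve Pearson correlations
    rows = {}
    for g in gene_ids:
        x = 1000.0 + 50.0 * latent[g]
        if noise_sd > 0:
            x = x + rng.normal(0.0, noise_sd, size=n_samples)
        rows[g] = x
    df = pd.DataFrame(rows, index=sample_ids).T
    df.index.name = "gene"

    for (g, cond), fold in inductions.items():
        cols = [s for s in sample_ids if group_labels[s] == cond]
        if g not in df.index or not cols:
            raise ValueError(f"induction target {(g, cond)!r} not in matrix")
        df.loc[g, cols] = df.loc[g, cols] * fold

    if (df.to_numpy() <= 0).any():
        raise RuntimeError("generated non-positive intensity; "
                           "increase baseline or reduce noise_sd")
    truth = {
        "query_gene": query_gene,
        "r_targets": query_r_targets,
        "inductions": {f"{g}|{c}": fold
                       for (g, c), fold in inductions.items()},
        "group_labels": group_labels,
    }
    return ExpressionMatrix(df, group_labels), truth


# ---------------------------------------------------------------------------
# plain-text writers


def write_fasta(records, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.description}\n" if rec.description.startswith(rec.id)
                     else f">{rec.id} {rec.description}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def truth_to_tsv(truths, path) -> None:
    pd.DataFrame(
        [{"record_id": t.record_id, "start": t.start, "end": t.end,
          "motif": t.motif_name, "instantiation": t.instantiation}
         for t in truths],
        columns=["record_id", "start", "end", "motif", "instantiation"],
    ).to_csv(path, sep="\t", index=False)
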