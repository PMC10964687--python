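"""Planted-motif dataset generator.

Emulates ChIP-seq-like peak sets at desk scale: n background sequences of
width t, with instances of a width-k consensus implanted according to an
occurrence model (OOPS: one per sequence; ZOOPS: Bernoulli(gamma); ANR:
truncated-Poisson count with mean gamma). Each implanted instance mutates
exactly j positions, j drawn uniformly from {0..d}, so the Hamming
distance bound d is a hard invariant of the truth, and the implied
per-column base distributions are known analytically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .background import BackgroundModel
from .seqio import ALPHABET, SequenceDataset

__all__ = ["PlantSpec", "PlantTruth", "generate_planted",
           "count_instances_recovered", "true_column_distributions"]


@dataclass
class PlantSpec:
    """Generator parameters for one planted dataset."""

    n: int = 100
    t: int = 100
    k: int = 10
    d: int = 1
    model: str = "zoops"
    gamma: float = 0.9
    consensus: str = "random"
    background: BackgroundModel | None = None
    seed: int = 42

    def __post_init__(self):
        if self.k > self.t:
            raise ValueError("motif width k must not exceed sequence width t")
        if not (0 <= self.d <= self.k):
            raise ValueError("0 <= d <= k required")
        if self.model == "zoops" and not (0 < self.gamma <= 1):
            raise ValueError("zoops gamma must be in (0, 1]")
        if self.model not in ("oops", "zoops", "anr"):
            raise ValueError("model must be oops, zoops or anr")


@dataclass
class PlantTruth:
    """Ground truth: where instances were implanted and what the mutation
    process implies per motif column."""

    consensus: str
    instances: list[tuple[int, int, str, int]]  # (seq idx, offset, string, n_mut)
    true_column_distributions: np.ndarray = field(repr=False)


def true_column_distributions(consensus: str, d: int, k: int) -> np.ndarray:
    """k x 4 column distributions implied by mutating Uniform{0..d}
    positions per instance.

    The per-position mutation probability is E[j]/k = d/(2k); a mutated
    position takes each of the three non-consensus bases with equal
    probability.
    """
    mu = d / (2.0 * k)
    cols = np.full((k, 4), mu / 3.0)
    for j, ch in enumerate(consensus):
        cols[j, ALPHABET.index(ch)] = 1.0 - mu
    return cols


def _instance_counts(spec: PlantSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.model == "oops":
        return np.ones(spec.n, dtype=int)
    if spec.model == "zoops":
        return (rng.random(spec.n) < spec.gamma).astype(int)
    counts = rng.poisson(spec.gamma, size=spec.n)
    cap = spec.t // spec.k  # non-overlapping implants must fit
    return np.minimum(counts, cap)


def generate_planted(spec: PlantSpec) -> tuple[SequenceDataset, PlantTruth]:
    """Sample a dataset and its ground truth from ``spec``.

    Background bases come from ``spec.background`` (uniform i.i.d. when
    None); implants are placed at uniform random offsets, rejected until
    non-overlapping within a sequence; reproducible under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    bg = spec.background or BackgroundModel.uniform()
    consensus = spec.consensus
    if consensus == "random":
        consensus = "".join(ALPHABET[c] for c in rng.integers(0, 4, spec.k))
    if len(consensus) != spec.k:
        raise ValueError("consensus length must equal k")
    counts = _instance_counts(spec, rng)
    records = []
    instances = []
    for i in range(spec.n):
        seq = list(bg.sample_sequence(spec.t, rng))
        placed: list[tuple[int, int]] = []
        for _ in range(counts[i]):
            for _attempt in range(1000):
                u = int(rng.integers(0, spec.t - spec.k + 1))
                if all(u + spec.k <= a or u >= b for a, b in placed):
                    break
            else:
                break  # no non-overlapping slot left
            inst = list(consensus)
            n_mut = int(rng.integers(0, spec.d + 1))
            pos = rng.choice(spec.k, size=n_mut, replace=False)
            for p in pos:
                orig = ALPHABET.index(inst[p])
                inst[p] = ALPHABET[(orig + 1 + rng.integers(0, 3)) % 4]
            seq[u:u + spec.k] = inst
            placed.append((u, u + spec.k))
            instances.append((i, u, "".join(inst), n_mut))
        records.append((f"seq_{i}", "".join(seq)))
    truth = PlantTruth(
        consensus=consensus,
        instances=instances,
        true_column_distributions=true_column_distributions(
            consensus, spec.d, spec.k
        ),
    )
    return SequenceDataset(records), truth


def count_instances_recovered(truth: PlantTruth, report, slack: int = 1) -> float:
    """Fraction of implanted instances whose sequence's top posterior
    offset lies within +-slack of the implant offset.

    ``report`` is a pipeline :class:`~treemotif.pipeline.MotifReport`
    carrying per-sequence best offsets.
    """
    if not truth.instances:
        raise ValueError("truth contains no instances")
    best = report.best_offsets
    hits = 0
    for seq_idx, offset, _, _ in truth.instances:
        b = best[seq_idx] if seq_idx < len(best) else None
        if b is not None and abs(b - offset) <= slack:
            hits += 1
    return hits / len(truth.instances)


def write_truth_tsv(truth: PlantTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_index\toffset\timplanted\tn_mutations\n")
        for i, u, s, nm in truth.instances:
            fh.write(f"{i}\t{u}\t{s}\t{nm}\n")
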