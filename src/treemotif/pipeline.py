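"""End-to-end motif discovery: preprocess -> count -> seed -> optimize ->
report.

The counting phase builds the k-mer trie, tests every stored k-mer for
enrichment against an order-r Markov background (fitted to a shuffled
control, or to a user-supplied control set), and greedily groups enriched
k-mers into mismatch neighborhoods. The top seeds are turned into PWMs and
refined by EM; reports are ranked by final log-likelihood. Additional
motifs (n_motifs > 1) are found by masking the occurrences of each
reported motif to N and re-counting — an experimental extension of the
single-motif design.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import background as bgmod
from . import em as emmod
from . import metrics as metmod
from . import smt as smtmod
from .seqio import SequenceDataset, read_fasta, normalize

logger = logging.getLogger("treemotif")


@dataclass
class PipelineConfig:
    """Full run configuration; defaults follow the standard single-motif
    ZOOPS setup (d=2 mismatch grouping, 1000 iterations max, 0.001
    log-likelihood tolerance)."""

    input: str | Path = ""
    k: int = 10
    output_dir: str | Path | None = None
    control: str | Path | None = None
    n_motifs: int = 1
    d: int = 2
    model: str = "zoops"
    max_iter: int = 1000
    tol: float = 1e-3
    alpha: float = 1e-3
    bg_order: int = 2
    shuffle: str = "markov"
    n_seeds: int = 10
    seed: int = 42
    match_weight: float = 0.7
    width_policy: str = "center_trim"

    def __post_init__(self):
        if self.shuffle not in ("markov", "euler"):
            raise ValueError("shuffle must be 'markov' or 'euler'")
        if self.n_motifs < 1 or self.n_seeds < 1:
            raise ValueError("n_motifs and n_seeds must be >= 1")


@dataclass
class MotifReport:
    """One discovered motif."""

    rank: int
    pwm: emmod.Pwm
    consensus: str
    seed_kmer: str
    aggregated_count: int
    q_value: float
    loglik: float
    iterations: int
    best_offsets: list[int | None] = field(default_factory=list, repr=False)


def _make_background(
    dataset: SequenceDataset, config: PipelineConfig
) -> bgmod.BackgroundModel:
    if config.control:
        control = normalize(read_fasta(config.control), "none")
    elif config.shuffle == "markov":
        control = bgmod.markov_shuffle(dataset, config.bg_order, config.seed)
    else:
        klet = max(2, config.bg_order + 1)
        control = SequenceDataset([
            (name, bgmod.euler_shuffle(seq, klet, config.seed + i))
            for i, (name, seq) in enumerate(dataset)
        ])
    return bgmod.fit_background(control, config.bg_order)


def _best_offsets(state: emmod.EmState) -> list[int | None]:
    """Top posterior offset per sequence; None when the ZOOPS absence
    mass dominates or the sequence was skipped."""
    out: list[int | None] = []
    for i, post in enumerate(state.posteriors):
        if state.skipped[i] or post.size == 0:
            out.append(None)
        elif state.absence[i] > post.max():
            out.append(None)
        else:
            out.append(int(post.argmax()))
    return out


def _mask_occurrences(
    dataset: SequenceDataset, state: emmod.EmState, k: int
) -> SequenceDataset:
    """Replace windows with occurrence posterior > 0.5 by N before
    searching for the next motif."""
    records = []
    for i, (name, seq) in enumerate(dataset):
        post = state.posteriors[i]
        chars = list(seq)
        for u in np.nonzero(post > 0.5)[0]:
            chars[u:u + k] = "N" * k
        records.append((name, "".join(chars)))
    return SequenceDataset(records)


def discover(
    dataset: SequenceDataset, config: PipelineConfig
) -> tuple[list[MotifReport], list[smtmod.EnrichedKmer]]:
    """Single-pass discovery on an in-memory dataset. Returns the ranked
    reports of this pass and the seed table that fed EM."""
    bg = _make_background(dataset, config)
    tree = smtmod.create_smt(dataset, config.k)
    enriched = smtmod.extract_enriched(tree, bg, config.alpha)
    if not enriched:
        logger.warning(
            "no k-mer enriched at alpha=%g; falling back to the most "
            "frequent k-mer", config.alpha,
        )
        best = max(tree.iter_kmers(), key=lambda e: e[1], default=None)
        if best is None:
            return [], []
        enriched = [smtmod.EnrichedKmer(best[0], best[1], float("nan"), 1.0, 1.0)]
    seeds = smtmod.group_seeds(tree, enriched, config.d, config.n_seeds)
    em_config = emmod.ModelConfig(
        model=config.model, max_iter=config.max_iter, tol=config.tol
    )
    results = []
    for seed_rec in seeds:
        start = emmod.seed_pwm(seed_rec.kmer, config.match_weight)
        res = emmod.run_em(dataset, start, bg, em_config)
        results.append((seed_rec, res))
    results.sort(key=lambda sr: -sr[1].trace[-1])
    reports = []
    for rank, (seed_rec, res) in enumerate(results, start=1):
        reports.append(MotifReport(
            rank=rank,
            pwm=res.pwm,
            consensus=res.pwm.consensus(),
            seed_kmer=seed_rec.kmer,
            aggregated_count=seed_rec.observed,
            q_value=seed_rec.q_value,
            loglik=res.trace[-1],
            iterations=res.iterations,
            best_offsets=_best_offsets(res.final_state),
        ))
    return reports, seeds


def run_pipeline(config: PipelineConfig) -> list[MotifReport]:
    """Full run: read and normalize the input, then discover
    ``config.n_motifs`` motifs, masking each motif's occurrences before
    searching for the next. Reports are re-ranked globally by
    log-likelihood."""
    t0 = time.time()
    dataset = normalize(read_fasta(config.input), config.width_policy)
    logger.info("loaded %d sequences (min width %d)",
                dataset.n, min(dataset.widths))
    reports: list[MotifReport] = []
    seeds_all: list[smtmod.EnrichedKmer] = []
    current = dataset
    for motif_idx in range(config.n_motifs):
        pass_reports, seeds = discover(current, config)
        seeds_all.extend(seeds)
        if not pass_reports:
            break
        top = pass_reports[0]
        top.rank = motif_idx + 1
        reports.append(top)
        if motif_idx + 1 < config.n_motifs:
            # reconstruct the winner's posterior state to mask occurrences
            bg = _make_background(current, config)
            em_config = emmod.ModelConfig(
                model=config.model, max_iter=1, tol=config.tol
            )
            state = emmod.e_step(current, top.pwm, bg, em_config)
            current = _mask_occurrences(current, state, config.k)
    reports.sort(key=lambda r: -r.loglik)
    for i, r in enumerate(reports, start=1):
        r.rank = i
    logger.info("pipeline finished in %.2f s", time.time() - t0)
    if config.output_dir is not None and reports:
        write_outputs(reports, seeds_all, config.output_dir, config)
    return reports


def write_outputs(
    reports: list[MotifReport],
    seeds: list[smtmod.EnrichedKmer],
    outdir: str | Path,
    config: PipelineConfig | None = None,
) -> None:
    """Write motifs.meme, motifs.jaspar, seeds.tsv and run.log."""
    if not reports:
        raise ValueError("no reports to write")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    named = [(f"motif_{r.rank}", r.pwm) for r in reports]
    metmod.write_meme(
        [(n, p, max(r.aggregated_count, 1))
         for (n, p), r in zip(named, reports)],
        outdir / "motifs.meme",
    )
    metmod.write_jaspar_pfm(named, outdir / "motifs.jaspar", nsites=1_000_000)
    smtmod.write_enriched_tsv(seeds, outdir / "seeds.tsv")
    with open(outdir / "run.log", "w") as fh:
        if config is not None:
            fh.write(f"config: {config}\n")
        for r in reports:
            fh.write(
                f"motif {r.rank}: consensus={r.consensus} "
                f"seed={r.seed_kmer} count={r.aggregated_count} "
                f"q={r.q_value:.3g} loglik={r.loglik:.4f} "
                f"iterations={r.iterations}\n"
            )
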