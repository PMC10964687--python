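"""PWM models and the fast EM optimizer under OOPS, ZOOPS and ANR
occurrence models.

The likelihood of a sequence given a motif at offset u factorizes into
background terms outside the window and PWM terms inside it. The fast
formulation computes each sequence's total background log-score once and
obtains every per-offset marginal as

    log P(s_i | p_u) = total_i - window_bg_i[u] + window_pwm_i[u],

i.e. the background contribution of the window is subtracted and the PWM
contribution added — a pure log-space refactoring of the naive
three-product likelihood, so every downstream posterior is identical to
the naive computation.

Occurrence models:

* OOPS  — exactly one motif occurrence per sequence, uniform over offsets.
* ZOOPS — zero or one occurrence; a sequence carries the motif with prior
  probability gamma, split uniformly over offsets.
* ANR   — every window independently carries the motif with probability
  gamma (per-window Bernoulli mixture).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp

from .background import BackgroundModel
from .seqio import ALPHABET, SequenceDataset, encode

MODELS = ("oops", "zoops", "anr")


@dataclass
class Pwm:
    """Position weight matrix: k x 4 row-stochastic table in A,C,G,T
    column order. The positive model."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM must be a k x 4 matrix")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.matrix[::-1, ::-1].copy())

    def log(self) -> np.ndarray:
        return np.log(self.matrix)


@dataclass
class ModelConfig:
    """EM run configuration.

    gamma is the prior probability that a sequence contains the motif
    (ZOOPS) or the per-window occurrence rate (ANR); it is re-estimated
    each M-step. Iteration stops when the log-likelihood gain drops below
    ``tol`` or after ``max_iter`` iterations.
    """

    model: str = "zoops"
    gamma: float = 0.5
    max_iter: int = 1000
    tol: float = 1e-3
    pseudocount: float = 0.1

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if not (0 < self.gamma <= 1):
            raise ValueError("gamma must be in (0, 1]")
        if self.max_iter < 1 or self.tol <= 0 or self.pseudocount <= 0:
            raise ValueError("max_iter >= 1, tol > 0, pseudocount > 0 required")


@dataclass
class EmState:
    """Per-sequence posteriors from one E-step.

    ``posteriors[i][u]`` is the posterior that sequence i carries the
    motif at offset u (for OOPS/ZOOPS the vector plus the ZOOPS absence
    mass sums to 1; for ANR entries are independent per-window values).
    ``absence[i]`` is the ZOOPS no-occurrence mass (0 for OOPS, unused for
    ANR). ``skipped`` marks sequences with no valid offset.
    """

    posteriors: list[np.ndarray]
    absence: np.ndarray
    loglik: float
    skipped: list[bool]


@dataclass
class EmResult:
    pwm: Pwm
    gamma: float
    trace: list[float]
    iterations: int
    converged: bool
    final_state: EmState | None = field(default=None, repr=False)


def seed_pwm(kmer: str, match_weight: float = 0.7) -> Pwm:
    """Initial PWM from a consensus k-mer: each row puts ``match_weight``
    on the consensus base and spreads the rest evenly."""
    if not (0.25 < match_weight < 1):
        raise ValueError("match_weight must be in (0.25, 1)")
    rows = []
    off = (1.0 - match_weight) / 3.0
    for ch in kmer:
        if ch not in ALPHABET:
            raise ValueError(f"non-ACGT symbol {ch!r} in seed k-mer")
        row = [off] * 4
        row[ALPHABET.index(ch)] = match_weight
        rows.append(row)
    return Pwm(np.array(rows))


def log_background_score(
    sequence: str, bg: BackgroundModel, k: int
) -> tuple[float, np.ndarray]:
    """Whole-sequence background log-score and per-offset window sums.

    Returns ``(total, window_sums)`` where ``total`` is the sum of
    per-position log-probabilities over the whole sequence and
    ``window_sums[u]`` the sum over positions u..u+k-1, computed with one
    cumulative-sum pass. Offsets whose window contains an N are NaN and
    excluded downstream; N positions contribute nothing to ``total``.
    """
    codes = np.asarray(encode(sequence))
    t = len(codes)
    if t < k:
        raise ValueError(f"sequence length {t} < k={k}")
    lp = bg.log_position_scores(codes)
    valid = np.isfinite(lp)
    total = float(lp[valid].sum())
    filled = np.where(valid, lp, 0.0)
    csum = np.concatenate(([0.0], np.cumsum(filled)))
    cbad = np.concatenate(([0], np.cumsum(~valid)))
    m = t - k + 1
    window_sums = csum[k:k + m] - csum[:m]
    bad_in_window = (cbad[k:k + m] - cbad[:m]) > 0
    window_sums = np.where(bad_in_window, np.nan, window_sums)
    return total, window_sums


def _window_pwm_scores(codes: np.ndarray, log_alpha: np.ndarray) -> np.ndarray:
    """Per-offset sum of PWM log-probabilities; NaN where the window
    contains an N."""
    k = log_alpha.shape[0]
    t = len(codes)
    m = t - k + 1
    scores = np.zeros(m)
    invalid = np.zeros(m, dtype=bool)
    for j in range(k):
        col = codes[j:j + m]
        bad = col < 0
        invalid |= bad
        scores += np.where(bad, 0.0, log_alpha[j, np.clip(col, 0, 3)])
    return np.where(invalid, np.nan, scores)


def log_marginal_offsets(
    sequence: str, pwm: Pwm, bg: BackgroundModel
) -> np.ndarray:
    """log P(s_i | motif at offset u) for every offset, via the
    subtract-window/add-PWM decomposition. Invalid offsets are NaN."""
    total, wsums = log_background_score(sequence, bg, pwm.width)
    codes = np.asarray(encode(sequence))
    pscores = _window_pwm_scores(codes, pwm.log())
    return total - wsums + pscores


def _sequence_cache(dataset: SequenceDataset, bg: BackgroundModel, k: int):
    """Precompute the per-sequence background quantities reused across
    every EM iteration."""
    cache = []
    for _, seq in dataset:
        if len(seq) < k:
            cache.append(None)
            continue
        codes = np.asarray(encode(seq))
        total, wsums = log_background_score(seq, bg, k)
        cache.append((codes, total, wsums))
    return cache


def e_step(
    dataset: SequenceDataset,
    pwm: Pwm,
    bg: BackgroundModel,
    config: ModelConfig,
    _cache=None,
) -> EmState:
    """Posterior occurrence probabilities under the current models.

    OOPS/ZOOPS posteriors are normalized per sequence (ZOOPS including the
    absence mass); ANR posteriors are independent per-window Bernoulli
    responsibilities. ``loglik`` is the observed-data log-likelihood.
    Sequences with no valid offset are skipped with a warning.
    """
    k = pwm.width
    log_alpha = pwm.log()
    if _cache is None:
        _cache = _sequence_cache(dataset, bg, k)
    gamma = config.gamma
    posteriors: list[np.ndarray] = []
    absence = np.zeros(dataset.n)
    skipped = [False] * dataset.n
    loglik = 0.0
    for i, entry in enumerate(_cache):
        if entry is None:
            skipped[i] = True
            posteriors.append(np.zeros(0))
            continue
        codes, total, wsums = entry
        pscores = _window_pwm_scores(codes, log_alpha)
        logm = total - wsums + pscores
        valid = np.isfinite(logm)
        nv = int(valid.sum())
        if nv == 0:
            warnings.warn(f"sequence {i}: no valid offset; skipped", stacklevel=2)
            skipped[i] = True
            posteriors.append(np.zeros(len(logm)))
            continue
        post = np.zeros(len(logm))
        if config.model == "oops":
            lv = logm[valid]
            lse = logsumexp(lv)
            post[valid] = np.exp(lv - lse)
            loglik += lse - np.log(nv)
        elif config.model == "zoops":
            lv = np.log(gamma) - np.log(nv) + logm[valid]
            if gamma < 1.0:
                la = np.log1p(-gamma) + total
                lse = logsumexp(np.append(lv, la))
                absence[i] = np.exp(la - lse)
            else:
                lse = logsumexp(lv)
                absence[i] = 0.0
            post[valid] = np.exp(lv - lse)
            loglik += lse
        else:  # anr
            lg = np.log(gamma)
            l1g = np.log1p(-gamma) if gamma < 1 else -np.inf
            a = lg + pscores[valid]
            b = l1g + wsums[valid]
            post[valid] = expit(a - b)
            loglik += float(np.logaddexp(a, b).sum())
        posteriors.append(post)
    return EmState(posteriors, absence, float(loglik), skipped)


def m_step(
    dataset: SequenceDataset, state: EmState, config: ModelConfig, k: int
) -> tuple[Pwm, float]:
    """Maximize the PWM and occurrence parameter given posteriors.

    PWM cell (j, b) is the pseudocount-smoothed posterior-weighted count
    of base b at motif position j; ZOOPS gamma becomes the mean
    per-sequence presence mass and ANR gamma the mean per-window
    responsibility.
    """
    counts = np.full((k, 4), config.pseudocount)
    presence = []
    window_post = []
    for i, (_, seq) in enumerate(dataset):
        if state.skipped[i]:
            continue
        post = state.posteriors[i]
        codes = np.asarray(encode(seq))
        m = len(post)
        nz = np.nonzero(post > 0)[0]
        if nz.size:
            w = post[nz]
            for j in range(k):
                col = codes[nz + j]
                ok = col >= 0
                np.add.at(counts[j], col[ok], w[ok])
        presence.append(post.sum() if config.model != "zoops"
                        else 1.0 - state.absence[i])
        if m:
            window_post.append(post)
    pwm = Pwm(counts / counts.sum(axis=1, keepdims=True))
    if config.model == "zoops":
        gamma = float(np.clip(np.mean(presence), 1e-6, 1.0)) if presence else config.gamma
    elif config.model == "anr":
        allp = np.concatenate(window_post) if window_post else np.array([config.gamma])
        gamma = float(np.clip(allp.mean(), 1e-6, 1 - 1e-6))
    else:
        gamma = 1.0
    return pwm, gamma


def run_em(
    dataset: SequenceDataset,
    start: Pwm,
    bg: BackgroundModel,
    config: ModelConfig,
) -> EmResult:
    """Alternate E and M steps from a seed PWM until the log-likelihood
    gain falls below ``config.tol`` or ``config.max_iter`` is reached."""
    k = start.width
    cache = _sequence_cache(dataset, bg, k)
    pwm = start
    cfg = ModelConfig(config.model, config.gamma, config.max_iter,
                      config.tol, config.pseudocount)
    trace: list[float] = []
    converged = False
    iterations = 0
    state = None
    for it in range(1, config.max_iter + 1):
        new_state = e_step(dataset, pwm, bg, cfg, _cache=cache)
        state = new_state
        if trace and (new_state.loglik - trace[-1]) < config.tol:
            converged = True
            break
        trace.append(new_state.loglik)
        pwm, cfg.gamma = m_step(dataset, new_state, cfg, k)
        iterations = it
    if not converged:
        # posteriors under the final PWM, for downstream occurrence calls
        state = e_step(dataset, pwm, bg, cfg, _cache=cache)
    return EmResult(pwm, cfg.gamma, trace, iterations, converged, state)
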