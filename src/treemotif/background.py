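"""Background (negative) sequence models and control-set generation.

The background is an order-r Markov chain over {A,C,G,T} — the negative
model against which motif occurrences are scored. Control datasets are
generated either by sampling from a fitted chain (Markov shuffle) or by an
exact k-let-preserving Eulerian-path shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seqio import ALPHABET, SequenceDataset, decode, encode

DEFAULT_PSEUDOCOUNT = 0.01


def _context_index(codes, start: int, order: int) -> int:
    """Base-4 index of the context codes[start:start+order]; -1 if it
    contains an N."""
    idx = 0
    for j in range(start, start + order):
        c = codes[j]
        if c < 0:
            return -1
        idx = idx * 4 + c
    return idx


@dataclass
class BackgroundModel:
    """Order-r Markov model over {A,C,G,T}.

    Attributes
    ----------
    order : int
        Context length r (0 gives an i.i.d. model).
    initial_distribution : ndarray, shape (4**r,)
        Probability of each length-r context at the start of a sequence.
    transitions : ndarray, shape (4**r, 4)
        ``transitions[ctx, b]`` = P(next base = b | context ctx). Rows sum
        to 1.
    mononucleotide : ndarray, shape (4,)
        Marginal single-base distribution, used to score the first r
        positions of a sequence (which lack a full context).
    """

    order: int
    initial_distribution: np.ndarray
    transitions: np.ndarray
    mononucleotide: np.ndarray

    def __post_init__(self):
        self.initial_distribution = np.asarray(self.initial_distribution, float)
        self.transitions = np.asarray(self.transitions, float)
        self.mononucleotide = np.asarray(self.mononucleotide, float)

    @classmethod
    def uniform(cls, order: int = 0) -> "BackgroundModel":
        nctx = 4 ** order
        return cls(
            order=order,
            initial_distribution=np.full(nctx, 1.0 / nctx),
            transitions=np.full((nctx, 4), 0.25),
            mononucleotide=np.full(4, 0.25),
        )

    def log_position_scores(self, codes: np.ndarray) -> np.ndarray:
        """Per-position log P(s_j | model) for an encoded sequence.

        Positions holding N (code -1), or whose context contains an N,
        yield NaN; callers mask windows touching them.
        """
        codes = np.asarray(codes)
        t = len(codes)
        r = self.order
        out = np.full(t, np.nan)
        logm = np.log(self.mononucleotide)
        logtr = np.log(self.transitions)
        for j in range(t):
            c = codes[j]
            if c < 0:
                continue
            if j < r:
                out[j] = logm[c]
            else:
                ctx = _context_index(codes, j - r, r)
                if ctx < 0:
                    out[j] = logm[c]
                else:
                    out[j] = logtr[ctx, c]
        return out

    def kmer_log_prob(self, kmer: str) -> float:
        """log P(w | model) for a k-mer with no N, scoring the first r
        symbols from the marginal base distribution."""
        codes = encode(kmer)
        if any(c < 0 for c in codes):
            raise ValueError(f"k-mer {kmer!r} contains non-ACGT symbols")
        lp = 0.0
        for j, c in enumerate(codes):
            if j < self.order:
                lp += np.log(self.mononucleotide[c])
            else:
                ctx = _context_index(codes, j - self.order, self.order)
                lp += np.log(self.transitions[ctx, c])
        return float(lp)

    def sample_sequence(self, length: int, rng: np.random.Generator) -> str:
        """Draw one sequence of the given length from the chain."""
        r = self.order
        codes = []
        if r == 0 or length <= r:
            codes = list(
                rng.choice(4, size=length, p=self.mononucleotide)
            )
        else:
            ctx = int(rng.choice(len(self.initial_distribution),
                                 p=self.initial_distribution))
            # unpack the start context into its r symbols
            start = []
            x = ctx
            for _ in range(r):
                start.append(x % 4)
                x //= 4
            codes = start[::-1]
            for _ in range(length - r):
                c = int(rng.choice(4, p=self.transitions[ctx]))
                codes.append(c)
                ctx = (ctx * 4 + c) % (4 ** r)
        return decode(codes)

    def save(self, path: str | Path) -> None:
        """Serialize as plain text: 'ORDER r' then one tab-separated line
        per context with the four A,C,G,T probabilities."""
        r = self.order
        lines = [f"ORDER\t{r}"]
        for ctx in range(4 ** r):
            label = _context_label(ctx, r)
            probs = "\t".join(f"{p:.10g}" for p in self.transitions[ctx])
            lines.append(f"{label}\t{probs}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "BackgroundModel":
        lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
        head = lines[0].split("\t")
        if head[0] != "ORDER":
            raise ValueError("background file must start with an ORDER line")
        r = int(head[1])
        trans = np.zeros((4 ** r, 4))
        for ln in lines[1:]:
            parts = ln.split("\t")
            ctx = _context_label_index(parts[0], r)
            trans[ctx] = [float(x) for x in parts[1:5]]
        nctx = 4 ** r
        init = np.full(nctx, 1.0 / nctx)
        mono = trans.mean(axis=0)
        mono = mono / mono.sum()
        return cls(r, init, trans, mono)


def _context_label(ctx: int, order: int) -> str:
    if order == 0:
        return "-"
    syms = []
    for _ in range(order):
        syms.append(ALPHABET[ctx % 4])
        ctx //= 4
    return "".join(reversed(syms))


def _context_label_index(label: str, order: int) -> int:
    if order == 0:
        return 0
    idx = 0
    for ch in label:
        idx = idx * 4 + ALPHABET.index(ch)
    return idx


def fit_background(
    dataset: SequenceDataset,
    order: int = 2,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> BackgroundModel:
    """Estimate an order-r Markov background from a dataset.

    Transition probabilities are pseudocount-smoothed relative frequencies
    of (context, symbol) pairs pooled over all sequences; windows
    containing N are skipped. Raises when no full (r+1)-window exists.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    nctx = 4 ** order
    counts = np.zeros((nctx, 4))
    init_counts = np.zeros(nctx)
    mono_counts = np.zeros(4)
    n_windows = 0
    for _, seq in dataset:
        codes = encode(seq)
        for c in codes:
            if c >= 0:
                mono_counts[c] += 1
        for j in range(order, len(codes)):
            c = codes[j]
            if c < 0:
                continue
            ctx = _context_index(codes, j - order, order)
            if ctx < 0:
                continue
            counts[ctx, c] += 1
            init_counts[ctx] += 1
            n_windows += 1
    if n_windows == 0:
        raise ValueError(
            f"no complete window of length {order + 1}; "
            "order too large for this dataset"
        )
    trans = counts + pseudocount
    trans /= trans.sum(axis=1, keepdims=True)
    init = init_counts + pseudocount
    init /= init.sum()
    mono = mono_counts + pseudocount
    mono /= mono.sum()
    return BackgroundModel(order, init, trans, mono)


def markov_shuffle(
    dataset: SequenceDataset, order: int = 2, seed: int = 42
) -> SequenceDataset:
    """Control dataset sampled from the order-r chain fitted to ``dataset``.

    Output has identical n and per-sequence widths; reproducible under a
    fixed seed.
    """
    model = fit_background(dataset, order)
    rng = np.random.default_rng(seed)
    out = []
    for name, seq in dataset:
        out.append((name, model.sample_sequence(len(seq), rng)))
    return SequenceDataset(out)


def _euler_shuffle_core(seq: str, klet: int, rng: np.random.Generator) -> str:
    """Eulerian-path shuffle of an N-free segment, preserving exact
    klet-length substring counts (Altschul–Erickson)."""
    k1 = klet - 1
    n = len(seq)
    if n <= klet:
        return seq
    vertices = [seq[i:i + k1] for i in range(n - k1 + 1)]
    edges: dict[str, list[str]] = {}
    for a, b in zip(vertices[:-1], vertices[1:]):
        edges.setdefault(a, []).append(b)
    start, end = vertices[0], vertices[-1]
    verts = list(edges.keys())
    # Pick a random "last edge" out of every vertex except the end such
    # that following last edges always reaches the end vertex; rejection
    # sample until that arborescence condition holds.
    for _ in range(10000):
        last = {}
        ok_verts = [v for v in verts if v != end]
        for v in ok_verts:
            last[v] = edges[v][rng.integers(len(edges[v]))]
        reachable = True
        for v in ok_verts:
            seen = set()
            cur = v
            while cur != end:
                if cur in seen or cur not in last:
                    reachable = False
                    break
                seen.add(cur)
                cur = last[cur]
            if not reachable:
                break
        if reachable:
            break
    else:  # pragma: no cover - rejection loop essentially always succeeds
        raise RuntimeError("Euler shuffle failed to find an arborescence")
    # Shuffle the remaining edges of each vertex; append the last edge.
    order = {}
    for v in verts:
        rest = list(edges[v])
        if v in last:
            rest.remove(last[v])
        perm = list(rng.permutation(len(rest)))
        shuffled = [rest[i] for i in perm]
        if v in last:
            shuffled.append(last[v])
        order[v] = shuffled
    # Walk the Eulerian path.
    pos = {v: 0 for v in verts}
    out = [start]
    cur = start
    total_edges = n - k1
    for _ in range(total_edges):
        nxt = order[cur][pos[cur]]
        pos[cur] += 1
        out.append(nxt)
        cur = nxt
    return out[0] + "".join(v[-1] for v in out[1:])


def euler_shuffle(sequence: str, klet: int = 2, seed: int = 42) -> str:
    """Shuffle a sequence while preserving its exact klet-count table.

    The sequence is viewed as an Eulerian path on the (klet-1)-mer graph
    and a random alternative path with the same edge multiset is drawn, so
    the multiset of klet-length substrings — and hence the first and last
    (klet-1)-mers — is exactly preserved. Segments split by N are shuffled
    independently; runs of N stay in place.
    """
    if klet < 2:
        raise ValueError("klet must be >= 2")
    if len(sequence) < klet:
        raise ValueError(f"sequence shorter than klet={klet}")
    rng = np.random.default_rng(seed)
    out = []
    i = 0
    s = sequence
    while i < len(s):
        if s[i] == "N":
            j = i
            while j < len(s) and s[j] == "N":
                j += 1
            out.append(s[i:j])
            i = j
        else:
            j = i
            while j < len(s) and s[j] != "N":
                j += 1
            seg = s[i:j]
            out.append(_euler_shuffle_core(seg, klet, rng) if len(seg) >= klet else seg)
            i = j
    return "".join(out)
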