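"""Sparse motif tree: k-mer counting trie, exact and bounded-mismatch
search, enrichment testing, and structural diagnostics.

The trie over fixed-width k-mers is stored as a growable integer matrix
with six columns per node row: child pointers for A, C, G, T, the
occurrence count, and the 2-bit-per-base numeric code of the k-mer spelled
by the root-to-node path (meaningful at depth-k "totalization" nodes,
which aggregate counts). Node ids are row indices starting at the root,
id 1. Per-occurrence addresses — (sequence index, 0-based offset) pairs —
live in an auxiliary table keyed by terminal node id, since a single
matrix cell cannot hold a list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .background import BackgroundModel
from .seqio import ALPHABET, SequenceDataset, encode

#: practical k-mer width range; outside it a warning is emitted
K_RANGE = (5, 35)
#: the numeric code uses 2 bits per base in a signed 64-bit cell
K_CODE_MAX = 31

_COL_COUNT = 4
_COL_CODE = 5


@dataclass
class KmerMatch:
    """A stored k-mer returned by a bounded-mismatch search."""

    kmer: str
    count: int
    distance: int
    addresses: list[tuple[int, int]]


@dataclass
class EnrichedKmer:
    """A k-mer with its observed count, background expectation and
    significance."""

    kmer: str
    observed: int
    expected: float
    p_value: float
    q_value: float


@dataclass
class SmtMatrix:
    """Growable nu x 6 integer table encoding the k-mer trie.

    ``table`` rows are nodes (row 0 unused so node ids equal row indices);
    columns 0-3 hold child pointers (0 = absent), column 4 the count and
    column 5 the numeric code. ``nu`` is the number of allocated nodes.
    """

    k: int
    table: np.ndarray
    nu: int = 1
    root: int = 1
    addresses: dict[int, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def n_terminals(self) -> int:
        return len(self.addresses)

    def total_count(self) -> int:
        """Sum of terminal counts = number of inserted k-windows."""
        return int(sum(self.table[t, _COL_COUNT] for t in self.addresses))

    def iter_kmers(self):
        """Yield (kmer, count, addresses) for every stored k-mer, in
        lexicographic order."""
        stack = [(self.root, [])]
        while stack:
            node, prefix = stack.pop()
            if len(prefix) == self.k:
                yield (
                    "".join(ALPHABET[c] for c in prefix),
                    int(self.table[node, _COL_COUNT]),
                    self.addresses[node],
                )
                continue
            for sym in range(3, -1, -1):
                child = self.table[node, sym]
                if child:
                    stack.append((int(child), prefix + [sym]))

    def decode_terminal(self, node: int) -> str:
        """Spell the k-mer from a terminal node's numeric code."""
        code = int(self.table[node, _COL_CODE])
        out = []
        for _ in range(self.k):
            out.append(ALPHABET[code & 3])
            code >>= 2
        return "".join(reversed(out))


def _grow(table: np.ndarray) -> np.ndarray:
    new = np.zeros((table.shape[0] * 2, 6), dtype=np.int64)
    new[: table.shape[0]] = table
    return new


def create_smt(dataset: SequenceDataset, k: int) -> SmtMatrix:
    """Build the trie from every N-free k-window of every sequence.

    Shared prefixes share nodes; re-inserting an existing k-mer only
    increments the terminal count and appends the new address. Sequences
    shorter than k contribute nothing. The node table over-allocates
    geometrically so node creation is amortized O(1).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > K_CODE_MAX:
        raise ValueError(f"k must be <= {K_CODE_MAX} (numeric code is 2 bits/base in a 64-bit cell)")
    if not (K_RANGE[0] <= k <= K_RANGE[1]):
        warnings.warn(
            f"k={k} outside the practical motif-width range {K_RANGE}",
            stacklevel=2,
        )
    table = np.zeros((16, 6), dtype=np.int64)
    smt = SmtMatrix(k=k, table=table)
    new_node = 2
    for seq_idx, (_, seq) in enumerate(dataset):
        codes = encode(seq)
        t = len(codes)
        for u in range(t - k + 1):
            window = codes[u:u + k]
            if any(c < 0 for c in window):
                continue
            node = smt.root
            for c in window:
                child = smt.table[node, c]
                if child == 0:
                    if new_node >= smt.table.shape[0]:
                        smt.table = _grow(smt.table)
                    smt.table[node, c] = new_node
                    node = new_node
                    new_node += 1
                else:
                    node = int(child)
            smt.table[node, _COL_COUNT] += 1
            if smt.table[node, _COL_COUNT] == 1:
                code = 0
                for c in window:
                    code = (code << 2) | c
                smt.table[node, _COL_CODE] = code
                smt.addresses[node] = []
            smt.addresses[node].append((seq_idx, u))
    smt.nu = new_node - 1
    return smt


def ksearch(smt: SmtMatrix, query: str) -> tuple[int, list[tuple[int, int]]]:
    """Exact lookup: returns (count, addresses), or (0, []) when the path
    is absent."""
    if len(query) != smt.k:
        raise ValueError(f"query length {len(query)} != k={smt.k}")
    node = smt.root
    for ch in query:
        c = ALPHABET.index(ch)
        child = smt.table[node, c]
        if child == 0:
            return 0, []
        node = int(child)
    return int(smt.table[node, _COL_COUNT]), list(smt.addresses.get(node, []))


def kdive(
    smt: SmtMatrix,
    query: str,
    d_max: int,
    collect: bool = False,
):
    """Depth-first bounded-mismatch search.

    Walks all root-to-leaf paths, accumulating mismatches against
    ``query`` and pruning a branch as soon as the mutation budget ``d_max``
    is exceeded. Reaching depth k is a match. With ``collect=False``
    returns the boolean "is any stored k-mer within Hamming distance
    d_max"; with ``collect=True`` returns every matching terminal as a
    :class:`KmerMatch` (so ``d_max = k`` enumerates the whole tree).
    """
    if d_max < 0:
        raise ValueError("d_max must be >= 0")
    if len(query) != smt.k:
        raise ValueError(f"query length {len(query)} != k={smt.k}")
    qcodes = [ALPHABET.index(ch) for ch in query]
    k = smt.k
    table = smt.table
    matches: list[KmerMatch] = []

    def dive(node: int, i: int, d: int) -> bool:
        if i >= k:
            if collect:
                matches.append(
                    KmerMatch(
                        kmer=smt.decode_terminal(node),
                        count=int(table[node, _COL_COUNT]),
                        distance=d,
                        addresses=list(smt.addresses[node]),
                    )
                )
                return True
            return True
        found = False
        for sym in range(4):
            child = table[node, sym]
            if child == 0:
                continue
            nd = d + (sym != qcodes[i])
            if nd > d_max:  # budget exceeded: prune this branch
                continue
            if dive(int(child), i + 1, nd):
                found = True
                if not collect:
                    return True
        return found

    resp = dive(smt.root, 0, 0)
    if collect:
        matches.sort(key=lambda m: (m.distance, m.kmer))
        return matches
    return resp


def occupancy(smt: SmtMatrix) -> float:
    """Fraction of non-empty child-pointer cells: occupied / (4 * nu).

    For a balanced tree with on average two children per node this is 0.5;
    real trees fall below that because branching thins with depth.
    """
    child_block = smt.table[1:smt.nu + 1, :4]
    return float(np.count_nonzero(child_block) / (4 * smt.nu))


def simulate_kdive_cost(
    d: int, p: float, reps: int = 10**6, seed: int = 42
) -> float:
    """Monte-Carlo mean of the per-fragment comparison count.

    Each symbol comparison is a mismatch with probability ``p`` and a
    fragment's scan stops at its d-th mismatch, so the comparison count is
    a sum of d geometric draws with mean d/p (a negative-binomial stopping
    process). Returns the empirical mean over ``reps`` fragments.
    """
    if not (0 < p <= 1):
        raise ValueError("p must be in (0, 1]")
    if d < 1 or reps < 1:
        raise ValueError("d and reps must be >= 1")
    rng = np.random.default_rng(seed)
    # trials-until-first-mismatch, d independent stretches per fragment
    draws = rng.geometric(p, size=(reps, d))
    return float(draws.sum(axis=1).mean())


def extract_enriched(
    smt: SmtMatrix,
    bg: BackgroundModel,
    alpha: float = 0.001,
    top: int | None = None,
) -> list[EnrichedKmer]:
    """Test every stored k-mer for enrichment over the background.

    For k-mer w with observed count x out of m scanned windows, the
    expected count is m * P(w|background) and the p-value the one-sided
    binomial tail P(X >= x). q-values are Benjamini-Hochberg adjusted over
    all stored k-mers. Returns records with q <= alpha sorted by ascending
    q, then descending count, then k-mer, truncated to ``top``.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    entries = [(w, c) for w, c, _ in smt.iter_kmers()]
    if not entries:
        return []
    m = smt.total_count()
    pvals = np.empty(len(entries))
    expected = np.empty(len(entries))
    for i, (w, c) in enumerate(entries):
        pw = np.exp(bg.kmer_log_prob(w))
        expected[i] = m * pw
        pvals[i] = stats.binom.sf(c - 1, m, pw)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out = [
        EnrichedKmer(w, c, float(e), float(p), float(q))
        for (w, c), e, p, q in zip(entries, expected, pvals, qvals)
        if q <= alpha
    ]
    out.sort(key=lambda r: (r.q_value, -r.observed, r.kmer))
    return out[:top] if top else out


def group_seeds(
    smt: SmtMatrix,
    enriched: list[EnrichedKmer],
    d: int = 2,
    n_seeds: int = 10,
) -> list[EnrichedKmer]:
    """Greedily collapse enriched k-mers into mismatch neighborhoods.

    Repeatedly takes the most significant unclaimed k-mer, aggregates the
    counts of all stored k-mers within Hamming distance ``d`` of it (via
    the bounded-mismatch search), claims that whole neighborhood so later
    seeds cannot re-count it, and records the seed with the aggregated
    count. Claimed neighborhoods are therefore pairwise disjoint and the
    aggregated counts never double-count a window.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    if d == 0:
        return enriched[:n_seeds]
    claimed: set[str] = set()
    seeds: list[EnrichedKmer] = []
    for rec in enriched:
        if len(seeds) >= n_seeds:
            break
        if rec.kmer in claimed:
            continue
        hood = [m for m in kdive(smt, rec.kmer, d, collect=True)
                if m.kmer not in claimed]
        agg = sum(m.count for m in hood)
        claimed.update(m.kmer for m in hood)
        seeds.append(
            EnrichedKmer(rec.kmer, int(agg), rec.expected, rec.p_value, rec.q_value)
        )
    return seeds


def write_enriched_tsv(records: list[EnrichedKmer], path) -> None:
    """Write an enriched-k-mer table: kmer, observed, expected, p, q."""
    with open(path, "w") as fh:
        fh.write("kmer\tobserved\texpected\tp_value\tq_value\n")
        for r in records:
            fh.write(
                f"{r.kmer}\t{r.observed}\t{r.expected:.6g}"
                f"\t{r.p_value:.6g}\t{r.q_value:.6g}\n"
            )
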