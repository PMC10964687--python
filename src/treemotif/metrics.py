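"""PWM comparison: column metrics, whole-matrix scores, and alignment of
a discovered motif against a reference of possibly different width.

Six column-wise measures are computed between probability 4-vectors a, b:

* Euclidean distance   sqrt(sum (a-b)^2)            0 iff equal
* Manhattan distance   sum |a-b|                    0 iff equal
* Bhattacharyya coeff. sum sqrt(a*b)                1 iff equal
* Hellinger distance   sqrt(1 - Bhattacharyya)      0 iff equal
* Sandelin-Wasserman   2 - sum (a-b)^2              2 iff equal
* Pearson correlation  of the two 4-vectors         1 iff proportional

A matrix-level score is the unweighted mean of its column values over the
aligned columns; hence hell^2 + bha = 1 and sw = 2 - euc^2 hold per
column, not for the averaged report.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .em import Pwm

JASPAR_PSEUDOCOUNT = 0.8


@dataclass
class MetricsReport:
    """The six comparison scores for an aligned motif pair."""

    euc: float
    man: float
    hell: float
    pcc: float
    bha: float
    sw: float

    def as_dict(self) -> dict[str, float]:
        return {
            "euc": self.euc, "man": self.man, "hell": self.hell,
            "pcc": self.pcc, "bha": self.bha, "sw": self.sw,
        }


@dataclass
class Alignment:
    """Placement of a query PWM on a reference: query column 0 sits at
    reference column ``offset`` (may be negative); ``strand`` is '-' when
    the reverse complement of the query aligns."""

    offset: int
    strand: str
    overlap: int


def compare_columns(a, b) -> dict[str, float]:
    """All six metrics for one pair of probability 4-vectors."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != (4,) or b.shape != (4,):
        raise ValueError("columns must be probability 4-vectors")
    if abs(a.sum() - 1) > 1e-6 or abs(b.sum() - 1) > 1e-6:
        raise ValueError("columns must each sum to 1")
    diff = a - b
    sq = float(diff @ diff)
    bha = float(np.sqrt(a * b).sum())
    # guard the fp boundary so identical columns give hell exactly 0
    bha = 1.0 if bha > 1.0 - 1e-12 else bha
    va, vb = a - a.mean(), b - b.mean()
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na < 1e-12 or nb < 1e-12:
        # zero-variance convention: equal constant columns correlate
        # perfectly, anything else gets 0
        pcc = 1.0 if np.allclose(a, b, atol=1e-9) else 0.0
    else:
        pcc = float(va @ vb / (na * nb))
    return {
        "euc": float(np.sqrt(sq)),
        "man": float(np.abs(diff).sum()),
        "hell": float(np.sqrt(1.0 - bha)),
        "pcc": pcc,
        "bha": bha,
        "sw": 2.0 - sq,
    }


def compare_pwms(a: Pwm, b: Pwm) -> MetricsReport:
    """Mean column-wise metrics for two equal-width PWMs."""
    if a.width != b.width:
        raise ValueError(
            f"width mismatch ({a.width} vs {b.width}); align first"
        )
    cols = [compare_columns(a.matrix[j], b.matrix[j]) for j in range(a.width)]
    return MetricsReport(**{
        key: float(np.mean([c[key] for c in cols]))
        for key in ("euc", "man", "hell", "pcc", "bha", "sw")
    })


def align_to_reference(
    query: Pwm, ref: Pwm, min_overlap: int = 4
) -> tuple[Alignment, MetricsReport]:
    """Best placement of ``query`` (either strand) on ``ref``.

    Scans every offset giving at least ``min_overlap`` overlapping
    columns, on the query as-is and reverse-complemented, and returns the
    placement maximizing the mean Bhattacharyya coefficient together with
    the metrics over the overlapping columns.
    """
    if min_overlap < 4:
        raise ValueError("min_overlap must be >= 4")
    best = None
    for strand, q in (("+", query), ("-", query.reverse_complement())):
        kq, kr = q.width, ref.width
        for offset in range(-kq + min_overlap, kr - min_overlap + 1):
            lo_q = max(0, -offset)
            hi_q = min(kq, kr - offset)
            overlap = hi_q - lo_q
            if overlap < min_overlap:
                continue
            qa = Pwm(q.matrix[lo_q:hi_q])
            ra = Pwm(ref.matrix[lo_q + offset:hi_q + offset])
            report = compare_pwms(qa, ra)
            key = (report.bha, strand == "+", -abs(offset))
            if best is None or key > best[0]:
                best = (key, Alignment(offset, strand, overlap), report)
    if best is None:
        raise ValueError("no offset achieves the minimum overlap")
    return best[1], best[2]


# --- JASPAR PFM and MEME minimal formats ---------------------------------

_ROW_RE = re.compile(r"^([ACGT])\s*\[?\s*([-\d.eE+\s]*?)\s*\]?\s*$")


def read_jaspar_pfm(
    path: str | Path, pseudocount: float = JASPAR_PSEUDOCOUNT
) -> list[tuple[str, Pwm]]:
    """Read JASPAR PFM motifs (">ID NAME" header, four count rows).

    Counts get ``pseudocount`` split evenly across the four cells of each
    column before normalization; the matrix is transposed into the k x 4
    row convention.
    """
    text = Path(path).read_text()
    out: list[tuple[str, Pwm]] = []
    name = None
    rows: dict[str, list[float]] = {}
    order = "ACGT"

    def flush():
        if name is None:
            return
        if set(rows) != set(order):
            raise ValueError(f"motif {name}: expected rows A,C,G,T, got {sorted(rows)}")
        lens = {len(rows[b]) for b in order}
        if len(lens) != 1:
            raise ValueError(f"motif {name}: rows of unequal length")
        counts = np.array([rows[b] for b in order]).T  # k x 4
        counts = counts + pseudocount / 4.0
        probs = counts / counts.sum(axis=1, keepdims=True)
        out.append((name, Pwm(probs)))

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].split()[0]
            rows = {}
            continue
        m = _ROW_RE.match(line)
        if not m:
            raise ValueError(f"unparseable PFM row: {line!r}")
        rows[m.group(1)] = [float(x) for x in m.group(2).split()]
    flush()
    if not out:
        raise ValueError(f"{path}: no motifs found")
    return out


def write_jaspar_pfm(
    motifs: list[tuple[str, Pwm]], path: str | Path, nsites: int = 100
) -> None:
    """Write PWMs as JASPAR PFMs, scaling probabilities to ``nsites``
    pseudo-counts."""
    lines = []
    for name, pwm in motifs:
        lines.append(f">{name} {name}")
        counts = pwm.matrix.T * nsites  # 4 x k
        for b, row in zip("ACGT", counts):
            cells = " ".join(f"{x:10.4f}" for x in row)
            lines.append(f"{b} [ {cells} ]")
    Path(path).write_text("\n".join(lines) + "\n")


def write_meme(
    motifs: list[tuple[str, Pwm, int]],
    path: str | Path,
    background: np.ndarray | None = None,
) -> None:
    """Write motifs in MEME minimal format.

    ``motifs`` entries are (name, pwm, nsites). ``background`` is the
    A,C,G,T frequency vector for the header (uniform when omitted).
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    lines = [
        "MEME version 4", "",
        "ALPHABET= ACGT", "",
        "strands: + -", "",
        "Background letter frequencies",
        "A {:.5f} C {:.5f} G {:.5f} T {:.5f}".format(*bg), "",
    ]
    for name, pwm, nsites in motifs:
        lines.append(f"MOTIF {name}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= {nsites} E= 0"
        )
        for row in pwm.matrix:
            lines.append(" " + " ".join(f"{x:.6f}" for x in row))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_metrics_tsv(
    pairs: list[tuple[str, str, MetricsReport]], path: str | Path
) -> None:
    """One row per (query id, reference id) pair with the six scores."""
    with open(path, "w") as fh:
        fh.write("query\treference\teuc\tman\thell\tpcc\tbha\tsw\n")
        for q, r, rep in pairs:
            fh.write(
                f"{q}\t{r}\t{rep.euc:.6f}\t{rep.man:.6f}\t{rep.hell:.6f}"
                f"\t{rep.pcc:.6f}\t{rep.bha:.6f}\t{rep.sw:.6f}\n"
            )
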