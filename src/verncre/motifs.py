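"""Position weight matrices: log-odds scanning and exact p-value thresholds.

Scores are scanned on both strands.  The score threshold for a requested
p-value is derived from the exact distribution of the log-odds score of a
random background sequence, computed by dynamic programming over a
discretized score lattice (convolution of per-position score
distributions), the same construction TFM-Pvalue and MOODS use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq))


@dataclass
class PWM:
    """Probability matrix over ACGT with a background model."""

    motif_id: str
    matrix: np.ndarray                      # L x 4 probabilities
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudo: float = 0.01

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix + self.pseudo
        self.matrix = m / m.sum(axis=1, keepdims=True)
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_consensus(cls, motif_id: str, consensus: str, p: float = 0.9) -> "PWM":
        q = (1.0 - p) / 3.0
        mat = np.full((len(consensus), 4), q)
        for i, b in enumerate(consensus.upper()):
            mat[i, ALPHABET.index(b)] = p
        return cls(motif_id, mat)

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background[None, :])

    def score_pvalue_threshold(self, p_threshold: float, grid: float = 1e-3) -> float:
        """Smallest score s with P(score >= s | background) <= p_threshold.

        For motifs up to 10 bp the full score distribution is expanded
        exactly; longer motifs use a lattice DP with per-position scores
        rounded up, so the lattice tail dominates the true tail and the
        returned threshold stays conservative.
        """
        lo = self.log_odds()
        if len(self) <= 10:
            scores = np.zeros(1)
            probs = np.ones(1)
            for i in range(len(self)):
                scores = (scores[:, None] + lo[i][None, :]).ravel()
                probs = (probs[:, None] * self.background[None, :]).ravel()
            order = np.argsort(-scores)
            uniq, inverse = np.unique(np.round(-scores[order], 12),
                                      return_inverse=True)
            tail_by_word = np.cumsum(probs[order])
            # tail probability at each distinct score (ties included)
            last_idx = np.flatnonzero(np.r_[np.diff(inverse) != 0, True])
            tail = tail_by_word[last_idx]
            values = -uniq[inverse[last_idx]]
            ok = np.flatnonzero(tail <= p_threshold)
            if ok.size == 0:
                return float(values[0] + 1.0)
            # tiny slack absorbs summation-order rounding in the scanner;
            # ties at the threshold are already counted in the tail
            return float(values[ok[-1]]) - 1e-9
        q = np.ceil(lo / grid).astype(np.int64)
        offset = q.min(axis=1)
        dist = {0: 1.0}  # lattice score (minus running offset) -> probability
        for i in range(len(self)):
            new: dict[int, float] = {}
            for s, pr in dist.items():
                for b in range(4):
                    key = s + int(q[i, b] - offset[i])
                    new[key] = new.get(key, 0.0) + pr * self.background[b]
            dist = new
        base = int(offset.sum())
        scores = np.array(sorted(dist), dtype=np.int64)
        probs = np.array([dist[int(s)] for s in scores])
        tail = np.cumsum(probs[::-1])[::-1]
        ok = np.flatnonzero(tail <= p_threshold)
        if ok.size == 0:
            return float((scores[-1] + base + 1) * grid)
        return float((scores[ok[0]] + base) * grid)


@dataclass(frozen=True)
class MotifHit:
    element_id: str
    motif_id: str
    position: int        # 0-based offset on the forward strand
    strand: str
    score: float


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(ALPHABET):
        code[ord(b)] = i
    return code[arr]


def _scan_one_strand(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    L = lo.shape[0]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for i in range(L):
        window = codes[i : i + n]
        bad = window < 0
        valid &= ~bad
        scores += np.where(bad, 0.0, lo[i, np.clip(window, 0, 3)])
    scores[~valid] = -np.inf
    return scores


def scan_motifs(
    sequences: dict[str, str],
    pwms: list[PWM],
    p_threshold: float = 1e-4,
) -> list[MotifHit]:
    """Log-odds scan of both strands of each sequence.

    A hit is reported wherever the score reaches the exact-DP threshold
    for `p_threshold` under the PWM's background model.
    """
    hits: list[MotifHit] = []
    for pwm in pwms:
        lo = pwm.log_odds()
        thr = pwm.score_pvalue_threshold(p_threshold)
        for elem_id, seq in sequences.items():
            if len(seq) < len(pwm):
                continue
            codes = _encode(seq)
            fwd = _scan_one_strand(codes, lo)
            for pos in np.flatnonzero(fwd >= thr):
                hits.append(MotifHit(elem_id, pwm.motif_id, int(pos), "+", float(fwd[pos])))
            rc = _encode(revcomp(seq))
            rev = _scan_one_strand(rc, lo)
            n = len(seq) - len(pwm)
            for pos in np.flatnonzero(rev >= thr):
                hits.append(MotifHit(elem_id, pwm.motif_id, int(n - pos), "-", float(rev[pos])))
    hits.sort(key=lambda h: (h.motif_id, h.element_id, h.position, h.strand))
    return hits


# ---------------------------------------------------------------- JASPAR I/O

def write_pwms(path, pwms: list[PWM], counts_scale: int = 100) -> None:
    """JASPAR 2016 matrix format (counts = probabilities x scale)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\t{pwm.motif_id}\n")
            counts = np.rint(pwm.matrix * counts_scale).astype(int)
            for j, base in enumerate(ALPHABET):
                row = "  ".join(f"{c:6d}" for c in counts[:, j])
                fh.write(f"{base}  [{row} ]\n")


def read_pwms(path) -> list[PWM]:
    """Read JASPAR text via Bio.motifs into PWM objects."""
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in ALPHABET], dtype=float).T
            mat = counts / counts.sum(axis=1, keepdims=True)
            out.append(PWM(m.matrix_id or m.name, mat))
    return out
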