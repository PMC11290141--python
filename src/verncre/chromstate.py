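"""Chromatin-state segmentation with a multivariate Bernoulli-emission HMM.

The genome is tiled into fixed bins; each of the five tracks (ATAC plus
four histone marks) is binarized per bin, and a K-state hidden Markov
model with independent Bernoulli emissions per track is trained by
Baum-Welch (scaled forward-backward, chromosome-boundary resets).
States are mapped onto four biological labels — activated, repressed,
mixed, unmodified — from their emission profiles, and per-gene labels
before/after treatment feed a transition analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genomio import Track
from .intervals import GeneModel, Interval

LABELS = ("activated", "repressed", "mixed", "unmodified")
LABEL_PRECEDENCE = {"mixed": 0, "activated": 1, "repressed": 2, "unmodified": 3}
DEFAULT_TRACKS = ("ATAC", "H3K4me3", "H3K36me3", "H3K27me3", "H3K27ac")


# ------------------------------------------------------------- binarization

@dataclass
class BinarizedMatrix:
    """Per-bin 0/1 calls for a set of tracks, chromosome by chromosome."""

    bin_size: int
    marks: tuple[str, ...]
    data: dict[str, np.ndarray]     # chrom -> (n_bins, n_marks) uint8

    def sequences(self) -> list[np.ndarray]:
        return [self.data[c] for c in sorted(self.data)]

    @property
    def n_bins(self) -> int:
        return sum(v.shape[0] for v in self.data.values())


def n_bins_for(length: int, bin_size: int) -> int:
    return -(-length // bin_size)


def binarize_peaks(
    peaks: list[Interval], chrom_sizes: dict[str, int], bin_size: int = 200
) -> dict[str, np.ndarray]:
    """Bin = 1 iff it overlaps a peak by >= 1 bp."""
    out = {c: np.zeros(n_bins_for(n, bin_size), dtype=np.uint8)
           for c, n in chrom_sizes.items()}
    for iv in peaks:
        arr = out.get(iv.chrom)
        if arr is None:
            continue
        b0, b1 = iv.start // bin_size, min(n_bins_for(iv.end, bin_size), arr.size)
        arr[b0:b1] = 1
    return out


def binarize_coverage(
    track: Track, bin_size: int = 200, p_threshold: float = 1e-4
) -> dict[str, np.ndarray]:
    """Bin = 1 iff the Poisson upper tail of its count vs the genome-wide
    mean per-bin rate is below p_threshold."""
    sums = {}
    total = 0.0
    nbins = 0
    for c, arr in track.items():
        n = n_bins_for(arr.size, bin_size)
        padded = np.zeros(n * bin_size)
        padded[: arr.size] = arr
        sums[c] = padded.reshape(n, bin_size).sum(axis=1)
        total += float(arr.sum())
        nbins += n
    lam = total / max(nbins, 1)
    return {
        c: (stats.poisson.sf(s - 1, lam) < p_threshold).astype(np.uint8)
        for c, s in sums.items()
    }


def stack_tracks(
    per_track: dict[str, dict[str, np.ndarray]],
    marks: tuple[str, ...] = DEFAULT_TRACKS,
    bin_size: int = 200,
) -> BinarizedMatrix:
    chroms = sorted(next(iter(per_track.values())))
    data = {
        c: np.stack([per_track[m][c] for m in marks], axis=1).astype(np.uint8)
        for c in chroms
    }
    return BinarizedMatrix(bin_size, tuple(marks), data)


# -------------------------------------------------------------------- model

@dataclass
class HMMModel:
    emissions: np.ndarray            # K x M Bernoulli probabilities
    transitions: np.ndarray          # K x K
    initial: np.ndarray              # K
    marks: tuple[str, ...]
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return self.emissions.shape[0]

    def validate(self) -> None:
        assert np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(self.initial.sum(), 1.0, atol=1e-9)
        assert ((self.emissions > 0) & (self.emissions < 1)).all()

    def to_json(self, path, label_map: dict[int, str] | None = None) -> None:
        obj = dict(
            n_states=self.n_states,
            marks=list(self.marks),
            emissions=self.emissions.tolist(),
            transitions=self.transitions.tolist(),
            initial=self.initial.tolist(),
            loglik_trace=self.loglik_trace,
        )
        if label_map is not None:
            obj["label_map"] = {str(k): v for k, v in label_map.items()}
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "HMMModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            np.array(obj["emissions"]), np.array(obj["transitions"]),
            np.array(obj["initial"]), tuple(obj["marks"]),
            obj.get("loglik_trace", []),
        )


def _log_emission_matrix(X: np.ndarray, emissions: np.ndarray) -> np.ndarray:
    """(T, K) log P(x_t | state k) for 0/1 rows under product-Bernoulli."""
    logp = np.log(emissions)
    log1p = np.log1p(-emissions)
    return X @ logp.T + (1 - X) @ log1p.T


try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (a and callable(a[0])) else a[0]


@njit(cache=True)
def _fb_kernel(B, A, pi):
    """Scaled forward-backward on the (row-max-normalized) emission matrix."""
    T, K = B.shape
    alpha = np.empty((T, K))
    beta = np.empty((T, K))
    c = np.empty(T)
    s = 0.0
    for k in range(K):
        alpha[0, k] = pi[k] * B[0, k]
        s += alpha[0, k]
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        s = 0.0
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += alpha[t - 1, j] * A[j, k]
            alpha[t, k] = acc * B[t, k]
            s += alpha[t, k]
        c[t] = s
        for k in range(K):
            alpha[t, k] /= s
    for k in range(K):
        beta[T - 1, k] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        denom = 0.0
        for j in range(K):
            bb = B[t + 1, j] * beta[t + 1, j]
            for i in range(K):
                denom += alpha[t, i] * A[i, j] * bb
        for i in range(K):
            acc = 0.0
            for j in range(K):
                bb = B[t + 1, j] * beta[t + 1, j]
                xi_sum[i, j] += alpha[t, i] * A[i, j] * bb / denom
                acc += A[i, j] * bb
            beta[t, i] = acc / c[t + 1]
    gamma = alpha * beta
    for t in range(T):
        s = 0.0
        for k in range(K):
            s += gamma[t, k]
        for k in range(K):
            gamma[t, k] /= s
    return gamma, xi_sum, np.sum(np.log(c))


def _forward_backward(logB: np.ndarray, A: np.ndarray, pi: np.ndarray):
    """Scaled forward-backward; returns (gamma, xi_sum, loglik)."""
    rowmax = logB.max(axis=1)
    B = np.exp(logB - rowmax[:, None])
    gamma, xi_sum, log_c = _fb_kernel(B, A, pi)
    # log(c) recovers the likelihood up to the per-row max subtracted from logB
    return gamma, xi_sum, float(log_c + rowmax.sum())


def sequence_loglik(model: HMMModel, X: np.ndarray) -> float:
    logB = _log_emission_matrix(X.astype(float), model.emissions)
    _, _, ll = _forward_backward(logB, model.transitions, model.initial)
    return ll


def train_hmm(
    binarized: BinarizedMatrix,
    n_states: int = 9,
    max_iter: int = 200,
    tol: float = 1e-4,
    restarts: int = 3,
    seed: int = 0,
    eps: float = 1e-4,
) -> HMMModel:
    """Baum-Welch with chromosome-boundary resets and seeded restarts.

    Emissions are clipped to [eps, 1-eps] to keep likelihoods finite on
    degenerate inputs.  The best of `restarts` random initializations is
    returned with states re-ordered by descending total emission (most
    "active" state first) so output files are byte-stable.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    seqs = [s.astype(float) for s in binarized.sequences()]
    if n_states == 1:
        # closed form: emissions are the observed marginal frequencies
        X = np.concatenate(seqs, axis=0)
        p = np.clip(X.mean(axis=0, keepdims=True), eps, 1 - eps)
        ll = float(np.sum(X @ np.log(p.T) + (1 - X) @ np.log(1 - p.T)))
        model = HMMModel(p, np.ones((1, 1)), np.ones(1), binarized.marks, [ll])
        model.validate()
        return model
    total_bins = sum(s.shape[0] for s in seqs)
    if total_bins < n_states * 50:
        raise ValueError(f"need >= {n_states * 50} bins to train {n_states} states")
    M = seqs[0].shape[1]
    best: HMMModel | None = None
    for r in range(restarts):
        rng = np.random.default_rng([seed, r])
        p = np.clip(rng.uniform(0.1, 0.9, size=(n_states, M)), eps, 1 - eps)
        A = rng.uniform(0.5, 1.5, size=(n_states, n_states)) + 5.0 * np.eye(n_states)
        A /= A.sum(axis=1, keepdims=True)
        pi = np.full(n_states, 1.0 / n_states)
        trace: list[float] = []
        for _ in range(max_iter):
            g_sum = np.zeros((n_states, M))
            g_tot = np.zeros(n_states)
            xi_tot = np.zeros((n_states, n_states))
            pi_new = np.zeros(n_states)
            ll = 0.0
            for X in seqs:
                logB = _log_emission_matrix(X, p)
                gamma, xi, l = _forward_backward(logB, A, pi)
                g_sum += gamma.T @ X
                g_tot += gamma.sum(axis=0)
                xi_tot += xi
                pi_new += gamma[0]
                ll += l
            trace.append(ll)
            p = np.clip(g_sum / g_tot[:, None], eps, 1 - eps)
            A = xi_tot / np.maximum(xi_tot.sum(axis=1, keepdims=True), 1e-300)
            A = np.clip(A, 1e-12, None)
            A /= A.sum(axis=1, keepdims=True)
            pi = pi_new / pi_new.sum()
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * abs(trace[-2]):
                break
        model = HMMModel(p, A, pi, binarized.marks, trace)
        if best is None or trace[-1] > best.loglik_trace[-1]:
            best = model
    assert best is not None
    order = np.argsort(-best.emissions.sum(axis=1), kind="mergesort")
    best = HMMModel(
        best.emissions[order],
        best.transitions[np.ix_(order, order)],
        best.initial[order],
        best.marks,
        best.loglik_trace,
    )
    best.validate()
    return best


def posterior(model: HMMModel, X: np.ndarray) -> np.ndarray:
    logB = _log_emission_matrix(X.astype(float), model.emissions)
    gamma, _, _ = _forward_backward(logB, model.transitions, model.initial)
    return gamma


def viterbi(model: HMMModel, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Most probable state path and its joint log-probability."""
    logB = _log_emission_matrix(X.astype(float), model.emissions)
    logA = np.log(model.transitions)
    T, K = logB.shape
    delta = np.empty((T, K))
    psi = np.zeros((T, K), dtype=np.int64)
    delta[0] = np.log(model.initial) + logB[0]
    for t in range(1, T):
        step = delta[t - 1][:, None] + logA
        psi[t] = step.argmax(axis=0)
        delta[t] = step.max(axis=0) + logB[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = delta[-1].argmax()
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, float(delta[-1].max())


# ----------------------------------------------------------------- decoding

@dataclass(frozen=True)
class StateSegment:
    interval: Interval
    state: int
    label: str


def decode_states(
    model: HMMModel,
    binarized: BinarizedMatrix,
    label_map: dict[int, str] | None = None,
) -> tuple[list[StateSegment], dict[str, np.ndarray]]:
    """Per-bin argmax-posterior state per chromosome, merged into segments."""
    if binarized.marks != model.marks:
        raise ValueError(
            f"track sets differ: model {model.marks} vs data {binarized.marks}"
        )
    if label_map is None:
        label_map = label_states(model)
    segments: list[StateSegment] = []
    per_bin: dict[str, np.ndarray] = {}
    bs = binarized.bin_size
    for chrom in sorted(binarized.data):
        states = posterior(model, binarized.data[chrom]).argmax(axis=1)
        per_bin[chrom] = states
        start = 0
        for t in range(1, len(states) + 1):
            if t == len(states) or states[t] != states[start]:
                st = int(states[start])
                segments.append(StateSegment(
                    Interval(chrom, start * bs, t * bs, name=f"state{st}"),
                    st, label_map[st],
                ))
                start = t
    return segments, per_bin


# ----------------------------------------------------------------- labeling

def label_states(
    model: HMMModel,
    active_marks: tuple[str, ...] = ("ATAC", "H3K4me3", "H3K36me3", "H3K27ac"),
    repressive_mark: str = "H3K27me3",
    thresh: float = 0.5,
) -> dict[int, str]:
    """Emission-based A/R/M/U map: active mark > thresh and/or H3K27me3 > thresh."""
    act_idx = [model.marks.index(m) for m in active_marks if m in model.marks]
    rep_idx = model.marks.index(repressive_mark)
    out = {}
    for k in range(model.n_states):
        active = bool((model.emissions[k, act_idx] > thresh).any())
        repressed = bool(model.emissions[k, rep_idx] > thresh)
        if active and repressed:
            out[k] = "mixed"
        elif active:
            out[k] = "activated"
        elif repressed:
            out[k] = "repressed"
        else:
            out[k] = "unmodified"
    return out


# --------------------------------------------------------------- gene labels

def gene_state(
    per_bin_labels: dict[str, np.ndarray],
    label_map: dict[int, str],
    genes: list[GeneModel],
    bin_size: int = 200,
    promoter_up: int = 2000,
) -> pd.Series:
    """bp-majority label over gene body plus 2 kb upstream.

    Ties break by mixed > activated > repressed > unmodified; genes on
    undecoded chromosomes get "unassigned".
    """
    labels = {}
    for g in genes:
        states = per_bin_labels.get(g.chrom)
        if states is None:
            labels[g.gene_id] = "unassigned"
            continue
        if g.strand == "+":
            s, e = max(0, g.interval.start - promoter_up), g.interval.end
        else:
            s, e = g.interval.start, g.interval.end + promoter_up
        b0, b1 = s // bin_size, min(-(-e // bin_size), len(states))
        if b1 <= b0:
            labels[g.gene_id] = "unassigned"
            continue
        bp: dict[str, int] = {}
        for b in range(b0, b1):
            lo, hi = max(s, b * bin_size), min(e, (b + 1) * bin_size)
            lab = label_map[int(states[b])]
            bp[lab] = bp.get(lab, 0) + (hi - lo)
        best = max(bp.items(), key=lambda kv: (kv[1], -LABEL_PRECEDENCE[kv[0]]))
        labels[g.gene_id] = best[0]
    return pd.Series(labels)


def state_transitions(
    labels_before: pd.Series, labels_after: pd.Series
) -> tuple[pd.DataFrame, float]:
    """(before, after) label transition counts and the maintained fraction."""
    missing = set(labels_before.index) ^ set(labels_after.index)
    if missing:
        raise ValueError(f"gene universes differ; mismatched ids: {sorted(missing)[:5]}")
    cats = list(LABELS) + ["unassigned"]
    table = pd.DataFrame(0, index=cats, columns=cats)
    for gid in labels_before.index:
        table.loc[labels_before[gid], labels_after[gid]] += 1
    assessed = table.loc[list(LABELS), list(LABELS)]
    total = int(assessed.to_numpy().sum())
    maintained = float(np.trace(assessed.to_numpy()) / total) if total else float("nan")
    return table, maintained
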