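"""Multivariate Bernoulli hidden Markov model over binarized mark presence.

The genome is tiled into 50-bp windows; each window carries a 0/1 vector
of mark presence (one bit per histone PTM / factor).  A K-state HMM with
product-Bernoulli emissions ``P(x | k) = prod_m E[k,m]^x_m (1-E[k,m])^(1-x_m)``
is learned by Baum-Welch EM jointly across tissues (every chromosome of
every tissue is an independent observation sequence sharing one parameter
set) and windows are decoded by the forward-backward posterior maximum.

The model object follows the Model/Results convention: ``BernoulliHMM``
is built from the binary matrices, ``fit()`` returns an ``HMMResults``
carrying emissions, transitions, the training log-likelihood trace and a
``summary()`` table, with ``segment()`` / enrichment helpers hanging off
the results.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from . import intervals as iv
from .containers import BinaryMatrix, Cher, GenomeAnnotation, Segmentation

log = logging.getLogger(__name__)

EMISSION_FLOOR = 1e-6


def binarize(
    chers_by_mark: Mapping[str, Sequence[Cher]],
    genome: GenomeAnnotation,
    window_bp: int = 50,
    tissue: str = "",
    mark_names: Optional[Sequence[str]] = None,
) -> BinaryMatrix:
    """Mark-presence matrix on the fixed window grid.

    A mark is present in window ``w`` iff ``[w*window_bp, (w+1)*window_bp)``
    overlaps one of its (final, replicate-combined) chers by >= 1 bp.
    Partial trailing windows are dropped; a cher beyond its chromosome end
    is an error.
    """
    marks = list(mark_names) if mark_names is not None else sorted(chers_by_mark)
    lengths = genome.chromosomes["length"]
    data = {
        chrom: np.zeros((int(L) // window_bp, len(marks)), dtype=np.uint8)
        for chrom, L in lengths.items()
    }
    for mi, mark in enumerate(marks):
        for c in chers_by_mark.get(mark, []):
            if c.chrom not in data:
                raise ValueError(f"cher on unknown chromosome {c.chrom}")
            if c.end > int(lengths[c.chrom]):
                raise ValueError(
                    f"{mark} cher [{c.start},{c.end}) beyond end of {c.chrom}"
                )
            n_w = data[c.chrom].shape[0]
            w0 = max(0, c.start // window_bp)
            w1 = min(n_w - 1, (c.end - 1) // window_bp)
            if w1 >= w0:
                data[c.chrom][w0 : w1 + 1, mi] = 1
    return BinaryMatrix(tissue=tissue, window_bp=window_bp, mark_names=marks, data=data)


def _emission_loglik(x: np.ndarray, emissions: np.ndarray) -> np.ndarray:
    """(T, K) log P(x_t | k); emissions are clipped away from exact 0/1."""
    e = np.clip(emissions, 1e-12, 1.0 - 1e-12)
    xf = x.astype(float)
    return xf @ np.log(e).T + (1.0 - xf) @ np.log1p(-e).T


try:  # compiled recursion kernels; the numpy path below is the reference
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a standard install here
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@_njit(cache=True)
def _fb_kernel(b, pi, a):  # pragma: no cover - exercised via _forward_backward
    t_len, k = b.shape
    alpha = np.empty((t_len, k))
    scale = np.empty(t_len)
    s = 0.0
    for j in range(k):
        alpha[0, j] = pi[j] * b[0, j]
        s += alpha[0, j]
    scale[0] = s
    if s <= 0:
        return alpha, np.zeros((k, k)), scale
    for j in range(k):
        alpha[0, j] /= s
    for t in range(1, t_len):
        s = 0.0
        for j in range(k):
            v = 0.0
            for i in range(k):
                v += alpha[t - 1, i] * a[i, j]
            v *= b[t, j]
            alpha[t, j] = v
            s += v
        scale[t] = s
        if s <= 0:
            return alpha, np.zeros((k, k)), scale
        for j in range(k):
            alpha[t, j] /= s
    beta = np.ones(k)
    xi_sum = np.zeros((k, k))
    gamma = np.empty((t_len, k))
    for j in range(k):
        gamma[t_len - 1, j] = alpha[t_len - 1, j]
    for t in range(t_len - 2, -1, -1):
        c = scale[t + 1]
        beta_new = np.empty(k)
        for i in range(k):
            acc = 0.0
            for j in range(k):
                bb = b[t + 1, j] * beta[j]
                xi_sum[i, j] += alpha[t, i] * a[i, j] * bb / c
                acc += a[i, j] * bb
            beta_new[i] = acc / c
        g = 0.0
        for i in range(k):
            gamma[t, i] = alpha[t, i] * beta_new[i]
            g += gamma[t, i]
        for i in range(k):
            gamma[t, i] /= g
        beta = beta_new
    return gamma, xi_sum, scale


def _forward_backward(
    b: np.ndarray, pi: np.ndarray, a: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Scaled forward-backward.

    ``b`` holds per-window emission likelihoods up to a per-row constant
    (row-rescaled is fine: the constants cancel in gamma/xi and are added
    back to the log-likelihood by the caller).  Returns (gamma, xi_sum,
    sum of log scale factors).
    """
    if _HAVE_NUMBA:
        gamma, xi_sum, scale = _fb_kernel(
            np.ascontiguousarray(b, dtype=np.float64),
            np.ascontiguousarray(pi, dtype=np.float64),
            np.ascontiguousarray(a, dtype=np.float64),
        )
        if np.any(scale <= 0):
            raise FloatingPointError("observation has zero likelihood under the model")
        return gamma, xi_sum, float(np.log(scale).sum())
    t_len, k = b.shape
    alpha = np.empty((t_len, k))
    scale = np.empty(t_len)
    v = pi * b[0]
    scale[0] = v.sum()
    if scale[0] <= 0:
        raise FloatingPointError("observation has zero likelihood under the model")
    alpha[0] = v / scale[0]
    for t in range(1, t_len):
        v = (alpha[t - 1] @ a) * b[t]
        scale[t] = v.sum()
        if scale[t] <= 0:
            raise FloatingPointError("observation has zero likelihood under the model")
        alpha[t] = v / scale[t]
    beta = np.empty((t_len, k))
    beta[-1] = 1.0
    xi_sum = np.zeros((k, k))
    for t in range(t_len - 2, -1, -1):
        bb = b[t + 1] * beta[t + 1]
        xi_sum += np.outer(alpha[t], bb) * a / scale[t + 1]
        beta[t] = (a @ bb) / scale[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma, xi_sum, float(np.log(scale).sum())


def _scaled_b(x: np.ndarray, emissions: np.ndarray) -> Tuple[np.ndarray, float]:
    logb = _emission_loglik(x, emissions)
    shift = logb.max(axis=1)
    return np.exp(logb - shift[:, None]), float(shift.sum())


class BernoulliHMM:
    """K-state HMM with independent Bernoulli emissions per mark.

    Parameters
    ----------
    matrices
        One or more :class:`BinaryMatrix` (e.g. one per tissue).  All must
        share the same mark set and ordering; each chromosome of each
        matrix is an independent observation sequence (joint learning
        across tissues).
    n_states
        Number of hidden chromatin states (15 or 50 in typical use).
    """

    def __init__(self, matrices: Sequence[BinaryMatrix], n_states: int):
        matrices = list(matrices)
        if not matrices:
            raise ValueError("at least one BinaryMatrix is required")
        if n_states < 1:
            raise ValueError("n_states must be >= 1")
        marks = matrices[0].mark_names
        for m in matrices[1:]:
            if m.mark_names != marks:
                raise ValueError("all matrices must share an identical mark ordering")
        self.matrices = matrices
        self.n_states = int(n_states)
        self.mark_names = list(marks)
        self.sequences: List[np.ndarray] = []
        for m in matrices:
            self.sequences.extend(m.sequences())
        self.sequences = [s for s in self.sequences if s.shape[0] > 0]
        total = sum(s.shape[0] for s in self.sequences)
        if total == 0:
            raise ValueError("empty binary matrices")
        if self.n_states > total:
            raise ValueError(f"n_states={n_states} exceeds total windows {total}")
        self._marginal = (
            np.concatenate(self.sequences).astype(float).mean(axis=0)
            if self.sequences
            else None
        )

    # -- estimation ---------------------------------------------------------

    def _init_params(self, rng: np.random.Generator, diag: float = 0.8):
        k, m = self.n_states, len(self.mark_names)
        emissions = np.clip(
            self._marginal[None, :] + rng.uniform(-0.25, 0.25, size=(k, m)), 0.02, 0.98
        )
        if k == 1:
            a = np.ones((1, 1))
        else:
            a = np.full((k, k), (1.0 - diag) / (k - 1))
            np.fill_diagonal(a, diag)
        pi = np.full(k, 1.0 / k)
        return pi, a, emissions

    def _em(self, pi, a, emissions, tol: float, max_iter: int):
        k = self.n_states
        history: List[float] = []
        for _ in range(max_iter):
            ll_total = 0.0
            pi_acc = np.zeros(k)
            trans_acc = np.zeros((k, k))
            gamma_tot = np.zeros(k)
            x_weighted = np.zeros((k, len(self.mark_names)))
            for x in self.sequences:
                b, shift = _scaled_b(x, emissions)
                gamma, xi, ll = _forward_backward(b, pi, a)
                ll_total += ll + shift
                pi_acc += gamma[0]
                trans_acc += xi
                gamma_tot += gamma.sum(axis=0)
                x_weighted += gamma.T @ x.astype(float)
            history.append(ll_total)
            # M-step
            pi = pi_acc / pi_acc.sum()
            rows = trans_acc.sum(axis=1, keepdims=True)
            a_new = np.where(rows > 0, trans_acc / np.where(rows > 0, rows, 1.0), 1.0 / k)
            a = a_new / a_new.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore"):
                e_new = x_weighted / gamma_tot[:, None]
            e_new = np.where(gamma_tot[:, None] > 0, e_new, emissions)
            emissions = np.clip(e_new, EMISSION_FLOOR, 1.0 - EMISSION_FLOOR)
            if len(history) > 1 and history[-1] - history[-2] < tol:
                break
        return pi, a, emissions, history

    def fit(
        self,
        seed: int = 0,
        n_restarts: int = 5,
        tol: float = 1e-4,
        max_iter: int = 500,
    ) -> "HMMResults":
        """Baum-Welch EM with random restarts; the best-likelihood restart wins."""
        best = None
        restart_logliks = []
        for r in range(max(1, n_restarts)):
            rng = np.random.default_rng([int(seed), r])
            pi, a, emissions = self._init_params(rng)
            pi, a, emissions, history = self._em(pi, a, emissions, tol=tol, max_iter=max_iter)
            restart_logliks.append(history[-1])
            if best is None or history[-1] > best[3][-1]:
                best = (pi, a, emissions, history)
        pi, a, emissions, history = best
        converged = len(history) < max_iter or (
            len(history) > 1 and history[-1] - history[-2] < tol
        )
        return HMMResults(
            model=self,
            pi=pi,
            transitions=a,
            emissions=emissions,
            train_log=np.asarray(history),
            restart_logliks=np.asarray(restart_logliks),
            converged=bool(converged),
        )


@dataclass
class HMMResults:
    """Fitted chromatin-state model: estimates, diagnostics, decoding."""

    model: Optional[BernoulliHMM]
    pi: np.ndarray
    transitions: np.ndarray
    emissions: np.ndarray
    train_log: np.ndarray = field(default_factory=lambda: np.empty(0))
    restart_logliks: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True
    mark_names: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.emissions = np.asarray(self.emissions, dtype=float)
        if not self.mark_names and self.model is not None:
            self.mark_names = list(self.model.mark_names)
        k = self.pi.size
        if self.transitions.shape != (k, k) or self.emissions.shape[0] != k:
            raise ValueError("inconsistent parameter shapes")
        if not np.allclose(self.pi.sum(), 1.0, atol=1e-9):
            raise ValueError("pi must sum to 1")
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if self.emissions.min() < 0 or self.emissions.max() > 1:
            raise ValueError("emissions must lie in [0, 1]")

    @property
    def n_states(self) -> int:
        return int(self.pi.size)

    @property
    def loglik(self) -> float:
        return float(self.train_log[-1]) if self.train_log.size else float("nan")

    # -- decoding -----------------------------------------------------------

    def posterior(self, x: np.ndarray) -> np.ndarray:
        """(T, K) forward-backward state posteriors for one sequence."""
        b, _ = _scaled_b(np.asarray(x), self.emissions)
        gamma, _, _ = _forward_backward(b, self.pi, self.transitions)
        return gamma

    def viterbi(self, x: np.ndarray) -> np.ndarray:
        """Most-likely single path (optional alternative to posterior decoding)."""
        logb = _emission_loglik(np.asarray(x), self.emissions)
        with np.errstate(divide="ignore"):
            la = np.log(np.clip(self.transitions, 1e-300, None))
            lpi = np.log(np.clip(self.pi, 1e-300, None))
        t_len, k = logb.shape
        delta = lpi + logb[0]
        back = np.zeros((t_len, k), dtype=np.int64)
        for t in range(1, t_len):
            cand = delta[:, None] + la
            back[t] = np.argmax(cand, axis=0)
            delta = cand[back[t], np.arange(k)] + logb[t]
        path = np.empty(t_len, dtype=np.int64)
        path[-1] = int(np.argmax(delta))
        for t in range(t_len - 2, -1, -1):
            path[t] = back[t + 1][path[t + 1]]
        return path

    def segment(self, matrix: BinaryMatrix, method: str = "posterior") -> Segmentation:
        """Per-window state assignment for one tissue.

        ``posterior`` (default) takes the argmax of the forward-backward
        marginals per window (ties break to the lowest state index);
        ``viterbi`` is available as an option.
        """
        if matrix.mark_names != self.mark_names:
            raise ValueError("matrix mark set differs from the model's")
        states: Dict[str, np.ndarray] = {}
        post: Dict[str, np.ndarray] = {}
        for chrom, x in matrix.data.items():
            if x.shape[0] == 0:
                states[chrom] = np.empty(0, dtype=np.int64)
                post[chrom] = np.empty(0)
                continue
            if method == "viterbi":
                states[chrom] = self.viterbi(x)
                post[chrom] = np.ones(x.shape[0])
            else:
                gamma = self.posterior(x)
                states[chrom] = np.argmax(gamma, axis=1).astype(np.int64)
                post[chrom] = gamma.max(axis=1)
        return Segmentation(
            tissue=matrix.tissue,
            n_states=self.n_states,
            window_bp=matrix.window_bp,
            states=states,
            posterior=post,
        )

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        lines = [
            f"BernoulliHMM results: K={self.n_states} states, "
            f"M={len(self.mark_names)} marks",
            f"log-likelihood: {self.loglik:.4f}  "
            f"(EM iterations: {self.train_log.size}, converged: {self.converged})",
            "",
            "Emission probabilities P(mark present | state):",
        ]
        df = self.emission_frame().round(3)
        lines.append(df.to_string())
        lines.append("")
        lines.append("Expected state dwell length (windows): "
                     + ", ".join(
                         f"E{k + 1}={1.0 / max(1e-12, 1.0 - self.transitions[k, k]):.1f}"
                         for k in range(self.n_states)
                     ))
        return "\n".join(lines)

    def emission_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.emissions,
            index=[f"E{k + 1}" for k in range(self.n_states)],
            columns=self.mark_names,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_states": self.n_states,
                "mark_names": self.mark_names,
                "pi": self.pi.tolist(),
                "transitions": self.transitions.tolist(),
                "emissions": self.emissions.tolist(),
                "train_log": self.train_log.tolist(),
                "converged": self.converged,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "HMMResults":
        d = json.loads(text)
        return cls(
            model=None,
            pi=np.array(d["pi"]),
            transitions=np.array(d["transitions"]),
            emissions=np.array(d["emissions"]),
            train_log=np.array(d.get("train_log", [])),
            converged=bool(d.get("converged", True)),
            mark_names=list(d["mark_names"]),
        )


def learn_hmm(
    matrices: Sequence[BinaryMatrix],
    n_states: int,
    seed: int = 0,
    n_restarts: int = 5,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> HMMResults:
    """Functional wrapper: build and fit a :class:`BernoulliHMM`."""
    return BernoulliHMM(matrices, n_states).fit(
        seed=seed, n_restarts=n_restarts, tol=tol, max_iter=max_iter
    )


def segment(results: HMMResults, matrix: BinaryMatrix, method: str = "posterior") -> Segmentation:
    return results.segment(matrix, method=method)


def state_coverage(seg: Segmentation) -> np.ndarray:
    """Fraction of windows assigned to each state (sums to 1)."""
    counts = np.zeros(seg.n_states)
    for s in seg.states.values():
        counts += np.bincount(s, minlength=seg.n_states)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty segmentation")
    return counts / total


def fold_enrichment(
    seg: Segmentation,
    features: Mapping[str, Mapping[str, Sequence[Tuple[int, int]]]],
    genome: GenomeAnnotation,
) -> pd.DataFrame:
    """States x features fold enrichments on the window grid.

    ``features`` maps feature name -> {chrom: [(start, end), ...]}.
    ``fold(k, f) = [overlap(k, f) / windows(k)] / [windows(f) / windows(genome)]``
    with all quantities counted in whole windows (a window belongs to a
    feature if it overlaps it by >= 1 bp).  Empty states or features give
    NaN with a warning.  Features outside chromosome bounds are an error.
    """
    lengths = genome.chromosomes["length"]
    state_masks = {chrom: s for chrom, s in seg.states.items()}
    total_windows = sum(s.size for s in state_masks.values())
    state_counts = state_coverage(seg) * total_windows

    out = pd.DataFrame(
        index=[f"E{k + 1}" for k in range(seg.n_states)], columns=list(features), dtype=float
    )
    for fname, per_chrom in features.items():
        fmask: Dict[str, np.ndarray] = {}
        f_windows = 0
        for chrom, s in state_masks.items():
            ivs = list(per_chrom.get(chrom, []))
            for a, b in ivs:
                if a < 0 or b > int(lengths[chrom]):
                    raise ValueError(f"feature {fname} [{a},{b}) outside {chrom} bounds")
            mask = iv.window_mask(ivs, s.size, seg.window_bp)
            fmask[chrom] = mask
            f_windows += int(mask.sum())
        if f_windows == 0:
            log.warning("feature %s covers no windows; enrichment undefined", fname)
            out[fname] = np.nan
            continue
        genome_frac = f_windows / total_windows
        for k in range(seg.n_states):
            nk = state_counts[k]
            if nk == 0:
                out.loc[f"E{k + 1}", fname] = np.nan
                continue
            overlap = sum(
                int(np.sum((state_masks[c] == k) & fmask[c])) for c in state_masks
            )
            out.loc[f"E{k + 1}", fname] = (overlap / nk) / genome_frac
    return out


def emission_summary(
    results: HMMResults,
    enrichment: Optional[pd.DataFrame] = None,
    emission_threshold: float = 0.5,
    enrich_threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-state main marks (emission >= 0.5) and assigned features (fold >= 2)."""
    rows = []
    for k in range(results.n_states):
        marks = [
            m
            for m, e in zip(results.mark_names, results.emissions[k])
            if e >= emission_threshold
        ]
        feats: List[str] = []
        if enrichment is not None:
            row = enrichment.loc[f"E{k + 1}"]
            feats = [str(f) for f, v in row.items() if np.isfinite(v) and v >= enrich_threshold]
        rows.append(
            {
                "state": f"E{k + 1}",
                "main_marks": ",".join(marks),
                "assigned_features": ",".join(feats),
            }
        )
    return pd.DataFrame(rows).set_index("state")


def match_states(
    a: HMMResults | np.ndarray, b: HMMResults | np.ndarray
) -> Tuple[np.ndarray, float]:
    """Optimal state correspondence between two models by emission distance.

    Minimum-total-L1 bijection (Hungarian assignment) between emission
    rows.  Returns ``(perm, mean_l1)`` where ``perm[i]`` is the state of
    ``b`` matched to state ``i`` of ``a`` and ``mean_l1`` is the mean L1
    row distance over matched pairs.  Models of different K get a best
    partial matching with a warning.
    """
    ea = a.emissions if isinstance(a, HMMResults) else np.asarray(a, dtype=float)
    eb = b.emissions if isinstance(b, HMMResults) else np.asarray(b, dtype=float)
    if ea.shape[0] != eb.shape[0]:
        warnings.warn("models differ in K; computing a partial matching")
    cost = cdist(ea, eb, metric="cityblock")
    ri, ci = linear_sum_assignment(cost)
    perm = np.full(ea.shape[0], -1, dtype=np.int64)
    perm[ri] = ci
    return perm, float(cost[ri, ci].mean())
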